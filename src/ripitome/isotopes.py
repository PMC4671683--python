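"""Peptide elemental compositions and theoretical isotope envelopes.

Relative quantification of a metabolically labeled sample rests on comparing
the isotope envelope of an unlabeled (light, all-:sup:`14`\\ N) peptide with
the envelope of its :sup:`15`\\ N-labeled (heavy) partner.  Both envelopes are
derived here from the peptide's elemental composition by convolving the
per-element isotopologue abundance vectors; the convolution is carried out in
the Fourier domain, which makes the cost essentially independent of the number
of atoms.

The isotope abundance table is shipped as a fixed constant so that envelopes
are bit-reproducible across environments.  Abundance vectors are indexed by
*neutron offset* — the number of extra neutrons relative to the lightest
isotope retained for that element — and the aggregated envelope uses a single
effective mass spacing between successive isotopologue peaks
(:data:`NEUTRON_MASS_SHIFT`), the standard approximation for peptide-scale
molecules where the fine structure of each isotopologue peak is not resolved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft

__all__ = [
    "ElementalComposition",
    "IsotopeDistribution",
    "peptide_composition",
    "isotope_distribution",
    "PROTON_MASS",
    "NEUTRON_MASS_SHIFT",
    "N14_MASS",
    "N15_MASS",
]

PROTON_MASS = 1.007276466622
#: effective mass spacing (Da) between successive aggregated isotopologue
#: peaks; intermediate between the 13C-12C (1.00336) and 15N-14N (0.99703)
#: single-substitution shifts.
NEUTRON_MASS_SHIFT = 1.00286864

# element -> tuple of (neutron offset, isotope mass / Da, natural abundance)
ISOTOPE_TABLE: dict[str, tuple[tuple[int, float, float], ...]] = {
    "C": ((0, 12.0, 0.9893), (1, 13.00335483507, 0.0107)),
    "H": ((0, 1.00782503207, 0.999885), (1, 2.01410177812, 0.000115)),
    "N": ((0, 14.0030740048, 0.99636), (1, 15.0001088989, 0.00364)),
    "O": (
        (0, 15.9949146196, 0.99757),
        (1, 16.9991317565, 0.00038),
        (2, 17.9991596129, 0.00205),
    ),
    "S": (
        (0, 31.9720711744, 0.9499),
        (1, 32.9714589098, 0.0075),
        (2, 33.967867004, 0.0425),
        (4, 35.96708071, 0.0001),
    ),
}

N14_MASS = ISOTOPE_TABLE["N"][0][1]
N15_MASS = ISOTOPE_TABLE["N"][1][1]
_WATER = {"H": 2, "O": 1}

# Monomer (residue) formulas for the 20 standard amino acids, as found in a
# peptide chain (i.e. free amino acid minus one water).
RESIDUE_FORMULAS: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}


@dataclass(frozen=True)
class ElementalComposition:
    """Atom counts of a molecule over the CHNOS elements."""

    c: int = 0
    h: int = 0
    n: int = 0
    o: int = 0
    s: int = 0

    def __post_init__(self) -> None:
        for name, count in self.as_dict().items():
            if not isinstance(count, (int, np.integer)) or count < 0:
                raise ValueError(
                    f"element count {name}={count!r} must be a nonnegative integer"
                )
        if self.total_atoms == 0:
            raise ValueError("composition must contain at least one atom")

    def as_dict(self) -> dict[str, int]:
        return {"C": self.c, "H": self.h, "N": self.n, "O": self.o, "S": self.s}

    @property
    def total_atoms(self) -> int:
        return self.c + self.h + self.n + self.o + self.s

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            self.c + other.c,
            self.h + other.h,
            self.n + other.n,
            self.o + other.o,
            self.s + other.s,
        )

    def formula(self) -> str:
        return "".join(
            f"{el}{cnt}" for el, cnt in self.as_dict().items() if cnt > 0
        )


def peptide_composition(sequence: str) -> ElementalComposition:
    """Elemental composition of an unmodified linear peptide.

    The composition is the sum of the residue formulas plus one water for the
    free termini.  Raises ``ValueError`` on an empty sequence or a character
    outside the 20 standard one-letter codes.
    """
    if not sequence:
        raise ValueError("peptide sequence must be nonempty")
    totals = {"C": 0, "H": _WATER["H"], "N": 0, "O": _WATER["O"], "S": 0}
    for ch in sequence:
        try:
            residue = RESIDUE_FORMULAS[ch]
        except KeyError:
            raise ValueError(f"unknown residue {ch!r} in peptide {sequence!r}") from None
        for el, cnt in residue.items():
            totals[el] += cnt
    return ElementalComposition(
        c=totals["C"], h=totals["H"], n=totals["N"], o=totals["O"], s=totals["S"]
    )


@dataclass(frozen=True)
class IsotopeDistribution:
    """Aggregated isotopologue envelope of one molecular species.

    ``abundances[k]`` is the relative abundance of the isotopologue carrying
    ``k`` extra neutrons over the monoisotopic (offset-0) species; the vector
    is normalized to unit sum.  ``n15_enrichment`` is ``None`` for natural
    nitrogen and the fractional :sup:`15`\\ N enrichment otherwise.
    """

    abundances: np.ndarray
    monoisotopic_mass: float
    mean_mass: float
    n15_enrichment: float | None = None

    def __post_init__(self) -> None:
        ab = np.asarray(self.abundances, dtype=float)
        object.__setattr__(self, "abundances", ab)
        if ab.ndim != 1 or ab.size == 0:
            raise ValueError("abundance vector must be a nonempty 1-d array")
        if (ab < -1e-12).any():
            raise ValueError("abundances must be nonnegative")

    def __len__(self) -> int:
        return int(self.abundances.size)

    def peak_masses(self) -> np.ndarray:
        """Neutral masses (Da) of the aggregated isotopologue peaks."""
        return self.monoisotopic_mass + NEUTRON_MASS_SHIFT * np.arange(len(self))


def _element_vector(
    element: str, n15_enrichment: float | None
) -> tuple[np.ndarray, float, float]:
    """Abundance-by-offset vector, base (offset-0) mass, and mean mass."""
    isotopes = ISOTOPE_TABLE[element]
    if element == "N" and n15_enrichment is not None:
        e = float(n15_enrichment)
        if e == 0.0:
            return np.array([1.0]), N14_MASS, N14_MASS
        if e == 1.0:
            return np.array([1.0]), N15_MASS, N15_MASS
        mean = (1.0 - e) * N14_MASS + e * N15_MASS
        return np.array([1.0 - e, e]), N14_MASS, mean
    max_offset = isotopes[-1][0]
    vec = np.zeros(max_offset + 1)
    mean = 0.0
    for offset, mass, abundance in isotopes:
        vec[offset] = abundance
        mean += abundance * mass
    return vec, isotopes[0][1], mean


def isotope_distribution(
    comp: ElementalComposition,
    n15_enrichment: float | None = None,
    tail_mass: float = 1e-12,
) -> IsotopeDistribution:
    """Theoretical isotope envelope of a composition by Fourier convolution.

    The envelope is the convolution of per-atom isotope abundance vectors;
    for ``n`` atoms of one element the n-fold self-convolution is computed as
    the n-th power of the element's transform, so the whole envelope is
    ``irfft(prod_e rfft(v_e)**count_e)``.  When ``n15_enrichment`` is given,
    the nitrogen abundance vector is replaced by ``(1-e, e)`` over
    (:sup:`14`\\ N, :sup:`15`\\ N); ``None`` keeps natural nitrogen.

    The returned vector is truncated once the remaining tail carries less
    than ``tail_mass`` probability and renormalized to unit sum.
    """
    if n15_enrichment is not None and not 0.0 <= n15_enrichment <= 1.0:
        raise ValueError(f"n15_enrichment must be in [0, 1], got {n15_enrichment}")
    vectors: list[tuple[np.ndarray, int]] = []
    mono = 0.0
    mean = 0.0
    max_len = 1
    for element, count in comp.as_dict().items():
        if count == 0:
            continue
        vec, base, elem_mean = _element_vector(element, n15_enrichment)
        mono += count * base
        mean += count * elem_mean
        max_len += count * (vec.size - 1)
        vectors.append((vec, count))

    nfft = next_fast_len(max_len)
    spectrum = np.ones(nfft // 2 + 1, dtype=complex)
    for vec, count in vectors:
        spectrum *= rfft(vec, nfft) ** count
    envelope = irfft(spectrum, nfft)[:max_len]
    envelope = np.clip(envelope, 0.0, None)

    # keep the shortest prefix whose complement carries < tail_mass
    tail = np.cumsum(envelope[::-1])[::-1]
    keep = int(np.argmax(tail < tail_mass)) if (tail < tail_mass).any() else max_len
    keep = max(keep, 1)
    envelope = envelope[:keep]
    envelope = envelope / envelope.sum()

    return IsotopeDistribution(
        abundances=envelope,
        monoisotopic_mass=mono,
        mean_mass=mean,
        n15_enrichment=n15_enrichment,
    )
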