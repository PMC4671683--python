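"""Assembly of the RNase-stratified protein interactome.

Mass-spectrometry protein hits from immunoprecipitations of resting and
activated cells, run with and without RNase A, are filtered (identification
FDR, species, contaminant list), collapsed to per-condition detection calls
across replicates, and partitioned into:

* the *whole* interactome — proteins detected in either condition without
  RNase treatment;
* *core* members (CIMs) — detected after RNase treatment, i.e. held by
  protein-protein contact rather than through the RNA scaffold;
* *peripheral* members (PIMs) — whole minus core, i.e. RNase-sensitive.

Venn partitions by condition are computed for both the whole and the core
layer.  Post-translational modification records are tallied per protein.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ProteinHit",
    "InteractomeSets",
    "DEFAULT_CONTAMINANTS",
    "PTM_TYPES",
    "filter_protein_hits",
    "detection_call",
    "assemble_interactome",
    "tally_ptms",
]

CONDITIONS = ("resting", "activated")
PTM_TYPES = ("PhosphoT", "PhosphoS", "Acetyl", "Methyl")

#: small default contaminant list: keratins, digestion enzyme, antibody
#: chains and abundant carry-over proteins commonly subtracted in IP-MS.
DEFAULT_CONTAMINANTS = frozenset(
    {
        "KRT1", "KRT2", "KRT5", "KRT9", "KRT10", "KRT14",
        "TRYP_PIG", "TRY1", "IGHG1", "IGHG2", "IGKC", "IGLC1",
        "ALB", "CASB_BOVIN",
    }
)


@dataclass(frozen=True)
class ProteinHit:
    accession: str
    species: str  # "human" or anything else
    fdr: float  # identification false-discovery estimate in [0, 1]
    condition: str  # "resting" | "activated"
    rnase_treated: bool
    replicate: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"FDR must be in [0, 1], got {self.fdr}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")


@dataclass(frozen=True)
class InteractomeSets:
    """Whole/core/peripheral partition with per-condition Venn regions."""

    whole: frozenset[str]
    core: frozenset[str]
    peripheral: frozenset[str]
    whole_venn: dict[str, frozenset[str]] = field(default_factory=dict)
    core_venn: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.core <= self.whole:
            raise ValueError("core must be a subset of the whole interactome")
        if self.core & self.peripheral:
            raise ValueError("core and peripheral must be disjoint")
        if len(self.core) + len(self.peripheral) != len(self.whole):
            raise ValueError("core + peripheral must partition the whole set")


def filter_protein_hits(
    hits: Sequence[ProteinHit],
    fdr_max: float = 0.01,
    contaminants: Iterable[str] = DEFAULT_CONTAMINANTS,
) -> list[ProteinHit]:
    """Keep hits with FDR strictly below threshold, human, not contaminant."""
    contaminant_set = set(contaminants)
    return [
        h
        for h in hits
        if h.fdr < fdr_max and h.species == "human" and h.accession not in contaminant_set
    ]


def detection_call(
    hits: Sequence[ProteinHit],
    n_replicates: Mapping[tuple[str, bool], int],
    min_replicates: int | None = None,
) -> dict[tuple[str, bool], frozenset[str]]:
    """Collapse replicate hits into per-(condition, RNase-state) detections.

    An accession is detected in a state iff it appears in at least
    ``min_replicates`` distinct replicates; the default is the strict
    majority ``ceil(n/2)`` of that state's replicate count.
    """
    reps: dict[tuple[str, bool], dict[str, set[int]]] = {}
    for h in hits:
        key = (h.condition, h.rnase_treated)
        reps.setdefault(key, {}).setdefault(h.accession, set()).add(h.replicate)

    detected: dict[tuple[str, bool], frozenset[str]] = {}
    for key, n in n_replicates.items():
        need = min_replicates if min_replicates is not None else math.ceil(n / 2)
        if need > n:
            raise ValueError(f"min_replicates {need} exceeds n_replicates {n}")
        members = reps.get(key, {})
        detected[key] = frozenset(
            acc for acc, seen in members.items() if len(seen) >= need
        )
    return detected


def assemble_interactome(
    detected: Mapping[tuple[str, bool], frozenset[str]],
) -> InteractomeSets:
    """Partition detection calls into whole/core/peripheral layers.

    ``detected`` maps (condition, rnase_treated) to accession sets for all
    four states.  The whole interactome is the union of the untreated
    detections; core is the union of the RNase-treated detections.  A core
    detection missing from the whole layer (possible under replicate
    dropout) is added to the whole set with a warning, since surviving
    RNase treatment implies association.
    """
    try:
        rest_whole = detected[("resting", False)]
        act_whole = detected[("activated", False)]
        rest_core = detected[("resting", True)]
        act_core = detected[("activated", True)]
    except KeyError as exc:
        raise ValueError(f"missing detection set for state {exc.args[0]}") from None

    whole = set(rest_whole | act_whole)
    core = set(rest_core | act_core)
    orphans = core - whole
    if orphans:
        warnings.warn(
            f"{len(orphans)} RNase-resistant accession(s) absent from the "
            "untreated runs; added to the whole interactome",
            stacklevel=2,
        )
        whole |= orphans
        rest_whole = frozenset(rest_whole | (orphans & rest_core))
        act_whole = frozenset(act_whole | (orphans & act_core))

    peripheral = whole - core
    whole_venn = {
        "resting_only": frozenset(rest_whole - act_whole),
        "activated_only": frozenset(act_whole - rest_whole),
        "shared": frozenset(rest_whole & act_whole),
    }
    core_venn = {
        "resting_only": frozenset(rest_core - act_core),
        "activated_only": frozenset(act_core - rest_core),
        "shared": frozenset(rest_core & act_core),
    }
    return InteractomeSets(
        whole=frozenset(whole),
        core=frozenset(core),
        peripheral=frozenset(peripheral),
        whole_venn=whole_venn,
        core_venn=core_venn,
    )


def tally_ptms(
    records: Sequence[tuple[str, int, str, str]] | pd.DataFrame,
    high_threshold: int = 3,
) -> tuple[pd.DataFrame, list[str]]:
    """Count post-translational modifications per protein and type.

    ``records`` rows are (accession, residue position, type, condition) with
    type among PhosphoT/PhosphoS/Acetyl/Methyl.  Returns a frame indexed by
    accession with one column per type plus ``total``, and the list of
    proteins carrying ``high_threshold`` or more modifications.
    """
    if isinstance(records, pd.DataFrame):
        rows = list(records[["accession", "position", "ptm_type", "condition"]]
                    .itertuples(index=False, name=None))
    else:
        rows = list(records)
    for acc, _pos, ptm_type, _cond in rows:
        if ptm_type not in PTM_TYPES:
            raise ValueError(f"unknown PTM type {ptm_type!r} on {acc}")

    counts = pd.DataFrame(0, index=sorted({r[0] for r in rows}),
                          columns=list(PTM_TYPES), dtype=int)
    for acc, _pos, ptm_type, _cond in rows:
        counts.loc[acc, ptm_type] += 1
    counts["total"] = counts.sum(axis=1)
    flagged = list(counts.index[counts["total"] >= high_threshold])
    return counts, flagged
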