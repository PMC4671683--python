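"""SILAC 14N/15N peptide quantification by least-squares envelope fitting.

One labeled/unlabeled peptide pair contributes a *mini-spectrum*: a short m/z
window containing both the light and the heavy isotope envelope.  The window
is modeled as a nonnegative linear combination of the two theoretical
envelopes projected onto the m/z grid,

    y(m/z) = A_light * P(d_light) + A_heavy * P(d_heavy) + noise,

and the amplitudes are obtained by nonnegative least squares.  The amplitude
ratio ``A_light / A_heavy`` is the peptide-level relative abundance; peptide
ratios within a protein are then log-transformed and tested against a null
ratio of 1 with a one-sample two-sided t-test, Benjamini-Hochberg corrected
across proteins.

Because the original envelope fits were screened by eye, the screening is
automated here with two explicit thresholds: a minimum signal-to-noise ratio
and a maximum residual fraction, plus a spectral-overlap flag raised when the
projected light and heavy envelopes share most of their grid support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import nnls
from scipy.stats import t as t_dist

from .enrichment import bh_adjust
from .isotopes import NEUTRON_MASS_SHIFT, PROTON_MASS, IsotopeDistribution

__all__ = [
    "PeakFeature",
    "PeakPair",
    "SpectrumWindow",
    "FtcFit",
    "ProteinQuantResult",
    "match_peak_pairs",
    "project_envelope",
    "fit_ls_ftc",
    "filter_fits",
    "protein_ratio_stats",
]

DEFAULT_RT_TOLERANCE = 30.0  # seconds; co-elution window for pairing
DEFAULT_FWHM = 0.02  # m/z; Gaussian line width of projected peaks


@dataclass(frozen=True)
class PeakFeature:
    """One detected isotope-envelope feature from the peak list."""

    feature_id: str
    peptides: tuple[str, ...]  # candidate identities; >1 means ambiguous
    charge: int
    rt: float  # seconds
    mz: float
    label: str  # "light" | "heavy"

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.mz <= 0:
            raise ValueError("m/z must be positive")
        if self.label not in ("light", "heavy"):
            raise ValueError(f"label must be light/heavy, got {self.label!r}")


@dataclass(frozen=True)
class PeakPair:
    pair_id: str
    light: PeakFeature
    heavy: PeakFeature
    peptide: str
    charge: int


@dataclass(frozen=True)
class SpectrumWindow:
    """Mini-spectrum extracted around one light/heavy envelope pair."""

    pair_id: str
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.ndim != 1 or mz.size < 2 or inten.shape != mz.shape:
            raise ValueError("window needs matching 1-d mz/intensity arrays")
        if not (np.diff(mz) > 0).all():
            raise ValueError("m/z grid must be strictly increasing")
        if not np.isfinite(inten).all():
            raise ValueError("intensities must be finite")


@dataclass
class FtcFit:
    """Result of fitting one mini-spectrum with two theoretical envelopes."""

    pair_id: str
    a_light: float
    a_heavy: float
    ratio: float  # A_light / A_heavy; may be inf/nan for one-sided fits
    rss: float
    residual_fraction: float
    snr: float
    overlap: bool
    accepted: bool = False
    reason: str | None = None

    @property
    def finite_ratio(self) -> bool:
        return math.isfinite(self.ratio) and self.ratio > 0


@dataclass(frozen=True)
class ProteinQuantResult:
    protein: str
    n_peptides: int
    mean_log_ratio: float
    sd_log_ratio: float
    t_stat: float
    p_value: float
    adj_p: float
    significant: bool
    direction: str  # "up" | "down" | "none"
    status: str  # "tested" | "untestable" | "untestable-degenerate"


def match_peak_pairs(
    features: Sequence[PeakFeature],
    rt_tolerance: float = DEFAULT_RT_TOLERANCE,
) -> tuple[list[PeakPair], list[tuple[str, str]]]:
    """Pair light and heavy features of the same peptide and charge state.

    A valid pair requires exactly one light and one heavy candidate for a
    (peptide, charge) combination, eluting within ``rt_tolerance`` seconds of
    each other.  Features carrying multiple candidate identities are
    discarded before pairing.  Returns ``(pairs, rejects)`` where rejects are
    ``(feature_id, reason)`` with reasons among ``ambiguous_identity``,
    ``charge_mismatch``, ``rt_mismatch``, ``duplicate_feature`` and
    ``unpaired``.
    """
    rejects: list[tuple[str, str]] = []
    usable: list[PeakFeature] = []
    for f in features:
        if len(f.peptides) != 1:
            rejects.append((f.feature_id, "ambiguous_identity"))
        else:
            usable.append(f)

    by_key: dict[tuple[str, int, str], list[PeakFeature]] = {}
    charges_by_peptide: dict[tuple[str, str], set[int]] = {}
    for f in usable:
        by_key.setdefault((f.peptides[0], f.charge, f.label), []).append(f)
        charges_by_peptide.setdefault((f.peptides[0], f.label), set()).add(f.charge)

    pairs: list[PeakPair] = []
    seen: set[tuple[str, int]] = set()
    for f in usable:
        peptide, charge = f.peptides[0], f.charge
        if (peptide, charge) in seen:
            continue
        seen.add((peptide, charge))
        lights = by_key.get((peptide, charge, "light"), [])
        heavies = by_key.get((peptide, charge, "heavy"), [])
        if len(lights) > 1 or len(heavies) > 1:
            for g in lights + heavies:
                rejects.append((g.feature_id, "duplicate_feature"))
            continue
        if not lights or not heavies:
            # a partner exists at another charge state -> charge mismatch
            present = lights + heavies
            missing_label = "heavy" if lights else "light"
            partner_charges = charges_by_peptide.get((peptide, missing_label), set())
            reason = "charge_mismatch" if partner_charges else "unpaired"
            for g in present:
                rejects.append((g.feature_id, reason))
            continue
        light, heavy = lights[0], heavies[0]
        if abs(light.rt - heavy.rt) > rt_tolerance:
            rejects.append((light.feature_id, "rt_mismatch"))
            rejects.append((heavy.feature_id, "rt_mismatch"))
            continue
        pairs.append(
            PeakPair(
                pair_id=f"{peptide}/{charge}",
                light=light,
                heavy=heavy,
                peptide=peptide,
                charge=charge,
            )
        )
    return pairs, rejects


def project_envelope(
    dist: IsotopeDistribution,
    charge: int,
    grid: np.ndarray,
    fwhm: float = DEFAULT_FWHM,
    centroid: bool = False,
) -> np.ndarray:
    """Project a neutral-mass envelope onto an m/z grid at a charge state.

    Peak k sits at ``(mono + k*delta_neutron + z*m_proton)/z``.  In profile
    mode each peak is a unit-height Gaussian of the given FWHM scaled by its
    abundance; in centroid mode abundances are snapped to the nearest grid
    point (useful for exact algebraic tests).
    """
    grid = np.asarray(grid, dtype=float)
    positions = (dist.peak_masses() + charge * PROTON_MASS) / charge
    out = np.zeros_like(grid)
    if centroid:
        idx = np.searchsorted(grid, positions)
        for pos, ab, i in zip(positions, dist.abundances, idx):
            j = int(np.clip(i, 0, grid.size - 1))
            if j > 0 and abs(grid[j - 1] - pos) < abs(grid[j] - pos):
                j -= 1
            out[j] += ab
        return out
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    for pos, ab in zip(positions, dist.abundances):
        out += ab * np.exp(-0.5 * ((grid - pos) / sigma) ** 2)
    return out


def _grid_covers(grid: np.ndarray, dist: IsotopeDistribution, charge: int) -> bool:
    """True if all non-negligible peaks of the envelope fall inside the grid."""
    main = dist.abundances > 1e-3
    positions = (dist.peak_masses()[main] + charge * PROTON_MASS) / charge
    return bool((positions >= grid[0]).all() and (positions <= grid[-1]).all())


def fit_ls_ftc(
    window: SpectrumWindow,
    d_light: IsotopeDistribution,
    d_heavy: IsotopeDistribution,
    charge: int,
    fwhm: float = DEFAULT_FWHM,
    centroid: bool = False,
) -> FtcFit:
    """Fit one mini-spectrum as a nonnegative combination of two envelopes.

    Minimizes ``sum((y - A_light*P_light - A_heavy*P_heavy)**2)`` subject to
    ``A >= 0``.  Raises ``ValueError`` if the grid does not cover both
    envelopes or the two projected envelopes are numerically identical
    (singular design).  Records the residual sum of squares, the residual
    fraction ``sqrt(RSS / sum(y**2))``, a signal-to-noise estimate (max of
    the fitted model over the residual standard deviation) and a spectral
    overlap flag (projected envelopes sharing more than half of their grid
    support).
    """
    if not _grid_covers(window.mz, d_light, charge):
        raise ValueError("window grid does not cover the light envelope")
    if not _grid_covers(window.mz, d_heavy, charge):
        raise ValueError("window grid does not cover the heavy envelope")

    p_light = project_envelope(d_light, charge, window.mz, fwhm, centroid)
    p_heavy = project_envelope(d_heavy, charge, window.mz, fwhm, centroid)
    scale = max(np.abs(p_light).max(), np.abs(p_heavy).max())
    if scale == 0 or np.abs(p_light - p_heavy).max() < 1e-10 * scale:
        raise ValueError("singular design: projected envelopes are identical")

    design = np.column_stack([p_light, p_heavy])
    amps, _ = nnls(design, window.intensity)
    fitted = design @ amps
    residual = window.intensity - fitted
    rss = float(residual @ residual)
    total = float(window.intensity @ window.intensity)
    residual_fraction = math.sqrt(rss / total) if total > 0 else 0.0

    noise_sd = float(residual.std(ddof=1)) if residual.size > 1 else 0.0
    peak = float(fitted.max())
    snr = peak / noise_sd if noise_sd > 1e-12 * max(peak, 1.0) else math.inf

    support_l = p_light > 0.01 * p_light.max()
    support_h = p_heavy > 0.01 * p_heavy.max()
    smaller = min(support_l.sum(), support_h.sum())
    overlap = bool(smaller > 0 and (support_l & support_h).sum() > 0.5 * smaller)

    a_light, a_heavy = float(amps[0]), float(amps[1])
    if a_heavy > 0:
        ratio = a_light / a_heavy
    else:
        ratio = math.inf if a_light > 0 else math.nan
    return FtcFit(
        pair_id=window.pair_id,
        a_light=a_light,
        a_heavy=a_heavy,
        ratio=ratio,
        rss=rss,
        residual_fraction=residual_fraction,
        snr=snr,
        overlap=overlap,
    )


def filter_fits(
    fits: Iterable[FtcFit],
    snr_min: float = 10.0,
    residual_fraction_max: float = 0.2,
) -> list[FtcFit]:
    """Automated stand-in for visual screening of envelope fits.

    A fit is accepted iff SNR >= ``snr_min``, residual fraction <=
    ``residual_fraction_max`` and the spectral-overlap flag is unset; the
    first failing criterion is recorded as the rejection reason.
    """
    if snr_min <= 0 or residual_fraction_max <= 0:
        raise ValueError("thresholds must be positive")
    out = []
    for fit in fits:
        if fit.overlap:
            out.append(replace(fit, accepted=False, reason="spectral_overlap"))
        elif fit.snr < snr_min:
            out.append(replace(fit, accepted=False, reason="low_snr"))
        elif fit.residual_fraction > residual_fraction_max:
            out.append(replace(fit, accepted=False, reason="high_residual"))
        else:
            out.append(replace(fit, accepted=True, reason=None))
    return out


def protein_ratio_stats(
    peptide_ratios: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    log_base: float = 2.0,
) -> list[ProteinQuantResult]:
    """Per-protein one-sample t-test of peptide log-ratios against a ratio of 1.

    For each protein the finite, positive peptide ratios are log-transformed
    and the mean log-ratio is tested against 0 with a two-sided one-sample
    t-test; p-values are Benjamini-Hochberg adjusted across the tested
    proteins and a protein is significant iff adjusted p < ``alpha``.
    Proteins with fewer than two usable ratios are reported ``untestable``;
    proteins whose log-ratios have zero spread are ``untestable-degenerate``
    rather than being assigned p = 0.
    """
    results: list[ProteinQuantResult] = []
    tested_idx: list[int] = []
    pvals: list[float] = []
    log_conv = math.log(log_base)

    for protein in peptide_ratios:
        ratios = [r for r in peptide_ratios[protein] if math.isfinite(r) and r > 0]
        logs = np.log(ratios) / log_conv if ratios else np.array([])
        n = len(ratios)
        if n < 2:
            results.append(
                ProteinQuantResult(
                    protein, n, float(logs.mean()) if n else math.nan, math.nan,
                    math.nan, math.nan, math.nan, False, "none", "untestable",
                )
            )
            continue
        mean = float(logs.mean())
        sd = float(logs.std(ddof=1))
        if sd == 0.0:
            results.append(
                ProteinQuantResult(
                    protein, n, mean, 0.0, math.nan, math.nan, math.nan,
                    False, "none", "untestable-degenerate",
                )
            )
            continue
        t_stat = mean / (sd / math.sqrt(n))
        p = 2.0 * float(t_dist.sf(abs(t_stat), df=n - 1))
        results.append(
            ProteinQuantResult(
                protein, n, mean, sd, t_stat, p, math.nan, False,
                "up" if mean > 0 else "down", "tested",
            )
        )
        tested_idx.append(len(results) - 1)
        pvals.append(p)

    if pvals:
        adj = bh_adjust(pvals)
        for idx, q in zip(tested_idx, adj):
            r = results[idx]
            significant = q < alpha
            results[idx] = ProteinQuantResult(
                r.protein, r.n_peptides, r.mean_log_ratio, r.sd_log_ratio,
                r.t_stat, r.p_value, q, significant,
                r.direction if significant else r.direction, r.status,
            )
    return results
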