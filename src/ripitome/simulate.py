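"""Synthetic inputs with planted truth for every pipeline stage.

Four seeded generators emulate the study designs this pipeline targets:

* negative-binomial gene counts for two groups (six samples per group, as in
  an activation RIP-seq/RNA-seq comparison) with a planted fraction of
  differentially expressed genes;
* light/heavy peptide isotope-envelope pairs at planted abundance ratios
  (three replicates' worth of proteins, ~5 tryptic-size peptides each) with
  Gaussian intensity noise;
* replicate protein-identification tables for resting/activated x RNase-/+
  immunoprecipitations with planted core/peripheral membership, shipped
  contaminants, non-human and high-FDR decoy hits, and per-replicate
  detection dropout;
* a gene-set collection (ImmuneMap-sized: 54 pathways by default) with
  planted enriched pathways overrepresented in the query list.

Every generator returns its planted truth keyed by entity identifier, so
downstream recovery and calibration are measurable without external data.
All randomness flows from ``SimulationConfig.seed``; identical configurations
give identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .interactome import DEFAULT_CONTAMINANTS, ProteinHit
from .isotopes import PROTON_MASS, NEUTRON_MASS_SHIFT, isotope_distribution, peptide_composition
from .silac import PeakFeature, SpectrumWindow, project_envelope

__all__ = [
    "SimulationConfig",
    "simulate_counts",
    "simulate_silac_spectra",
    "simulate_protein_table",
    "simulate_genesets",
    "write_hit_tables",
    "write_features",
    "write_windows",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the four synthetic-data generators.

    Defaults mirror the emulated study designs: n = 6/group sequencing
    replicates, n = 3/group SILAC (expressed as ~`n_proteins` quantifiable
    proteins), n = 6 untreated and n = 4 RNase-treated MS replicates, and a
    54-pathway immune gene-set collection.
    """

    seed: int = 0

    # count simulator
    n_genes: int = 2000
    n_samples_per_group: int = 6
    nb_dispersion: float = 0.1
    de_fraction: float = 0.2
    de_log2fc_magnitude: float = 2.0
    library_sizes: tuple[int, ...] | None = None  # default: 500 reads/gene

    # SILAC simulator
    n_proteins: int = 20
    peptides_per_protein: float = 5.0  # Poisson mean, min 1 per protein
    ratio_log2_mean: float = 1.0
    ratio_log2_sd: float = 0.2
    noise_sd: float = 5.0  # intensity units; ~SNR 50 at default amplitudes
    n15_enrichment: float = 1.0
    decoy_fraction: float = 0.0  # pairs violating the co-elution rule
    rt_tolerance: float = 30.0  # seconds

    # protein-table simulator
    core_fraction: float = 0.3
    contaminant_fraction: float = 0.1
    replicate_dropout: float = 0.1
    n_replicates_whole: int = 6
    n_replicates_rnase: int = 4
    condition_profile_probs: tuple[float, float, float] = (0.8, 0.15, 0.05)

    # gene-set simulator
    n_pathways: int = 54
    pathway_size_range: tuple[int, int] = (50, 200)
    planted_enriched: int = 5
    universe_size: int = 10000
    query_size: int = 1000
    enriched_query_fraction: float = 0.5

    def __post_init__(self) -> None:
        fractions = {
            "de_fraction": self.de_fraction,
            "n15_enrichment": self.n15_enrichment,
            "decoy_fraction": self.decoy_fraction,
            "core_fraction": self.core_fraction,
            "contaminant_fraction": self.contaminant_fraction,
            "replicate_dropout": self.replicate_dropout,
            "enriched_query_fraction": self.enriched_query_fraction,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        counts = {
            "n_genes": self.n_genes,
            "n_samples_per_group": self.n_samples_per_group,
            "n_proteins": self.n_proteins,
            "n_replicates_whole": self.n_replicates_whole,
            "n_replicates_rnase": self.n_replicates_rnase,
            "n_pathways": self.n_pathways,
            "universe_size": self.universe_size,
            "query_size": self.query_size,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be nonnegative")
        if self.de_log2fc_magnitude <= 0:
            raise ValueError("de_log2fc_magnitude must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.peptides_per_protein <= 0:
            raise ValueError("peptides_per_protein must be positive")
        if self.planted_enriched < 0 or self.planted_enriched > self.n_pathways:
            raise ValueError("planted_enriched must be in [0, n_pathways]")
        lo, hi = self.pathway_size_range
        if not 1 <= lo <= hi:
            raise ValueError("pathway_size_range must satisfy 1 <= lo <= hi")
        if hi > self.universe_size:
            raise ValueError("pathways cannot be larger than the universe")
        if abs(sum(self.condition_profile_probs) - 1.0) > 1e-9:
            raise ValueError("condition_profile_probs must sum to 1")
        if self.library_sizes is not None and len(self.library_sizes) != 2 * self.n_samples_per_group:
            raise ValueError("library_sizes must list one depth per sample")


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, cfg.seed])


def simulate_counts(
    cfg: SimulationConfig,
    noise_stream: int = 11,
) -> tuple[pd.DataFrame, pd.Series, dict[str, str], pd.DataFrame]:
    """Two-group NB count matrix with planted differential expression.

    Gene baseline abundances are log-normal; a ``de_fraction`` of genes is
    shifted by ``de_log2fc_magnitude`` on the log2 scale, applied
    symmetrically (``2**(±lfc/2)`` in the two groups) with up- and
    down-regulated genes paired at equal baselines.  That keeps the total
    expected abundance of the two groups identical, so total-count library
    normalization is exact and non-DE genes stay exactly null.  Per-sample
    means are rescaled so every column's expected sum equals the configured
    library size.  Counts are NB with variance ``mu + phi*mu**2``.

    Returns ``(counts, exon-model lengths, sample->group labels, truth)``
    where truth is indexed by gene with ``is_de`` and signed ``log2fc``
    (group B over group A).

    ``noise_stream`` selects the random stream used for the NB sampling
    alone; two calls differing only in the stream share the planted truth
    and gene structure but carry independent counting noise (e.g. a
    pull-down and a whole-transcriptome readout of the same biology).
    """
    rng = _rng(cfg, 1)  # structure: baselines, DE selection, lengths
    noise = _rng(cfg, noise_stream)
    n, m = cfg.n_genes, cfg.n_samples_per_group
    genes = [f"GENE{i:05d}" for i in range(n)]
    samples = [f"A_{j+1}" for j in range(m)] + [f"B_{j+1}" for j in range(m)]
    groups = {s: s.split("_")[0] for s in samples}
    if cfg.library_sizes is None:
        lib = np.full(2 * m, 500.0 * n)
    else:
        lib = np.asarray(cfg.library_sizes, dtype=float)

    base = rng.lognormal(mean=0.0, sigma=1.2, size=n)
    n_de = 2 * int(round(cfg.de_fraction * n / 2.0))
    de_idx = rng.choice(n, size=n_de, replace=False)
    up, down = de_idx[: n_de // 2], de_idx[n_de // 2 :]
    base[down] = base[up]  # paired baselines -> exact group mass balance
    log2fc = np.zeros(n)
    log2fc[up] = cfg.de_log2fc_magnitude
    log2fc[down] = -cfg.de_log2fc_magnitude

    mean_a = base * 2.0 ** (-log2fc / 2.0)
    mean_b = base * 2.0 ** (+log2fc / 2.0)
    counts = np.empty((n, 2 * m), dtype=np.int64)
    for j, sample in enumerate(samples):
        mu = mean_a if groups[sample] == "A" else mean_b
        mu = mu * (lib[j] / mu.sum())
        if cfg.nb_dispersion == 0:
            counts[:, j] = noise.poisson(mu)
        else:
            size = 1.0 / cfg.nb_dispersion
            p = size / (size + mu)
            counts[:, j] = noise.negative_binomial(size, p)

    lengths = pd.Series(rng.integers(200, 10001, size=n), index=genes, name="exon_bp")
    truth = pd.DataFrame({"is_de": log2fc != 0.0, "log2fc": log2fc}, index=genes)
    return (
        pd.DataFrame(counts, index=genes, columns=samples),
        lengths,
        groups,
        truth,
    )


def _random_peptides(rng: np.random.Generator, count: int) -> list[str]:
    """Unique random peptide sequences spanning tryptic sizes (8-20 aa)."""
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < count:
        length = int(rng.integers(8, 21))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
        if seq not in seen:
            seen.add(seq)
            out.append(seq)
    return out


def simulate_silac_spectra(
    cfg: SimulationConfig,
) -> tuple[list[PeakFeature], list[SpectrumWindow], pd.DataFrame]:
    """Light/heavy peptide feature pairs and their mini-spectra.

    Each protein carries a true abundance ratio ``2**N(ratio_log2_mean,
    ratio_log2_sd)`` shared by its peptides.  For every peptide a light
    (pure :sup:`14`\\ N) and heavy (:sup:`15`\\ N at ``n15_enrichment``)
    feature is emitted at the same charge state, with retention times
    jittered uniformly within half the co-elution tolerance (a configurable
    decoy fraction instead violates the tolerance to exercise rejection).
    Window intensities are ``A_light*P(light) + A_heavy*P(heavy) + Gaussian
    noise`` with ``A_light/A_heavy`` equal to the true ratio.

    Returns ``(features, windows, truth)`` with truth indexed by peptide
    (``protein``, ``true_ratio``, ``charge``, ``is_decoy``).
    """
    rng = _rng(cfg, 2)
    n_peptides = np.maximum(
        1, rng.poisson(cfg.peptides_per_protein, size=cfg.n_proteins)
    )
    peptides = _random_peptides(rng, int(n_peptides.sum()))
    protein_of: list[str] = []
    for i, k in enumerate(n_peptides):
        protein_of += [f"PROT{i:04d}"] * int(k)
    protein_ratio = {
        f"PROT{i:04d}": 2.0 ** rng.normal(cfg.ratio_log2_mean, cfg.ratio_log2_sd)
        for i in range(cfg.n_proteins)
    }

    features: list[PeakFeature] = []
    windows: list[SpectrumWindow] = []
    truth_rows = []
    for idx, (peptide, protein) in enumerate(zip(peptides, protein_of)):
        charge = int(rng.choice([2, 3]))
        ratio = protein_ratio[protein]
        comp = peptide_composition(peptide)
        d_light = isotope_distribution(comp, n15_enrichment=0.0)
        d_heavy = isotope_distribution(comp, n15_enrichment=cfg.n15_enrichment)

        rt = float(rng.uniform(300.0, 3000.0))
        is_decoy = bool(rng.random() < cfg.decoy_fraction)
        jitter = (
            cfg.rt_tolerance * 2.0
            if is_decoy
            else float(rng.uniform(-0.5, 0.5) * cfg.rt_tolerance)
        )
        mz_light = (d_light.monoisotopic_mass + charge * PROTON_MASS) / charge
        mz_heavy = (d_heavy.monoisotopic_mass + charge * PROTON_MASS) / charge
        features.append(
            PeakFeature(f"F{idx:05d}_L", (peptide,), charge, rt, mz_light, "light")
        )
        features.append(
            PeakFeature(f"F{idx:05d}_H", (peptide,), charge, rt + jitter, mz_heavy, "heavy")
        )

        lo = mz_light - 1.0 / charge
        hi = (
            d_heavy.monoisotopic_mass
            + (len(d_heavy) + 1) * NEUTRON_MASS_SHIFT
            + charge * PROTON_MASS
        ) / charge
        grid = np.arange(lo, hi, 0.005)
        a_heavy = float(rng.lognormal(math.log(1000.0), 0.3))
        a_light = ratio * a_heavy
        clean = a_light * project_envelope(d_light, charge, grid) + a_heavy * project_envelope(
            d_heavy, charge, grid
        )
        intensity = clean + rng.normal(0.0, cfg.noise_sd, size=grid.size)
        windows.append(SpectrumWindow(f"{peptide}/{charge}", grid, intensity))
        truth_rows.append((peptide, protein, ratio, charge, is_decoy))

    truth = pd.DataFrame(
        truth_rows, columns=["peptide", "protein", "true_ratio", "charge", "is_decoy"]
    ).set_index("peptide")
    return features, windows, truth


def simulate_protein_table(
    cfg: SimulationConfig,
) -> tuple[list[ProteinHit], pd.DataFrame]:
    """Replicate protein-hit tables for the four IP states with planted sets.

    Members split into core (detected with and without RNase) and peripheral
    (RNase-sensitive, untreated runs only); each member carries a condition
    profile (shared / activated-only / resting-only).  Contaminant
    accessions from the shipped list, non-human hits and above-threshold-FDR
    hits are mixed in to exercise filtering; per-replicate dropout removes
    true members at rate ``replicate_dropout``.

    Truth is indexed by accession with ``membership`` in
    {core, peripheral, contaminant, background} and the condition profile.
    """
    rng = _rng(cfg, 3)
    n = cfg.n_proteins
    members = [f"P{i:04d}" for i in range(n)]
    n_core = int(round(cfg.core_fraction * n))
    membership = {acc: ("core" if i < n_core else "peripheral") for i, acc in enumerate(members)}
    profiles = rng.choice(
        ["shared", "activated_only", "resting_only"],
        size=n,
        p=list(cfg.condition_profile_probs),
    )
    profile = dict(zip(members, profiles))

    contaminants = sorted(DEFAULT_CONTAMINANTS)[: int(round(cfg.contaminant_fraction * n))]
    n_background = max(2, n // 10)
    high_fdr = [f"X{i:04d}" for i in range(n_background)]
    nonhuman = [f"YEAST{i:03d}" for i in range(n_background)]

    def allowed(acc: str, condition: str, rnase: bool) -> bool:
        if rnase and membership[acc] != "core":
            return False
        prof = profile[acc]
        return prof == "shared" or prof == f"{condition}_only"

    hits: list[ProteinHit] = []
    states = [
        ("resting", False, cfg.n_replicates_whole),
        ("activated", False, cfg.n_replicates_whole),
        ("resting", True, cfg.n_replicates_rnase),
        ("activated", True, cfg.n_replicates_rnase),
    ]
    for condition, rnase, n_reps in states:
        for rep in range(1, n_reps + 1):
            for acc in members:
                if allowed(acc, condition, rnase) and rng.random() >= cfg.replicate_dropout:
                    hits.append(
                        ProteinHit(acc, "human", float(rng.uniform(0.0, 0.009)),
                                   condition, rnase, rep)
                    )
            for acc in contaminants:
                if rng.random() < 0.9:
                    hits.append(
                        ProteinHit(acc, "human", float(rng.uniform(0.0, 0.009)),
                                   condition, rnase, rep)
                    )
            for acc in high_fdr:
                if rng.random() < 0.7:
                    hits.append(
                        ProteinHit(acc, "human", float(rng.uniform(0.02, 0.5)),
                                   condition, rnase, rep)
                    )
            for acc in nonhuman:
                if rng.random() < 0.7:
                    hits.append(
                        ProteinHit(acc, "yeast", float(rng.uniform(0.0, 0.009)),
                                   condition, rnase, rep)
                    )

    truth_rows = [(acc, membership[acc], profile[acc]) for acc in members]
    truth_rows += [(acc, "contaminant", "shared") for acc in contaminants]
    truth_rows += [(acc, "background", "shared") for acc in high_fdr + nonhuman]
    truth = pd.DataFrame(
        truth_rows, columns=["accession", "membership", "condition_profile"]
    ).set_index("accession")
    return hits, truth


def simulate_genesets(
    cfg: SimulationConfig,
) -> tuple[GeneSetCollection, list[str], list[str], pd.DataFrame]:
    """Pathway collection plus a query list with planted enrichment.

    The first ``planted_enriched`` pathways contribute a fixed fraction of
    their genes to the query list; the rest of the query is drawn uniformly
    from the remaining universe.  With ``planted_enriched=0`` the query is a
    uniform draw (the null used for calibration).

    Returns ``(collection, query, universe, truth)`` with truth indexed by
    pathway name (``is_enriched``).
    """
    rng = _rng(cfg, 4)
    universe = [f"G{i:05d}" for i in range(cfg.universe_size)]
    lo, hi = cfg.pathway_size_range
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    names = [f"PW{i:03d}" for i in range(cfg.n_pathways)]
    for name in names:
        size = int(rng.integers(lo, hi + 1))
        genes = rng.choice(cfg.universe_size, size=size, replace=False)
        sets[name] = frozenset(universe[g] for g in genes)
        descriptions[name] = "synthetic immune-style pathway"
    collection = GeneSetCollection(sets=sets, descriptions=descriptions)

    query: set[str] = set()
    planted = names[: cfg.planted_enriched]
    for name in planted:
        genes = sorted(sets[name])
        take = int(round(cfg.enriched_query_fraction * len(genes)))
        chosen = rng.choice(len(genes), size=take, replace=False)
        query.update(genes[i] for i in chosen)
    remaining = cfg.query_size - len(query)
    if remaining > 0:
        pool = sorted(set(universe) - query)
        extra = rng.choice(len(pool), size=remaining, replace=False)
        query.update(pool[i] for i in extra)

    truth = pd.DataFrame(
        {"is_enriched": [name in planted for name in names]}, index=names
    )
    return collection, sorted(query), universe, truth


# ---------------------------------------------------------------------------
# plain-text writers for the external TSV interfaces


def write_features(features: Sequence[PeakFeature], path: str | Path) -> None:
    rows = [
        (f.feature_id, ";".join(f.peptides), f.charge, f.rt, f.mz, f.label)
        for f in features
    ]
    pd.DataFrame(
        rows, columns=["feature_id", "peptide", "charge", "rt_s", "mz", "label"]
    ).to_csv(path, sep="\t", index=False)


def write_windows(windows: Sequence[SpectrumWindow], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {"feature_pair_id": w.pair_id, "mz": w.mz, "intensity": w.intensity}
        )
        for w in windows
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_hit_tables(hits: Sequence[ProteinHit], outdir: str | Path) -> list[Path]:
    """One ``hits_<condition>_<rnase±>_<rep>.tsv`` per replicate run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(
        [
            (h.condition, "rnase+" if h.rnase_treated else "rnase-",
             h.replicate, h.accession, h.species, h.fdr)
            for h in hits
        ],
        columns=["condition", "rnase", "replicate", "accession", "species", "fdr"],
    )
    paths = []
    for (condition, rnase, rep), grp in frame.groupby(["condition", "rnase", "replicate"]):
        path = outdir / f"hits_{condition}_{rnase}_{rep}.tsv"
        grp[["accession", "species", "fdr"]].to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths
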