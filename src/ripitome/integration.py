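"""Set-arithmetic reporting and end-to-end pipeline orchestration.

The published readouts of this kind of study are mostly set identities:
Venn partitions of protein sets, class sizes of differentially expressed and
alternatively spliced genes, and integer percentages of bound transcripts
that change expression concordantly.  This module computes those reports
from identifier sets and drives a full seeded synthetic run of every stage.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import expression, interactome, silac
from .enrichment import hypergeometric_enrichment
from .isotopes import isotope_distribution, peptide_composition
from .simulate import (
    SimulationConfig,
    simulate_counts,
    simulate_genesets,
    simulate_protein_table,
    simulate_silac_spectra,
)

__all__ = [
    "venn_counts",
    "round_half_away",
    "percent",
    "OverlapReport",
    "overlap_bound_expression",
    "run_pipeline",
]


def venn_counts(set_a: Iterable, set_b: Iterable) -> tuple[int, int, int]:
    """Sizes of the (A-only, B-only, shared) partition of two id sets."""
    a, b = set(set_a), set(set_b)
    return len(a - b), len(b - a), len(a & b)


def round_half_away(x: float) -> int:
    """Round to the nearest integer with halves away from zero.

    Printed percentages in this literature (67% for 143/214, 82% for
    131/159) follow this convention rather than banker's rounding.
    """
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percent(numerator: int, denominator: int) -> int:
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty set is undefined")
    return round_half_away(100.0 * numerator / denominator)


@dataclass(frozen=True)
class OverlapReport:
    """Overlap of bound-transcript calls with expression/splicing calls."""

    n_bound_up: int
    n_bound_down: int
    concordant_up: int  # bound-up genes that are DE-up
    concordant_down: int  # bound-down genes that are DE-down
    spliced_up: int  # bound-up genes also alternatively spliced
    spliced_down: int
    spliced_not_de_up: int
    spliced_not_de_down: int

    @property
    def concordance_fraction(self) -> float:
        bound = self.n_bound_up + self.n_bound_down
        return (self.concordant_up + self.concordant_down) / bound if bound else math.nan

    def percentages(self) -> dict[str, int]:
        out = {}
        for direction, n in (("up", self.n_bound_up), ("down", self.n_bound_down)):
            if n == 0:
                continue
            out[f"concordant_{direction}_pct"] = percent(
                getattr(self, f"concordant_{direction}"), n)
            out[f"spliced_{direction}_pct"] = percent(
                getattr(self, f"spliced_{direction}"), n)
            out[f"spliced_not_de_{direction}_pct"] = percent(
                getattr(self, f"spliced_not_de_{direction}"), n)
        return out


def overlap_bound_expression(
    bound_up: Iterable[str],
    bound_down: Iterable[str],
    de: pd.DataFrame,
    spliced_genes: Iterable[str],
) -> OverlapReport:
    """Cross bound-transcript direction sets with DE calls and splicing.

    ``de`` is the frame from :func:`ripitome.expression.differential_expression`
    (``direction`` column in {up, down, none}).  For each bound set the
    report counts genes differentially expressed in the matching direction,
    genes also alternatively spliced, and genes spliced but not DE.
    """
    up, down = set(bound_up), set(bound_down)
    spliced = set(spliced_genes)
    de_up = set(de.index[de["direction"] == "up"])
    de_down = set(de.index[de["direction"] == "down"])
    de_any = de_up | de_down
    return OverlapReport(
        n_bound_up=len(up),
        n_bound_down=len(down),
        concordant_up=len(up & de_up),
        concordant_down=len(down & de_down),
        spliced_up=len(up & spliced),
        spliced_down=len(down & spliced),
        spliced_not_de_up=len((up & spliced) - de_any),
        spliced_not_de_down=len((down & spliced) - de_any),
    )


def run_pipeline(
    cfg: SimulationConfig,
    outdir: str | Path,
    alpha: float = 0.05,
    fdr_max: float = 0.01,
) -> dict:
    """Full seeded synthetic run: simulate -> quantify -> assemble -> enrich.

    Writes the stage TSVs plus a machine-readable ``report.json`` under
    ``outdir`` and returns the report dictionary.  The run is deterministic
    in the configuration (including its seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "config": asdict(cfg)}

    # --- counts: differential binding/expression ---
    counts, lengths, groups, truth_de = simulate_counts(cfg)
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    lengths.rename("exon_bp").to_csv(outdir / "lengths.tsv", sep="\t")
    fpkm = expression.compute_fpkm(counts, lengths)
    fpkm.to_csv(outdir / "fpkm.tsv", sep="\t")
    expressed = expression.filter_expressed(fpkm, groups, rule="rnaseq")
    de = expression.differential_expression(counts.loc[expressed], groups, alpha=alpha)
    de.to_csv(outdir / "de_results.tsv", sep="\t")
    called = set(de.index[de["direction"] != "none"])
    planted = set(truth_de.index[truth_de["is_de"]])
    recovered = len(called & planted)
    report["differential_expression"] = {
        "n_expressed": len(expressed),
        "n_significant": len(called),
        "recovery_fraction": recovered / len(planted) if planted else math.nan,
        "false_discovery_proportion": (
            len(called - planted) / len(called) if called else 0.0
        ),
    }

    # --- SILAC ratios ---
    features, windows, truth_silac = simulate_silac_spectra(cfg)
    pairs, rejects = silac.match_peak_pairs(features)
    window_by_id = {w.pair_id: w for w in windows}
    fits = []
    ratios_by_protein: dict[str, list[float]] = {}
    for pair in pairs:
        comp = peptide_composition(pair.peptide)
        d_light = isotope_distribution(comp, n15_enrichment=0.0)
        d_heavy = isotope_distribution(comp, n15_enrichment=cfg.n15_enrichment)
        fit = silac.fit_ls_ftc(window_by_id[pair.pair_id], d_light, d_heavy, pair.charge)
        fits.append(fit)
    fits = silac.filter_fits(fits)
    for pair, fit in zip(pairs, fits):
        if fit.accepted and fit.finite_ratio:
            protein = truth_silac.loc[pair.peptide, "protein"]
            ratios_by_protein.setdefault(protein, []).append(fit.ratio)
    quant = silac.protein_ratio_stats(ratios_by_protein, alpha=alpha)
    pd.DataFrame([asdict_fit(f) for f in fits]).to_csv(
        outdir / "fits.tsv", sep="\t", index=False
    )
    errors = [
        abs(f.ratio - truth_silac.loc[p.peptide, "true_ratio"])
        / truth_silac.loc[p.peptide, "true_ratio"]
        for p, f in zip(pairs, fits)
        if f.accepted and f.finite_ratio
    ]
    report["silac"] = {
        "n_pairs": len(pairs),
        "n_rejected_features": len(rejects),
        "median_relative_ratio_error": float(pd.Series(errors).median()) if errors else math.nan,
        "n_significant_proteins": sum(q.significant for q in quant),
    }

    # --- interactome ---
    hits, truth_protein = simulate_protein_table(cfg)
    filtered = interactome.filter_protein_hits(hits, fdr_max=fdr_max)
    n_reps = {
        ("resting", False): cfg.n_replicates_whole,
        ("activated", False): cfg.n_replicates_whole,
        ("resting", True): cfg.n_replicates_rnase,
        ("activated", True): cfg.n_replicates_rnase,
    }
    detected = interactome.detection_call(filtered, n_reps)
    sets = interactome.assemble_interactome(detected)
    report["interactome"] = {
        "whole": len(sets.whole),
        "core": len(sets.core),
        "peripheral": len(sets.peripheral),
        "whole_venn": {k: len(v) for k, v in sets.whole_venn.items()},
        "core_venn": {k: len(v) for k, v in sets.core_venn.items()},
    }

    # --- enrichment ---
    collection, query, universe, truth_paths = simulate_genesets(cfg)
    results, dropped = hypergeometric_enrichment(query, collection, universe, alpha=alpha)
    hit_paths = {r.pathway for r in results if r.significant}
    planted_paths = set(truth_paths.index[truth_paths["is_enriched"]])
    report["enrichment"] = {
        "n_pathways": len(collection),
        "n_significant": len(hit_paths),
        "planted_recovered": len(hit_paths & planted_paths),
        "n_planted": len(planted_paths),
        "query_genes_outside_universe": dropped,
    }

    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def asdict_fit(fit: silac.FtcFit) -> dict:
    return {
        "pair_id": fit.pair_id,
        "a_light": fit.a_light,
        "a_heavy": fit.a_heavy,
        "ratio": fit.ratio,
        "snr": fit.snr,
        "residual_fraction": fit.residual_fraction,
        "accepted": fit.accepted,
        "reason": fit.reason or "",
    }
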