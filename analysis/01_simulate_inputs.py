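#!/usr/bin/env python
"""Generate every synthetic pipeline input with its planted truth.

Writes the count matrix with gene lengths and group labels, the SILAC
feature/mini-spectrum tables, the replicate protein-hit tables for the four
IP states, and the gene-set collection with its query list — each with a
sidecar truth table keyed by entity identifier.
"""

import argparse
from pathlib import Path

import pandas as pd

from ripitome.enrichment import write_gmt
from ripitome.simulate import (
    SimulationConfig,
    simulate_counts,
    simulate_genesets,
    simulate_protein_table,
    simulate_silac_spectra,
    write_features,
    write_hit_tables,
    write_windows,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results/01_sim"))
    args = parser.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=args.seed)

    counts, lengths, groups, truth_de = simulate_counts(cfg)
    counts.to_csv(out / "counts.tsv", sep="\t")
    lengths.to_csv(out / "lengths.tsv", sep="\t")
    pd.Series(groups, name="group").rename_axis("sample").to_csv(out / "groups.tsv", sep="\t")
    truth_de.to_csv(out / "truth_genes.tsv", sep="\t")
    print(f"counts: {counts.shape[0]} genes x {counts.shape[1]} samples, "
          f"{int(truth_de['is_de'].sum())} planted DE genes")

    features, windows, truth_silac = simulate_silac_spectra(cfg)
    write_features(features, out / "features.tsv")
    write_windows(windows, out / "windows.tsv")
    truth_silac.to_csv(out / "truth_peptides.tsv", sep="\t")
    print(f"SILAC: {len(truth_silac)} peptide pairs over {cfg.n_proteins} proteins")

    hits, truth_protein = simulate_protein_table(cfg)
    paths = write_hit_tables(hits, out / "hits")
    truth_protein.to_csv(out / "truth_proteins.tsv", sep="\t")
    n_core = int((truth_protein.membership == "core").sum())
    print(f"interactome: {len(paths)} replicate hit tables, {n_core} planted core members")

    collection, query, universe, truth_paths = simulate_genesets(cfg)
    write_gmt(collection, out / "sets.gmt")
    (out / "query.txt").write_text("\n".join(query) + "\n")
    (out / "universe.txt").write_text("\n".join(universe) + "\n")
    truth_paths.to_csv(out / "truth_pathways.tsv", sep="\t")
    print(f"gene sets: {len(collection)} pathways, "
          f"{int(truth_paths['is_enriched'].sum())} planted enriched")


if __name__ == "__main__":
    main()
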