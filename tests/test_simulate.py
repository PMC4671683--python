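"""Determinism, planted-truth bookkeeping and statistical structure of the
synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest

from ripitome import expression, silac
from ripitome.simulate import (
    SimulationConfig,
    simulate_counts,
    simulate_genesets,
    simulate_protein_table,
    simulate_silac_spectra,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, message",
        [
            ({"de_fraction": 1.5}, "de_fraction"),
            ({"n15_enrichment": -0.1}, "n15_enrichment"),
            ({"replicate_dropout": 2.0}, "replicate_dropout"),
            ({"n_genes": 0}, "n_genes"),
            ({"nb_dispersion": -1.0}, "nb_dispersion"),
            ({"pathway_size_range": (0, 5)}, "pathway_size_range"),
            ({"pathway_size_range": (10, 20), "universe_size": 15}, "universe"),
            ({"planted_enriched": 99}, "planted_enriched"),
        ],
    )
    def test_invalid_fields_rejected_by_name(self, kwargs, message):
        with pytest.raises(ValueError, match=message):
            SimulationConfig(**kwargs)


class TestDeterminism:
    def test_counts_byte_identical_across_runs(self):
        cfg = SimulationConfig(seed=1, n_genes=300)
        c1, l1, g1, t1 = simulate_counts(cfg)
        c2, l2, g2, t2 = simulate_counts(cfg)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_series_equal(l1, l2)
        assert g1 == g2
        pd.testing.assert_frame_equal(t1, t2)

    def test_spectra_identical_across_runs(self):
        cfg = SimulationConfig(seed=2, n_proteins=4)
        f1, w1, t1 = simulate_silac_spectra(cfg)
        f2, w2, t2 = simulate_silac_spectra(cfg)
        assert f1 == f2
        assert all(np.array_equal(a.intensity, b.intensity) for a, b in zip(w1, w2))
        pd.testing.assert_frame_equal(t1, t2)

    def test_protein_tables_and_genesets_identical_across_runs(self):
        cfg = SimulationConfig(seed=3, n_proteins=30, universe_size=500,
                               query_size=50, n_pathways=6,
                               pathway_size_range=(10, 30))
        h1, t1 = simulate_protein_table(cfg)
        h2, t2 = simulate_protein_table(cfg)
        assert h1 == h2
        pd.testing.assert_frame_equal(t1, t2)
        c1, q1, u1, p1 = simulate_genesets(cfg)
        c2, q2, u2, p2 = simulate_genesets(cfg)
        assert c1.sets == c2.sets and q1 == q2 and u1 == u2
        pd.testing.assert_frame_equal(p1, p2)

    def test_different_seeds_differ(self):
        c1, *_ = simulate_counts(SimulationConfig(seed=1, n_genes=300))
        c2, *_ = simulate_counts(SimulationConfig(seed=2, n_genes=300))
        assert not c1.equals(c2)


class TestCounts:
    def test_null_configuration_has_no_de_truth(self):
        _, _, _, truth = simulate_counts(SimulationConfig(seed=1, de_fraction=0.0))
        assert not truth["is_de"].any()
        assert (truth["log2fc"] == 0).all()

    def test_truth_covers_every_gene_exactly_once(self):
        counts, lengths, _, truth = simulate_counts(SimulationConfig(seed=5, n_genes=400))
        assert list(truth.index) == list(counts.index)
        assert truth.index.is_unique
        assert list(lengths.index) == list(counts.index)

    def test_column_sums_match_configured_library_sizes(self):
        # mean realized depth over 100 seeded replicates within 3 SE of the
        # configured library size, for every sample
        cfg0 = SimulationConfig(seed=0, n_genes=200, n_samples_per_group=2)
        lib = 200 * 500.0
        sums = np.array(
            [
                simulate_counts(SimulationConfig(seed=s, n_genes=200,
                                                 n_samples_per_group=2))[0].sum(axis=0)
                for s in range(100)
            ],
            dtype=float,
        )
        mean = sums.mean(axis=0)
        se = sums.std(axis=0, ddof=1) / np.sqrt(sums.shape[0])
        assert (np.abs(mean - lib) <= 3 * se).all()

    def test_planted_de_recovered_downstream(self):
        # 2000 genes, 20% DE at |log2fc|=2, dispersion 0.1, n=3/group
        cfg = SimulationConfig(seed=1, n_samples_per_group=3)
        counts, _, groups, truth = simulate_counts(cfg)
        de = expression.differential_expression(counts, groups)
        called = set(de.index[de["direction"] != "none"])
        planted = set(truth.index[truth["is_de"]])
        assert len(called & planted) / len(planted) >= 0.70
        assert len(called - planted) / max(len(called), 1) <= 0.10


class TestSilacSpectra:
    def test_noiseless_unit_ratios_fit_exactly(self):
        cfg = SimulationConfig(seed=3, n_proteins=4, noise_sd=0.0,
                               ratio_log2_mean=0.0, ratio_log2_sd=0.0)
        features, windows, _ = simulate_silac_spectra(cfg)
        pairs, rejects = silac.match_peak_pairs(features, cfg.rt_tolerance)
        assert not rejects
        by_id = {w.pair_id: w for w in windows}
        from ripitome.isotopes import isotope_distribution, peptide_composition

        for pair in pairs:
            comp = peptide_composition(pair.peptide)
            fit = silac.fit_ls_ftc(
                by_id[pair.pair_id],
                isotope_distribution(comp, 0.0),
                isotope_distribution(comp, cfg.n15_enrichment),
                pair.charge,
            )
            assert fit.ratio == pytest.approx(1.0, abs=1e-10)

    def test_truth_lists_each_peptide_once_with_its_protein(self):
        cfg = SimulationConfig(seed=6, n_proteins=6)
        features, windows, truth = simulate_silac_spectra(cfg)
        assert truth.index.is_unique
        assert len(features) == 2 * len(truth)
        assert len(windows) == len(truth)
        assert set(truth["protein"]) <= {f"PROT{i:04d}" for i in range(6)}

    def test_decoys_violate_coelution_and_are_rejected(self):
        cfg = SimulationConfig(seed=8, n_proteins=10, decoy_fraction=1.0)
        features, _, truth = simulate_silac_spectra(cfg)
        assert truth["is_decoy"].all()
        pairs, rejects = silac.match_peak_pairs(features, cfg.rt_tolerance)
        assert not pairs
        assert {r for _, r in rejects} == {"rt_mismatch"}


class TestProteinTable:
    def test_peripheral_members_never_in_rnase_treated_runs(self):
        cfg = SimulationConfig(seed=2, n_proteins=80)
        hits, truth = simulate_protein_table(cfg)
        peripheral = set(truth.index[truth.membership == "peripheral"])
        assert not any(h.accession in peripheral for h in hits if h.rnase_treated)

    def test_truth_covers_all_emitted_accessions(self):
        cfg = SimulationConfig(seed=2, n_proteins=50)
        hits, truth = simulate_protein_table(cfg)
        assert truth.index.is_unique
        assert {h.accession for h in hits} <= set(truth.index)


class TestGenesets:
    def test_empty_query_gives_all_pvalues_one(self):
        from ripitome.enrichment import hypergeometric_enrichment

        cfg = SimulationConfig(seed=1, universe_size=500, query_size=10,
                               n_pathways=8, pathway_size_range=(10, 40),
                               planted_enriched=0)
        coll, _, universe, _ = simulate_genesets(cfg)
        results, _ = hypergeometric_enrichment([], coll, universe)
        assert all(r.p_value == 1.0 for r in results)

    def test_fully_contained_planted_pathway_ranks_first(self):
        from ripitome.enrichment import hypergeometric_enrichment

        cfg = SimulationConfig(seed=4, universe_size=1000, query_size=120,
                               n_pathways=10, pathway_size_range=(20, 60),
                               planted_enriched=1, enriched_query_fraction=1.0)
        coll, query, universe, truth = simulate_genesets(cfg)
        planted = truth.index[truth["is_enriched"]][0]
        assert coll[planted] <= set(query)
        results, _ = hypergeometric_enrichment(query, coll, universe)
        best = min(results, key=lambda r: r.p_value)
        assert best.pathway == planted

    def test_pathway_sizes_respect_configured_range(self):
        cfg = SimulationConfig(seed=4, universe_size=800, query_size=50,
                               n_pathways=12, pathway_size_range=(15, 25))
        coll, _, universe, _ = simulate_genesets(cfg)
        assert all(15 <= len(coll[name]) <= 25 for name in coll)
        assert set().union(*(coll[n] for n in coll)) <= set(universe)
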