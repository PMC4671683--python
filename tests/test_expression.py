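"""FPKM conversion, expression filters, NB exact test and splicing scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ripitome.expression import (
    classify_genes,
    compute_fpkm,
    differential_expression,
    filter_expressed,
    nb_exact_test,
    splicing_scores,
)

from _oracles import nb_exact_pvalue_bruteforce


class TestComputeFpkm:
    def test_unit_case(self):
        # count 100 on a 1 kb gene in a 1e6-read library -> FPKM 100
        counts = pd.DataFrame({"s1": [100, 999900]}, index=["g1", "g2"])
        lengths = pd.Series([1000, 5000], index=["g1", "g2"])
        fpkm = compute_fpkm(counts, lengths)
        assert fpkm.loc["g1", "s1"] == pytest.approx(100.0)

    def test_zero_count_gives_zero_fpkm(self, toy_counts):
        counts, _ = toy_counts
        lengths = pd.Series(1000, index=counts.index)
        fpkm = compute_fpkm(counts, lengths)
        assert (fpkm.to_numpy() == 0).sum() == (counts.to_numpy() == 0).sum()

    def test_invariant_under_uniform_scaling_of_a_sample(self, toy_counts):
        counts, _ = toy_counts
        lengths = pd.Series(np.arange(1, 5) * 700, index=counts.index)
        doubled = counts.copy()
        doubled["A_1"] = counts["A_1"] * 2
        pd.testing.assert_frame_equal(
            compute_fpkm(counts, lengths), compute_fpkm(doubled, lengths)
        )

    def test_round_trip_recovers_counts(self, toy_counts):
        counts, _ = toy_counts
        lengths = pd.Series([800, 1200, 3000, 450], index=counts.index)
        fpkm = compute_fpkm(counts, lengths)
        lib = counts.sum(axis=0)
        back = fpkm.mul(lengths / 1e3, axis=0).mul(lib / 1e6, axis=1)
        assert np.allclose(back.to_numpy(), counts.to_numpy(), rtol=1e-9)

    def test_missing_length_names_genes(self, toy_counts):
        counts, _ = toy_counts
        lengths = pd.Series([1000, 1000], index=["g1", "g2"])
        with pytest.raises(ValueError, match="g3"):
            compute_fpkm(counts, lengths)


class TestFilterExpressed:
    def _fpkm(self, rows):
        return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))],
                            columns=["A_1", "A_2", "A_3", "B_1", "B_2", "B_3"])

    groups = {f"{g}_{i}": g for g in "AB" for i in (1, 2, 3)}

    def test_gene_just_above_threshold_in_one_group_retained(self):
        fpkm = self._fpkm([[2 ** -1.9] * 3 + [0.0] * 3])
        assert filter_expressed(fpkm, self.groups, rule="rnaseq") == ["g0"]

    def test_exactly_half_the_samples_is_not_a_majority(self):
        # above threshold in 3 of 6 per... here 1 of 3? use 2-sample groups
        fpkm = pd.DataFrame(
            [[1.0, 0.0, 1.0, 0.0]],
            index=["g0"], columns=["A_1", "A_2", "B_1", "B_2"],
        )
        groups = {"A_1": "A", "A_2": "A", "B_1": "B", "B_2": "B"}
        assert filter_expressed(fpkm, groups, log2_threshold=-2) == []

    def test_all_zero_gene_dropped(self):
        fpkm = self._fpkm([[0.0] * 6])
        assert filter_expressed(fpkm, self.groups, rule="rnaseq") == []

    def test_ripseq_rule_uses_higher_default_threshold(self):
        fpkm = self._fpkm([[1.0] * 6])  # log2 = 0: passes -2, fails +2
        assert filter_expressed(fpkm, self.groups, rule="rnaseq") == ["g0"]
        assert filter_expressed(fpkm, self.groups, rule="ripseq") == []


class TestNbExactTest:
    @pytest.mark.parametrize(
        "sum_a, sum_b, n_a, n_b, phi",
        [
            (10, 10, 3, 3, 0.1),
            (0, 25, 3, 3, 0.1),
            (30, 30, 6, 6, 0.05),
            (5, 40, 2, 4, 0.2),
            (17, 43, 4, 2, 0.4),
            (60, 0, 3, 3, 0.01),
            (12, 34, 5, 3, 1.0),
        ],
    )
    def test_matches_bruteforce_conditional_enumeration(self, sum_a, sum_b, n_a, n_b, phi):
        mine = nb_exact_test(sum_a, sum_b, n_a, n_b, phi)
        oracle = nb_exact_pvalue_bruteforce(sum_a, sum_b, n_a, n_b, phi)
        assert mine == pytest.approx(oracle, abs=1e-12)

    def test_zero_total_is_uninformative(self):
        assert nb_exact_test(0, 0, 3, 3, 0.1) == 1.0


class TestDifferentialExpression:
    def test_identical_groups_are_exactly_null(self):
        cols = ["A_1", "A_2", "B_1", "B_2"]
        rng = np.random.default_rng(0)
        col = rng.poisson(100, size=50)
        counts = pd.DataFrame({c: col for c in cols},
                              index=[f"g{i}" for i in range(50)])
        groups = {c: c.split("_")[0] for c in cols}
        de = differential_expression(counts, groups)
        assert (de["log2fc"] == 0).all()
        assert (de["direction"] == "none").all()

    def test_requires_two_samples_per_group(self, toy_counts):
        counts, _ = toy_counts
        groups = {"A_1": "A", "A_2": "B", "B_1": "B", "B_2": "B"}
        with pytest.raises(ValueError, match="two samples"):
            differential_expression(counts, groups)

    def test_direction_follows_fold_change_sign(self):
        rng = np.random.default_rng(1)
        n = 200
        base = rng.poisson(200, n).astype(float) + 1
        cols = {}
        for j in range(3):
            cols[f"A_{j}"] = rng.poisson(base)
        for j in range(3):
            cols[f"B_{j}"] = rng.poisson(base * np.where(np.arange(n) < 20, 8.0, 1.0))
        counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(n)])
        groups = {c: c.split("_")[0] for c in cols}
        de = differential_expression(counts, groups)
        called_up = de.index[de["direction"] == "up"]
        assert set(called_up) >= {f"g{i}" for i in range(20)} - set(
            de.index[de["padj"] >= 0.05]
        )
        assert (de.loc[called_up, "log2fc"] > 0).all()


class TestSplicingScores:
    def _table(self, incl_a, excl_a, incl_b, excl_b, gene_level=1000.0):
        return pd.DataFrame(
            {
                "gene": ["g1"] * 3,
                "role": ["inclusion", "exclusion", "gene"],
                "ctrl_1": [incl_a, excl_a, gene_level],
                "kd_1": [incl_b, excl_b, gene_level],
            }
        )

    groups = {"ctrl_1": "control", "kd_1": "knockdown"}

    def test_identical_conditions_score_zero(self):
        table = self._table(200.0, 100.0, 200.0, 100.0)
        res = splicing_scores(table, self.groups, "control", "knockdown")
        assert res.loc["g1", "si_inclusion"] == pytest.approx(0.0)
        assert res.loc["g1", "reciprocity"] == pytest.approx(0.0)
        assert not res.loc["g1", "spliced"]

    def test_reciprocal_switch_gives_opposite_unit_indices(self):
        table = self._table(200.0, 100.0, 100.0, 200.0)
        res = splicing_scores(table, self.groups, "control", "knockdown")
        assert res.loc["g1", "si_inclusion"] == pytest.approx(-1.0)
        assert res.loc["g1", "si_exclusion"] == pytest.approx(1.0)
        assert res.loc["g1", "reciprocity"] == pytest.approx(-1.0)
        assert bool(res.loc["g1", "spliced"])

    def test_probe_brighter_in_control_scores_negative(self):
        table = self._table(300.0, 100.0, 150.0, 100.0)
        res = splicing_scores(table, self.groups, "control", "knockdown")
        assert res.loc["g1", "si_inclusion"] < 0

    def test_antisymmetric_under_condition_swap(self):
        table = self._table(220.0, 130.0, 140.0, 260.0, gene_level=900.0)
        fwd = splicing_scores(table, self.groups, "control", "knockdown")
        rev = splicing_scores(table, self.groups, "knockdown", "control")
        assert fwd.loc["g1", "reciprocity"] == pytest.approx(
            -rev.loc["g1", "reciprocity"]
        )

    def test_nonpositive_intensity_rejected(self):
        table = self._table(0.0, 100.0, 100.0, 200.0)
        with pytest.raises(ValueError, match="positive"):
            splicing_scores(table, self.groups, "control", "knockdown")


class TestClassifyGenes:
    def test_set_algebra_example(self):
        classes = classify_genes({"a", "b"}, {"b", "c"})
        assert classes.to_dict() == {"a": "DE_only", "b": "DE_and_AS", "c": "AS_only"}

    def test_disjoint_sets_have_empty_intersection_class(self):
        classes = classify_genes({"a"}, {"b"})
        assert "DE_and_AS" not in set(classes)

    def test_classes_partition_the_universe(self):
        universe = {f"g{i}" for i in range(100)}
        rng = np.random.default_rng(2)
        de = set(rng.choice(sorted(universe), 30, replace=False))
        spliced = set(rng.choice(sorted(universe), 25, replace=False))
        classes = classify_genes(de, spliced, universe)
        assert set(classes.index) == universe
        sizes = classes.value_counts()
        assert sizes.sum() == len(universe)
        assert sizes.get("DE_and_AS", 0) == len(de & spliced)


@given(st.lists(st.floats(0.001, 1000), min_size=2, max_size=8))
def test_fpkm_columns_sum_to_one_million_per_kb_weighted(values):
    # column identity: sum_g FPKM * len_kb = 1e6 * (colsum/colsum) -> constant
    counts = pd.DataFrame({"s": np.round(np.asarray(values)).astype(int) + 1})
    lengths = pd.Series(1000, index=counts.index)
    fpkm = compute_fpkm(counts, lengths)
    assert fpkm["s"].sum() == pytest.approx(1e6, rel=1e-9)
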