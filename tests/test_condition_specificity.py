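"""Experiment ordering, the clustering score S, and the reversal/slope tests."""

import numpy as np
import pytest

from bsmv import (
    ExpressionMatrix,
    ValidationError,
    build_variant_groupings,
    clustering_permutation_test,
    clustering_score,
    generate_scenario,
    order_experiments,
    rank_profiles,
    reversal_assessment,
    reversal_rank_test,
    reversal_scenario,
    affinity_scenario,
    slope_sign_test,
)
from bsmv.condition_specificity import ExperimentOrdering
from bsmv.io_formats import ConditionMetadata

from conftest import (
    brute_force_clustering,
    exact_clustering_p,
    grouping_from_labels,
)


def matrix_from(rows: dict[str, list[float]]) -> ExpressionMatrix:
    genes = list(rows)
    vals = np.array([rows[g] for g in genes], dtype=float)
    return ExpressionMatrix(genes, [f"c{i}" for i in range(vals.shape[1])], vals)


def ordering_from_ranks(rank_of: dict[str, int], pair=("A", "T")) -> ExperimentOrdering:
    conds = sorted(rank_of)
    ordering = sorted(conds, key=lambda c: rank_of[c])
    return ExperimentOrdering(
        variant_pair=pair,
        condition_ids=conds,
        statistics=np.zeros(len(conds)),
        ordering=ordering,
        experiment_rank=dict(rank_of),
    )


class TestOrderExperiments:
    def test_identical_means_lexical_order(self):
        rows = {
            "a1": [1.0, 2.0, 3.0], "a2": [3.0, 2.0, 1.0],
            "t1": [1.0, 2.0, 3.0], "t2": [3.0, 2.0, 1.0],
        }
        g = grouping_from_labels({"A": ("a1", "a2"), "T": ("t1", "t2")})
        o = order_experiments(g, matrix_from(rows), ("A", "T"))
        np.testing.assert_array_equal(o.statistics, np.zeros(3))
        assert o.ordering == ["c0", "c1", "c2"]

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        rows = {f"g{i}": rng.normal(size=6).tolist() for i in range(4)}
        g = grouping_from_labels({"A": ("g0", "g1"), "T": ("g2", "g3")})
        m = matrix_from(rows)
        fwd = order_experiments(g, m, ("A", "T"))
        rev = order_experiments(g, m, ("T", "A"))
        np.testing.assert_allclose(rev.statistics, -fwd.statistics)
        assert rev.ordering == fwd.ordering[::-1]

    def test_planted_reversal_extreme_ranks(self):
        cfg = reversal_scenario(seed=5, noise_sd=0.0)
        data = generate_scenario(cfg)
        g = build_variant_groupings(data.sites, "TF01", cfg.variable_position)
        o = order_experiments(g, data.expression, ("A", "T"))
        types = data.metadata.experiment_type
        top6 = {types[c] for c in o.ordering[:6]}
        bottom6 = {types[c] for c in o.ordering[-6:]}
        assert top6 == {"desiccation"} and bottom6 == {"MMS"}

    def test_requires_two_genes_per_variant(self):
        g = grouping_from_labels({"A": ("g0",), "T": ("g1", "g2")})
        with pytest.raises(ValidationError):
            order_experiments(
                g, matrix_from({f"g{i}": [1.0, 2.0] for i in range(3)}), ("A", "T")
            )

    def test_variance_normalization_mode(self):
        rng = np.random.default_rng(3)
        rows = {f"g{i}": rng.normal(size=4).tolist() for i in range(4)}
        g = grouping_from_labels({"A": ("g0", "g1"), "T": ("g2", "g3")})
        m = matrix_from(rows)
        o_sd = order_experiments(g, m, ("A", "T"), normalize="sd")
        o_var = order_experiments(g, m, ("A", "T"), normalize="var")
        pooled_sd = np.vstack([m.values[:2], m.values[2:]]).std(axis=0, ddof=1)
        np.testing.assert_allclose(o_var.statistics, o_sd.statistics / pooled_sd)


class TestClusteringScore:
    def test_separated_hand_oracle(self):
        o = ordering_from_ranks({"c1": 1, "c2": 2, "c3": 3, "c4": 4})
        meta = ConditionMetadata({"c1": "X", "c2": "X", "c3": "Y", "c4": "Y"})
        s, c_w, c_q, a, b = clustering_score(o, meta)
        assert (c_w, c_q, a, b) == (1.0, 2.0, 2, 4)
        assert s == 1.0

    def test_interleaved_scores_lower_than_separated(self):
        o = ordering_from_ranks({"c1": 1, "c2": 2, "c3": 3, "c4": 4})
        inter = ConditionMetadata({"c1": "X", "c2": "Y", "c3": "X", "c4": "Y"})
        sep = ConditionMetadata({"c1": "X", "c2": "X", "c3": "Y", "c4": "Y"})
        s_inter = clustering_score(o, inter)[0]
        s_sep = clustering_score(o, sep)[0]
        ranks = np.array([1.0, 2.0, 3.0, 4.0])
        assert s_inter == pytest.approx(
            brute_force_clustering(ranks, ["X", "Y", "X", "Y"])[0]
        )
        assert s_inter < s_sep

    def test_single_type_errors(self):
        o = ordering_from_ranks({"c1": 1, "c2": 2})
        with pytest.raises(ValidationError):
            clustering_score(o, ConditionMetadata({"c1": "X", "c2": "X"}))

    def test_decomposition_identity(self):
        # A*C_W + B*C_Q equals the total pairwise rank distance
        rng = np.random.default_rng(7)
        n = 9
        ranks = {f"c{i}": r + 1 for i, r in enumerate(rng.permutation(n))}
        labels = dict(zip(sorted(ranks), rng.choice(["X", "Y", "Z"], size=n)))
        labels[sorted(ranks)[0]] = "X"
        labels[sorted(ranks)[1]] = "X"  # guarantee a same-type pair
        o = ordering_from_ranks(ranks)
        s, c_w, c_q, a, b = clustering_score(o, ConditionMetadata(labels))
        rank_vals = np.array([ranks[c] for c in sorted(ranks)], dtype=float)
        total = sum(
            abs(rank_vals[i] - rank_vals[j])
            for i in range(n) for j in range(i + 1, n)
        )
        assert a * c_w + b * c_q == pytest.approx(total)


class TestClusteringPermutation:
    def test_matches_exhaustive_enumeration(self):
        o = ordering_from_ranks({"c1": 1, "c2": 2, "c3": 3, "c4": 4})
        meta = ConditionMetadata({"c1": "X", "c2": "X", "c3": "Y", "c4": "Y"})
        n_mc = 10000
        res = clustering_permutation_test(o, meta, n_permutations=n_mc, seed=0)
        p_exact = exact_clustering_p(
            np.array([1.0, 2.0, 3.0, 4.0]), ["X", "X", "Y", "Y"]
        )
        se = np.sqrt(p_exact * (1 - p_exact) / n_mc)
        assert abs(res.p_value - p_exact) <= 3 * se + 1 / n_mc

    def test_degenerate_all_tie(self):
        # both types perfectly interleaved with symmetric ranks: every
        # arrangement of the label multiset gives some S; identical-label
        # multiset {X,X} over 2 conditions is fully degenerate
        o = ordering_from_ranks({"c1": 1, "c2": 2, "c3": 3})
        meta = ConditionMetadata({"c1": "X", "c2": "X", "c3": "Y"})
        res = clustering_permutation_test(o, meta, n_permutations=500, seed=1)
        # with 3 conditions and label multiset {X,X,Y} only 3 arrangements
        # exist; p must be one of the attainable mass points and in (0, 1]
        assert 0 < res.p_value <= 1

    def test_planted_reversal_clusters(self, reversal_data):
        g = build_variant_groupings(reversal_data.sites, "TF01", 4)
        o = order_experiments(g, reversal_data.expression, ("A", "T"))
        res = clustering_permutation_test(
            o, reversal_data.metadata, n_permutations=2000, seed=2
        )
        assert res.S > 0 and res.p_value < 0.05
        assert res.A + res.B == len(o.ordering) * (len(o.ordering) - 1) // 2


class TestReversalRankTest:
    def test_perfect_reversal(self):
        rows = {
            "a1": [1.0, 2.0, 3.0], "a2": [1.0, 2.0, 3.0],
            "t1": [3.0, 2.0, 1.0], "t2": [3.0, 2.0, 1.0],
        }
        g = grouping_from_labels({"A": ("a1", "a2"), "T": ("t1", "t2")})
        rho, p = reversal_rank_test(g, rank_profiles(matrix_from(rows)), ("A", "T"))
        assert rho == pytest.approx(-1.0)
        assert p < 0.5

    def test_identical_profiles_positive(self):
        rows = {g: [1.0, 2.0, 3.0, 4.0] for g in ("a1", "a2", "t1", "t2")}
        g = grouping_from_labels({"A": ("a1", "a2"), "T": ("t1", "t2")})
        rho, p = reversal_rank_test(g, rank_profiles(matrix_from(rows)), ("A", "T"))
        assert rho == pytest.approx(1.0)
        assert p > 0.5

    def test_constant_mean_rank_undefined(self):
        rows = {g: [1.0, 1.0, 1.0] for g in ("a1", "a2", "t1", "t2")}
        g = grouping_from_labels({"A": ("a1", "a2"), "T": ("t1", "t2")})
        rho, p = reversal_rank_test(g, rank_profiles(matrix_from(rows)), ("A", "T"))
        assert np.isnan(rho) and p == 1.0

    def test_reversal_significant_affinity_not(self):
        rev = generate_scenario(reversal_scenario(seed=9))
        aff = generate_scenario(affinity_scenario(seed=9))
        for data, expect_sig in ((rev, True), (aff, False)):
            g = build_variant_groupings(data.sites, "TF01", 4)
            r = rank_profiles(data.expression)
            rho, p = reversal_rank_test(g, r, ("A", "T"))
            if expect_sig:
                assert rho < 0 and p < 0.05
            else:
                assert not (rho < 0 and p < 0.05)


class TestSlopeSignTest:
    def test_noiseless_lines_pass(self):
        e = 6
        rows = {
            "a1": list(range(e, 0, -1)), "a2": list(range(e, 0, -1)),
            "t1": list(range(1, e + 1)), "t2": list(range(1, e + 1)),
        }
        g = grouping_from_labels({"A": ("a1", "a2"), "T": ("t1", "t2")})
        m = matrix_from(rows)
        r = rank_profiles(m)
        # fixed ordering c0..c5: A's mean ranks decrease exactly linearly
        # along it, T's increase, with zero residual
        o = ordering_from_ranks({f"c{i}": i + 1 for i in range(e)})
        slope_a, p_a, slope_b, p_b, passes = slope_sign_test(g, r, o, ("A", "T"))
        assert slope_a == pytest.approx(-1.0) and slope_b == pytest.approx(1.0)
        assert p_a < 1e-6 and p_b < 1e-6
        assert passes

    def test_flat_groups_fail(self):
        rows = {g: [1.0, 1.0, 1.0, 1.0] for g in ("a1", "a2", "t1", "t2")}
        g = grouping_from_labels({"A": ("a1", "a2"), "T": ("t1", "t2")})
        m = matrix_from(rows)
        o = order_experiments(g, m, ("A", "T"))
        slope_a, _, slope_b, _, passes = slope_sign_test(
            g, rank_profiles(m), o, ("A", "T")
        )
        assert slope_a == 0.0 and slope_b == 0.0 and not passes

    def test_slope_matches_normal_equations(self):
        y = np.array([2.0, 2.5, 4.0, 3.5, 5.0])
        x = np.arange(1, 6, dtype=float)
        slope_oracle = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        from scipy.stats import linregress

        assert linregress(x, y).slope == pytest.approx(slope_oracle)

    def test_too_few_experiments(self):
        rows = {g: [1.0, 2.0] for g in ("a1", "a2", "t1", "t2")}
        g = grouping_from_labels({"A": ("a1", "a2"), "T": ("t1", "t2")})
        m = matrix_from(rows)
        o = order_experiments(g, m, ("A", "T"))
        with pytest.raises(ValidationError):
            slope_sign_test(g, rank_profiles(m), o, ("A", "T"))

    def test_combined_assessment_on_planted_pair(self, reversal_data):
        g = build_variant_groupings(reversal_data.sites, "TF01", 4)
        r = rank_profiles(reversal_data.expression)
        o = order_experiments(g, reversal_data.expression, ("A", "T"))
        res = reversal_assessment(g, r, o, ("A", "T"))
        assert res.passes_both
        # the inert "C" group should not pass against either planted variant
        o_ac = order_experiments(g, reversal_data.expression, ("A", "C"))
        assert not reversal_assessment(g, r, o_ac, ("A", "C")).passes_both
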