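"""Rank-sum testing on cluster weights, set algebra, subset validation."""
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from somscreen import (
    Comparison,
    MouseClass,
    TrainingParams,
    cluster_weight_sets,
    discriminant_proteins,
    set_algebra,
    subset_validation,
    wilcoxon_rank_sum,
)
from somscreen.discriminant import COMPARISONS
from somscreen.maps import ClassCluster
from somscreen.som import SOMap
from somscreen import hexgrid


def enumeration_p_value(a, b):
    """Independent oracle: exact two-sided rank-sum p by full enumeration."""
    pooled = sorted(list(a) + list(b))
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    na = len(a)
    u_obs = sum(ranks[v] for v in a) - na * (na + 1) / 2
    us = [sum(rs) - na * (na + 1) / 2
          for rs in combinations(range(1, len(pooled) + 1), na)]
    n = len(us)
    lo = sum(u <= u_obs for u in us) / n
    hi = sum(u >= u_obs for u in us) / n
    return min(1.0, 2 * min(lo, hi))


def make_som_with_weights(weights, side):
    return SOMap(side=side, weights=np.asarray(weights, float), seed=0,
                 params=TrainingParams(), trained=True)


def cluster_of(code, coords, n_meas=15):
    return ClassCluster(MouseClass.from_code(code), frozenset(coords), n_meas)


class TestWilcoxon:
    def test_complete_separation_of_three_vs_three(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], mode="exact") == pytest.approx(0.1)

    def test_identical_samples_give_p_one(self):
        assert wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_approx_tracks_exact_enumeration(self):
        rng = np.random.default_rng(17)
        for na in (3, 4, 5, 6):
            for nb in (3, 4, 6):
                if na + nb > 12:
                    continue
                a = rng.normal(size=na)
                b = rng.normal(0.8, size=nb)
                p_exact = enumeration_p_value(a, b)
                p_approx = wilcoxon_rank_sum(a, b, mode="approx")
                assert abs(p_exact - p_approx) <= 0.02

    def test_exact_mode_matches_enumeration_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            a = rng.normal(size=int(rng.integers(3, 7)))
            b = rng.normal(0.5, size=int(rng.integers(3, 7)))
            assert wilcoxon_rank_sum(a, b, mode="exact") == \
                pytest.approx(enumeration_p_value(a, b), abs=1e-12)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=8, unique=True),
           st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=8, unique=True))
    def test_symmetry_and_monotone_invariance(self, a, b):
        p = wilcoxon_rank_sum(a, b)
        assert wilcoxon_rank_sum(b, a) == pytest.approx(p)
        f = lambda xs: [np.arctan(x / 2000.0) for x in xs]  # strictly increasing
        assert wilcoxon_rank_sum(f(a), f(b)) == pytest.approx(p)


class TestClusterWeightSets:
    def test_values_pool_all_clusters_of_the_class(self):
        side = 4
        w = np.arange(side * side * 2, dtype=float).reshape(side * side, 2)
        som = make_som_with_weights(w, side)
        clusters = [cluster_of("c-SC-s", [(0, 0), (0, 1), (0, 2)]),
                    cluster_of("c-SC-s", [(2, 0), (2, 1)]),
                    cluster_of("c-CS-s", [(3, 0), (3, 1)])]
        vals = cluster_weight_sets(som, clusters, "c-SC-s")
        assert vals.shape == (5, 2)  # 3 + 2 nodes pooled
        expect = sorted(w[hexgrid.node_index(c, side), 0]
                        for c in [(0, 0), (0, 1), (0, 2), (2, 0), (2, 1)])
        assert sorted(vals[:, 0]) == expect

    def test_single_protein_map_returns_scalar_weights(self):
        som = make_som_with_weights([[0.1], [0.5], [0.9], [0.3]], 2)
        vals = cluster_weight_sets(som, [cluster_of("t-CS-m", [(0, 0), (0, 1)])],
                                   "t-CS-m")
        assert sorted(vals[:, 0]) == [0.1, 0.5]

    def test_class_without_clusters_fails_loudly(self):
        som = make_som_with_weights([[0.0]] * 4, 2)
        with pytest.raises(ValueError, match="t-SC-s"):
            cluster_weight_sets(som, [], "t-SC-s")


class TestDiscriminantProteins:
    @staticmethod
    def planted_map():
        side = 5
        rng = np.random.default_rng(4)
        w = rng.normal(0.5, 0.05, size=(side * side, 2))
        a_nodes = [(0, c) for c in range(5)] + [(1, c) for c in range(2)]
        b_nodes = [(4, c) for c in range(5)] + [(3, c) for c in range(2)]
        for coord in a_nodes:
            w[hexgrid.node_index(coord, side), 0] += 3.0  # protein 1 shifted
        som = make_som_with_weights(w, side)
        clusters = [cluster_of("c-CS-s", a_nodes), cluster_of("c-SC-s", b_nodes)]
        return som, clusters

    def test_planted_weight_shift_is_detected_and_null_is_not(self):
        som, clusters = self.planted_map()
        res = discriminant_proteins(som, clusters, COMPARISONS["NL"], ["Pa", "Pb"])
        assert res.significant == {"Pa"}
        assert res.p_values["Pa"] < 0.05 <= res.p_values["Pb"]
        assert res.n_nodes_a == res.n_nodes_b == 7

    def test_alpha_zero_gives_empty_set(self):
        som, clusters = self.planted_map()
        res = discriminant_proteins(som, clusters, COMPARISONS["NL"],
                                    ["Pa", "Pb"], alpha=0.0)
        assert res.significant == set()

    def test_invariant_to_protein_column_order(self):
        som, clusters = self.planted_map()
        perm = make_som_with_weights(som.weights[:, ::-1], som.side)
        res = discriminant_proteins(som, clusters, COMPARISONS["NL"], ["Pa", "Pb"])
        res_perm = discriminant_proteins(perm, clusters, COMPARISONS["NL"],
                                         ["Pb", "Pa"])
        assert res.significant == res_perm.significant
        assert res.p_values == {p: res_perm.p_values[p] for p in ("Pa", "Pb")}

    def test_bh_correction_only_shrinks_the_set(self):
        som, clusters = self.planted_map()
        plain = discriminant_proteins(som, clusters, COMPARISONS["NL"], ["Pa", "Pb"])
        bh = discriminant_proteins(som, clusters, COMPARISONS["NL"], ["Pa", "Pb"],
                                   correction="bh")
        assert bh.significant <= plain.significant


class TestSetAlgebra:
    def test_intersection_union_difference(self):
        sets = {"A": {"x", "y"}, "B": {"y", "z"}, "C": {"z"}}
        assert set_algebra(sets, "A & B") == {"y"}
        assert set_algebra(sets, "A & A") == {"x", "y"}
        assert set_algebra(sets, "(A | B) - C") == {"x", "y"}

    def test_hyphenated_comparison_names(self):
        sets = {"MEM-base": {"x", "y"}, "NL": {"y"}}
        assert set_algebra(sets, "MEM-base & NL") == {"y"}

    def test_unknown_name_rejected(self):
        with pytest.raises(KeyError):
            set_algebra({"A": set()}, "A & B")

    def test_planted_shared_effects_recovered(self, small_data):
        _, truth = small_data
        sets = truth.discriminant_sets
        shared = set_algebra(sets, "NL & NLm & FL & RL")
        # all four contrasts differ exactly in the learning factor
        assert shared == sets["NL"] == {"P001", "P002", "P003", "P004"}


class TestSubsetValidation:
    def test_full_panel_subset_reproduces_baseline(self, small_data, fast_params):
        from somscreen import multi_run_select
        from somscreen.dataset import normalize_minmax, subset
        ds, _ = small_data
        classes = ["c-CS-s", "c-SC-s"]
        report = subset_validation(ds, ds.protein_names, classes=classes,
                                   n_runs=2, params=fast_params, base_seed=3,
                                   include_complement=False,
                                   nominal_replicates=6)
        sub = normalize_minmax(subset(ds, classes=classes))
        baseline = multi_run_select(sub.values, sub.class_codes, 3, n_runs=2,
                                    params=fast_params, base_seed=3)
        got = [r.epsilon_q for r in report.subset.selection.runs]
        want = [r.epsilon_q for r in baseline.runs]
        assert got == pytest.approx(want, abs=0)

    def test_planted_subset_separates_and_complement_does_not(self, small_data,
                                                              fast_params):
        ds, truth = small_data
        classes = ["c-CS-s", "c-SC-s", "c-CS-m", "c-SC-m"]
        planted = sorted(truth.discriminant_sets["NL"])
        report = subset_validation(ds, planted, classes=classes, n_runs=2,
                                   params=fast_params, base_seed=1,
                                   focus_classes=("c-CS-s", "c-SC-s"),
                                   nominal_replicates=6)
        tab = report.table()
        assert list(tab["n_proteins"]) == [4, 8]
        assert report.subset.n_mixed_focus == 0

    def test_empty_or_unknown_subset_rejected(self, small_data):
        ds, _ = small_data
        with pytest.raises(ValueError):
            subset_validation(ds, [])
        with pytest.raises(ValueError):
            subset_validation(ds, ["P999"])


def test_comparison_catalogue_is_the_nine_standard_contrasts():
    assert len(COMPARISONS) == 9
    nl = COMPARISONS["NL"]
    assert (nl.class_a.code, nl.class_b.code) == ("c-CS-s", "c-SC-s")
    for cmp in COMPARISONS.values():
        assert cmp.class_a != cmp.class_b
    with pytest.raises(ValueError):
        Comparison("bad", nl.class_a, nl.class_a)
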