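"""Gene filtering, pattern taxonomy, similarity, clustering, marker ranking."""

import numpy as np
import pandas as pd
import pytest

from crcsubtype import (
    ExpressionMatrix,
    FilterSpec,
    SampleMetadata,
    anova_filter,
    hierarchical_cluster,
    model_similarity,
    pattern_classify,
    rank_two_group_markers,
)
from crcsubtype.synthetic_data import ModelSystemSpec, simulate_model_systems


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Textbook BH: q_(i) = min_{j>=i} p_(j) * n / j, by explicit loops."""
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running_min = np.inf
    for idx in range(n - 1, -1, -1):
        i = order[idx]
        running_min = min(running_min, p[i] * n / (idx + 1))
        q[i] = min(running_min, 1.0)
    return q


def _three_group_meta(n_per_group: int = 2) -> SampleMetadata:
    rows = []
    for ms in ("monolayer2D", "spheroid", "xenograft"):
        for i in range(n_per_group):
            rows.append({"sample_id": f"{ms}_{i}", "cell_line": "CL",
                         "model_system": ms, "group": None})
    return SampleMetadata(pd.DataFrame(rows))


class TestAnovaFilter:
    def test_hand_anova_f_statistic(self):
        # groups {1,2,3},{2,3,4},{3,4,5}: MSB=3, MSW=1 -> F=3 (df 2, 6)
        meta = _three_group_meta(3)
        cols = {
            "monolayer2D_0": 1, "monolayer2D_1": 2, "monolayer2D_2": 3,
            "spheroid_0": 2, "spheroid_1": 3, "spheroid_2": 4,
            "xenograft_0": 3, "xenograft_1": 4, "xenograft_2": 5,
        }
        m = ExpressionMatrix(
            pd.DataFrame(cols, index=["g1"], dtype=float), feature_level="gene"
        )
        spec = FilterSpec(0.5, 0.1, "monolayer2D", ["spheroid", "xenograft"])
        res = anova_filter(m, meta, spec)
        assert res.table.loc["g1", "F"] == pytest.approx(3.0)

    def test_log2fc_is_difference_of_means(self):
        meta = _three_group_meta(2)
        data = pd.DataFrame(
            {"monolayer2D_0": [2.0], "monolayer2D_1": [2.0],
             "spheroid_0": [3.5], "spheroid_1": [3.5],
             "xenograft_0": [2.2], "xenograft_1": [1.8]},
            index=["g1"],
        )
        m = ExpressionMatrix(data, feature_level="gene")
        spec = FilterSpec(0.9, 0.1, "monolayer2D", ["spheroid", "xenograft"])
        res = anova_filter(m, meta, spec)
        assert res.table.loc["g1", "log2FC_spheroid_vs_monolayer2D"] == pytest.approx(1.5)
        assert res.table.loc["g1", "log2FC_xenograft_vs_monolayer2D"] == pytest.approx(0.0)

    def test_bh_hand_example(self):
        q = brute_force_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_bh_matches_brute_force_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(3, 40))
            np.testing.assert_allclose(
                multipletests(p, method="fdr_bh")[1], brute_force_bh(p), atol=1e-12
            )

    def test_small_group_is_error(self):
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": ["a", "b", "c"], "cell_line": ["CL"] * 3,
            "model_system": ["monolayer2D", "monolayer2D", "spheroid"],
        }))
        m = ExpressionMatrix(
            pd.DataFrame(np.ones((2, 3)), index=["g1", "g2"],
                         columns=["a", "b", "c"]),
            feature_level="gene",
        )
        spec = FilterSpec(0.05, 1.0, "monolayer2D", ["spheroid"])
        with pytest.raises(ValueError, match="spheroid"):
            anova_filter(m, meta, spec)

    def test_passing_set_shrinks_with_stricter_lfc(self):
        matrix, meta, _ = simulate_model_systems(ModelSystemSpec(seed=2))
        loose = FilterSpec(0.01, 1.5, "monolayer2D", ["spheroid", "xenograft"])
        strict = FilterSpec(0.01, 2.0, "monolayer2D", ["spheroid", "xenograft"])
        n_loose = len(anova_filter(matrix, meta, loose).passing)
        n_strict = len(anova_filter(matrix, meta, strict).passing)
        assert n_strict < n_loose
        assert set(anova_filter(matrix, meta, strict).passing) <= set(
            anova_filter(matrix, meta, loose).passing
        )


class TestPatternClassify:
    def _matrix_from_means(self, means: dict[str, tuple[float, float, float]]):
        meta = _three_group_meta(1)
        data = {
            "monolayer2D_0": {g: v[0] for g, v in means.items()},
            "spheroid_0": {g: v[1] for g, v in means.items()},
            "xenograft_0": {g: v[2] for g, v in means.items()},
        }
        m = ExpressionMatrix(pd.DataFrame(data), feature_level="gene")
        return m, meta

    @pytest.mark.parametrize(
        "mu,expected",
        [
            ((1.0, 2.0, 3.1), "increasing"),
            ((1.0, 2.0, 2.1), "increase_then_plateau"),
            ((3.0, 2.0, 1.0), "decreasing"),
            ((3.0, 2.0, 2.1), "decrease_then_plateau"),
            ((1.0, 1.1, 1.0), "none"),
        ],
    )
    def test_rule_application(self, mu, expected):
        m, meta = self._matrix_from_means({"g1": mu, "g2": (0.0, 5.0, 9.0)})
        res = pattern_classify(m, meta, delta=0.25)
        assert res.loc["g1", "category"] == expected

    def test_planted_fixture_counts_recovered_exactly(self):
        spec = ModelSystemSpec(sigma=1e-12, marker_log2fc=None, seed=0)
        matrix, meta, truth = simulate_model_systems(spec)
        res = pattern_classify(matrix, meta, delta=0.25)
        counts = res["category"].value_counts()
        assert counts["increasing"] == 64
        assert counts["decreasing"] == 25
        assert counts["increase_then_plateau"] == 3
        assert counts["decrease_then_plateau"] == 18
        assert counts["none"] == 42
        assert (res["category"] == truth).all()
        assert res.attrs["characteristic_fraction"] == pytest.approx(110 / 152)

    def test_missing_model_system_is_error(self):
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": ["a", "b"], "cell_line": ["CL"] * 2,
            "model_system": ["monolayer2D", "spheroid"],
        }))
        m = ExpressionMatrix(
            pd.DataFrame(np.ones((2, 2)), index=["g1", "g2"], columns=["a", "b"]),
            feature_level="gene",
        )
        with pytest.raises(ValueError, match="xenograft"):
            pattern_classify(m, meta)


class TestModelSimilarity:
    @pytest.mark.parametrize(
        "x,y,r",
        [((1, 2, 3), (2, 4, 6), 1.0), ((1, 2, 3), (3, 2, 1), -1.0),
         ((1, 2, 3), (1, 3, 2), 0.5)],
    )
    def test_hand_pearson(self, x, y, r):
        from scipy.stats import pearsonr

        assert pearsonr(x, y)[0] == pytest.approx(r)

    def test_planted_spheroid_closer_structure(self):
        matrix, meta, _ = simulate_model_systems(ModelSystemSpec(seed=4))
        genes = [g for g in matrix.feature_ids if g != "MARKER"]
        report = model_similarity(matrix, meta, genes=genes)
        assert (report["closer_to_xenograft"] == "spheroid").all()
        assert report["r_spheroid_xenograft"].between(-1, 1).all()


class TestHierarchicalCluster:
    def test_identical_pair_merges_first(self):
        data = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [9.0, 1.0, 4.0]},
            index=["g1", "g2", "g3"],
        )
        m = ExpressionMatrix(data, feature_level="gene")
        res = hierarchical_cluster(m, distance="euclidean")
        first = res.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}  # a and b
        assert first[2] == pytest.approx(0.0)

    def test_hand_agglomeration_1d(self):
        data = pd.DataFrame(
            {"a": [0.0], "b": [1.0], "c": [10.0], "d": [11.0]}, index=["g"]
        )
        m = ExpressionMatrix(data, feature_level="gene")
        res = hierarchical_cluster(m, distance="euclidean", linkage_method="average")
        heights = res.linkage[:, 2]
        np.testing.assert_allclose(heights, [1.0, 1.0, 10.0])

    def test_newick_contains_all_leaves(self, small_matrix):
        res = hierarchical_cluster(small_matrix)
        assert res.newick.endswith(";")
        for sid in small_matrix.sample_ids:
            assert sid in res.newick

    def test_leaf_order_deterministic(self, small_matrix):
        a = hierarchical_cluster(small_matrix).leaf_order
        b = hierarchical_cluster(small_matrix).leaf_order
        assert a == b


class TestMarkers:
    def _fixture(self):
        rows = []
        for g, grp in [("r0", "resistant"), ("r1", "resistant"),
                       ("s0", "sensitive"), ("s1", "sensitive")]:
            rows.append({"sample_id": g, "cell_line": g, "model_system": "xenograft",
                         "group": grp})
        meta = SampleMetadata(pd.DataFrame(rows))
        rng = np.random.default_rng(9)
        data = pd.DataFrame(
            rng.normal(7, 0.3, (20, 4)),
            index=[f"g{i:02d}" for i in range(20)], columns=["r0", "r1", "s0", "s1"],
        )
        data.loc["CAV1"] = [15.64, 15.64, 7.0, 7.0]  # +8.64 log2 in resistant
        return ExpressionMatrix(data, feature_level="gene"), meta

    def test_planted_marker_ranked_first_with_400x_fold(self):
        m, meta = self._fixture()
        table = rank_two_group_markers(m, meta, "resistant", "sensitive")
        assert table.index[0] == "CAV1"
        assert table.loc["CAV1", "log2FC"] == pytest.approx(8.64)
        assert table.loc["CAV1", "fold"] == pytest.approx(2 ** 8.64, rel=1e-9)
        assert table.loc["CAV1", "fold"] == pytest.approx(398.93, abs=0.05)

    def test_group_swap_negates_log2fc(self):
        m, meta = self._fixture()
        ab = rank_two_group_markers(m, meta, "resistant", "sensitive")
        ba = rank_two_group_markers(m, meta, "sensitive", "resistant")
        np.testing.assert_allclose(
            ab["log2FC"].sort_index(), -ba["log2FC"].sort_index(), atol=1e-12
        )

    def test_all_equal_ties_broken_by_gene_id(self):
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": ["a", "b"], "cell_line": ["x", "y"],
            "model_system": ["xenograft"] * 2, "group": ["A", "B"],
        }))
        data = pd.DataFrame({"a": [1.0, 1.0], "b": [1.0, 1.0]}, index=["g2", "g1"])
        m = ExpressionMatrix(data, feature_level="gene")
        table = rank_two_group_markers(m, meta, "A", "B")
        assert (table["log2FC"] == 0).all()
        assert list(table.index) == ["g1", "g2"]

    def test_empty_group_is_error(self):
        m, meta = self._fixture()
        with pytest.raises(ValueError, match="empty"):
            rank_two_group_markers(m, meta, "resistant", "nonexistent")
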