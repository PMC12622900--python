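"""Distances, Ward dendrograms, Newick serialisation, plot data."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from conet.clustering import (Dendrogram, DistanceMatrix,
                              dendrogram_from_newick, dendrogram_to_newick,
                              highlight_genes, sample_distances,
                              scatter_data, volcano_data, ward_dendrogram)
from conet.errors import ConfigError
from conet.go_scoring import GoAnnotation
from conftest import make_design, make_matrix


def dist_from_points(points, labels=None):
    points = np.asarray(points, dtype=float)
    labels = labels or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(labels=labels,
                          values=squareform(pdist(points)))


def naive_ward_oracle(points):
    """Independent oracle: agglomerate by the minimum increase in total
    within-cluster sum of squares, recomputed from raw coordinates at
    every step; the merge height is sqrt(2 * delta ESS)."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            pa, pb = points[clusters[a]], points[clusters[b]]
            na, nb = len(pa), len(pb)
            delta = (na * nb / (na + nb)) * np.sum(
                (pa.mean(axis=0) - pb.mean(axis=0)) ** 2)
            if best is None or delta < best[0] - 1e-12:
                best = (delta, a, b)
        delta, a, b = best
        merges.append((a, b, np.sqrt(2 * delta),
                       len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return np.array(merges)


class TestSampleDistances:
    def test_identical_columns_zero_distance(self):
        mat = make_matrix(np.tile([[3.0], [4.0]], (1, 6)))
        assert sample_distances(mat).values.max() == 0.0

    def test_three_four_five(self):
        meta = make_design().iloc[[0, 2]].reset_index(drop=True)
        data = pd.DataFrame([[0.0, 3.0], [0.0, 4.0]],
                            index=["g0", "g1"],
                            columns=list(meta["sample_id"]))
        from conet.expression import ExpressionMatrix
        mat = ExpressionMatrix(data=data, meta=meta)
        assert sample_distances(mat).values[0, 1] == 5.0

    def test_matches_per_gene_sum_oracle(self, rng):
        mat = make_matrix(rng.uniform(0, 100, size=(100, 6)))
        dist = sample_distances(mat)
        vals = mat.data.to_numpy()
        for i in range(6):
            for j in range(6):
                oracle = np.sqrt(np.sum((vals[:, i] - vals[:, j]) ** 2))
                assert dist.values[i, j] == pytest.approx(oracle, rel=1e-12)

    def test_fewer_than_two_samples_rejected(self):
        df = pd.DataFrame({"s": [1.0, 2.0]})
        with pytest.raises(ConfigError):
            sample_distances(df)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ConfigError, match="symmetric"):
            DistanceMatrix(labels=["a", "b"],
                           values=np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_triangle_inequality_on_random_data(self, rng):
        mat = make_matrix(rng.uniform(0, 50, size=(40, 6)))
        d = sample_distances(mat).values
        for i, j, k in itertools.permutations(range(6), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestWardDendrogram:
    def test_two_samples_single_merge(self):
        dist = DistanceMatrix(labels=["a", "b"],
                              values=np.array([[0.0, 5.0], [5.0, 0.0]]))
        tree = ward_dendrogram(dist)
        assert tree.merges.shape == (1, 4)
        assert tree.merges[0, 2] == 5.0
        assert tree.merges[0, 3] == 2

    def test_nearest_pair_merges_first(self):
        dist = dist_from_points([[0.0], [1.0], [10.0]])
        tree = ward_dendrogram(dist)
        assert sorted(tree.merges[0, :2]) == [0, 1]
        assert tree.merges[0, 2] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_variance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        points = rng.normal(size=(6, 3))
        tree = ward_dendrogram(dist_from_points(points))
        oracle = naive_ward_oracle(points)
        np.testing.assert_array_equal(tree.merges[:, :2], oracle[:, :2])
        np.testing.assert_allclose(tree.merges[:, 2], oracle[:, 2],
                                   rtol=1e-9)
        np.testing.assert_array_equal(tree.merges[:, 3], oracle[:, 3])

    @pytest.mark.parametrize("n", [4, 6, 9])
    def test_matches_scipy_ward_linkage(self, n):
        rng = np.random.default_rng(n)
        points = rng.normal(size=(n, 4))
        tree = ward_dendrogram(dist_from_points(points))
        z = linkage(pdist(points), method="ward")
        np.testing.assert_allclose(
            np.sort(tree.merges[:, 2]), np.sort(z[:, 2]), rtol=1e-9)
        np.testing.assert_allclose(
            np.sort(tree.merges[:, :2], axis=1), np.sort(z[:, :2], axis=1))

    def test_heights_monotone_on_random_instances(self):
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            tree = ward_dendrogram(
                dist_from_points(rng.normal(size=(7, 5))))
            assert (np.diff(tree.merges[:, 2]) >= -1e-12).all()

    def test_duplicate_samples_merge_first_at_zero(self, rng):
        points = rng.normal(size=(5, 3))
        points[3] = points[1]
        tree = ward_dendrogram(dist_from_points(points))
        assert sorted(tree.merges[0, :2]) == [1, 3]
        assert tree.merges[0, 2] == 0.0


class TestNewick:
    def test_single_merge_half_height_convention(self):
        tree = Dendrogram(labels=["A", "B"],
                          merges=np.array([[0, 1, 2.0, 2]]))
        assert dendrogram_to_newick(tree) == "(A:1,B:1):0;"

    def test_empty_tree_rejected(self):
        tree = Dendrogram(labels=[], merges=np.zeros((0, 4)))
        with pytest.raises(ConfigError):
            dendrogram_to_newick(tree)

    def _canonical(self, tree):
        members = tree.cluster_members()
        n = tree.n_leaves
        return sorted((round(h, 9), members[n + m])
                      for m, (_l, _r, h, _s) in enumerate(tree.merges))

    @pytest.mark.parametrize("n", [3, 6])
    def test_round_trip_preserves_topology_and_heights(self, n):
        rng = np.random.default_rng(n)
        labels = [f"L{i}" for i in range(n)]
        tree = ward_dendrogram(
            dist_from_points(rng.normal(size=(n, 3)), labels=labels))
        back = dendrogram_from_newick(dendrogram_to_newick(tree))
        assert self._canonical(back) == self._canonical(tree)
        np.testing.assert_allclose(np.sort(back.heights),
                                   np.sort(tree.heights), atol=1e-9)


class TestScatterData:
    def test_identical_groups_on_diagonal(self, rng):
        vals = rng.uniform(1, 100, size=(20, 6))
        vals[:, 2:4] = vals[:, 4:6]
        mat = make_matrix(vals)
        plot = scatter_data(mat, ["PhaC_1", "PhaC_2"],
                            ["PhaBC_1", "PhaBC_2"])
        np.testing.assert_allclose(plot.frame["x"], plot.frame["y"])

    def test_doubled_gene_sits_on_guide_line(self, rng):
        vals = np.tile(rng.uniform(1, 100, size=(10, 1)), (1, 6))
        vals[4, 4:6] *= 2.0
        mat = make_matrix(vals)
        plot = scatter_data(mat, ["PhaC_1", "PhaC_2"],
                            ["PhaBC_1", "PhaBC_2"], fc_lines=[2.0])
        row = plot.frame.iloc[4]
        assert row["y"] == pytest.approx(2.0 * row["x"], rel=1e-12)

    def test_group_mean_oracle(self, rng):
        mat = make_matrix(rng.uniform(1, 100, size=(15, 6)))
        gx, gy = ["VC_1", "VC_2"], ["PhaC_1", "PhaBC_1"]
        plot = scatter_data(mat, gx, gy)
        np.testing.assert_allclose(plot.frame["x"],
                                   mat.data[gx].to_numpy().mean(axis=1))
        np.testing.assert_allclose(plot.frame["y"],
                                   mat.data[gy].to_numpy().mean(axis=1))

    def test_overlapping_groups_rejected(self, rng):
        mat = make_matrix(rng.uniform(1, 10, size=(5, 6)))
        with pytest.raises(ConfigError, match="overlap"):
            scatter_data(mat, ["VC_1"], ["VC_1", "PhaC_1"])


class TestVolcanoData:
    def test_null_gene_at_origin_with_p_one(self):
        mat = make_matrix([[7, 7, 7, 7, 7, 7]])
        row = volcano_data(mat).frame.iloc[0]
        assert row["x"] == 0.0
        assert row["p_value"] == 1.0
        assert row["y"] == 0.0

    def test_zero_variance_nonzero_mean_gets_sentinel(self):
        mat = make_matrix([[10, 10, 20, 20, 20, 20]])
        row = volcano_data(mat).frame.iloc[0]
        assert row["p_value"] == np.finfo(float).tiny
        assert bool(row["degenerate"])

    def test_t_statistic_matches_closed_form(self, rng):
        mat = make_matrix(rng.uniform(10, 100, size=(30, 6)))
        frame = volcano_data(mat).frame
        data = mat.data.to_numpy()
        control_mean = data[:, :2].mean(axis=1)
        logr = np.log2(data[:, 2:] / control_mean[:, None])
        m, sd = logr.mean(axis=1), logr.std(axis=1, ddof=1)
        t = m / (sd / 2.0)  # n = 4 treatment arrays
        from scipy import stats
        p = 2 * stats.t.sf(np.abs(t), df=3)
        np.testing.assert_allclose(frame["p_value"], p, rtol=1e-12)
        np.testing.assert_allclose(
            frame["x"], np.log2((data[:, 2:] / control_mean[:, None])
                                .mean(axis=1)), rtol=1e-12)


class TestHighlightGenes:
    def test_exactly_members_flagged(self, rng):
        mat = make_matrix(rng.uniform(1, 10, size=(6, 6)),
                          genes=[f"g{i}" for i in range(6)])
        ann = GoAnnotation([("g1", "T"), ("g3", "T"), ("g5", "U")])
        plot = scatter_data(mat, ["VC_1", "VC_2"], ["PhaC_1", "PhaC_2"])
        flagged = highlight_genes(plot, ann, "T")
        assert set(flagged.frame.index[flagged.frame["highlight"]]) == \
            {"g1", "g3"}

    def test_unknown_term_lists_near_matches(self, rng):
        mat = make_matrix(rng.uniform(1, 10, size=(3, 6)))
        ann = GoAnnotation([("g0", "GO:0000123")])
        plot = scatter_data(mat, ["VC_1"], ["PhaC_1"])
        with pytest.raises(KeyError, match="GO:0000123"):
            highlight_genes(plot, ann, "GO:0000124")

    def test_term_with_no_plotted_member_flags_nothing(self, rng):
        mat = make_matrix(rng.uniform(1, 10, size=(3, 6)))
        ann = GoAnnotation([("absent", "T")])
        plot = scatter_data(mat, ["VC_1"], ["PhaC_1"])
        assert highlight_genes(plot, ann, "T").frame["highlight"].sum() == 0
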