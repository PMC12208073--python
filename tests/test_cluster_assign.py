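"""kNN imputation, cosine/Ward clustering, t-test splitting, assignment."""

import numpy as np
import pytest

from snacs.core_io import GenotypeMatrix, HashExpression, SnacsConfig, MULTIPLET, NO_CALL
from snacs.cluster_assign import (assign_clusters_to_hashes, cluster_verdict,
                                  cut_and_split, hierarchical_cluster,
                                  impute_missing_knn)
from snacs.hash_model import BackgroundModel


def _matrix(values):
    values = np.asarray(values, dtype=float)
    return GenotypeMatrix([f"c{i}" for i in range(values.shape[0])],
                          [f"s{j}" for j in range(values.shape[1])], values)


def _fixed_model(hash_id, q95, q75=None):
    """Background whose empirical quantiles are pinned for testing."""
    # a point mass at q95 makes every percentile equal q95; for distinct
    # percentiles interpolate a linear ramp ending at q95
    if q75 is None:
        sample = np.full(100, q95)
    else:
        sample = np.linspace(2 * q75 - q95, q95, 101)  # q(75) ~ q75, q(100)=q95
    return BackgroundModel(hash_id, 0.0, sample, 1.0, 2)


class TestImputation:
    def test_no_missing_identity(self):
        G = _matrix([[0, 1], [1, 0], [1, 1]])
        out, filtered = impute_missing_knn(G)
        np.testing.assert_array_equal(out.values, G.values)
        assert filtered == []

    def test_majority_vote_of_forced_neighbors(self):
        # c0 misses s0; its 5 nearest neighbours c1..c5 (identical elsewhere)
        # carry [1,1,1,0,0] there; c6+ are far away
        vals = np.array([
            [np.nan, 1, 1, 1, 0],
            [1,      1, 1, 1, 0],
            [1,      1, 1, 1, 0],
            [1,      1, 1, 1, 0],
            [0,      1, 1, 1, 0],
            [0,      1, 1, 1, 0],
            [0,      0, 0, 0, 1],
            [0,      0, 0, 0, 1],
        ], dtype=float)
        out, _ = impute_missing_knn(_matrix(vals))
        assert out.values[0, 0] == 1.0

    def test_tie_vote_imputes_wildtype(self):
        # neighbours' values at the missing SNP: [1,1,0,0,missing] -> 2-2 -> 0
        vals = np.array([
            [np.nan, 1, 1, 1, 0],
            [1,      1, 1, 1, 0],
            [1,      1, 1, 1, 0],
            [0,      1, 1, 1, 0],
            [0,      1, 1, 1, 0],
            [np.nan, 1, 1, 1, 0],
            [1,      0, 0, 0, 1],
        ], dtype=float)
        out, _ = impute_missing_knn(_matrix(vals))
        assert out.values[0, 0] == 0.0

    def test_cell_missing_all_panel_snps_filtered(self):
        vals = np.array([[np.nan, np.nan], [0, 1], [1, 0], [0, 0]], dtype=float)
        out, filtered = impute_missing_knn(_matrix(vals))
        assert filtered == ["c0"]
        assert out.cell_ids == ["c1", "c2", "c3"]
        assert not np.isnan(out.values).any()


class TestHierarchicalCluster:
    def test_orthogonal_blocks_split_exactly(self):
        vals = np.zeros((40, 6))
        vals[:20, :3] = 1
        vals[20:, 3:] = 1
        tree = hierarchical_cluster(_matrix(vals))
        E = HashExpression([f"c{i}" for i in range(40)], ["h"],
                           np.zeros((40, 1)))
        A = cut_and_split(tree, 2, E)
        parts = [set(idx) for idx in A.clusters.values()]
        assert sorted(map(len, parts)) == [20, 20]
        assert set(range(20)) in parts

    def test_duplicate_rows_merge_at_height_zero(self):
        vals = np.array([[1, 0, 1], [1, 0, 1], [0, 1, 0]], dtype=float)
        tree = hierarchical_cluster(_matrix(vals))
        assert tree.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_merge_heights_nondecreasing_random(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            vals = (rng.random((50, 10)) < 0.5).astype(float)
            tree = hierarchical_cluster(_matrix(vals))
            heights = tree.linkage[:, 2]
            assert (np.diff(heights) >= -1e-10).all()

    def test_all_zero_row_gets_maximal_distance(self):
        vals = np.array([[0, 0, 0], [1, 1, 0], [1, 1, 0]], dtype=float)
        tree = hierarchical_cluster(_matrix(vals))  # must not raise / NaN
        assert np.isfinite(tree.linkage).all()


class TestCutAndSplit:
    def _planted(self, seed=0, n_each=30, delta=5.0):
        """Three populations, one hiding inside another's genotype cluster.

        Populations 1a and 1b share the main genotype block (so the n=2 cut
        merges them) but differ in one minor SNP — the structure a doublet
        population leaves — and strongly in hash h2; the t-test split must
        recover all three.
        """
        rng = np.random.default_rng(seed)
        g1a = np.tile([1, 1, 0, 0, 0], (n_each, 1)).astype(float)
        g1b = np.tile([1, 1, 0, 0, 1], (n_each, 1)).astype(float)
        g2 = np.tile([0, 0, 1, 1, 0], (n_each, 1)).astype(float)
        vals = np.vstack([g1a, g1b, g2])
        n = vals.shape[0]
        hashes = np.zeros((n, 2))
        hashes[:, 0] = rng.normal(0, 1, n)
        hashes[n_each:2 * n_each, 1] = delta          # second half of genotype-1
        hashes[:, 1] += rng.normal(0, 1, n)
        G = _matrix(vals)
        E = HashExpression(G.cell_ids, ["h1", "h2"], hashes)
        return G, E, n_each

    def test_hash_split_recovers_three_populations(self):
        G, E, n_each = self._planted()
        tree = hierarchical_cluster(G)
        A = cut_and_split(tree, 2, E, SnacsConfig())
        sizes = sorted(len(v) for v in A.clusters.values())
        assert sizes == [n_each, n_each, n_each]

    def test_homogeneous_hashes_keep_exactly_n_clusters(self):
        G, E, _ = self._planted()
        flat = HashExpression(E.cell_ids, ["h1"],
                              np.random.default_rng(1).normal(0, 1, (len(E.cell_ids), 1)))
        tree = hierarchical_cluster(G)
        A = cut_and_split(tree, 2, flat, SnacsConfig())
        assert len(A.clusters) == 2

    def test_split_isolating_single_cell_rejected(self):
        # one outlier cell with huge hash value inside a cluster: a split
        # that isolates it would violate min_cluster_size
        rng = np.random.default_rng(2)
        vals = np.tile([1, 0], (20, 1)).astype(float)
        hashes = rng.normal(0, 0.1, (20, 1))
        hashes[7] = 50.0
        G = _matrix(vals)
        E = HashExpression(G.cell_ids, ["h1"], hashes)
        tree = hierarchical_cluster(G)
        A = cut_and_split(tree, 1, E, SnacsConfig())
        assert all(len(v) >= 2 for v in A.clusters.values())

    def test_n_larger_than_cells_errors(self):
        G = _matrix([[0, 1], [1, 0]])
        tree = hierarchical_cluster(G)
        E = HashExpression(G.cell_ids, ["h"], np.zeros((2, 1)))
        with pytest.raises(Exception, match="cut"):
            cut_and_split(tree, 3, E)


class TestAssignClusters:
    def test_verdict_rules(self):
        # 10-cell toy; thresholds pinned at 1.0 for both hashes
        models = {"h1": _fixed_model("h1", 1.0), "h2": _fixed_model("h2", 1.0)}
        vals = np.zeros((10, 2))
        vals[:6, 0] = 2.0      # 60% above threshold for h1 only
        verdict = cluster_verdict(vals, list(range(10)), ["h1", "h2"],
                                  models, 95, 0.5)
        assert verdict == "h1"

        vals2 = np.zeros((10, 2))
        vals2[:8, 0] = 2.0
        vals2[:7, 1] = 2.0      # 80% and 70% -> multiplet
        assert cluster_verdict(vals2, list(range(10)), ["h1", "h2"],
                               models, 95, 0.5) == MULTIPLET

        vals3 = np.zeros((10, 2))
        vals3[:5, 0] = 2.0      # exactly 50%: strict inequality -> no_call
        assert cluster_verdict(vals3, list(range(10)), ["h1", "h2"],
                               models, 95, 0.5) == NO_CALL

    def test_round1_calls_cover_all_clustered_cells(self):
        rng = np.random.default_rng(3)
        vals = np.vstack([np.tile([1, 0], (15, 1)), np.tile([0, 1], (15, 1))])
        G = _matrix(vals.astype(float))
        hashes = np.zeros((30, 2))
        hashes[:15, 0] = 3.0
        hashes[15:, 1] = 3.0
        hashes += rng.normal(0, 0.2, (30, 2))
        E = HashExpression(G.cell_ids, ["h1", "h2"], hashes)
        models = {"h1": _fixed_model("h1", 1.0), "h2": _fixed_model("h2", 1.0)}
        tree = hierarchical_cluster(G)
        A = cut_and_split(tree, 2, E)
        calls = assign_clusters_to_hashes(A, E, models)
        assert {c.cell_id for c in calls} == set(G.cell_ids)
        by_cell = {c.cell_id: c.label for c in calls}
        assert all(by_cell[f"c{i}"] == "h1" for i in range(15))
        assert all(by_cell[f"c{i}"] == "h2" for i in range(15, 30))
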