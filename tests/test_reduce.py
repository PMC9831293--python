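import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats
from sklearn.metrics import silhouette_score

from cyclegate import (
    CellByFeatureMatrix,
    Embedding,
    ValidationError,
    cluster_cells,
    iterative_lsi,
    order_trajectory,
    smooth_over_pseudotime,
    tfidf,
)


def counts(X, prefix="c"):
    X = np.asarray(X)
    return CellByFeatureMatrix(
        [f"{prefix}{i}" for i in range(X.shape[0])],
        [f"f{j}" for j in range(X.shape[1])],
        sp.csr_matrix(X),
    )


class TestTfidf:
    def test_idf_closed_form(self):
        m = counts([[1, 0], [2, 0], [3, 0]])
        out = tfidf(m).X.toarray()
        idf = np.log(1 + 3 / 4)  # feature present in every cell
        assert out[0, 0] == pytest.approx(1.0 * idf)

    def test_absent_feature_zero_column(self):
        m = counts([[1, 0], [2, 0]])
        assert np.all(tfidf(m).X.toarray()[:, 1] == 0)

    def test_depth_invariance(self):
        m1 = counts([[1, 2, 3], [4, 0, 1]])
        m2 = counts([[2, 4, 6], [4, 0, 1]])
        np.testing.assert_allclose(
            tfidf(m1).X.toarray()[0], tfidf(m2).X.toarray()[0], atol=1e-12
        )


class TestIterativeLsi:
    def _two_populations(self, n=120, f=60, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.poisson(0.2, size=(n, f))
        labels = np.repeat([0, 1], n // 2)
        X[labels == 0, : f // 2] += rng.poisson(3.0, size=(n // 2, f // 2))
        X[labels == 1, f // 2 :] += rng.poisson(3.0, size=(n // 2, f // 2))
        return counts(X), labels

    def test_planted_populations_separate(self):
        m, labels = self._two_populations()
        emb = iterative_lsi(m, d=5, k_clusters=2, seed=1)
        assert silhouette_score(emb.coordinates, labels) > 0.5

    def test_deterministic_given_seed(self):
        m, _ = self._two_populations(seed=3)
        a = iterative_lsi(m, d=4, seed=7).coordinates
        b = iterative_lsi(m, d=4, seed=7).coordinates
        np.testing.assert_array_equal(a, b)

    def test_d_reduced_with_warning(self):
        m = counts(np.random.default_rng(0).poisson(2, size=(6, 5)))
        with pytest.warns(UserWarning, match="reduced"):
            emb = iterative_lsi(m, d=30, n_iterations=1)
        assert emb.d == 4

    def test_cell_order_invariance(self):
        m, _ = self._two_populations(seed=5)
        emb = iterative_lsi(m, d=4, n_iterations=1, seed=2)
        perm = np.random.default_rng(1).permutation(m.shape[0])
        m2 = CellByFeatureMatrix(
            [m.barcodes[i] for i in perm], m.features, m.X[perm], kind="counts"
        )
        emb2 = iterative_lsi(m2, d=4, n_iterations=1, seed=2)
        a = pd.DataFrame(emb.coordinates, index=emb.barcodes)
        b = pd.DataFrame(emb2.coordinates, index=emb2.barcodes).loc[a.index]
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-8)


class TestClusterCells:
    def test_two_blobs_exact_recovery(self):
        """ARI vs truth = 1.0, verified with an sklearn-free exhaustive label
        matching (both assignments of cluster ids to blobs tried)."""
        rng = np.random.default_rng(2)
        pts = np.vstack(
            [rng.normal(0, 0.1, size=(40, 3)), rng.normal(5, 0.1, size=(40, 3))]
        )
        truth = np.repeat([0, 1], 40)
        emb = Embedding([f"c{i}" for i in range(80)], pts)
        labels = cluster_cells(emb, k=2, seed=0)
        matches = max(
            (labels == truth).sum(), (labels == 1 - truth).sum()
        )
        assert matches == 80

    def test_k_one_rejected(self):
        emb = Embedding(["a", "b"], np.zeros((2, 2)))
        with pytest.raises(ValidationError):
            cluster_cells(emb, k=1)

    def test_k_exceeding_cells_rejected(self):
        emb = Embedding(["a", "b"], np.zeros((2, 2)))
        with pytest.raises(ValidationError):
            cluster_cells(emb, k=3)

    def test_duplicate_points_share_label(self):
        pts = np.array([[0.0, 0], [0, 0], [0, 0], [9, 9], [9, 9]])
        emb = Embedding([f"c{i}" for i in range(5)], pts)
        labels = cluster_cells(emb, k=2, seed=0)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1


class TestOrderTrajectory:
    def test_formula_forced_example(self):
        # k=2, centroids at 0 and 1 in 1-D; cell at 0.25 in cluster 0
        pts = np.array([[0.0], [0.25], [-0.25], [1.0], [1.25], [0.75]])
        labels = np.array([0, 0, 0, 1, 1, 1])
        emb = Embedding([f"c{i}" for i in range(6)], pts)
        traj = order_trajectory(emb, labels, [0, 1])
        assert traj.pseudotime["c1"] == pytest.approx(12.5)

    def test_cell_at_next_centroid_t_one(self):
        pts = np.array([[0.0], [1.0], [1.0], [2.0]])
        labels = np.array([0, 0, 1, 1])
        emb = Embedding(list("abcd"), pts)
        traj = order_trajectory(emb, labels, [0, 1])
        # cell 'b' sits exactly at centroid of cluster 1... projection t
        c0, c1 = 0.5, 1.5
        t = (1.0 - c0) / (c1 - c0)
        assert traj.segment_t["b"] == pytest.approx(t)
        # a cell exactly at the next centroid projects to t = 1
        pts2 = np.array([[0.0], [1.5], [1.0], [2.0]])
        emb2 = Embedding(list("abcd"), pts2)
        traj2 = order_trajectory(emb2, labels, [0, 1])
        assert traj2.segment_t["b"] == pytest.approx(1.0)

    def test_monotone_chain_spearman_one(self):
        # constructed so at most one cell per cluster clips to t=0: the
        # pseudotime ordering then matches the line coordinate exactly
        x = np.array([0.0, 2.0, 3.0, 5.0, 6.0, 8.0])
        labels = np.array([0, 0, 1, 1, 2, 2])
        emb = Embedding([f"c{i}" for i in range(6)], x[:, None])
        traj = order_trajectory(emb, labels, [0, 1, 2])
        rho = stats.spearmanr(traj.pseudotime.to_numpy(), x).statistic
        assert rho == pytest.approx(1.0)

    def test_absent_path_cluster_rejected(self):
        emb = Embedding(list("ab"), np.zeros((2, 2)))
        with pytest.raises(ValidationError):
            order_trajectory(emb, np.array([0, 0]), [0, 1])

    def test_pseudotime_bounds(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(40, 2))
        labels = rng.integers(0, 3, size=40)
        labels[:3] = [0, 1, 2]
        emb = Embedding([f"c{i}" for i in range(40)], pts)
        traj = order_trajectory(emb, labels, [0, 1, 2])
        pt = traj.pseudotime.dropna()
        assert ((pt >= 0) & (pt <= 100)).all()


class TestSmoothOverPseudotime:
    def _pt(self, values):
        return pd.Series(values, index=[f"c{i}" for i in range(len(values))])

    def test_constant_feature(self):
        pt = self._pt(np.linspace(0, 100, 20))
        vals = pd.DataFrame(np.ones((2, 20)), columns=pt.index)
        out = smooth_over_pseudotime(vals, pt, n_bins=10)
        np.testing.assert_allclose(out.to_numpy(), 1.0)

    def test_linear_feature_monotone(self):
        pt = self._pt(np.linspace(0, 100, 50))
        vals = pd.DataFrame([pt.to_numpy()], columns=pt.index)
        out = smooth_over_pseudotime(vals, pt, n_bins=20)
        assert (np.diff(out.to_numpy()[0]) >= 0).all()

    def test_single_occupied_bin_constant_extension(self):
        pt = self._pt([50.0, 50.0])
        vals = pd.DataFrame([[3.0, 5.0]], columns=pt.index)
        out = smooth_over_pseudotime(vals, pt, n_bins=10)
        np.testing.assert_allclose(out.to_numpy(), 4.0)

    def test_no_pseudotime_rejected(self):
        pt = self._pt([np.nan, np.nan])
        vals = pd.DataFrame([[1.0, 2.0]], columns=pt.index)
        with pytest.raises(ValidationError):
            smooth_over_pseudotime(vals, pt)
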