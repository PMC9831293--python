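from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

from cyclegate import (
    CellByFeatureMatrix,
    Gene,
    GenomeModel,
    ValidationError,
    bh_adjust,
    call_markers,
    cc_sensitivity,
    filter_cells_rna,
    normalize_log,
    rank_sum_test,
    summarize_cc_sensitivity,
    wilcoxon_de,
)


def norm_matrix(X, barcodes=None):
    X = np.asarray(X, dtype=float)
    return CellByFeatureMatrix(
        barcodes or [f"c{i}" for i in range(X.shape[0])],
        [f"g{j}" for j in range(X.shape[1])],
        sp.csr_matrix(X),
        kind="normalized",
    )


def permutation_oracle_ranksum(x, y):
    """Independent oracle: enumerate all group relabelings, two-sided tail of
    the rank-sum W of the first group around its permutation mean."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    mu = ranks.sum() * n1 / len(pooled)
    dev = abs(w_obs - mu)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


class TestRankSum:
    def test_enumerated_example(self):
        # A={1,2,3} vs B={4,5,6}: 2 of C(6,3)=20 assignments are as extreme
        assert rank_sum_test(np.array([1, 2, 3]), np.array([4, 5, 6])) == pytest.approx(0.1)

    def test_identical_groups(self):
        p = rank_sum_test(np.array([2.0, 2.0, 2.0]), np.array([2.0, 2.0, 2.0]))
        assert p == 1.0

    def test_exact_branch_matches_permutation_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n1, n2 = rng.integers(2, 5, size=2)
            x = rng.integers(0, 6, size=n1).astype(float)
            y = rng.integers(0, 6, size=n2).astype(float)
            assert rank_sum_test(x, y) == pytest.approx(
                permutation_oracle_ranksum(x, y), abs=1e-12
            )


class TestBhAdjust:
    def bruteforce_bh(self, p):
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        out = np.empty(m)
        prev = np.inf
        for rank_from_top in range(m, 0, -1):
            i = order[rank_from_top - 1]
            val = min(prev, p[i] * m / rank_from_top)
            out[i] = val
            prev = val
        return np.minimum(out, 1.0)

    def test_hand_computed_examples(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        np.testing.assert_allclose(bh_adjust([0.04, 0.5]), [0.08, 0.5])
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_matches_bruteforce_on_grid(self):
        grid = [0.001, 0.01, 0.04, 0.2, 0.5, 1.0]
        rng = np.random.default_rng(0)
        for _ in range(200):
            k = rng.integers(1, 7)
            p = rng.choice(grid, size=k)
            np.testing.assert_allclose(bh_adjust(p), self.bruteforce_bh(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.1, 1.5])

    def test_fdr_at_least_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=40)
        assert (bh_adjust(p) >= p - 1e-12).all()


class TestWilcoxonDe:
    def test_identical_groups_null_result(self):
        X = np.tile([[1.0, 2.0, 0.0]], (6, 1))
        m = norm_matrix(X)
        de = wilcoxon_de(m, ["c0", "c1", "c2"], ["c3", "c4", "c5"])
        assert (de.p_value == 1.0).all()
        np.testing.assert_allclose(de.log2fc, 0.0, atol=1e-12)

    def test_label_swap_negates_log2fc_preserves_p(self):
        rng = np.random.default_rng(3)
        m = norm_matrix(rng.uniform(0, 4, size=(30, 8)))
        a = [f"c{i}" for i in range(15)]
        b = [f"c{i}" for i in range(15, 30)]
        de1 = wilcoxon_de(m, a, b)
        de2 = wilcoxon_de(m, b, a)
        np.testing.assert_allclose(de1.log2fc, -de2.log2fc, atol=1e-10)
        np.testing.assert_allclose(de1.p_value, de2.p_value, atol=1e-10)

    def test_overlapping_groups_rejected(self):
        m = norm_matrix(np.zeros((4, 2)))
        with pytest.raises(ValidationError):
            wilcoxon_de(m, ["c0", "c1"], ["c1", "c2"])

    def test_small_group_rejected(self):
        m = norm_matrix(np.zeros((4, 2)))
        with pytest.raises(ValidationError):
            wilcoxon_de(m, ["c0"], ["c1", "c2"])

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, size=(60, 3))
        X[:30, 0] += 3.0
        m = norm_matrix(X)
        de = wilcoxon_de(m, [f"c{i}" for i in range(30)], [f"c{i}" for i in range(30, 60)])
        assert de.p_value[0] < 1e-6 and de.log2fc[0] > 1
        assert de.p_value[1] > 0.01


class TestCallMarkers:
    def _matrix(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 0.5, size=(200, 5))
        labels = np.repeat([0, 1], 100)
        X[labels == 1, 0] += 4.0  # feature g0 exclusive to cluster 1
        return norm_matrix(X), labels

    def test_planted_marker_found(self):
        m, labels = self._matrix()
        markers = call_markers(m, labels)
        assert markers["1"].feature_id.tolist() == ["g0"]
        assert "g0" not in markers["0"].feature_id.tolist()

    def test_uniform_feature_no_marker(self):
        m, labels = self._matrix()
        markers = call_markers(m, labels)
        for df in markers.values():
            assert "g3" not in df.feature_id.tolist()

    def test_infinite_threshold_empty(self):
        m, labels = self._matrix()
        markers = call_markers(m, labels, log2fc_min=np.inf)
        assert all(len(df) == 0 for df in markers.values())

    def test_single_cluster_rejected(self):
        m, _ = self._matrix()
        with pytest.raises(ValidationError):
            call_markers(m, np.zeros(200))


class TestFilterCellsRna:
    def _matrix(self, mito_counts, other_per_feature, n_features):
        genome = GenomeModel(
            [("chr1", 10_000)],
            [Gene(f"g{j}", "chr1", "+", j * 10, j * 10, j * 10 + 5) for j in range(400)],
            mito_gene_ids=frozenset({"g0"}),
        )
        row = np.zeros(400)
        row[0] = mito_counts
        row[1:n_features] = other_per_feature
        m = CellByFeatureMatrix(
            ["cell"], [f"g{j}" for j in range(400)], sp.csr_matrix(row[None, :])
        )
        return m, genome

    @pytest.mark.parametrize(
        "mito,per,nfeat,kept",
        [
            (359, 10, 250, False),  # 359/2849 = 12.601% mito: just over
            (199, 7, 200, True),  # exactly 12.5% mito, exactly 200 features
            (0, 1, 199, False),  # too few detected features
        ],
    )
    def test_boundaries(self, mito, per, nfeat, kept):
        m, genome = self._matrix(mito, per, nfeat)
        assert (filter_cells_rna(m, genome) == ["cell"]) is kept


class TestCcSensitivity:
    def _matrix_with_phases(self, profile, n_per_phase=30, noise=0.05, seed=0):
        """One gene following `profile` (G1, S, G2M log2 means) plus null genes."""
        rng = np.random.default_rng(seed)
        phases = ["G1"] * n_per_phase + ["S"] * n_per_phase + ["G2M"] * n_per_phase
        mean_of = dict(zip(["G1", "S", "G2M"], profile))
        X = rng.uniform(1.0, 1.2, size=(3 * n_per_phase, 4))
        X[:, 0] = [mean_of[p] + rng.normal(0, noise) for p in phases]
        m = norm_matrix(np.clip(X, 0, None))
        return m, pd.Series(phases, index=m.barcodes)

    def test_g2m_biased_gene(self):
        # elevated only in G2M: z ~ (-0.7, -0.6, +1.3), largest |z| in G2M
        m, phases = self._matrix_with_phases([1.0, 1.1, 3.0])
        calls = cc_sensitivity(m, phases).set_index("gene_id")
        assert bool(calls.loc["g0", "sensitive"])
        assert calls.loc["g0", "biased_phase"] == "G2M"

    def test_weak_ratios_insensitive(self):
        m, phases = self._matrix_with_phases([1.0, 1.05, 1.1], noise=0.02)
        calls = cc_sensitivity(m, phases, fc_min=1.3).set_index("gene_id")
        assert not calls.loc["g0", "sensitive"]
        assert calls.loc["g0", "biased_phase"] == "none"

    def test_s_biased_gene(self):
        m, phases = self._matrix_with_phases([1.0, 3.0, 1.05])
        calls = cc_sensitivity(m, phases).set_index("gene_id")
        assert calls.loc["g0", "biased_phase"] == "S"

    def test_z_rule_most_deviant_phase(self):
        """The biased phase is where the z-scaled phase mean deviates most:
        a phase-specific elevation points to that phase, a phase-specific
        depression also points to the depressed phase."""
        up = np.array([1.0, 1.0, 3.0])  # G2M-only elevation
        z = (up - up.mean()) / up.std()
        assert np.argmax(np.abs(z)) == 2
        down = np.array([3.0, 3.0, 1.0])  # G2M-only depression
        z = (down - down.mean()) / down.std()
        assert np.argmax(np.abs(z)) == 2

    def test_missing_phase_group_rejected(self):
        m = norm_matrix(np.ones((4, 2)))
        phases = pd.Series(["G1", "G1", "S", "S"], index=m.barcodes)
        with pytest.raises(ValidationError):
            cc_sensitivity(m, phases)


class TestSummarize:
    def _calls(self):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(10)],
                "sensitive": [True] * 7 + [False] * 3,
                "biased_phase": ["G1"] * 4 + ["S"] * 2 + ["G2M"] + ["none"] * 3,
            }
        )

    def test_panel_fraction(self):
        s = summarize_cc_sensitivity(self._calls(), [f"g{i}" for i in range(10)])
        assert s["sensitive_pct"] == 70.0
        assert s["bias_G1_pct"] == 40.0

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValidationError):
            summarize_cc_sensitivity(self._calls(), ["nope"])
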