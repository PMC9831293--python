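from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from cyclegate import (
    ValidationError,
    count_insertions,
    filter_cells_atac,
    gene_scores,
    make_union_peakset,
    tss_enrichment_scores,
)
from tests.conftest import make_fragments


def peaks_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])


class TestUnionPeakset:
    def test_greedy_iteration_hand_example(self):
        """A (score 5) kills overlapping B; C survives untouched."""
        pk = peaks_df(
            [("chr1", 100, 601, 5.0), ("chr1", 400, 901, 3.0), ("chr1", 1000, 1501, 1.0)]
        )
        out = make_union_peakset([pk], width=501)
        assert out.start.tolist() == [100, 1000]
        assert out.score.tolist() == [5.0, 1.0]

    def test_non_overlapping_input_unchanged(self):
        pk = peaks_df([("chr1", 0, 501, 1.0), ("chr1", 1000, 1501, 2.0)])
        out = make_union_peakset([pk], width=501)
        assert out.start.tolist() == [0, 1000]

    def test_equal_scores_leftmost_vs_bruteforce(self):
        """Tie-break keeps the leftmost peak; the greedy result must match
        the maximum-cardinality non-overlapping selection found by brute
        force over all subsets (<= 10 peaks, fixed width)."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            starts = np.sort(rng.integers(300, 3000, size=8))
            pk = peaks_df([("chr1", int(s), int(s) + 501, 1.0) for s in starts])
            out = make_union_peakset([pk], width=501)
            centers = ((pk.start + pk.end) // 2).to_numpy()
            s2 = centers - 250
            best = 0
            for r in range(1, 9):
                for sub in combinations(range(8), r):
                    sel = np.sort(s2[list(sub)])
                    if np.all(np.diff(sel) >= 501):
                        best = max(best, r)
            assert len(out) == best
            # leftmost preference: first kept peak is the leftmost input peak
            assert out.start.min() == s2.min()

    def test_order_invariance_distinct_scores(self):
        rng = np.random.default_rng(11)
        starts = rng.integers(0, 5000, size=12)
        scores = rng.permutation(np.arange(12)) + 1.0
        pk = peaks_df(
            [("chr1", int(s), int(s) + 501, float(sc)) for s, sc in zip(starts, scores)]
        )
        a = make_union_peakset([pk], width=501)
        b = make_union_peakset([pk.sample(frac=1, random_state=4)], width=501)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_input(self):
        assert len(make_union_peakset([], width=501)) == 0

    def test_recenters_to_width(self):
        pk = peaks_df([("chr1", 1000, 1100, 1.0)])
        out = make_union_peakset([pk], width=501)
        assert (out.end - out.start).tolist() == [501]
        assert out.start.tolist() == [1050 - 250]


class TestCountInsertions:
    def test_both_insertions_inside(self):
        frags = make_fragments([("chr1", 100, 200, "A", 1)])
        pk = peaks_df([("chr1", 50, 551, 0.0)])
        m = count_insertions(frags, pk)
        assert m.X.toarray().tolist() == [[2]]

    def test_one_insertion_inside(self):
        frags = make_fragments([("chr1", 100, 700, "A", 1)])
        pk = peaks_df([("chr1", 50, 551, 0.0)])
        m = count_insertions(frags, pk)
        assert m.X.toarray().tolist() == [[1]]

    def test_duplicate_count_weighting(self):
        frags = make_fragments([("chr1", 100, 200, "A", 3)])
        pk = peaks_df([("chr1", 50, 551, 0.0)])
        assert count_insertions(frags, pk).X.toarray().tolist() == [[6]]

    def test_conservation_bound(self):
        rng = np.random.default_rng(0)
        frags = make_fragments(
            [
                ("chr1", int(s), int(s) + int(l), f"bc{rng.integers(5)}", int(c))
                for s, l, c in zip(
                    rng.integers(0, 10_000, 300),
                    rng.integers(50, 400, 300),
                    rng.integers(1, 4, 300),
                )
            ]
        )
        pk = peaks_df([("chr1", i * 1000, i * 1000 + 501, 0.0) for i in range(10)])
        m = count_insertions(frags, pk)
        assert m.X.sum() <= 2 * frags["count"].sum()

    def test_equals_bruteforce_scan(self):
        """Vectorized counting must agree with a per-insertion O(F x P) scan."""
        rng = np.random.default_rng(7)
        n = 2000
        frags = make_fragments(
            [
                (rng.choice(["chr1", "chr2"]), int(s), int(s) + int(l), f"bc{rng.integers(8)}", 1)
                for s, l in zip(rng.integers(0, 20_000, n), rng.integers(30, 500, n))
            ]
        )
        pk = pd.concat(
            [
                peaks_df([(c, i * 2000 + 300, i * 2000 + 801, 0.0) for i in range(10)])
                for c in ("chr1", "chr2")
            ],
            ignore_index=True,
        )
        m = count_insertions(frags, pk)
        brute = np.zeros(m.shape)
        bc_i = {b: i for i, b in enumerate(m.barcodes)}
        pk_list = list(
            pk.sort_values(["chrom", "start"]).itertuples(index=False)
        )
        for f in frags.itertuples(index=False):
            for pos in (f.start, f.end - 1):
                for j, p in enumerate(pk_list):
                    if p.chrom == f.chrom and p.start <= pos < p.end:
                        brute[bc_i[f.barcode], j] += f.count
        np.testing.assert_array_equal(m.X.toarray(), brute)

    def test_overlapping_peaks_rejected(self):
        frags = make_fragments([("chr1", 100, 200, "A", 1)])
        pk = peaks_df([("chr1", 0, 501, 0.0), ("chr1", 400, 901, 0.0)])
        with pytest.raises(ValidationError):
            count_insertions(frags, pk)


class TestTssEnrichment:
    def test_uniform_insertions_near_one(self, tiny_genome):
        rng = np.random.default_rng(1)
        n = 50_000
        starts = rng.integers(0, 99_000, size=n)
        frags = make_fragments(
            [("chr1", int(s), int(s) + 100, "A", 1) for s in starts]
        )
        qc = tss_enrichment_scores(frags, tiny_genome)
        assert qc.tss_enrichment.iloc[0] == pytest.approx(1.0, abs=0.35)

    def test_all_insertions_at_tss_hit_cap(self, tiny_genome):
        frags = make_fragments([("chr1", 10_000, 10_020, "A", 1)] * 50)
        qc = tss_enrichment_scores(frags, tiny_genome)
        assert qc.tss_enrichment.iloc[0] == 100.0

    def test_zero_fragment_barcode(self, tiny_genome):
        frags = make_fragments([("chr1", 10_000, 10_020, "A", 1)])
        qc = tss_enrichment_scores(frags, tiny_genome, barcodes=["A", "B"])
        row = qc.set_index("barcode").loc["B"]
        assert row.tss_enrichment == 0.0 and not row.passed

    def test_no_genes_rejected(self):
        from cyclegate import GenomeModel

        frags = make_fragments([("chr1", 10, 20, "A", 1)])
        with pytest.raises(ValidationError):
            tss_enrichment_scores(frags, GenomeModel([("chr1", 1000)], []))


class TestFilterCellsAtac:
    @pytest.mark.parametrize(
        "tss,frags,kept",
        [
            (3.9, 5000, False),  # enrichment below threshold
            (4.0, 1000, True),  # boundary inclusive on both axes
            (10.0, 999, False),  # too few fragments
        ],
    )
    def test_boundaries(self, tss, frags, kept):
        qc = pd.DataFrame(
            {"barcode": ["A"], "n_fragments": [frags], "tss_enrichment": [tss]}
        )
        assert (filter_cells_atac(qc) == ["A"]) is kept


class TestGeneScores:
    def test_single_insertion_single_window(self, tiny_genome):
        frags = make_fragments([("chr1", 12_000, 12_100, "A", 1)])
        m = gene_scores(frags, tiny_genome)
        row = dict(zip(m.features, m.X.toarray()[0]))
        assert row["gA"] == 2 and row["gB"] == 0 and row["gM"] == 0

    def test_minus_strand_upstream_direction(self, tiny_genome):
        # gB: '-' strand, body 35k-40k, upstream extension to 42k
        frags = make_fragments([("chr1", 41_000, 41_050, "A", 1)])
        m = gene_scores(frags, tiny_genome)
        assert dict(zip(m.features, m.X.toarray()[0]))["gB"] == 2
        # beyond the 2 kb upstream margin: not counted
        frags2 = make_fragments([("chr1", 42_500, 42_550, "A", 1)])
        m2 = gene_scores(frags2, tiny_genome)
        assert m2.X.sum() == 0

    def test_overlapping_windows_double_count_vs_bruteforce(self):
        from cyclegate import Gene, GenomeModel

        genome = GenomeModel(
            [("chr1", 50_000)],
            [
                Gene("g1", "chr1", "+", 10_000, 10_000, 20_000),
                Gene("g2", "chr1", "+", 15_000, 15_000, 25_000),
            ],
        )
        rng = np.random.default_rng(3)
        frags = make_fragments(
            [
                ("chr1", int(s), int(s) + 80, f"bc{rng.integers(3)}", 1)
                for s in rng.integers(0, 49_000, 500)
            ]
        )
        m = gene_scores(frags, genome)
        windows = {"g1": (8000, 20_000), "g2": (13_000, 25_000)}
        brute = np.zeros(m.shape)
        bc_i = {b: i for i, b in enumerate(m.barcodes)}
        for f in frags.itertuples(index=False):
            for pos in (f.start, f.end - 1):
                for j, g in enumerate(m.features):
                    lo, hi = windows[g]
                    if lo <= pos < hi:
                        brute[bc_i[f.barcode], j] += 1
        np.testing.assert_array_equal(m.X.toarray(), brute)


def test_high_tss_factor_cells_enriched():
    """Monotonicity: cells simulated with TSS insertion enrichment score far
    above background-only expectation."""
    from cyclegate import SimulationConfig, simulate_experiment, tss_enrichment_scores

    cfg = SimulationConfig(
        seed=8, n_cells={"M0": 30, "M1": 0, "M2": 0, "M2p": 0, "M1rep": 0},
        n_peaks=400, n_genes=200, n_coaccessible_pairs=10,
    )
    sim = simulate_experiment(cfg)
    qc = tss_enrichment_scores(sim.fragments["M0"], sim.genome)
    lo_cfg = SimulationConfig(
        seed=8, n_cells={"M0": 30, "M1": 0, "M2": 0, "M2p": 0, "M1rep": 0},
        n_peaks=400, n_genes=200, n_coaccessible_pairs=10,
        tss_insertion_enrichment_factor=1.0,
    )
    lo = simulate_experiment(lo_cfg)
    qc_lo = tss_enrichment_scores(lo.fragments["M0"], lo.genome)
    assert qc.tss_enrichment.median() > qc_lo.tss_enrichment.median() + 2
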