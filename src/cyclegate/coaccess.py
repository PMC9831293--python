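"""Cell-aggregate peak co-accessibility and peak-to-gene annotation.

Co-accessibility is the Pearson correlation of two peaks' accessibility
across low-overlapping aggregates of embedding neighbors, restricted to
same-chromosome peak pairs whose centers are within a 250 kb window.  A peak
is linked to a gene when it lies within 250 kb of the gene's TSS and is
co-accessible (correlation above a cutoff) with one of the gene's promoter
peaks (peaks overlapping TSS +/- 1 kb).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .io import CellByFeatureMatrix, GenomeModel, ValidationError
from .reduce import Embedding


@dataclass(frozen=True)
class CoAccessPair:
    peak_i: str
    peak_j: str
    distance: int
    correlation: float


@dataclass(frozen=True)
class GeneLink:
    gene_id: str
    peak_id: str
    promoter_peak_id: str
    distance_to_tss: int
    correlation: float


def default_n_aggregates(n_cells: int, n_per_aggregate: int) -> int:
    """Candidate seed count before overlap filtering."""
    return int(min(100, max(2, n_cells / n_per_aggregate * 5)))


def make_aggregates(
    embedding: Embedding,
    counts: CellByFeatureMatrix,
    n_per_aggregate: int = 500,
    max_overlap_fraction: float = 0.8,
    n_aggregates: int | None = None,
    seed: int = 0,
) -> tuple[CellByFeatureMatrix, list[np.ndarray]]:
    """Build low-overlapping cell aggregates from embedding neighborhoods.

    Each aggregate is a seed cell's ``n_per_aggregate`` nearest neighbors
    (including itself); candidates whose membership overlaps an already
    accepted aggregate by more than ``max_overlap_fraction`` are discarded.
    Seeds are visited in a seeded random order until ``n_aggregates`` are
    accepted or candidates run out.  Aggregate profile = summed counts of
    member cells.  Raises when fewer than 2 aggregates can be formed.
    """
    if counts.barcodes != embedding.barcodes:
        raise ValidationError("embedding and counts must share barcode order")
    n_cells = len(embedding.barcodes)
    if n_per_aggregate > n_cells:
        raise ValidationError("n_per_aggregate exceeds number of cells")
    if n_aggregates is None:
        n_aggregates = default_n_aggregates(n_cells, n_per_aggregate)

    nn = NearestNeighbors(n_neighbors=n_per_aggregate).fit(embedding.coordinates)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_cells)
    accepted: list[np.ndarray] = []
    accepted_sets: list[set[int]] = []
    max_shared = int(max_overlap_fraction * n_per_aggregate)
    for seed_cell in order:
        if len(accepted) >= n_aggregates:
            break
        members = nn.kneighbors(
            embedding.coordinates[seed_cell : seed_cell + 1], return_distance=False
        )[0]
        mset = set(members.tolist())
        if any(len(mset & prev) > max_shared for prev in accepted_sets):
            continue
        accepted.append(np.sort(members))
        accepted_sets.append(mset)
    if len(accepted) < 2:
        raise ValidationError("could not form >= 2 low-overlapping aggregates")

    profiles = np.vstack(
        [np.asarray(counts.X[m].sum(axis=0)).ravel() for m in accepted]
    )
    agg = CellByFeatureMatrix(
        [f"agg_{i:03d}" for i in range(len(accepted))],
        list(counts.features),
        sp.csr_matrix(profiles),
        kind="counts",
    )
    return agg, accepted


def coaccessibility(
    aggregates: CellByFeatureMatrix,
    peaks: pd.DataFrame,
    window: int = 250_000,
) -> pd.DataFrame:
    """Pearson co-accessibility of same-chromosome peak pairs within
    ``window`` bp (center-to-center).

    Aggregate profiles are depth-normalized by their genome-wide column sums
    and log2(1 + x) transformed before correlating.  Zero-variance peaks get
    correlation 0 with ``undefined=True``.  Pairs are stored once with
    peak_i left of peak_j.
    """
    if aggregates.shape[0] < 3:
        raise ValidationError("need >= 3 aggregates for co-accessibility")
    peaks = peaks.reset_index(drop=True)
    pid = peaks["peak_id"].to_numpy()
    if set(pid) != set(aggregates.features):
        raise ValidationError("peak table does not match aggregate matrix features")

    X = aggregates.X.toarray().astype(float)
    totals = X.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    Xn = np.log2(1.0 + 1e4 * X / totals)
    # reorder columns to the peak table's order
    col_of = {f: i for i, f in enumerate(aggregates.features)}
    Xn = Xn[:, [col_of[p] for p in pid]]

    mu = Xn.mean(axis=0)
    sd = Xn.std(axis=0)
    undefined = sd == 0
    Z = (Xn - mu) / np.where(undefined, 1.0, sd)
    n = Xn.shape[0]

    centers = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    rows = []
    for chrom in peaks["chrom"].unique():
        sel = np.flatnonzero((peaks["chrom"] == chrom).to_numpy())
        order = sel[np.argsort(centers[sel], kind="mergesort")]
        c = centers[order]
        hi = np.searchsorted(c, c + window, side="right")
        for a_pos, a in enumerate(order):
            for b_pos in range(a_pos + 1, hi[a_pos]):
                b = order[b_pos]
                dist = int(abs(c[b_pos] - c[a_pos]))
                if undefined[a] or undefined[b]:
                    r, und = 0.0, True
                else:
                    r, und = float(Z[:, a] @ Z[:, b] / n), False
                rows.append((pid[a], pid[b], dist, r, und))
    return pd.DataFrame(
        rows, columns=["peak_i", "peak_j", "distance", "correlation", "undefined"]
    )


def link_peaks_to_genes(
    pairs: pd.DataFrame,
    peaks: pd.DataFrame,
    genome: GenomeModel,
    min_correlation: float = 0.45,
    promoter_window: int = 1000,
    link_window: int = 250_000,
) -> pd.DataFrame:
    """Annotate peaks to putative target genes through promoter
    co-accessibility.

    A gene's promoter peaks are those overlapping TSS +/- ``promoter_window``
    bp.  Any other peak whose center lies within ``link_window`` of the TSS
    is linked iff it forms a co-accessibility pair with a promoter peak at
    correlation >= ``min_correlation``.  Genes without promoter peaks simply
    yield no links.
    """
    peaks = peaks.reset_index(drop=True)
    centers = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    corr = {}
    for r in pairs.itertuples(index=False):
        corr[(r.peak_i, r.peak_j)] = r.correlation
        corr[(r.peak_j, r.peak_i)] = r.correlation

    links = []
    gt = genome.gene_table()
    for chrom, genes_sub in gt.groupby("chrom"):
        sel = np.flatnonzero((peaks["chrom"] == chrom).to_numpy())
        if not len(sel):
            continue
        order = sel[np.argsort(centers[sel], kind="mergesort")]
        c = centers[order]
        starts = peaks["start"].to_numpy()[order]
        ends = peaks["end"].to_numpy()[order]
        ids = peaks["peak_id"].to_numpy()[order]
        for g in genes_sub.itertuples(index=False):
            prom_mask = (starts <= g.tss + promoter_window) & (
                ends > g.tss - promoter_window
            )
            promoters = ids[prom_mask]
            if not len(promoters):
                continue
            lo = np.searchsorted(c, g.tss - link_window, side="left")
            hi = np.searchsorted(c, g.tss + link_window, side="right")
            for k in range(lo, hi):
                peak = ids[k]
                if peak in promoters:
                    continue
                best = None
                for prom in promoters:
                    r = corr.get((peak, prom))
                    if r is not None and r >= min_correlation:
                        if best is None or r > best[1]:
                            best = (prom, r)
                if best is not None:
                    links.append(
                        (g.gene_id, peak, best[0], int(c[k] - g.tss), best[1])
                    )
    return pd.DataFrame(
        links,
        columns=["gene_id", "peak_id", "promoter_peak_id", "distance_to_tss", "correlation"],
    )
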