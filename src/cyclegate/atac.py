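"""Fragment-level ATAC computation: union peak set, Tn5 insertion counting,
TSS-enrichment QC, and gene activity scores.

Every fragment contributes two insertion sites (start and end - 1), each
weighted by the fragment's duplicate count.  All "less than X" QC filters keep
values equal to X (inclusive boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CellByFeatureMatrix, GenomeModel, ValidationError


@dataclass(frozen=True)
class QCRecord:
    barcode: str
    n_fragments: int
    tss_enrichment: float
    passed: bool


# ---------------------------------------------------------------------------
# union peak set
# ---------------------------------------------------------------------------


def make_union_peakset(peak_lists: list[pd.DataFrame], width: int = 501) -> pd.DataFrame:
    """Iteratively merge per-sample peak calls into one non-overlapping set.

    All peaks are first re-centered to the fixed ``width`` around their
    midpoint.  Retention is greedy by descending score: keep the
    highest-scoring peak, discard everything overlapping it, repeat.  Ties are
    broken towards the leftmost (chrom name, then start) peak.  Output is
    sorted by coordinate with ids ``chrom:start-end``.
    """
    frames = [df for df in peak_lists if len(df)]
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "score", "peak_id"])
    allp = pd.concat(frames, ignore_index=True).copy()
    if "score" not in allp.columns:
        allp["score"] = 0.0
    half = width // 2
    centers = (allp["start"].to_numpy() + allp["end"].to_numpy()) // 2
    allp["start"] = centers - half
    allp["end"] = centers - half + width
    if (allp["start"] < 0).any():
        raise ValidationError("re-centered peak extends below position 0")

    allp = allp.sort_values(
        ["score", "chrom", "start"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    kept_rows = []
    kept_by_chrom: dict[str, list[int]] = {}
    for row in allp.itertuples(index=False):
        starts = kept_by_chrom.setdefault(row.chrom, [])
        # fixed width: overlap iff |start difference| < width
        lo = np.searchsorted(starts, row.start - width + 1)
        hi = np.searchsorted(starts, row.start + width)
        if lo != hi:
            continue
        starts.insert(int(lo), row.start)
        kept_rows.append((row.chrom, int(row.start), int(row.end), float(row.score)))
    out = pd.DataFrame(kept_rows, columns=["chrom", "start", "end", "score"])
    out = out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    out["peak_id"] = [f"{c}:{s}-{e}" for c, s, e in zip(out.chrom, out.start, out.end)]
    return out


def _check_non_overlapping(peaks: pd.DataFrame) -> None:
    for _, sub in peaks.groupby("chrom"):
        s = sub.sort_values("start")
        if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
            raise ValidationError("peaks must be non-overlapping")


# ---------------------------------------------------------------------------
# insertion counting
# ---------------------------------------------------------------------------


def _insertions(fragments: pd.DataFrame) -> pd.DataFrame:
    """Expand fragments into their two insertion sites with weights."""
    a = fragments[["chrom", "start", "barcode", "count"]].rename(columns={"start": "pos"})
    b = fragments[["chrom", "end", "barcode", "count"]].rename(columns={"end": "pos"})
    b["pos"] = b["pos"] - 1
    return pd.concat([a, b], ignore_index=True)


def count_insertions(
    fragments: pd.DataFrame,
    peaks: pd.DataFrame,
    barcodes: list[str] | None = None,
) -> CellByFeatureMatrix:
    """Cells x peaks matrix of Tn5 insertions falling inside each peak.

    ``peaks`` must be non-overlapping (precondition error otherwise); each
    fragment contributes its start and end-1 positions, weighted by ``count``.
    """
    _check_non_overlapping(peaks)
    peaks = peaks.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    if "peak_id" not in peaks.columns:
        peaks = peaks.copy()
        peaks["peak_id"] = [
            f"{c}:{s}-{e}" for c, s, e in zip(peaks.chrom, peaks.start, peaks.end)
        ]
    if barcodes is None:
        barcodes = sorted(fragments["barcode"].unique())
    bc_codes = pd.Categorical(fragments["barcode"], categories=barcodes)
    ins = _insertions(
        fragments.assign(_bc=bc_codes.codes)[
            ["chrom", "start", "end", "_bc", "count"]
        ].rename(columns={"_bc": "barcode"})
    )
    ins = ins[ins["barcode"] >= 0]

    n_cells, n_peaks = len(barcodes), len(peaks)
    rows, cols, vals = [], [], []
    for chrom, sub in ins.groupby("chrom", sort=False):
        pk = peaks[peaks.chrom == chrom]
        if not len(pk):
            continue
        starts = pk["start"].to_numpy()
        ends = pk["end"].to_numpy()
        offsets = pk.index.to_numpy()
        pos = sub["pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        rows.append(sub["barcode"].to_numpy()[ok])
        cols.append(offsets[idx[ok]])
        vals.append(sub["count"].to_numpy()[ok])
    if rows:
        X = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_cells, n_peaks),
        ).tocsr()
    else:
        X = sp.csr_matrix((n_cells, n_peaks))
    return CellByFeatureMatrix(list(barcodes), peaks["peak_id"].tolist(), X, kind="counts")


# ---------------------------------------------------------------------------
# TSS enrichment QC
# ---------------------------------------------------------------------------


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Merge sorted [start, end) intervals (n x 2)."""
    if not len(iv):
        return iv
    iv = iv[np.argsort(iv[:, 0])]
    merged = [iv[0].tolist()]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged)


def _count_in_windows(pos: np.ndarray, windows: np.ndarray) -> np.ndarray:
    """Boolean mask of positions inside any window; windows merged/sorted."""
    if not len(windows):
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(windows[:, 0], pos, side="right") - 1
    return (idx >= 0) & (pos < windows[np.clip(idx, 0, None), 1])


def tss_enrichment_scores(
    fragments: pd.DataFrame,
    genome: GenomeModel,
    center_halfwidth: int = 50,
    flank: tuple[int, int] = (1901, 2000),
    cap: float = 100.0,
    min_tss: float = 4.0,
    min_fragments: int = 1000,
    barcodes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-barcode TSS enrichment: insertion rate per bp within +/-50 bp of
    any TSS over the rate in distal flank windows (1901-2000 bp on both
    sides), floored to avoid division by zero and capped at ``cap``.

    Returns a DataFrame (barcode, n_fragments, tss_enrichment, passed) using
    inclusive thresholds ``min_tss`` / ``min_fragments``.
    """
    if not genome.genes:
        raise ValidationError("genome has no genes; cannot compute TSS enrichment")
    center_w, flank_w = {}, {}
    gt = genome.gene_table()
    for chrom, sub in gt.groupby("chrom"):
        t = sub["tss"].to_numpy()
        center = np.stack([t - center_halfwidth, t + center_halfwidth + 1], axis=1)
        fl = np.concatenate(
            [
                np.stack([t - flank[1], t - flank[0] + 1], axis=1),
                np.stack([t + flank[0], t + flank[1] + 1], axis=1),
            ]
        )
        center_w[chrom] = _merge_intervals(np.clip(center, 0, None))
        flank_w[chrom] = _merge_intervals(np.clip(fl, 0, None))
    center_bp = sum((w[:, 1] - w[:, 0]).sum() for w in center_w.values())
    flank_bp = sum((w[:, 1] - w[:, 0]).sum() for w in flank_w.values())

    ins = _insertions(fragments)
    in_center = np.zeros(len(ins), dtype=bool)
    in_flank = np.zeros(len(ins), dtype=bool)
    for chrom, sub in ins.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        loc = sub.index.to_numpy()
        if chrom in center_w:
            in_center[loc] = _count_in_windows(pos, center_w[chrom])
            in_flank[loc] = _count_in_windows(pos, flank_w[chrom])

    w = ins["count"].to_numpy().astype(float)
    df = pd.DataFrame(
        {
            "barcode": ins["barcode"].to_numpy(),
            "w": w,
            "center": w * in_center,
            "flank": w * in_flank,
        }
    )
    agg = df.groupby("barcode", sort=True).sum()
    frag_counts = fragments.groupby("barcode", sort=True)["count"].sum()
    agg["n_fragments"] = frag_counts.reindex(agg.index).fillna(0).astype(int)
    center_rate = agg["center"] / center_bp
    flank_rate = agg["flank"] / flank_bp
    floor = 1e-9
    enrichment = np.minimum(cap, center_rate / np.maximum(flank_rate, floor))
    enrichment[(agg["center"] == 0) & (agg["flank"] == 0)] = 0.0
    out = pd.DataFrame(
        {
            "barcode": agg.index,
            "n_fragments": agg["n_fragments"].to_numpy(),
            "tss_enrichment": enrichment.to_numpy(),
        }
    )
    if barcodes is not None:
        # barcodes without any fragments: enrichment 0, not passed
        out = (
            out.set_index("barcode")
            .reindex(barcodes)
            .fillna({"n_fragments": 0, "tss_enrichment": 0.0})
            .astype({"n_fragments": int})
            .reset_index()
        )
    out["passed"] = (out["tss_enrichment"] >= min_tss) & (out["n_fragments"] >= min_fragments)
    return out.reset_index(drop=True)


def filter_cells_atac(
    qc: pd.DataFrame, min_tss: float = 4.0, min_fragments: int = 1000
) -> list[str]:
    """Keep barcodes with tss_enrichment >= min_tss and n_fragments >=
    min_fragments (boundaries inclusive)."""
    keep = (qc["tss_enrichment"] >= min_tss) & (qc["n_fragments"] >= min_fragments)
    return qc.loc[keep, "barcode"].tolist()


# ---------------------------------------------------------------------------
# gene scores
# ---------------------------------------------------------------------------


def gene_scores(
    fragments: pd.DataFrame,
    genome: GenomeModel,
    upstream_bp: int = 2000,
    downstream_bp: int = 0,
    barcodes: list[str] | None = None,
) -> CellByFeatureMatrix:
    """Cells x genes matrix of summed Tn5 insertions in gene windows.

    The window is the gene body extended ``upstream_bp`` upstream of the TSS
    (strand-aware; on '-' genes this extends to larger genomic coordinates)
    and ``downstream_bp`` past the other end.  Overlapping gene windows each
    count shared insertions: no splitting, uniform weighting.
    """
    gt = genome.gene_table()
    win_start = np.where(
        gt.strand == "+", gt.start - upstream_bp, gt.start - downstream_bp
    )
    win_end = np.where(gt.strand == "+", gt.end + downstream_bp, gt.end + upstream_bp)
    win_start = np.clip(win_start, 0, None)

    if barcodes is None:
        barcodes = sorted(fragments["barcode"].unique())
    bc_index = {b: i for i, b in enumerate(barcodes)}
    ins = _insertions(fragments)
    ins = ins[ins["barcode"].isin(bc_index)]

    n_cells, n_genes = len(barcodes), len(gt)
    rows, cols, vals = [], [], []
    for chrom, sub in ins.groupby("chrom", sort=False):
        gsel = np.flatnonzero((gt.chrom == chrom).to_numpy())
        if not len(gsel):
            continue
        order = np.argsort(sub["pos"].to_numpy(), kind="mergesort")
        pos = sub["pos"].to_numpy()[order]
        bc = sub["barcode"].map(bc_index).to_numpy()[order]
        wt = sub["count"].to_numpy()[order]
        for gi in gsel:
            lo = np.searchsorted(pos, win_start[gi], side="left")
            hi = np.searchsorted(pos, win_end[gi], side="left")
            if hi > lo:
                rows.append(bc[lo:hi])
                cols.append(np.full(hi - lo, gi))
                vals.append(wt[lo:hi])
    if rows:
        X = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_cells, n_genes),
        ).tocsr()
    else:
        X = sp.csr_matrix((n_cells, n_genes))
    return CellByFeatureMatrix(list(barcodes), gt["gene_id"].tolist(), X, kind="counts")
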