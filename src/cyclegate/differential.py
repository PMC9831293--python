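"""Two-group differential testing, BH correction, marker calling, RNA QC, and
the cell-cycle-sensitivity / phase-bias classifier.

Conventions
-----------
* Rank tests run on the values as given (ranks are transform-invariant).
* Fold changes are computed on the depth-normalized linear scale: for a
  ``normalized`` (log2) matrix the values are back-transformed with 2^x - 1
  before averaging, and log2fc = log2((mean_a + eps) / (mean_b + eps)) with
  eps = 1 / n_cells.  The stated thresholds (e.g. Log2FC >= 1 meaning a 2x
  change) refer to this count-scale fold change.
* Exact rank-sum p-values are enumerated over group assignments (tie-safe via
  midranks) when both groups have <= 8 observations; larger problems use the
  tie-corrected normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CellByFeatureMatrix, GenomeModel, ValidationError, delog

EXACT_MAX_PER_GROUP = 8
PHASES = ("G1", "S", "G2M")


@dataclass(frozen=True)
class DifferentialRecord:
    feature_id: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    log2fc: float
    p_value: float
    fdr: float


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by enumeration of group assignments.

    Statistic: U of the first group from midranks.  p = P(|U' - n1*n2/2| >=
    |U - n1*n2/2|) over all C(n1+n2, n1) equally likely assignments (the U
    distribution is symmetric under exchangeability, ties included).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    ranks = _midranks(np.concatenate([x, y]))
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    dev = abs(u_obs - mu)
    total = 0
    hits = 0
    rank_total = ranks.sum()
    for idx in combinations(range(n1 + n2), n1):
        total += 1
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        if abs(u - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p: exact enumeration when both groups are small
    (<= 8), tie-corrected normal approximation otherwise."""
    if len(x) <= EXACT_MAX_PER_GROUP and len(y) <= EXACT_MAX_PER_GROUP:
        return exact_rank_sum_p(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def _dense(matrix: CellByFeatureMatrix, rows: np.ndarray) -> np.ndarray:
    X = matrix.X[rows]
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def wilcoxon_de(
    matrix: CellByFeatureMatrix,
    cells_a,
    cells_b,
    group_a: str = "a",
    group_b: str = "b",
) -> pd.DataFrame:
    """Per-feature two-group comparison (a vs b).

    Returns a DataFrame with feature_id, mean_a, mean_b (linear normalized
    means), log2fc, p_value and BH fdr across features.  Groups must be
    disjoint and have >= 2 cells each.
    """
    idx = matrix.barcode_index()
    rows_a = np.array([idx[b] for b in cells_a])
    rows_b = np.array([idx[b] for b in cells_b])
    if len(rows_a) < 2 or len(rows_b) < 2:
        raise ValidationError("both groups need >= 2 cells")
    if set(rows_a) & set(rows_b):
        raise ValidationError("groups overlap")

    ranks_src = matrix.X
    if matrix.kind == "normalized":
        lin = delog(matrix)
    else:
        lin = matrix.X.astype(float)
    mean_a = np.asarray(lin[rows_a].mean(axis=0)).ravel()
    mean_b = np.asarray(lin[rows_b].mean(axis=0)).ravel()
    eps = 1.0 / matrix.shape[0]
    log2fc = np.log2(mean_a + eps) - np.log2(mean_b + eps)

    xa = np.asarray(ranks_src[rows_a].todense() if sp.issparse(ranks_src) else ranks_src[rows_a])
    xb = np.asarray(ranks_src[rows_b].todense() if sp.issparse(ranks_src) else ranks_src[rows_b])
    if len(rows_a) <= EXACT_MAX_PER_GROUP and len(rows_b) <= EXACT_MAX_PER_GROUP:
        pvals = np.array(
            [exact_rank_sum_p(xa[:, j], xb[:, j]) for j in range(xa.shape[1])]
        )
    else:
        with np.errstate(all="ignore"):
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided",
                                     method="asymptotic", axis=0)
        pvals = np.asarray(res.pvalue, dtype=float)
        # constant features: identical groups -> p = 1
        const = (xa.std(axis=0) == 0) & (xb.std(axis=0) == 0) & (
            xa[0] == xb[0]
        )
        pvals = np.where(const, 1.0, pvals)
        pvals = np.nan_to_num(pvals, nan=1.0)
    out = pd.DataFrame(
        {
            "feature_id": matrix.features,
            "group_a": group_a,
            "group_b": group_b,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "p_value": pvals,
        }
    )
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# BH correction
# ---------------------------------------------------------------------------


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# signed-rank test (paired), used by the behavior profile
# ---------------------------------------------------------------------------


def signed_rank_test(x: np.ndarray, y: np.ndarray, exact_max: int = 25) -> float:
    """Two-sided Wilcoxon signed-rank p for paired samples.

    Zero differences are dropped (standard convention); if no nonzero
    differences remain the p-value is 1.  Exact enumeration over the 2^n sign
    assignments for n <= ``exact_max``, tie-corrected normal approximation
    beyond.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = _midranks(np.abs(d))
    w_pos = ranks[d > 0].sum()
    mu = n * (n + 1) / 4
    if n <= exact_max:
        # distribution of W+ over independent sign flips of the observed ranks
        dist = np.zeros(1)
        dist[0] = 1.0
        scale = 2  # work on doubled ranks so midranks stay integral
        r2 = np.round(ranks * scale).astype(int)
        total_len = int(r2.sum()) + 1
        dist = np.zeros(total_len)
        dist[0] = 1.0
        for r in r2:
            nxt = dist.copy()
            nxt[r:] += dist[: total_len - r]
            dist = nxt
        dist /= dist.sum()
        w2 = int(round(w_pos * scale))
        mu2 = r2.sum() / 2
        dev = abs(w2 - mu2)
        support = np.arange(total_len)
        return float(dist[np.abs(support - mu2) >= dev - 1e-9].sum())
    # normal approximation with tie correction
    tie_term = 0.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    z = (w_pos - mu) / sigma
    return float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# markers and RNA QC
# ---------------------------------------------------------------------------


def call_markers(
    matrix: CellByFeatureMatrix,
    labels,
    fdr_max: float = 0.01,
    log2fc_min: float = 1.25,
) -> dict[str, pd.DataFrame]:
    """One-vs-rest rank-sum markers per cluster, thresholded on FDR and
    log2 fold change, ranked by decreasing log2fc."""
    labels = pd.Series(np.asarray(labels), index=matrix.barcodes)
    uniq = labels.unique()
    if len(uniq) < 2:
        raise ValidationError("need >= 2 clusters to call markers")
    out = {}
    for cl in sorted(uniq, key=str):
        cells_a = labels.index[labels == cl].tolist()
        cells_b = labels.index[labels != cl].tolist()
        de = wilcoxon_de(matrix, cells_a, cells_b, group_a=str(cl), group_b="rest")
        hits = de[(de.fdr <= fdr_max) & (de.log2fc >= log2fc_min)]
        out[str(cl)] = hits.sort_values("log2fc", ascending=False).reset_index(drop=True)
    return out


def filter_cells_rna(
    matrix: CellByFeatureMatrix,
    genome: GenomeModel,
    max_mito_pct: float = 12.5,
    min_features: int = 200,
) -> list[str]:
    """Keep barcodes with mito% <= max_mito_pct and >= min_features detected
    features (boundaries inclusive).  Doublet scores are out of scope."""
    if matrix.kind != "counts":
        raise ValidationError("filter_cells_rna expects raw counts")
    mito_cols = [i for i, f in enumerate(matrix.features) if f in genome.mito_gene_ids]
    totals = matrix.cell_totals().astype(float)
    mito = (
        np.asarray(matrix.X[:, mito_cols].sum(axis=1)).ravel()
        if mito_cols
        else np.zeros(len(totals))
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(totals > 0, 100.0 * mito / totals, 0.0)
    detected = np.asarray((matrix.X > 0).sum(axis=1)).ravel()
    keep = (mito_pct <= max_mito_pct) & (detected >= min_features)
    return [b for b, k in zip(matrix.barcodes, keep) if k]


# ---------------------------------------------------------------------------
# cell-cycle sensitivity
# ---------------------------------------------------------------------------


def cc_sensitivity(
    matrix: CellByFeatureMatrix,
    phases: pd.Series,
    fc_min: float = 1.3,
    padj_max: float = 0.001,
) -> pd.DataFrame:
    """Call cell-cycle-sensitive genes and their biased phase.

    Runs the rank-sum test for all three phase pairs (BH across genes within
    each pair); a gene is sensitive when any pair shows |FC| >= fc_min at
    fdr <= padj_max.  For sensitive genes the three per-phase means of the
    log2-normalized expression (a variance-stabilizing-transform proxy) are
    z-scaled and the biased phase is the one with the largest |z|.
    """
    phases = pd.Series(phases)
    groups = {ph: phases.index[phases == ph].tolist() for ph in PHASES}
    for ph, cells in groups.items():
        if len(cells) < 2:
            raise ValidationError(f"phase group {ph} has < 2 cells")

    lfc_min = np.log2(fc_min)
    sensitive = np.zeros(matrix.shape[1], dtype=bool)
    pair_tables = {}
    for a, b in (("G1", "S"), ("G1", "G2M"), ("S", "G2M")):
        de = wilcoxon_de(matrix, groups[a], groups[b], group_a=a, group_b=b)
        pair_tables[f"{a}_vs_{b}"] = de
        sensitive |= (np.abs(de.log2fc.to_numpy()) >= lfc_min) & (
            de.fdr.to_numpy() <= padj_max
        )

    idx = matrix.barcode_index()
    log_means = np.vstack(
        [
            np.asarray(matrix.X[[idx[b] for b in groups[ph]]].mean(axis=0)).ravel()
            for ph in PHASES
        ]
    )  # 3 x genes
    mu = log_means.mean(axis=0)
    sd = log_means.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (log_means - mu) / sd, 0.0)
    arg = np.argmax(np.abs(z), axis=0)
    biased = np.where(sensitive, np.array(PHASES, dtype=object)[arg], "none")
    out = pd.DataFrame(
        {
            "gene_id": matrix.features,
            "sensitive": sensitive,
            "biased_phase": biased,
            "max_abs_scaled": np.abs(z).max(axis=0),
        }
    )
    out.attrs["pair_tables"] = pair_tables
    return out


def summarize_cc_sensitivity(calls: pd.DataFrame, gene_panel) -> dict[str, float]:
    """Fraction of a gene panel called sensitive, plus per-phase bias
    fractions (percentages over the panel)."""
    panel = [g for g in gene_panel if g in set(calls.gene_id)]
    if not panel:
        raise ValidationError("gene panel shares no genes with the calls")
    sub = calls.set_index("gene_id").loc[panel]
    n = len(sub)
    out = {"n_panel": float(n), "sensitive_pct": 100.0 * sub.sensitive.mean()}
    for ph in PHASES:
        out[f"bias_{ph}_pct"] = 100.0 * (sub.biased_phase == ph).mean()
    return out
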