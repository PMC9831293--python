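"""Signature module scores and discrete cell-cycle phase assignment.

The module score of a gene signature is the mean expression of the signature
genes minus the mean of expression-matched control genes, computed per cell
on log-normalized data.  Phase calls follow the standard two-score rule: G1
when both the S and G2M scores are non-positive, otherwise the phase with the
larger score (ties above zero resolve to S, a documented convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CellByFeatureMatrix, ValidationError


@dataclass(frozen=True)
class Signature:
    name: str
    gene_ids: frozenset[str]

    def __init__(self, name: str, gene_ids) -> None:
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "gene_ids", frozenset(gene_ids))
        if not self.gene_ids:
            raise ValidationError(f"signature {name!r} is empty")


def module_score(
    matrix: CellByFeatureMatrix,
    signature: Signature,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell module score for one signature.

    Genes are ranked by dataset-average expression and cut into ``n_bins``
    equal-frequency bins; each signature gene draws ``n_ctrl`` control genes
    from its bin (without replacement when the bin is large enough, with
    replacement otherwise).  Score = mean(signature genes) - mean(control
    pool).  Deterministic given ``seed``; signature genes missing from the
    matrix are dropped with a warning.
    """
    if matrix.kind != "normalized":
        raise ValidationError("module_score expects a log-normalized matrix")
    feat_index = matrix.feature_index()
    present = [g for g in sorted(signature.gene_ids) if g in feat_index]
    missing = signature.gene_ids - set(present)
    if missing:
        warnings.warn(
            f"signature {signature.name!r}: {len(missing)} gene(s) not in matrix, dropped"
        )
    if not present:
        raise ValidationError(f"signature {signature.name!r} shares no genes with the matrix")

    rng = np.random.default_rng(seed)
    X = matrix.X
    avg = np.asarray(X.mean(axis=0)).ravel()
    order = np.argsort(avg, kind="mergesort")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    bins = (rank * n_bins) // len(order)

    sig_idx = np.array([feat_index[g] for g in present])
    ctrl_idx: list[np.ndarray] = []
    for gi in sig_idx:
        pool = np.flatnonzero(bins == bins[gi])
        if len(pool) >= n_ctrl:
            ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=False))
        else:
            ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=True))
    ctrl = np.concatenate(ctrl_idx)

    sig_mean = np.asarray(X[:, sig_idx].mean(axis=1)).ravel()
    # control pool mean keeps multiplicity (a gene drawn twice counts twice)
    ctrl_mean = np.asarray(X[:, ctrl].mean(axis=1)).ravel()
    return pd.Series(sig_mean - ctrl_mean, index=matrix.barcodes, name=signature.name)


def assign_phase(s_score, g2m_score):
    """Vectorized phase call: G1 iff both scores <= 0, else argmax (tie -> S)."""
    s = np.asarray(s_score, dtype=float)
    g = np.asarray(g2m_score, dtype=float)
    out = np.where((s <= 0) & (g <= 0), "G1", np.where(s >= g, "S", "G2M"))
    if out.ndim == 0:
        return str(out)
    return out


def score_cell_cycle(
    matrix: CellByFeatureMatrix,
    s_genes,
    g2m_genes,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Convenience wrapper: S and G2M module scores plus discrete phase call
    per barcode."""
    s = module_score(matrix, Signature("S", s_genes), n_bins, n_ctrl, seed)
    g = module_score(matrix, Signature("G2M", g2m_genes), n_bins, n_ctrl, seed + 1)
    return pd.DataFrame(
        {
            "barcode": matrix.barcodes,
            "s_score": s.to_numpy(),
            "g2m_score": g.to_numpy(),
            "phase": assign_phase(s.to_numpy(), g.to_numpy()),
        }
    )
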