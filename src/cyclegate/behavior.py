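"""Transient / memory / primed classification of polarization-induced open
chromatin regions, using the priming design (M0 -> M2 -> washout M2p).

A peak is "induced" in a condition when its condition-vs-M0 differential
shows log2FC >= 1 at FDR <= 0.01.  The four-way truth table:

    induced in M2, not in M2p  -> transient
    induced in M2 and in M2p   -> memory  (retained accessibility)
    induced only in M2p        -> primed
    otherwise                  -> unchanged

"Retained accessibility" is operationalized as significant induction in
M2p vs M0 (not M2p vs M2): the only reading that yields three disjoint
classes plus a remainder from two condition-vs-baseline contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential import signed_rank_test
from .io import CellByFeatureMatrix, ValidationError


@dataclass(frozen=True)
class BehaviorCall:
    peak_id: str
    induced_m2: bool
    induced_m2p: bool
    behavior: str


def classify_behavior(
    diff_m2_vs_m0: pd.DataFrame,
    diff_m2p_vs_m0: pd.DataFrame,
    fdr_max: float = 0.01,
    log2fc_min: float = 1.0,
) -> pd.DataFrame:
    """Classify each peak from its two condition-vs-baseline differentials.

    Both tables must cover the same peak universe (error otherwise).  Pure
    function of the two induction masks; permutation-invariant and
    idempotent.
    """
    a = diff_m2_vs_m0.set_index("feature_id")
    b = diff_m2p_vs_m0.set_index("feature_id")
    if set(a.index) != set(b.index):
        raise ValidationError("differential tables cover different peak universes")
    b = b.loc[a.index]
    ind_m2 = (a.log2fc >= log2fc_min) & (a.fdr <= fdr_max)
    ind_m2p = (b.log2fc >= log2fc_min) & (b.fdr <= fdr_max)
    behavior = np.select(
        [ind_m2 & ~ind_m2p, ind_m2 & ind_m2p, ~ind_m2 & ind_m2p],
        ["transient", "memory", "primed"],
        default="unchanged",
    )
    return pd.DataFrame(
        {
            "peak_id": a.index,
            "induced_m2": ind_m2.to_numpy(),
            "induced_m2p": ind_m2p.to_numpy(),
            "behavior": behavior,
        }
    ).reset_index(drop=True)


def behavior_accessibility_profile(
    matrix: CellByFeatureMatrix,
    labels,
    behavior_calls: pd.DataFrame,
    compare: tuple | None = None,
    min_peaks: int = 5,
) -> tuple[pd.DataFrame, dict[str, float | None]]:
    """Median normalized accessibility of each behavior class per cluster.

    For every behavior class, each peak's mean accessibility is computed per
    cluster; the table reports the median over the class's peaks.  When
    ``compare`` names two clusters, a paired Wilcoxon signed-rank test over
    the class's peaks compares them (classes with fewer than ``min_peaks``
    peaks get p = None with a warning).
    """
    labels = pd.Series(np.asarray(labels), index=matrix.barcodes)
    clusters = sorted(labels.unique(), key=str)
    feat_index = matrix.feature_index()
    calls = behavior_calls[behavior_calls.peak_id.isin(feat_index)]

    # per-cluster mean accessibility per peak
    per_cluster = {}
    for cl in clusters:
        rows = np.flatnonzero((labels == cl).to_numpy())
        per_cluster[cl] = np.asarray(matrix.X[rows].mean(axis=0)).ravel()

    med_rows = []
    pvals: dict[str, float | None] = {}
    for beh, sub in calls.groupby("behavior"):
        cols = np.array([feat_index[p] for p in sub.peak_id])
        for cl in clusters:
            med_rows.append((beh, cl, float(np.median(per_cluster[cl][cols]))))
        if compare is not None:
            ca, cb = compare
            if len(cols) < min_peaks:
                warnings.warn(f"behavior class {beh!r} has < {min_peaks} peaks; p omitted")
                pvals[beh] = None
            else:
                pvals[beh] = signed_rank_test(
                    per_cluster[ca][cols], per_cluster[cb][cols]
                )
    medians = pd.DataFrame(med_rows, columns=["behavior", "cluster", "median_accessibility"])
    return medians, pvals
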