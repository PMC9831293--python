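"""TF-IDF / iterative LSI embedding, k-means clustering, and cluster-path
pseudotime ordering."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import svds
from sklearn.cluster import KMeans

from .io import CellByFeatureMatrix, ValidationError, normalize_log


@dataclass
class Embedding:
    """Low-dimensional cell embedding with per-iteration feature metadata."""

    barcodes: list[str]
    coordinates: np.ndarray  # cells x d
    iteration_features: list[list[str]] = field(default_factory=list)

    @property
    def d(self) -> int:
        return self.coordinates.shape[1]

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if not np.isfinite(self.coordinates).all():
            raise ValidationError("embedding has non-finite entries")
        if self.coordinates.shape[0] != len(self.barcodes):
            raise ValidationError("embedding rows do not match barcodes")


@dataclass
class Trajectory:
    """Ordered cluster path with per-cell pseudotime in [0, 100]."""

    path: list[int]
    pseudotime: pd.Series  # NaN outside the path
    segment_t: pd.Series


def tfidf(matrix: CellByFeatureMatrix) -> CellByFeatureMatrix:
    """Term frequency (depth-normalized counts) times inverse document
    frequency log(1 + n_cells / (1 + n_cells with feature > 0))."""
    if matrix.kind != "counts":
        raise ValidationError(f"tfidf expects counts, got {matrix.kind!r}")
    X = matrix.X.astype(float).tocsr()
    totals = np.asarray(X.sum(axis=1)).ravel()
    inv = np.divide(1.0, totals, out=np.zeros_like(totals), where=totals > 0)
    tf = sp.diags(inv) @ X
    df_count = np.asarray((X > 0).sum(axis=0)).ravel()
    idf = np.log(1.0 + X.shape[0] / (1.0 + df_count))
    out = tf @ sp.diags(idf)
    return CellByFeatureMatrix(list(matrix.barcodes), list(matrix.features), out, kind="tfidf")


def _svd_embed(X: sp.spmatrix, d: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Truncated SVD; returns (U * S, V).  Components ordered by decreasing
    singular value; sign fixed by forcing the first nonzero loading of each
    component positive (determinism up to machine precision)."""
    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(min(X.shape))
    u, s, vt = svds(sp.csr_matrix(X), k=d, v0=v0)
    order = np.argsort(s)[::-1]
    u, s, vt = u[:, order], s[order], vt[order]
    for j in range(d):
        load = vt[j]
        nz = np.flatnonzero(np.abs(load) > 1e-12)
        if len(nz) and load[nz[0]] < 0:
            vt[j] = -load
            u[:, j] = -u[:, j]
    return u * s, vt


def iterative_lsi(
    matrix: CellByFeatureMatrix,
    d: int = 30,
    n_iterations: int = 2,
    n_top_features: int = 5000,
    k_clusters: int = 5,
    seed: int = 0,
) -> Embedding:
    """Iterative latent semantic indexing.

    Iteration 1 runs TF-IDF on the most abundant features followed by
    truncated SVD (components scaled by singular values) and a provisional
    k-means clustering; subsequent iterations re-select the features most
    variable across provisional cluster pseudo-bulk profiles and repeat the
    TF-IDF/SVD step.  Deterministic given the seed.
    """
    n_cells, n_features = matrix.shape
    limit = min(n_cells, n_features) - 1
    if d > limit:
        warnings.warn(f"d={d} exceeds matrix rank bound; reduced to {limit}")
        d = limit
    if d < 2:
        raise ValidationError("need at least 2 embedding dimensions")

    totals = np.asarray(matrix.X.sum(axis=0)).ravel()
    n_top = min(n_top_features, n_features)
    features = np.asarray(matrix.features)
    sel = np.sort(np.argsort(totals)[::-1][:n_top])
    iteration_features: list[list[str]] = []
    coords = None
    for it in range(n_iterations):
        sub = CellByFeatureMatrix(
            list(matrix.barcodes), features[sel].tolist(), matrix.X[:, sel], kind="counts"
        )
        iteration_features.append(features[sel].tolist())
        coords, _ = _svd_embed(tfidf(sub).X, d, seed)
        if it == n_iterations - 1:
            break
        labels = cluster_cells(
            Embedding(list(matrix.barcodes), coords), k=min(k_clusters, n_cells), seed=seed
        )
        # pseudo-bulk per provisional cluster, log2-normalized, variance ranking
        groups = pd.Series(labels).groupby(labels).groups
        prof = np.vstack(
            [np.asarray(matrix.X[list(ix)].sum(axis=0)).ravel() for ix in groups.values()]
        )
        pb = CellByFeatureMatrix(
            [f"cluster_{g}" for g in groups], list(matrix.features), sp.csr_matrix(prof),
            kind="counts",
        )
        logprof = normalize_log(pb).X.toarray()
        var = logprof.var(axis=0)
        sel = np.sort(np.argsort(var)[::-1][:n_top])
    return Embedding(list(matrix.barcodes), coords, iteration_features)


def cluster_cells(embedding: Embedding, k: int, seed: int = 0) -> np.ndarray:
    """Deterministic k-means (k-means++ init, fixed seed) on the embedding."""
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > len(embedding.barcodes):
        raise ValidationError("k exceeds number of cells")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    return km.fit_predict(embedding.coordinates)


def order_trajectory(
    embedding: Embedding, labels: np.ndarray, path: list[int]
) -> Trajectory:
    """Order cells along a user-defined cluster path.

    Within path cluster i (1-based), a cell's segment coordinate t is its
    scalar projection onto the vector from centroid_i to centroid_{i+1},
    clipped to [0, 1] (the last cluster reuses the preceding vector, measured
    from its own centroid).  pseudotime = 100 * (i - 1 + t) / k.
    """
    labels = np.asarray(labels)
    for c in path:
        if not (labels == c).any():
            raise ValidationError(f"path cluster {c} absent from labels")
    cents = np.vstack([embedding.coordinates[labels == c].mean(axis=0) for c in path])
    k = len(path)
    pt = np.full(len(labels), np.nan)
    tt = np.full(len(labels), np.nan)
    for i, c in enumerate(path):
        mask = labels == c
        if i < k - 1:
            origin, vec = cents[i], cents[i + 1] - cents[i]
        else:
            origin, vec = cents[i], cents[i] - cents[i - 1]
        denom = float(vec @ vec)
        if denom == 0:
            t = np.zeros(mask.sum())
        else:
            t = ((embedding.coordinates[mask] - origin) @ vec) / denom
        t = np.clip(t, 0.0, 1.0)
        tt[mask] = t
        pt[mask] = 100.0 * (i + t) / k
    idx = pd.Index(embedding.barcodes, name="barcode")
    return Trajectory(list(path), pd.Series(pt, index=idx), pd.Series(tt, index=idx))


def smooth_over_pseudotime(
    values: pd.DataFrame, pseudotime: pd.Series, n_bins: int = 100
) -> pd.DataFrame:
    """Bin per-cell values (features x cells) into equal-width pseudotime bins.

    Bin value = mean over member cells; empty interior bins are linearly
    interpolated and edge bins constant-extended.
    """
    pt = pseudotime.dropna()
    if pt.empty:
        raise ValidationError("no cells with pseudotime")
    cells = [c for c in values.columns if c in pt.index]
    if not cells:
        raise ValidationError("values share no cells with the pseudotime index")
    v = values[cells].to_numpy(dtype=float)
    t = pt.loc[cells].to_numpy()
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    bin_of = np.clip(np.digitize(t, edges) - 1, 0, n_bins - 1)
    out = np.full((v.shape[0], n_bins), np.nan)
    for b in range(n_bins):
        mask = bin_of == b
        if mask.any():
            out[:, b] = v[:, mask].mean(axis=1)
    centers = (edges[:-1] + edges[1:]) / 2
    occupied = ~np.isnan(out[0])
    if not occupied.all():
        for r in range(out.shape[0]):
            out[r] = np.interp(centers, centers[occupied], out[r, occupied])
    return pd.DataFrame(out, index=values.index, columns=centers)
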