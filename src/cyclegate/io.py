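"""Readers/writers for the standard formats the pipeline touches.

Coordinates are 0-based half-open (BED convention) throughout. Fragments are
assumed already Tn5-shifted by upstream preprocessing; no further +4/-5 offset
is applied here. Gzip is detected by file suffix.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """A record violates a domain invariant (coordinates, counts, ...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class Fragment(NamedTuple):
    """One sequenced accessibility fragment: interval + cell barcode.

    ``start`` is 0-based inclusive, ``end`` exclusive; ``count`` carries PCR
    duplicates (>= 1).
    """

    chrom: str
    start: int
    end: int
    barcode: str
    count: int = 1


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    tss: int
    start: int  # body start
    end: int  # body end (exclusive)


@dataclass
class GenomeModel:
    """Chromosome sizes plus gene annotation (TSS, body, strand).

    Invariants: gene ids unique; 0 <= tss < chromosome length;
    body start < body end; tss equals body start on '+' and body end on '-'.
    """

    chromosomes: list[tuple[str, int]]
    genes: list[Gene] = field(default_factory=list)
    mito_gene_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        sizes = dict(self.chromosomes)
        if len(sizes) != len(self.chromosomes):
            raise ValidationError("duplicate chromosome names")
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.chrom not in sizes:
                raise ValidationError(f"gene {g.gene_id}: unknown chrom {g.chrom!r}")
            if not (0 <= g.tss < sizes[g.chrom]):
                raise ValidationError(f"gene {g.gene_id}: tss out of bounds")
            if not g.start < g.end:
                raise ValidationError(f"gene {g.gene_id}: body start >= body end")
            if g.strand == "+" and g.tss != g.start:
                raise ValidationError(f"gene {g.gene_id}: '+' gene must have tss == start")
            if g.strand == "-" and g.tss != g.end:
                raise ValidationError(f"gene {g.gene_id}: '-' gene must have tss == end")
            if g.strand not in "+-":
                raise ValidationError(f"gene {g.gene_id}: bad strand {g.strand!r}")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(n for _, n in self.chromosomes)

    def gene_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g.gene_id, g.chrom, g.strand, g.tss, g.start, g.end) for g in self.genes],
            columns=["gene_id", "chrom", "strand", "tss", "start", "end"],
        )


@dataclass
class CellByFeatureMatrix:
    """Sparse cells x features matrix shared by both modalities.

    ``kind`` records the scale: raw ``counts``, depth-log ``normalized``, or
    ``tfidf``. Rows follow ``barcodes``, columns follow ``features``.
    """

    barcodes: list[str]
    features: list[str]
    X: sp.csr_matrix
    kind: str = "counts"

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        if self.X.shape != (len(self.barcodes), len(self.features)):
            raise ValidationError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.features)} features"
            )
        if self.kind == "counts":
            if self.X.nnz and (self.X.data < 0).any():
                raise ValidationError("counts matrix has negative entries")
            if self.X.nnz and np.any(self.X.data != np.round(self.X.data)):
                raise ValidationError("counts matrix has non-integer entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.X.sum(axis=1)).ravel()

    def barcode_index(self) -> dict[str, int]:
        return {b: i for i, b in enumerate(self.barcodes)}

    def feature_index(self) -> dict[str, int]:
        return {f: i for i, f in enumerate(self.features)}

    def subset_cells(self, barcodes: Sequence[str]) -> "CellByFeatureMatrix":
        idx = self.barcode_index()
        rows = [idx[b] for b in barcodes]
        return CellByFeatureMatrix(list(barcodes), list(self.features), self.X[rows], self.kind)


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "count"]


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fragments(path: str | Path, genome: GenomeModel | None = None) -> pd.DataFrame:
    """Read a fragments TSV(.gz) into a validated DataFrame.

    Columns: chrom, start, end, barcode and an optional count (default 1).
    Raises :class:`FormatError` naming the offending line for malformed rows
    and :class:`ValidationError` for coordinate-invariant violations.
    """
    path = Path(path)
    # leading full-line comments only ('#' may legitimately appear in barcodes)
    skip = 0
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#"):
                skip += 1
            else:
                break
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            skiprows=skip,
            dtype={0: str, 3: str},
            compression="gzip" if str(path).endswith(".gz") else None,
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: cannot parse fragments file: {exc}") from exc
    if df.shape[1] < 4:
        raise FormatError(f"{path}: fragments file needs >= 4 columns, got {df.shape[1]}")
    df = df.iloc[:, :5]
    if df.shape[1] == 4:
        df[4] = 1
    df.columns = FRAGMENT_COLUMNS
    for col in ("start", "end", "count"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() | (coerced != np.floor(coerced))
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise FormatError(f"{path}: line {line}: non-integer value in column {col!r}")
        df[col] = coerced.astype(np.int64)
    _validate_fragment_frame(df, genome, str(path))
    return df


def _validate_fragment_frame(df: pd.DataFrame, genome: GenomeModel | None, where: str) -> None:
    bad = (df["start"].to_numpy() < 0) | (df["start"].to_numpy() >= df["end"].to_numpy())
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 1
        raise ValidationError(f"{where}: line {line}: requires 0 <= start < end")
    if (df["count"].to_numpy() < 1).any():
        line = int(np.flatnonzero(df["count"].to_numpy() < 1)[0]) + 1
        raise ValidationError(f"{where}: line {line}: count must be >= 1")
    if genome is not None:
        sizes = genome.chrom_sizes
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in sizes:
                raise ValidationError(f"{where}: unknown chromosome {chrom!r}")
            if (sub["end"].to_numpy() > sizes[chrom]).any():
                raise ValidationError(f"{where}: fragment beyond end of {chrom}")


def iter_fragments(df: pd.DataFrame) -> Iterator[Fragment]:
    """Yield :class:`Fragment` records from a fragments DataFrame."""
    for row in df.itertuples(index=False):
        yield Fragment(row.chrom, int(row.start), int(row.end), row.barcode, int(row.count))


def write_fragments(df: pd.DataFrame, path: str | Path) -> None:
    """Write a fragments DataFrame as TSV; `.gz` suffix gzips (mtime=0 so
    identical content yields identical bytes)."""
    path = Path(path)
    text = df.to_csv(sep="\t", header=False, index=False)
    if str(path).endswith(".gz"):
        with open(path, "wb") as raw:
            with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as fh:
                fh.write(text.encode())
    else:
        path.write_text(text)


# ---------------------------------------------------------------------------
# peaks (BED)
# ---------------------------------------------------------------------------


def read_peaks_bed(path: str | Path, genome: GenomeModel | None = None) -> pd.DataFrame:
    """Read a BED file of peaks -> DataFrame(chrom, start, end, score).

    The score column is optional and defaults to 0.
    """
    path = Path(path)
    rows = []
    with _open_text(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {i}: BED needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {i}: non-integer coordinate") from exc
            score = 0.0
            if len(parts) >= 4 and parts[3] != "":
                try:
                    score = float(parts[3])
                except ValueError as exc:
                    raise FormatError(f"{path}: line {i}: non-numeric score") from exc
            if start < 0 or end < 0:
                raise ValidationError(f"{path}: line {i}: negative coordinate")
            if start >= end:
                raise ValidationError(f"{path}: line {i}: start >= end")
            rows.append((parts[0], start, end, score))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
    if genome is not None and len(df):
        sizes = genome.chrom_sizes
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in sizes:
                raise ValidationError(f"{path}: unknown chromosome {chrom!r}")
            if (sub["end"].to_numpy() > sizes[chrom]).any():
                raise ValidationError(f"{path}: peak beyond end of {chrom}")
    return df


def write_peaks_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("chrom", "start", "end", "score") if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# MatrixMarket matrix + barcodes/features TSVs
# ---------------------------------------------------------------------------


def write_matrix_mtx(matrix: CellByFeatureMatrix, directory: str | Path) -> list[Path]:
    """Write matrix.mtx + barcodes.tsv + features.tsv (rows = barcodes)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mtx = directory / "matrix.mtx"
    coo = matrix.X.tocoo()
    if matrix.kind == "counts":
        coo = coo.astype(np.int64)
    mmwrite(str(mtx), coo, comment=f"kind={matrix.kind}")
    (directory / "barcodes.tsv").write_text("".join(b + "\n" for b in matrix.barcodes))
    (directory / "features.tsv").write_text("".join(f + "\n" for f in matrix.features))
    return [mtx, directory / "barcodes.tsv", directory / "features.tsv"]


def read_matrix_mtx(directory: str | Path, kind: str = "counts") -> CellByFeatureMatrix:
    """Read matrix.mtx + barcodes.tsv + features.tsv back into a matrix.

    Raises :class:`FormatError` when the MTX header disagrees with the TSV
    lengths. Round-trips :func:`write_matrix_mtx` exactly for integer data.
    """
    directory = Path(directory)
    X = sp.csr_matrix(mmread(str(directory / "matrix.mtx")))
    barcodes = (directory / "barcodes.tsv").read_text().splitlines()
    features = (directory / "features.tsv").read_text().splitlines()
    if X.shape != (len(barcodes), len(features)):
        raise FormatError(
            f"{directory}: matrix header {X.shape} does not match "
            f"{len(barcodes)} barcodes / {len(features)} features"
        )
    return CellByFeatureMatrix(barcodes, features, X, kind=kind)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize_log(matrix: CellByFeatureMatrix, scale: float = 1e4) -> CellByFeatureMatrix:
    """Depth-normalize and log2-transform counts.

    entry = log2(1 + scale * count / cell_total); cells with zero total map to
    all-zero rows. Invariant to per-cell multiplicative depth scaling.
    """
    if matrix.kind != "counts":
        raise ValidationError(f"normalize_log expects counts, got kind={matrix.kind!r}")
    totals = matrix.cell_totals().astype(float)
    inv = np.divide(scale, totals, out=np.zeros_like(totals), where=totals > 0)
    X = matrix.X.tocsr(copy=True).astype(float)
    X = sp.diags(inv) @ X
    X.data = np.log2(1.0 + X.data)
    return CellByFeatureMatrix(list(matrix.barcodes), list(matrix.features), X, kind="normalized")


def delog(matrix: CellByFeatureMatrix) -> sp.csr_matrix:
    """Back-transform a ``normalized`` matrix to the linear depth-normalized
    scale (2^x - 1); used for fold-change computation."""
    X = matrix.X.copy().astype(float)
    X.data = np.exp2(X.data) - 1.0
    return X
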