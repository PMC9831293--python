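"""Synthetic single-cell multiome generator with planted ground truth.

Emulates the structure of a cytokine-polarization experiment on macrophages:
five conditions (resting M0, IFNG-polarized M1, IL-4-polarized M2, IL-4
primed/washed-out M2p, and IL-4-primed then IFNG-repolarized M1rep), three
latent cell-cycle phases per condition, phase-biased polarization genes, and
open-chromatin regions with transient / memory / primed dynamics.  Every
simulated feature carries a truth label so each analysis stage can be tested
by parameter recovery.

Model summary
-------------
RNA counts are negative binomial with mean
``mu = baseline * 2^(sum of active log2 effects)`` where effects switch on by
(condition, phase, gene class).  ATAC fragments are sampled per cell from
independent Poisson rates per peak (class- and condition-dependent weights),
plus uniform genomic background and extra short-fragment insertion mass at
TSSs.  Co-accessible enhancer/promoter peak pairs share a per-cell latent
on/off state with a configurable correlation.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .io import (
    CellByFeatureMatrix,
    Gene,
    GenomeModel,
    ValidationError,
    write_fragments,
    write_matrix_mtx,
    write_peaks_bed,
)

CONDITIONS = ("M0", "M1", "M2", "M2p", "M1rep")
PHASES = ("G1", "S", "G2M")
GENE_CLASSES = (
    "cc_marker_S",
    "cc_marker_G2M",
    "induced_G1biased",
    "induced_SG2Mbiased",
    "induced_insensitive",
    "repressed",
    "null",
)
PEAK_CLASSES = ("transient", "memory", "primed", "constitutive", "null")


class ConfigError(ValueError):
    """Simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """All knobs of the stated synthetic world, with defaults.

    Phase proportions default to (0.80, 0.13, 0.07): a resting-macrophage
    FACS distribution of roughly 73/12/6 percent G1/S/G2M renormalized over
    the three detected phases.  Effect sizes default to log2FC 2, comfortably
    above every downstream calling threshold (1.3x for phase bias, 2x for
    chromatin induction).
    """

    seed: int = 0
    n_cells: dict[str, int] = field(
        default_factory=lambda: {c: 600 for c in CONDITIONS}
    )
    phase_proportions: tuple[float, float, float] = (0.80, 0.13, 0.07)
    n_genes: int = 1000
    n_peaks: int = 2000
    gene_class_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "cc_marker_S": 0.08,
            "cc_marker_G2M": 0.07,
            "induced_G1biased": 0.08,
            "induced_SG2Mbiased": 0.07,
            "induced_insensitive": 0.05,
            "repressed": 0.05,
        }
    )
    peak_class_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "transient": 0.30,
            "memory": 0.10,
            "primed": 0.15,
            "constitutive": 0.25,
        }
    )
    effect_log2fc: float = 2.0
    cc_marker_log2fc: float = 5.0  # on/off contrast of canonical phase markers
    # markers carry little baseline UMI mass (off outside their phase), so
    # their induction barely shifts per-cell totals
    cc_marker_baseline_scale: float = 0.05
    m1rep_attenuation: float = 0.5
    rna_dispersion: float = 10.0  # NB inverse-dispersion (size)
    rna_counts_per_cell: float = 10000.0
    rna_baseline_sigma: float = 1.5  # lognormal spread of per-gene means
    mean_fragments_per_cell: float = 2400.0
    frip: float = 0.25  # fraction of fragments falling in peaks
    tss_insertion_enrichment_factor: float = 10.0
    n_coaccessible_pairs: int = 50
    latent_pair_correlation: float = 0.8
    pair_on_prob: float = 0.5
    pair_open_weight: float = 64.0
    pair_closed_weight: float = 0.5
    peak_width: int = 501
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 20_000_000, "chr2": 20_000_000}
    )
    gene_body_bp: int = 10_000
    n_mito_genes: int = 10
    mito_fraction: float = 0.05

    def validate(self) -> None:
        if sum(self.gene_class_fractions.values()) > 1 + 1e-9:
            raise ConfigError("gene class fractions sum to > 1")
        if sum(self.peak_class_fractions.values()) > 1 + 1e-9:
            raise ConfigError("peak class fractions sum to > 1")
        p = self.phase_proportions
        if len(p) != 3 or any(x < 0 or x > 1 for x in p) or abs(sum(p) - 1) > 1e-6:
            raise ConfigError("phase proportions must be three values in [0,1] summing to 1")
        if any(v < 0 for v in self.n_cells.values()):
            raise ConfigError("negative cell count")
        if set(self.n_cells) - set(CONDITIONS):
            raise ConfigError(f"unknown conditions {set(self.n_cells) - set(CONDITIONS)}")
        for name in ("n_genes", "n_peaks", "peak_width", "gene_body_bp"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if 2 * self.n_coaccessible_pairs > self.n_peaks:
            raise ConfigError("n_peaks too small for the requested co-accessible pairs")
        if self.n_coaccessible_pairs > self.n_genes:
            raise ConfigError("n_genes too small for the requested co-accessible pairs")
        if not 0 <= self.latent_pair_correlation <= 1:
            raise ConfigError("latent_pair_correlation must be in [0,1]")
        if not 0 < self.frip < 1:
            raise ConfigError("frip must be in (0,1)")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["phase_proportions"] = list(self.phase_proportions)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "phase_proportions" in data:
            data["phase_proportions"] = tuple(data["phase_proportions"])
        cfg = cls(**data)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# truth table
# ---------------------------------------------------------------------------


@dataclass
class TruthTable:
    """Planted labels: per-gene class/bias, per-peak behavior, per-cell
    condition+phase, and the planted enhancer-promoter-gene triples."""

    genes: pd.DataFrame  # gene_id, gene_class, is_mito, promoter_peak, enhancer_peak
    peaks: pd.DataFrame  # peak_id, chrom, start, end, peak_class
    cells: pd.DataFrame  # barcode, condition, phase
    pairs: pd.DataFrame  # gene_id, promoter_peak, enhancer_peak
    config: SimulationConfig

    @property
    def signatures(self) -> dict[str, list[str]]:
        """Cell-cycle signature gene sets implied by the planted classes."""
        g = self.genes
        return {
            "S": g.loc[g.gene_class == "cc_marker_S", "gene_id"].tolist(),
            "G2M": g.loc[g.gene_class == "cc_marker_G2M", "gene_id"].tolist(),
        }

    def expected_cc_calls(self, condition: str) -> pd.DataFrame:
        """Planted cell-cycle sensitivity and biased phase within a condition.

        A gene is sensitive when its planted phase means differ by >= 1.3x for
        some phase pair; the biased phase is the one with the largest absolute
        z-scaled log2 mean, mirroring the classifier's rule so that recovery
        tests measure estimation error, not label convention.
        """
        rows = []
        for gene_id, klass in zip(self.genes.gene_id, self.genes.gene_class):
            mults = np.array(
                [gene_multiplier(klass, condition, ph, self.config) for ph in PHASES]
            )
            ratio = mults.max() / mults.min()
            sensitive = bool(ratio >= 1.3)
            if sensitive:
                lm = np.log2(mults)
                z = (lm - lm.mean()) / lm.std()
                biased = PHASES[int(np.argmax(np.abs(z)))]
            else:
                biased = "none"
            rows.append((gene_id, sensitive, biased))
        return pd.DataFrame(rows, columns=["gene_id", "sensitive", "biased_phase"])

    def behavior_truth(self) -> pd.Series:
        """Map planted peak classes to expected behavior labels."""
        mapping = {"transient": "transient", "memory": "memory", "primed": "primed"}
        return self.peaks.set_index("peak_id")["peak_class"].map(
            lambda c: mapping.get(c, "unchanged")
        )

    def match_peaks(self, peak_df: pd.DataFrame) -> pd.Series:
        """Match derived (e.g. union) peak intervals to truth peak ids by
        containment of the truth peak center; unmatched -> NA."""
        out = pd.Series(pd.NA, index=peak_df.index, dtype="object")
        for chrom, sub in peak_df.groupby("chrom"):
            truth = self.peaks[self.peaks.chrom == chrom]
            centers = ((truth.start + truth.end) // 2).to_numpy()
            order = np.argsort(centers)
            centers_sorted = centers[order]
            ids = truth.peak_id.to_numpy()[order]
            lo = np.searchsorted(centers_sorted, sub.start.to_numpy(), side="left")
            hi = np.searchsorted(centers_sorted, sub.end.to_numpy(), side="left")
            hit = hi > lo
            out.loc[sub.index[hit]] = ids[lo[hit]]
        return out

    def to_dir(self, directory: str | Path) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        feats = self.genes.copy()
        feats.insert(0, "feature_kind", "gene")
        feats = feats.rename(columns={"gene_id": "feature_id", "gene_class": "feature_class"})
        pk = self.peaks.copy()
        pk.insert(0, "feature_kind", "peak")
        pk = pk.rename(columns={"peak_id": "feature_id", "peak_class": "feature_class"})
        features = pd.concat([feats, pk], ignore_index=True)
        f1 = directory / "truth_features.tsv"
        f2 = directory / "truth_cells.tsv"
        features.to_csv(f1, sep="\t", index=False)
        self.cells.to_csv(f2, sep="\t", index=False)
        return [f1, f2]


# ---------------------------------------------------------------------------
# effect activation rules
# ---------------------------------------------------------------------------


def gene_multiplier(gene_class: str, condition: str, phase: str, cfg: SimulationConfig) -> float:
    """Expression multiplier 2^(active log2 effects) for one (class, condition,
    phase) combination.  M1rep reuses the M1-induced program with effects
    attenuated by ``m1rep_attenuation`` (dampened IFNG responsiveness after
    IL-4 priming)."""
    up = 2.0 ** cfg.effect_log2fc
    att = 2.0 ** (cfg.effect_log2fc * cfg.m1rep_attenuation)
    cc_up = 2.0 ** cfg.cc_marker_log2fc
    if gene_class == "cc_marker_S":
        return cc_up if phase == "S" else 1.0
    if gene_class == "cc_marker_G2M":
        return cc_up if phase == "G2M" else 1.0
    if gene_class == "induced_G1biased":
        if condition in ("M1", "M2") and phase == "G1":
            return up
        if condition == "M1rep" and phase == "G1":
            return att
        return 1.0
    if gene_class == "induced_SG2Mbiased":
        return up if (condition == "M2" and phase in ("S", "G2M")) else 1.0
    if gene_class == "induced_insensitive":
        if condition in ("M1", "M2"):
            return up
        if condition == "M1rep":
            return att
        return 1.0
    if gene_class == "repressed":
        return 1.0 / up if condition != "M0" else 1.0
    return 1.0


def peak_weight(peak_class: str, condition: str, cfg: SimulationConfig) -> float:
    """Relative accessibility weight of a non-pair peak in a condition."""
    up = 2.0 ** cfg.effect_log2fc
    if peak_class == "transient":
        return up if condition == "M2" else 1.0
    if peak_class == "memory":
        return up if condition in ("M2", "M2p") else 1.0
    if peak_class == "primed":
        return up if condition == "M2p" else 1.0
    if peak_class == "constitutive":
        return up
    return 1.0


# ---------------------------------------------------------------------------
# genome / feature layout
# ---------------------------------------------------------------------------


def _build_layout(cfg: SimulationConfig, rng: np.random.Generator):
    """Deterministic genome layout.

    Each planted enhancer-promoter-gene triple occupies its own 500 kb
    cassette (promoter peak overlapping the gene TSS, enhancer 20-200 kb
    downstream), so triples are separated by more than the 250 kb linking
    window.  Background peaks are evenly spaced in the remaining sequence and
    background gene TSSs sit midway between background peaks, away from any
    peak's promoter window.
    """
    chroms = list(cfg.chrom_lengths.items())
    half = cfg.peak_width // 2
    cassette_span = 500_000
    n_pairs = cfg.n_coaccessible_pairs

    # distribute cassettes across chromosomes proportionally to length
    lengths = np.array([ln for _, ln in chroms], dtype=float)
    cass_per_chrom = np.floor(n_pairs * lengths / lengths.sum()).astype(int)
    while cass_per_chrom.sum() < n_pairs:
        cass_per_chrom[int(np.argmin(cass_per_chrom * 1.0 / lengths))] += 1
    for (name, ln), k in zip(chroms, cass_per_chrom):
        if k * cassette_span > 0.8 * ln:
            raise ConfigError(f"{name} too short for {k} co-accessibility cassettes")

    peak_rows = []  # peak_id, chrom, start, end, class
    gene_rows = []  # gene_id, chrom, strand, tss, start, end
    pair_rows = []  # gene_id, promoter_peak, enhancer_peak
    peak_i = 0
    gene_i = 0

    def add_peak(chrom: str, center: int, klass: str) -> str:
        nonlocal peak_i
        pid = f"peak_{peak_i:05d}"
        peak_i += 1
        peak_rows.append((pid, chrom, center - half, center - half + cfg.peak_width, klass))
        return pid

    for (chrom, ln), k in zip(chroms, cass_per_chrom):
        for j in range(k):
            base = j * cassette_span
            prom_center = base + 100_000
            dist = int(rng.integers(20_000, 200_001))
            prom = add_peak(chrom, prom_center, "pair_promoter")
            enh = add_peak(chrom, prom_center + dist, "pair_enhancer")
            gid = f"gene_{gene_i:04d}"
            gene_i += 1
            gene_rows.append(
                (gid, chrom, "+", prom_center, prom_center, prom_center + cfg.gene_body_bp)
            )
            pair_rows.append((gid, prom, enh))

    # background peaks in the sequence left over after the cassettes
    n_bg_peaks = cfg.n_peaks - 2 * n_pairs
    n_bg_genes = cfg.n_genes - n_pairs
    regions = []
    for (chrom, ln), k in zip(chroms, cass_per_chrom):
        start = k * cassette_span + 50_000
        end = ln - 50_000
        regions.append((chrom, start, end))
    span = np.array([e - s for _, s, e in regions], dtype=float)
    pk_per_region = np.floor(n_bg_peaks * span / span.sum()).astype(int)
    while pk_per_region.sum() < n_bg_peaks:
        pk_per_region[int(np.argmax(span / (pk_per_region + 1)))] += 1

    centers_by_region: dict[int, np.ndarray] = {}
    for ri, ((chrom, start, end), k) in enumerate(zip(regions, pk_per_region)):
        if k == 0:
            centers_by_region[ri] = np.array([], dtype=int)
            continue
        spacing = (end - start) / (k + 1)
        centers = (start + spacing * np.arange(1, k + 1)).astype(int)
        for c in centers:
            add_peak(chrom, int(c), "_bg_")
        centers_by_region[ri] = centers

    # background gene TSSs on their own grid, nudged off promoter windows
    gene_per_region = np.floor(n_bg_genes * span / span.sum()).astype(int)
    while gene_per_region.sum() < n_bg_genes:
        gene_per_region[int(np.argmax(span / (gene_per_region + 1)))] += 1
    margin = 1300 + half  # clear of TSS +/- 1 kb promoter windows around peaks
    bg_gene_slots: list[tuple[str, int]] = []
    for ri, ((chrom, start, end), k) in enumerate(zip(regions, gene_per_region)):
        if k == 0:
            continue
        spacing = (end - start) / (k + 1)
        tss = (start + spacing * np.arange(1, k + 1)).astype(int)
        centers = centers_by_region[ri]
        if len(centers):
            pos = np.searchsorted(centers, tss)
            for j in range(len(tss)):
                for neighbor in (pos[j] - 1, pos[j]):
                    if 0 <= neighbor < len(centers) and abs(int(tss[j]) - int(centers[neighbor])) < margin:
                        tss[j] = centers[neighbor] + margin
        bg_gene_slots.extend((chrom, int(t)) for t in tss)

    if n_bg_genes > len(bg_gene_slots):
        raise ConfigError("n_genes too large for the genome layout")
    for idx_slot in range(n_bg_genes):
        chrom, tss = bg_gene_slots[idx_slot]
        strand = "+" if idx_slot % 2 == 0 else "-"
        gid = f"gene_{gene_i:04d}"
        gene_i += 1
        ln = cfg.chrom_lengths[chrom]
        if strand == "+":
            start, end = tss, min(tss + cfg.gene_body_bp, ln - 1)
        else:
            start, end = max(tss - cfg.gene_body_bp, 0), tss
        gene_rows.append((gid, chrom, strand, tss, start, end))

    peaks = pd.DataFrame(peak_rows, columns=["peak_id", "chrom", "start", "end", "peak_class"])
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "strand", "tss", "start", "end"])

    # assign background peak classes by exact rounded counts
    bg_idx = peaks.index[peaks.peak_class == "_bg_"].to_numpy()
    perm = rng.permutation(bg_idx)
    counts = {k: int(round(f * cfg.n_peaks)) for k, f in cfg.peak_class_fractions.items()}
    if sum(counts.values()) > len(bg_idx):
        raise ConfigError("peak class fractions leave no room for null background peaks")
    pos = 0
    for klass in PEAK_CLASSES[:-1]:
        k = counts.get(klass, 0)
        peaks.loc[perm[pos : pos + k], "peak_class"] = klass
        pos += k
    peaks.loc[peaks.peak_class == "_bg_", "peak_class"] = "null"

    pairs = pd.DataFrame(pair_rows, columns=["gene_id", "promoter_peak", "enhancer_peak"])
    return peaks, genes, pairs


def _assign_gene_classes(cfg: SimulationConfig, genes: pd.DataFrame, pairs: pd.DataFrame,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Exact rounded class counts; triple genes stay 'null' so linking truth
    is independent of expression truth."""
    genes = genes.copy()
    genes["gene_class"] = "null"
    bg = genes.index[~genes.gene_id.isin(pairs.gene_id)].to_numpy()
    perm = rng.permutation(bg)
    counts = {k: int(round(f * cfg.n_genes)) for k, f in cfg.gene_class_fractions.items()}
    if sum(counts.values()) > len(bg):
        raise ConfigError("gene class fractions leave no room for null genes")
    pos = 0
    for klass in GENE_CLASSES[:-1]:
        k = counts.get(klass, 0)
        genes.loc[perm[pos : pos + k], "gene_class"] = klass
        pos += k
    genes["is_mito"] = False
    null_bg = genes.index[(genes.gene_class == "null") & genes.index.isin(bg)].to_numpy()
    mito = rng.choice(null_bg, size=min(cfg.n_mito_genes, len(null_bg)), replace=False)
    genes.loc[mito, "is_mito"] = True
    return genes


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    genome: GenomeModel
    fragments: dict[str, pd.DataFrame]
    peak_beds: dict[str, pd.DataFrame]
    rna: CellByFeatureMatrix
    truth: TruthTable


def _sample_cells(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    props = np.asarray(cfg.phase_proportions, dtype=float)
    for cond in CONDITIONS:
        n = int(cfg.n_cells.get(cond, 0))
        if n == 0:
            continue
        phases = rng.choice(len(PHASES), size=n, p=props)
        for i in range(n):
            rows.append((f"{cond}-{i:05d}", cond, PHASES[phases[i]]))
    return pd.DataFrame(rows, columns=["barcode", "condition", "phase"])


def _simulate_rna(cfg: SimulationConfig, cells: pd.DataFrame, genes: pd.DataFrame,
                  rng: np.random.Generator) -> CellByFeatureMatrix:
    n_cells, n_genes = len(cells), len(genes)
    baseline = rng.lognormal(mean=0.0, sigma=cfg.rna_baseline_sigma, size=n_genes)
    cc_mask = genes.gene_class.isin(["cc_marker_S", "cc_marker_G2M"]).to_numpy()
    baseline[cc_mask] *= cfg.cc_marker_baseline_scale
    mito_mask = genes.is_mito.to_numpy()
    if mito_mask.any() and cfg.mito_fraction > 0:
        other = baseline[~mito_mask].sum()
        target = cfg.mito_fraction / (1 - cfg.mito_fraction) * other
        baseline[mito_mask] *= target / baseline[mito_mask].sum()
    baseline *= cfg.rna_counts_per_cell / baseline.sum()

    # multiplier lookup per (condition, phase, class)
    mult = {}
    for cond in CONDITIONS:
        for ph in PHASES:
            mult[(cond, ph)] = np.array(
                [gene_multiplier(k, cond, ph, cfg) for k in GENE_CLASSES]
            )
    class_idx = genes.gene_class.map({k: i for i, k in enumerate(GENE_CLASSES)}).to_numpy()

    mu = np.empty((n_cells, n_genes))
    for i, (cond, ph) in enumerate(zip(cells.condition, cells.phase)):
        mu[i] = baseline * mult[(cond, ph)][class_idx]
    size = cfg.rna_dispersion
    lam = rng.gamma(shape=size, scale=mu / size)
    counts = rng.poisson(lam)
    X = sp.csr_matrix(counts)
    return CellByFeatureMatrix(cells.barcode.tolist(), genes.gene_id.tolist(), X, kind="counts")


def _pair_latents(cfg: SimulationConfig, n_cells: int, n_pairs: int,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell on/off states for enhancer (e) and promoter (p) of each pair.

    With probability ``latent_pair_correlation`` both sides copy one shared
    Bernoulli(p_on) draw; otherwise they are independent, giving the stated
    correlation between the two binary states.
    """
    p = cfg.pair_on_prob
    shared = rng.random((n_cells, n_pairs)) < cfg.latent_pair_correlation
    common = rng.random((n_cells, n_pairs)) < p
    ind_e = rng.random((n_cells, n_pairs)) < p
    ind_p = rng.random((n_cells, n_pairs)) < p
    e = np.where(shared, common, ind_e)
    pr = np.where(shared, common, ind_p)
    return e, pr


def _positions_to_fragments(chrom_arr, mid, length, chrom_sizes, barcodes) -> pd.DataFrame:
    start = mid - length // 2
    end = start + length
    max_len = np.array([chrom_sizes[c] for c in chrom_arr])
    start = np.clip(start, 0, None)
    end = np.minimum(end, max_len)
    ok = start < end
    return pd.DataFrame(
        {
            "chrom": np.asarray(chrom_arr)[ok],
            "start": start[ok],
            "end": end[ok],
            "barcode": np.asarray(barcodes)[ok],
        }
    )


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate fragments, per-sample peak BEDs, a paired RNA count matrix, a
    genome model and the :class:`TruthTable`.  Deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    peaks, gene_layout, pairs = _build_layout(config, rng)
    genes = _assign_gene_classes(config, gene_layout, pairs, rng)
    cells = _sample_cells(config, rng)
    if len(cells) == 0:
        raise ConfigError("no cells requested")

    genome = GenomeModel(
        chromosomes=list(config.chrom_lengths.items()),
        genes=[
            Gene(r.gene_id, r.chrom, r.strand, int(r.tss), int(r.start), int(r.end))
            for r in genes.itertuples()
        ],
        mito_gene_ids=frozenset(genes.loc[genes.is_mito, "gene_id"]),
    )

    rna = _simulate_rna(config, cells, genes, rng)

    # --- ATAC fragments -------------------------------------------------
    chrom_sizes = config.chrom_lengths
    is_pair = peaks.peak_class.str.startswith("pair_").to_numpy()
    pair_peak_idx = np.flatnonzero(is_pair)
    other_idx = np.flatnonzero(~is_pair)
    pk_chrom = peaks.chrom.to_numpy()
    pk_start = peaks.start.to_numpy()

    # map pair columns: enhancer state drives the enhancer peak, promoter the
    # promoter peak
    pid_to_col = {pid: j for j, pid in enumerate(peaks.peak_id)}
    enh_cols = np.array([pid_to_col[p] for p in pairs.enhancer_peak])
    prom_cols = np.array([pid_to_col[p] for p in pairs.promoter_peak])

    mean_pair_w = (
        config.pair_on_prob * config.pair_open_weight
        + (1 - config.pair_on_prob) * config.pair_closed_weight
    )
    frag_frames: dict[str, pd.DataFrame] = {}
    peak_beds: dict[str, pd.DataFrame] = {}
    tss_arr = genes.tss.to_numpy()
    tss_chrom = genes.chrom.to_numpy()
    genome_bp = genome.total_length
    tss_bp = 101 * len(genes)
    f = config.tss_insertion_enrichment_factor
    non_peak_mean = config.mean_fragments_per_cell * (1 - config.frip)
    bg_mean = non_peak_mean / (1 + (f - 1) * tss_bp / genome_bp)
    tss_mean = non_peak_mean - bg_mean
    chrom_names = [c for c, _ in genome.chromosomes]
    chrom_probs = np.array([ln for _, ln in genome.chromosomes], dtype=float)
    chrom_probs /= chrom_probs.sum()

    for cond in CONDITIONS:
        sub = cells[cells.condition == cond]
        n = len(sub)
        if n == 0:
            continue
        w_other = np.array([peak_weight(k, cond, config) for k in peaks.peak_class.to_numpy()[other_idx]])
        total_w = w_other.sum() + len(pair_peak_idx) * mean_pair_w
        unit = config.frip * config.mean_fragments_per_cell / total_w

        # per-cell rates: background class peaks (condition-level) + pair peaks
        lam_other = np.broadcast_to(w_other * unit, (n, len(other_idx)))
        e_state, p_state = _pair_latents(config, n, len(pairs), rng)
        w_on, w_off = config.pair_open_weight, config.pair_closed_weight
        lam_pair = np.empty((n, 2 * len(pairs)))
        lam_pair[:, 0::2] = np.where(p_state, w_on, w_off) * unit
        lam_pair[:, 1::2] = np.where(e_state, w_on, w_off) * unit
        pair_cols = np.empty(2 * len(pairs), dtype=int)
        pair_cols[0::2] = prom_cols
        pair_cols[1::2] = enh_cols

        counts_other = rng.poisson(lam_other)
        counts_pair = rng.poisson(lam_pair)

        cell_ids, peak_ids_local = np.nonzero(counts_other)
        reps = counts_other[cell_ids, peak_ids_local]
        cell_rep = np.repeat(cell_ids, reps)
        peak_rep = np.repeat(other_idx[peak_ids_local], reps)
        c2, p2 = np.nonzero(counts_pair)
        reps2 = counts_pair[c2, p2]
        cell_rep = np.concatenate([cell_rep, np.repeat(c2, reps2)])
        peak_rep = np.concatenate([peak_rep, np.repeat(pair_cols[p2], reps2)])

        m = len(cell_rep)
        mids = pk_start[peak_rep] + rng.integers(0, config.peak_width, size=m)
        lens = rng.integers(60, 181, size=m)
        frag_peak = _positions_to_fragments(
            pk_chrom[peak_rep], mids, lens, chrom_sizes, sub.barcode.to_numpy()[cell_rep]
        )

        # uniform background
        n_bg = rng.poisson(bg_mean, size=n)
        tot_bg = int(n_bg.sum())
        bg_cells = np.repeat(np.arange(n), n_bg)
        bg_chrom_i = rng.choice(len(chrom_names), size=tot_bg, p=chrom_probs)
        bg_chrom = np.array(chrom_names, dtype=object)[bg_chrom_i]
        bg_max = np.array([chrom_sizes[c] for c in bg_chrom])
        bg_mid = (rng.random(tot_bg) * bg_max).astype(np.int64)
        bg_len = rng.integers(120, 221, size=tot_bg)
        frag_bg = _positions_to_fragments(
            bg_chrom, bg_mid, bg_len, chrom_sizes, sub.barcode.to_numpy()[bg_cells]
        )

        # short promoter-proximal fragments (TSS insertion enrichment)
        n_tss = rng.poisson(tss_mean, size=n)
        tot_tss = int(n_tss.sum())
        tss_cells = np.repeat(np.arange(n), n_tss)
        gpick = rng.integers(0, len(tss_arr), size=tot_tss)
        t_mid = tss_arr[gpick] + rng.integers(-15, 16, size=tot_tss)
        t_len = rng.integers(30, 71, size=tot_tss)
        frag_tss = _positions_to_fragments(
            tss_chrom[gpick], t_mid, t_len, chrom_sizes, sub.barcode.to_numpy()[tss_cells]
        )

        frames = pd.concat([frag_peak, frag_bg, frag_tss], ignore_index=True)
        frames["count"] = 1
        frames = frames.sort_values(
            ["chrom", "start", "end", "barcode"], kind="mergesort"
        ).reset_index(drop=True)
        frag_frames[cond] = frames[["chrom", "start", "end", "barcode", "count"]]

        # per-sample called peak list: jittered intervals, weight-scaled score
        w_all = np.empty(len(peaks))
        w_all[other_idx] = w_other
        w_all[pair_peak_idx] = mean_pair_w
        jitter = rng.integers(-50, 51, size=len(peaks))
        score = w_all * np.clip(1 + 0.05 * rng.standard_normal(len(peaks)), 0.5, None)
        bed = pd.DataFrame(
            {
                "chrom": pk_chrom,
                "start": pk_start + jitter,
                "end": pk_start + jitter + config.peak_width,
                "score": score,
            }
        )
        peak_beds[cond] = bed.sort_values(["chrom", "start"], kind="mergesort").reset_index(
            drop=True
        )

    truth_genes = genes[["gene_id", "gene_class", "is_mito"]].merge(
        pairs, on="gene_id", how="left"
    )
    truth = TruthTable(
        genes=truth_genes,
        peaks=peaks[["peak_id", "chrom", "start", "end", "peak_class"]].copy(),
        cells=cells,
        pairs=pairs,
        config=config,
    )
    return SimulatedExperiment(config, genome, frag_frames, peak_beds, rna, truth)


# ---------------------------------------------------------------------------
# fixture writer
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture(sim: SimulatedExperiment, directory: str | Path) -> dict:
    """Write all standard-format files plus truth tables; returns a manifest
    listing paths, the seed, and content checksums."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for cond, frames in sim.fragments.items():
        p = directory / f"fragments_{cond}.tsv.gz"
        write_fragments(frames, p)
        paths.append(p)
    for cond, bed in sim.peak_beds.items():
        p = directory / f"peaks_{cond}.bed"
        write_peaks_bed(bed, p)
        paths.append(p)
    paths.extend(write_matrix_mtx(sim.rna, directory / "rna"))
    paths.extend(sim.truth.to_dir(directory))
    genome_tbl = sim.genome.gene_table()
    genome_tbl["is_mito"] = genome_tbl.gene_id.isin(sim.genome.mito_gene_ids)
    genome_path = directory / "genes.tsv"
    genome_tbl.to_csv(genome_path, sep="\t", index=False)
    chrom_path = directory / "chrom_sizes.tsv"
    pd.DataFrame(sim.genome.chromosomes, columns=["chrom", "length"]).to_csv(
        chrom_path, sep="\t", index=False
    )
    manifest = {
        "seed": sim.config.seed,
        "files": {p.name: {"path": str(p), "sha256": _sha256(p)} for p in paths},
        "annotation": {p.name: str(p) for p in (genome_path, chrom_path)},
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
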