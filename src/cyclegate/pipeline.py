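"""End-to-end orchestration: simulate (or load) a multiome experiment, run
every analysis stage in order, write TSV artifacts, and score recovery
against planted truth when available.

Stage order: simulate/load -> ATAC QC -> union peaks -> insertion matrix ->
RNA QC -> iterative LSI -> clustering -> cell-cycle scoring -> markers ->
CC-sensitivity -> behavior classification -> co-accessibility -> gene links
-> report.  Every stage appends to a deterministic ``pipeline.log`` (no
timestamps); wall-clock timings go to ``timings.json``, the only
non-deterministic artifact.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import atac, behavior, ccscore, coaccess, differential, reduce, simulate
from .io import CellByFeatureMatrix, GenomeModel, Gene, normalize_log, read_fragments, \
    read_matrix_mtx, read_peaks_bed


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All pipeline thresholds, at their published defaults."""

    seed: int = 0
    # ATAC QC
    min_tss: float = 4.0
    min_fragments: int = 1000
    # RNA QC
    max_mito_pct: float = 12.5
    min_features: int = 200
    # marker calling (chromatin clusters) and scRNA DE
    marker_fdr: float = 0.01
    marker_log2fc: float = 1.25
    rna_de_fdr: float = 0.01
    rna_de_log2fc: float = 0.25
    # open-chromatin induction (behavior classes)
    ocr_fdr: float = 0.01
    ocr_log2fc: float = 1.0
    # cell-cycle sensitivity
    cc_fc_min: float = 1.3
    cc_padj_max: float = 0.001
    cc_condition: str = "M2"
    # co-accessibility / linking
    coaccess_window: int = 250_000
    promoter_window: int = 1000
    link_window: int = 250_000
    aggregate_size: int = 500
    aggregate_max_overlap: float = 0.8
    n_aggregates: int | None = None
    min_link_correlation: float = 0.45
    # cell-cycle signatures (fall back to the simulator's planted sets)
    s_genes: list[str] | None = None
    g2m_genes: list[str] | None = None
    # peaks & reduction
    peak_width: int = 501
    lsi_dims: int = 30
    lsi_iterations: int = 2
    lsi_top_features: int = 5000
    k_clusters: int = 10
    # simulation (used with simulate=True)
    simulation: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["simulation"]["phase_proportions"] = list(
            self.simulation.phase_proportions
        )
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        sim = data.pop("simulation", {})
        if "phase_proportions" in sim:
            sim["phase_proportions"] = tuple(sim["phase_proportions"])
        cfg = cls(**data, simulation=simulate.SimulationConfig(**sim))
        cfg.simulation.validate()
        return cfg


def _load_experiment(input_dir: Path) -> simulate.SimulatedExperiment:
    """Load a fixture directory written by :func:`simulate.write_fixture`."""
    genes = pd.read_csv(input_dir / "genes.tsv", sep="\t")
    chroms = pd.read_csv(input_dir / "chrom_sizes.tsv", sep="\t")
    genome = GenomeModel(
        chromosomes=list(zip(chroms.chrom, chroms.length.astype(int))),
        genes=[
            Gene(r.gene_id, r.chrom, r.strand, int(r.tss), int(r.start), int(r.end))
            for r in genes.itertuples()
        ],
        mito_gene_ids=frozenset(genes.loc[genes.is_mito, "gene_id"]) if "is_mito" in genes else frozenset(),
    )
    fragments, beds = {}, {}
    for cond in simulate.CONDITIONS:
        fp = input_dir / f"fragments_{cond}.tsv.gz"
        bp = input_dir / f"peaks_{cond}.bed"
        if fp.exists():
            fragments[cond] = read_fragments(fp, genome)
        if bp.exists():
            beds[cond] = read_peaks_bed(bp, genome)
    rna = read_matrix_mtx(input_dir / "rna")
    cells_path = input_dir / "truth_cells.tsv"
    truth = None
    if cells_path.exists() and (input_dir / "truth_features.tsv").exists():
        cells = pd.read_csv(cells_path, sep="\t")
        feats = pd.read_csv(input_dir / "truth_features.tsv", sep="\t")
        gsub = feats[feats.feature_kind == "gene"].rename(
            columns={"feature_id": "gene_id", "feature_class": "gene_class"}
        )[["gene_id", "gene_class", "is_mito", "promoter_peak", "enhancer_peak"]]
        psub = feats[feats.feature_kind == "peak"].rename(
            columns={"feature_id": "peak_id", "feature_class": "peak_class"}
        )[["peak_id", "chrom", "start", "end", "peak_class"]]
        psub = psub.astype({"start": int, "end": int})
        pairs = gsub.dropna(subset=["promoter_peak"])[
            ["gene_id", "promoter_peak", "enhancer_peak"]
        ].reset_index(drop=True)
        truth = simulate.TruthTable(gsub.reset_index(drop=True), psub.reset_index(drop=True),
                                    cells, pairs, simulate.SimulationConfig())
    return simulate.SimulatedExperiment(
        simulate.SimulationConfig(), genome, fragments, beds, rna, truth
    )


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    do_simulate: bool = True,
    input_dir: str | Path | None = None,
) -> dict:
    """Run all stages; returns the report dict.  Partial outputs are retained
    on failure and the failing stage is named in the raised error."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    timings: dict[str, float] = {}
    report: dict = {"seed": config.seed, "stages": []}

    def log(msg: str) -> None:
        log_lines.append(msg)

    def flush_log() -> None:
        (out / "pipeline.log").write_text("".join(l + "\n" for l in log_lines))

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                log(f"[stage] {name}")
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 3)
                report["stages"].append(name)
                flush_log()
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, str(exc)) from exc
                return False

        return _Stage()

    log(f"seed={config.seed}")
    log("thresholds=" + json.dumps(
        {k: v for k, v in dataclasses.asdict(config).items() if k != "simulation"},
        sort_keys=True, default=str))

    with stage("simulate" if do_simulate else "load"):
        if do_simulate:
            sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
            sim = simulate.simulate_experiment(sim_cfg)
        else:
            if input_dir is None:
                raise ValueError("input_dir required when do_simulate=False")
            sim = _load_experiment(Path(input_dir))
        genome = sim.genome
        conditions = list(sim.fragments)
        log(f"conditions={conditions} cells={sum(len(f.barcode.unique()) for f in sim.fragments.values())}")

    with stage("atac_qc"):
        qc_frames = []
        for cond, frags in sim.fragments.items():
            qc = atac.tss_enrichment_scores(
                frags, genome, min_tss=config.min_tss, min_fragments=config.min_fragments
            )
            qc.insert(0, "condition", cond)
            qc_frames.append(qc)
        qc_all = pd.concat(qc_frames, ignore_index=True)
        qc_all.to_csv(out / "qc_atac.tsv", sep="\t", index=False)
        kept_atac = qc_all.loc[qc_all.passed, "barcode"].tolist()
        log(f"atac_cells_kept={len(kept_atac)}/{len(qc_all)}")
        if not kept_atac:
            raise ValueError("no cells passed ATAC QC")

    with stage("union_peaks"):
        union = atac.make_union_peakset(list(sim.peak_beds.values()), width=config.peak_width)
        union.to_csv(out / "union_peaks.tsv", sep="\t", index=False)
        log(f"union_peaks={len(union)}")
        if not len(union):
            raise ValueError("empty union peak set")

    with stage("insertion_matrix"):
        all_frags = pd.concat(sim.fragments.values(), ignore_index=True)
        all_frags = all_frags[all_frags.barcode.isin(set(kept_atac))]
        peak_counts = atac.count_insertions(all_frags, union, barcodes=sorted(kept_atac))
        peak_norm = normalize_log(peak_counts)
        log(f"insertion_matrix={peak_counts.shape} sum={int(peak_counts.X.sum())}")

    with stage("rna_qc"):
        kept_rna = differential.filter_cells_rna(
            sim.rna, genome, max_mito_pct=config.max_mito_pct, min_features=config.min_features
        )
        log(f"rna_cells_kept={len(kept_rna)}/{len(sim.rna.barcodes)}")
        if not kept_rna:
            raise ValueError("no cells passed RNA QC")
        # paired modalities: work on the barcode intersection
        shared = sorted(set(kept_rna) & set(kept_atac))
        if not shared:
            raise ValueError("no barcodes shared between modalities after QC")
        rna_counts = sim.rna.subset_cells(shared)
        rna_norm = normalize_log(rna_counts)
        peak_counts = peak_counts.subset_cells(shared)
        peak_norm = peak_norm.subset_cells(shared)
        log(f"shared_cells={len(shared)}")

    with stage("lsi"):
        embedding = reduce.iterative_lsi(
            peak_counts,
            d=config.lsi_dims,
            n_iterations=config.lsi_iterations,
            n_top_features=config.lsi_top_features,
            k_clusters=config.k_clusters,
            seed=config.seed,
        )
        emb_df = pd.DataFrame(
            embedding.coordinates,
            index=pd.Index(embedding.barcodes, name="barcode"),
            columns=[f"LSI_{i+1}" for i in range(embedding.d)],
        )
        emb_df.round(6).to_csv(out / "embedding.tsv", sep="\t")

    with stage("cluster"):
        labels = reduce.cluster_cells(embedding, k=config.k_clusters, seed=config.seed)
        log(f"clusters={np.bincount(labels).tolist()}")

    with stage("cc_score"):
        if config.s_genes and config.g2m_genes:
            s_genes, g2m_genes = config.s_genes, config.g2m_genes
        elif sim.truth is not None:
            sigs = sim.truth.signatures
            s_genes, g2m_genes = sigs["S"], sigs["G2M"]
        else:
            raise ValueError("cell-cycle signatures required (config or truth tables)")
        phase_calls = ccscore.score_cell_cycle(
            rna_norm, s_genes, g2m_genes, seed=config.seed
        )
        meta = phase_calls.copy()
        meta["cluster"] = labels
        if sim.truth is not None:
            cond_map = sim.truth.cells.set_index("barcode")["condition"]
            meta["condition"] = cond_map.reindex(meta.barcode).to_numpy()
        else:
            meta["condition"] = [b.split("-")[0] for b in meta.barcode]
        meta.round(6).to_csv(out / "cell_metadata.tsv", sep="\t", index=False)
        log("phase_fractions=" + json.dumps(
            meta.phase.value_counts(normalize=True).round(4).to_dict(), sort_keys=True))

    with stage("markers"):
        atac_markers = differential.call_markers(
            peak_norm, labels, fdr_max=config.marker_fdr, log2fc_min=config.marker_log2fc
        )
        mk = pd.concat(
            [df.assign(cluster=cl) for cl, df in atac_markers.items()], ignore_index=True
        )
        mk.round(6).to_csv(out / "markers_atac.tsv", sep="\t", index=False)
        cond_labels = meta.condition.to_numpy()
        rna_markers = differential.call_markers(
            rna_norm, cond_labels, fdr_max=config.rna_de_fdr, log2fc_min=config.rna_de_log2fc
        )
        mkr = pd.concat(
            [df.assign(condition=cl) for cl, df in rna_markers.items()], ignore_index=True
        )
        mkr.round(6).to_csv(out / "markers_rna.tsv", sep="\t", index=False)
        log(f"atac_markers={len(mk)} rna_markers={len(mkr)}")

    with stage("cc_sensitivity"):
        sel = meta.condition == config.cc_condition
        cc_calls = None
        if sel.any():
            sub_barcodes = meta.barcode[sel].tolist()
            sub_phases = pd.Series(
                meta.phase[sel].to_numpy(), index=sub_barcodes
            )
            if all((sub_phases == ph).sum() >= 2 for ph in simulate.PHASES):
                cc_calls = differential.cc_sensitivity(
                    rna_norm.subset_cells(sub_barcodes),
                    sub_phases,
                    fc_min=config.cc_fc_min,
                    padj_max=config.cc_padj_max,
                )
                cc_calls.round(6).to_csv(out / "cc_sensitivity.tsv", sep="\t", index=False)
                log(f"cc_sensitive={int(cc_calls.sensitive.sum())}/{len(cc_calls)}")
            else:
                log("cc_sensitivity skipped: a phase group has < 2 cells")
        else:
            log(f"cc_sensitivity skipped: no {config.cc_condition} cells")

    with stage("behavior"):
        beh_calls = None
        cond_series = pd.Series(meta.condition.to_numpy(), index=meta.barcode.to_numpy())
        have = {c: (cond_series == c).sum() for c in ("M0", "M2", "M2p")}
        if all(v >= 2 for v in have.values()):
            cells_of = lambda c: cond_series.index[cond_series == c].tolist()
            d_m2 = differential.wilcoxon_de(peak_norm, cells_of("M2"), cells_of("M0"),
                                            "M2", "M0")
            d_m2p = differential.wilcoxon_de(peak_norm, cells_of("M2p"), cells_of("M0"),
                                             "M2p", "M0")
            beh_calls = behavior.classify_behavior(
                d_m2, d_m2p, fdr_max=config.ocr_fdr, log2fc_min=config.ocr_log2fc
            )
            beh_calls.to_csv(out / "behavior.tsv", sep="\t", index=False)
            log("behavior_counts=" + json.dumps(
                beh_calls.behavior.value_counts().to_dict(), sort_keys=True))
        else:
            log("behavior skipped: need M0, M2 and M2p cells")

    with stage("coaccessibility"):
        agg, members = coaccess.make_aggregates(
            embedding,
            peak_counts,
            n_per_aggregate=min(config.aggregate_size, len(shared)),
            max_overlap_fraction=config.aggregate_max_overlap,
            n_aggregates=config.n_aggregates,
            seed=config.seed,
        )
        pairs = coaccess.coaccessibility(agg, union, window=config.coaccess_window)
        pairs.round(6).to_csv(out / "coaccess_pairs.tsv", sep="\t", index=False)
        log(f"aggregates={agg.shape[0]} pairs={len(pairs)}")

    with stage("links"):
        links = coaccess.link_peaks_to_genes(
            pairs,
            union,
            genome,
            min_correlation=config.min_link_correlation,
            promoter_window=config.promoter_window,
            link_window=config.link_window,
        )
        links.round(6).to_csv(out / "gene_links.tsv", sep="\t", index=False)
        log(f"gene_links={len(links)}")

    with stage("report"):
        if sim.truth is not None:
            report["recovery"] = recovery_report(
                sim.truth, meta, cc_calls, beh_calls, union, links, config
            )
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (out / "timings.json").write_text(json.dumps(timings, indent=2, sort_keys=True))
    return report


def recovery_report(
    truth: simulate.TruthTable,
    meta: pd.DataFrame,
    cc_calls: pd.DataFrame | None,
    beh_calls: pd.DataFrame | None,
    union: pd.DataFrame,
    links: pd.DataFrame,
    config: PipelineConfig,
) -> dict:
    """Score every stage against the planted truth; metrics in [0, 1]."""
    out: dict = {}
    tcells = truth.cells.set_index("barcode")
    merged = meta.join(tcells, on="barcode", rsuffix="_true")
    ok = merged.phase_true.notna() if "phase_true" in merged else merged.phase.notna()
    if "phase_true" not in merged:
        merged["phase_true"] = merged["phase"]
    out["phase_accuracy"] = float((merged.phase == merged.phase_true).mean())
    out["phase_fractions_assigned"] = merged.phase.value_counts(normalize=True).round(4).to_dict()
    out["phase_fractions_true"] = merged.phase_true.value_counts(normalize=True).round(4).to_dict()

    if cc_calls is not None:
        expected = truth.expected_cc_calls(config.cc_condition).set_index("gene_id")
        joined = cc_calls.set_index("gene_id").join(expected, rsuffix="_true").dropna(
            subset=["sensitive_true"]
        )
        tp = (joined.sensitive & joined.sensitive_true).sum()
        fn = (~joined.sensitive & joined.sensitive_true).sum()
        fp = (joined.sensitive & ~joined.sensitive_true).sum()
        tn = (~joined.sensitive & ~joined.sensitive_true).sum()
        out["cc_sensitivity_recall"] = float(tp / max(tp + fn, 1))
        out["cc_false_positive_rate"] = float(fp / max(fp + tn, 1))
        tp_rows = joined[joined.sensitive & joined.sensitive_true]
        out["cc_bias_accuracy"] = float(
            (tp_rows.biased_phase == tp_rows.biased_phase_true).mean()
        ) if len(tp_rows) else float("nan")

    if beh_calls is not None:
        match = truth.match_peaks(union.set_index("peak_id").loc[beh_calls.peak_id].reset_index())
        truth_beh = truth.behavior_truth()
        tlabels = pd.Series(
            [truth_beh.get(m, "unchanged") if pd.notna(m) else "unchanged" for m in match],
            index=beh_calls.index,
        )
        out["behavior"] = {}
        for cls in ("transient", "memory", "primed"):
            pred = beh_calls.behavior == cls
            act = tlabels == cls
            tp = int((pred & act).sum())
            out["behavior"][cls] = {
                "precision": tp / max(int(pred.sum()), 1),
                "recall": tp / max(int(act.sum()), 1),
                "n_called": int(pred.sum()),
                "n_true": int(act.sum()),
            }

    if len(truth.pairs):
        union_truth = truth.match_peaks(union)
        utid = pd.Series(union_truth.to_numpy(), index=union.peak_id.to_numpy())
        truth_links = set(zip(truth.pairs.gene_id, truth.pairs.enhancer_peak))
        pred_links = set()
        for r in links.itertuples(index=False):
            t = utid.get(r.peak_id)
            if pd.notna(t):
                pred_links.add((r.gene_id, t))
        tp = len(pred_links & truth_links)
        out["link_precision"] = tp / max(len(pred_links), 1)
        out["link_recall"] = tp / max(len(truth_links), 1)
        out["n_links"] = len(links)
    return out
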