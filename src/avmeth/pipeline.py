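"""End-to-end orchestration: one YAML config drives simulate -> preprocess
-> differential -> integrate, with structured logging, a run record and
bit-reproducible outputs under a single run directory."""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .data_model import (
    AnalysisConfig,
    ArrayDataset,
    ExpressionMatrix,
    Manifest,
    write_dmp_bed,
    write_dmp_table,
    write_json,
    write_manifest,
    write_matrix,
    write_sample_sheet,
    read_manifest,
    read_array_dataset,
    read_matrix,
    read_sample_sheet,
)
from .differential import aggregate_dmrs, differential_analysis, expression_logfc
from .integrate import (
    gene_summary_table,
    integrate_genes,
    quadrant_region_table,
    records_to_frame,
)
from .preprocess import (
    ClusteringResult,
    compute_beta_m,
    global_methylation,
    hierarchical_cluster,
    normalize_type2,
    qc_filter,
    top_variable,
)
from .simulate import NoiseSpec, TruthSpec, simulate_dataset, simulate_manifest

log = logging.getLogger("avmeth")


@dataclass
class PipelineRunRecord:
    config: dict
    stage_seconds: dict[str, float] = field(default_factory=dict)
    probe_counts: dict[str, int] = field(default_factory=dict)
    output_files: list[str] = field(default_factory=list)
    version: str = __version__

    def to_json(self, path: str | Path) -> None:
        write_json(asdict(self), path)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    if "simulate" in cfg and "inputs" in cfg:
        raise ValueError("config must name either real inputs or a simulate block, not both")
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ValueError("config must contain a 'simulate' or an 'inputs' block")
    if "seed" not in cfg:
        raise ValueError("config must set an explicit seed")
    return cfg


def analysis_config_from(cfg: dict) -> AnalysisConfig:
    params = dict(cfg.get("analysis", {}))
    params.setdefault("seed", cfg["seed"])
    return AnalysisConfig(**params)


def _simulate_stage(cfg: dict, out_dir: Path) -> tuple[ArrayDataset, ExpressionMatrix]:
    sim = dict(cfg["simulate"])
    seed = cfg["seed"]
    manifest = simulate_manifest(
        n_genes=sim.get("n_genes", 2000),
        probes_per_gene_range=tuple(sim.get("probes_per_gene_range", (3, 12))),
        sex_chrom_fraction=sim.get("sex_chrom_fraction", 0.05),
        seed=seed,
    )
    truth_spec = TruthSpec(**sim.get("truth", {}))
    noise = NoiseSpec(**sim.get("noise", {}))
    dataset, expression, truth = simulate_dataset(
        manifest,
        n_pairs=sim.get("n_pairs", 9),
        truth_spec=truth_spec,
        noise=noise,
        seed=seed,
        dmr_block_size=sim.get("dmr_block_size"),
    )
    write_manifest(manifest, out_dir / "manifest.csv")
    write_sample_sheet(dataset.samples, out_dir / "samples.csv")
    write_matrix(dataset.meth, out_dir / "meth.tsv")
    write_matrix(dataset.unmeth, out_dir / "unmeth.tsv")
    write_matrix(dataset.detection_p, out_dir / "detection_p.tsv")
    write_matrix(dataset.negctrl, out_dir / "negctrl.tsv", label="control_id")
    write_matrix(expression.values, out_dir / "expression.tsv", label="gene")
    truth.to_json(out_dir / "truth.json")
    return dataset, expression


def _load_inputs(cfg: dict) -> tuple[ArrayDataset, ExpressionMatrix]:
    paths = cfg["inputs"]
    manifest = read_manifest(paths["manifest"])
    dataset = read_array_dataset(
        paths["meth"],
        paths["unmeth"],
        paths.get("detection_p"),
        paths["samples"],
        manifest,
        negctrl_path=paths.get("negctrl"),
    )
    expr_values = read_matrix(paths["expression"], label="gene")
    expression = ExpressionMatrix(
        values=expr_values[dataset.samples.sample_ids], samples=dataset.samples
    )
    return dataset, expression


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None) -> PipelineRunRecord:
    """Execute every stage defined by the config; see module docstring."""
    cfg = load_config(config_path)
    out_dir = Path(out_dir or cfg.get("out_dir", "avmeth_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    record = PipelineRunRecord(config=cfg)
    config = analysis_config_from(cfg)
    failed_marker = out_dir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    stage = "setup"
    try:
        t0 = time.perf_counter()
        stage = "simulate" if "simulate" in cfg else "load_inputs"
        if "simulate" in cfg:
            dataset, expression = _simulate_stage(cfg, out_dir)
        else:
            dataset, expression = _load_inputs(cfg)
        record.stage_seconds[stage] = time.perf_counter() - t0
        record.probe_counts["input"] = len(dataset.probe_ids)

        stage = "preprocess"
        t0 = time.perf_counter()
        filtered = qc_filter(dataset, config)
        matrices = compute_beta_m(filtered)
        matrices = normalize_type2(matrices, filtered.annotation)
        record.probe_counts["post_qc"] = len(matrices.kept_probe_ids)
        summary = global_methylation(matrices, filtered.samples)
        write_json(matrices.qc_log, out_dir / "qc_log.json")
        write_json(
            {
                "per_sample_mean_beta": summary.per_sample_mean_beta,
                "per_group_mean_beta": summary.per_group_mean_beta,
            },
            out_dir / "global_methylation.json",
        )
        write_matrix(matrices.beta, out_dir / "beta.tsv")
        write_matrix(matrices.mvalue, out_dir / "mvalue.tsv")
        top = top_variable(matrices, min(config.top_n_variable, len(matrices.kept_probe_ids)))
        clustering = hierarchical_cluster(matrices, probe_ids=top)
        _write_clustering(clustering, out_dir)
        record.stage_seconds[stage] = time.perf_counter() - t0

        stage = "differential"
        t0 = time.perf_counter()
        dmps, hyper = differential_analysis(matrices, filtered.samples, config)
        record.probe_counts["dmps"] = int(dmps["is_dmp"].sum())
        write_dmp_table(dmps, out_dir / "dmp.tsv")
        bed_log = write_dmp_bed(dmps[dmps["is_dmp"]], filtered.annotation, out_dir / "dmp.bed")
        dmrs = aggregate_dmrs(
            dmps, filtered.annotation, config.dmr_min_probes, config.dmr_max_gap
        )
        dmrs.to_csv(out_dir / "dmr.tsv", sep="\t", index=False, float_format="%.6g")
        de = expression_logfc(expression, config)
        de.to_csv(out_dir / "expression_logfc.tsv", sep="\t", index=False, float_format="%.6g")
        write_json(
            {
                "d0": None if hyper is None else hyper.d0,
                "s0_sq": None if hyper is None else hyper.s0_sq,
                "bed": bed_log,
            },
            out_dir / "differential_meta.json",
        )
        record.stage_seconds[stage] = time.perf_counter() - t0

        stage = "integrate"
        t0 = time.perf_counter()
        records, int_log = integrate_genes(dmps, de, filtered.annotation, config)
        flat = records_to_frame(records)
        flat.to_csv(out_dir / "probe_quadrants.tsv", sep="\t", index=False, float_format="%.6g")
        gene_summary_table(records).to_csv(
            out_dir / "gene_summary.tsv", sep="\t", index=False, float_format="%.6g"
        )
        table = quadrant_region_table(records, filtered.annotation)
        table.counts.to_csv(out_dir / "quadrant_region_counts.tsv", sep="\t")
        table.proportions.to_csv(
            out_dir / "quadrant_region_proportions.tsv", sep="\t", float_format="%.6g"
        )
        write_json(int_log, out_dir / "integration_log.json")
        record.stage_seconds[stage] = time.perf_counter() - t0
    except Exception as exc:
        failed_marker.write_text(f"stage={stage}\nerror={exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    record.output_files = sorted(
        str(p.relative_to(out_dir)) for p in out_dir.iterdir() if p.is_file()
    )
    record.to_json(out_dir / "run_record.json")
    record.output_files.append("run_record.json")
    return record


def _write_clustering(clustering: ClusteringResult, out_dir: Path) -> None:
    clustering.merge_frame().to_csv(
        out_dir / "clustering_merges.tsv", sep="\t", index=False, float_format="%.6g"
    )
    (out_dir / "clustering_sample_order.txt").write_text(
        "\n".join(clustering.sample_order) + "\n"
    )
    pd.Series(clustering.k2_labels, name="cluster").rename_axis("sample_id").to_csv(
        out_dir / "clustering_k2.tsv", sep="\t"
    )
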