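"""End-to-end orchestration: data -> MI -> partition -> indicators ->
distances -> layout, with a reproducible result bundle on disk.

A single global seed is split deterministically into per-stage seeds
(simulation, layout), so one integer reproduces the whole run. A
low-count pre-filter (drop genes whose mean expression is below 5, the
conventional RNA-seq floor) is applied by default in file mode and is
configurable; its effect is logged and recorded in the manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import ConfigurationError
from .io import (
    ExpressionMatrix,
    GeneAnnotation,
    read_annotation,
    read_expression,
    write_annotation,
    write_expression,
    write_mi_matrix,
)
from .indicators import delta_grp, indicator_table, write_indicator_table
from .distances import (
    cis_trans_comparison,
    condition_comparison,
    write_distance_table,
)
from .layout import build_chromosome_graph, export_graph, force_directed_layout
from .mi import EstimatorConfig, MIMatrix, compute_mi_matrix
from .partition import GRPCollection, partition_grp, summary_frame
from .simulate import SimulationConfig, generate_annotation, generate_expression_pair

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Full configuration of one analysis run."""

    mode: str = "synthetic"  # "synthetic" | "files"
    simulation: SimulationConfig | None = None
    tumor_expression: str | None = None
    control_expression: str | None = None
    annotation: str | None = None
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    n_bins_pdf: int = 100
    layout_seed: int | None = None
    layout_iterations: int = 500
    output_dir: str = "grpspace_results"
    strict_annotation: bool = False
    low_count_filter: bool = True
    low_count_threshold: float = 5.0
    n_workers: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in {"synthetic", "files"}:
            raise ConfigurationError(f"mode must be 'synthetic' or 'files', got {self.mode!r}")
        file_keys = [self.tumor_expression, self.control_expression, self.annotation]
        if self.mode == "synthetic":
            if any(file_keys):
                raise ConfigurationError(
                    "synthetic mode must not set expression/annotation paths"
                )
            if self.simulation is None:
                self.simulation = SimulationConfig()
        else:
            if self.simulation is not None:
                raise ConfigurationError("files mode must not set a simulation section")
            if not all(file_keys):
                raise ConfigurationError(
                    "files mode requires tumor_expression, control_expression "
                    "and annotation paths"
                )
        if self.n_bins_pdf < 2:
            raise ConfigurationError("n_bins_pdf must be >= 2")
        if self.layout_iterations < 1:
            raise ConfigurationError("layout_iterations must be positive")
        if self.low_count_threshold < 0:
            raise ConfigurationError("low_count_threshold must be >= 0")


@dataclass
class ResultBundle:
    """In-memory handles plus file paths of everything a run produced."""

    config: PipelineConfig
    annotation: GeneAnnotation
    control_expression: ExpressionMatrix
    tumor_expression: ExpressionMatrix
    mi_control: MIMatrix
    mi_tumor: MIMatrix
    grps_control: GRPCollection
    grps_tumor: GRPCollection
    indicator_rows: list
    condition_records: list
    cis_trans_records: dict  # (condition, metric) -> records
    graphs: dict  # condition -> ChromosomeGraph
    layouts: dict  # condition -> LayoutResult
    manifest: dict
    paths: dict[str, Path]


_KNOWN_KEYS = {
    "": {
        "mode", "simulation", "tumor_expression", "control_expression",
        "annotation", "estimator", "n_bins_pdf", "layout_seed",
        "layout_iterations", "output_dir", "strict_annotation",
        "low_count_filter", "low_count_threshold", "n_workers", "seed",
    },
    "simulation": {f.name for f in dataclasses.fields(SimulationConfig)},
    "estimator": {f.name for f in dataclasses.fields(EstimatorConfig)},
}


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and cross-validate a YAML pipeline config file.

    Unknown keys are errors (no silent typos); messages name the
    offending dotted key.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    for section in ("", "simulation", "estimator"):
        block = raw if section == "" else raw.get(section) or {}
        if not isinstance(block, dict):
            raise ConfigurationError(f"{path}: section {section!r} must be a mapping")
        unknown = set(block) - _KNOWN_KEYS[section]
        if section == "":
            unknown -= {"simulation", "estimator"}
        if unknown:
            dotted = [f"{section}.{k}" if section else k for k in sorted(unknown)]
            raise ConfigurationError(f"{path}: unknown config key(s): {dotted}")
    kwargs = {k: v for k, v in raw.items() if k not in {"simulation", "estimator"}}
    try:
        if "simulation" in raw and raw["simulation"] is not None:
            sim = dict(raw["simulation"])
            if "chromosome_weights" in sim:
                sim["chromosome_weights"] = {
                    str(k): float(v) for k, v in sim["chromosome_weights"].items()
                }
            if "trans_factor_groups" in sim and sim["trans_factor_groups"] is not None:
                sim["trans_factor_groups"] = [
                    [str(c) for c in grp] for grp in sim["trans_factor_groups"]
                ]
            kwargs["simulation"] = SimulationConfig(**sim)
        if "estimator" in raw and raw["estimator"] is not None:
            kwargs["estimator"] = EstimatorConfig(**raw["estimator"])
        return PipelineConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigurationError):
            raise
        raise ConfigurationError(f"{path}: {exc}") from exc


def _stage_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(3)
    return {
        "simulation": int(state[0] % 2**31),
        "permutation": int(state[1] % 2**31),
        "layout": int(state[2] % 2**31),
    }


def _low_count_filter(
    control: ExpressionMatrix, tumor: ExpressionMatrix, threshold: float
) -> tuple[ExpressionMatrix, ExpressionMatrix, int]:
    """Drop genes whose mean expression is below *threshold* in either arm."""
    keep_c = control.values.mean(axis=1) >= threshold
    keep_t = tumor.values.mean(axis=1) >= threshold
    keep_genes = {
        g for g, ok in zip(control.gene_ids, keep_c) if ok
    } & {g for g, ok in zip(tumor.gene_ids, keep_t) if ok}
    n_dropped = len(set(control.gene_ids) | set(tumor.gene_ids)) - len(keep_genes)

    def _subset(expr: ExpressionMatrix) -> ExpressionMatrix:
        mask = [g in keep_genes for g in expr.gene_ids]
        return ExpressionMatrix(
            gene_ids=[g for g, m in zip(expr.gene_ids, mask) if m],
            sample_ids=expr.sample_ids,
            values=expr.values[np.array(mask)],
            condition=expr.condition,
        )

    return _subset(control), _subset(tumor), n_dropped


def run_pipeline(cfg: PipelineConfig) -> ResultBundle:
    """Execute every stage in order and write the result bundle.

    Re-running with an identical config reproduces identical tables.
    """
    t0 = time.time()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    layout_seed = cfg.layout_seed if cfg.layout_seed is not None else seeds["layout"]
    timings: dict[str, float] = {}
    paths: dict[str, Path] = {}

    # stage: input data
    t = time.time()
    if cfg.mode == "synthetic":
        sim = dataclasses.replace(cfg.simulation, seed=seeds["simulation"])
        annotation = generate_annotation(sim)
        control, tumor = generate_expression_pair(annotation, sim)
        write_annotation(annotation, out / "annotation.bed")
        write_expression(control, out / "expression_control.tsv")
        write_expression(tumor, out / "expression_tumor.tsv")
        paths["annotation"] = out / "annotation.bed"
        n_dropped = 0
    else:
        annotation = read_annotation(cfg.annotation, strict=cfg.strict_annotation)
        control = read_expression(cfg.control_expression, "control")
        tumor = read_expression(cfg.tumor_expression, "tumor")
        if cfg.low_count_filter:
            control, tumor, n_dropped = _low_count_filter(
                control, tumor, cfg.low_count_threshold
            )
            logger.info(
                "low-count filter (mean < %g): dropped %d gene(s)",
                cfg.low_count_threshold, n_dropped,
            )
        else:
            n_dropped = 0
    timings["input"] = time.time() - t
    logger.info(
        "input: %d genes, %d control + %d tumor samples",
        control.n_genes, control.n_samples, tumor.n_samples,
    )

    # stage: MI matrices
    t = time.time()
    mi_control = compute_mi_matrix(control, cfg.estimator, cfg.n_workers)
    mi_control.estimator_meta["condition"] = "control"
    mi_tumor = compute_mi_matrix(tumor, cfg.estimator, cfg.n_workers)
    mi_tumor.estimator_meta["condition"] = "tumor"
    for name, mi in (("control", mi_control), ("tumor", mi_tumor)):
        p = out / f"mi_{name}.h5"
        write_mi_matrix(mi, p)
        paths[f"mi_{name}"] = p
    timings["mi"] = time.time() - t

    # stage: partition
    t = time.time()
    grps_control = partition_grp(mi_control, annotation, strict=cfg.strict_annotation)
    grps_tumor = partition_grp(mi_tumor, annotation, strict=cfg.strict_annotation)
    for name, col in (("control", grps_control), ("tumor", grps_tumor)):
        p = out / f"subgrp_summary_{name}.tsv"
        summary_frame(col).to_csv(p, sep="\t", index=False)
        paths[f"subgrp_summary_{name}"] = p
    timings["partition"] = time.time() - t

    # stage: change indicators
    t = time.time()
    deltas = delta_grp(grps_tumor, grps_control)
    indicator_rows = indicator_table(deltas)
    paths["indicators"] = out / "indicators.tsv"
    write_indicator_table(indicator_rows, paths["indicators"])
    timings["indicators"] = time.time() - t

    # stage: distribution distances
    t = time.time()
    condition_records = condition_comparison(grps_tumor, grps_control)
    paths["condition_ks"] = out / "condition_ks.tsv"
    write_distance_table(condition_records, paths["condition_ks"])
    cis_trans_records = {}
    for cond_name, col in (("control", grps_control), ("tumor", grps_tumor)):
        for metric in ("ks", "hellinger"):
            records = cis_trans_comparison(col, metric=metric, n_bins_pdf=cfg.n_bins_pdf)
            cis_trans_records[(cond_name, metric)] = records
            p = out / f"cis_trans_{metric}_{cond_name}.tsv"
            write_distance_table(records, p)
            paths[f"cis_trans_{metric}_{cond_name}"] = p
    timings["distances"] = time.time() - t

    # stage: chromosome graph + layout
    t = time.time()
    graphs, layouts = {}, {}
    for cond_name in ("control", "tumor"):
        graph = build_chromosome_graph(
            cis_trans_records[(cond_name, "hellinger")], condition=cond_name
        )
        lay = force_directed_layout(graph, seed=layout_seed, n_iterations=cfg.layout_iterations)
        graphs[cond_name] = graph
        layouts[cond_name] = lay
        p = out / f"chromosome_graph_{cond_name}.graphml"
        export_graph(graph, lay, p, format="graphml")
        paths[f"graph_{cond_name}"] = p
        coords = out / f"layout_{cond_name}.tsv"
        with open(coords, "w") as handle:
            handle.write("chromosome\tx\ty\n")
            for node, (x, y) in lay.coordinates.items():
                handle.write(f"{node}\t{x:.17g}\t{y:.17g}\n")
        paths[f"layout_{cond_name}"] = coords
    timings["layout"] = time.time() - t

    manifest = {
        "package_version": __version__,
        "config": _config_echo(cfg),
        "seeds": {**seeds, "layout_used": layout_seed},
        "n_genes_analyzed": control.n_genes,
        "n_genes_dropped_low_count": n_dropped,
        "n_sub_programs": len(grps_control.sub_grps),
        "timings_sec": {k: round(v, 3) for k, v in timings.items()},
        "total_sec": round(time.time() - t0, 3),
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return ResultBundle(
        config=cfg,
        annotation=annotation,
        control_expression=control,
        tumor_expression=tumor,
        mi_control=mi_control,
        mi_tumor=mi_tumor,
        grps_control=grps_control,
        grps_tumor=grps_tumor,
        indicator_rows=indicator_rows,
        condition_records=condition_records,
        cis_trans_records=cis_trans_records,
        graphs=graphs,
        layouts=layouts,
        manifest=manifest,
        paths=paths,
    )


def _config_echo(cfg: PipelineConfig) -> dict:
    echo = dataclasses.asdict(cfg)
    return json.loads(json.dumps(echo, default=str))
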