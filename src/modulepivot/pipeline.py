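"""End-to-end orchestration: modules → enrichment → pivots → targets → PPI.

One validated config drives the whole run.  Every stage writes deterministic
TSVs into the output directory and the run ends with a ``manifest.json``
listing each data output with its SHA-256 hash, so a rerun on identical
inputs is byte-identical and trivially checkable.  The run log (which
carries wall-clock timings) is kept out of the manifest.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import logging
import time
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import to_tree

from . import coexpression, drug_response, ppi as ppi_mod
from .data_io import (
    read_expression,
    read_gmt,
    read_interactions,
    read_ppi_edges,
    write_sif,
    write_table,
)
from .enrichment import cross_module_term_counts, enrich_module
from .pivot import core_regulators, pivot_scan

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """All config violations, reported at once."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Paths and parameters of a full run.

    Defaults follow the conventional cutoffs of each stage: GO-style
    enrichment at p = q = 0.01, pivots at raw p < 0.01 with at least two
    interacting pairs, interaction scores kept at >= 0.5 (inclusive), PPI
    edges at > 950 (strict), oversized co-expression modules removed at 500
    genes.
    """

    # inputs (None disables the stages that need them)
    expression: str | None = None
    design: str | None = None
    gmt: str | None = None
    interactions: str | None = None
    ppi_edges: str | None = None
    ppi_nodes: str | None = None  # optional node-subset file (one ID per line)
    out_dir: str = "modulepivot_out"
    seed: int = 0

    # co-expression
    power: int | str | None = None  # None = sample-size default; "scalefree"
    signed: bool = False
    r2_cutoff: float = 0.85
    cut_height: float = 0.95  # fraction of the merge-height range
    min_module_size: int = 30
    max_module_size: int = 500

    # enrichment
    enrich_p_cutoff: float = 0.01
    enrich_q_cutoff: float = 0.01
    min_term_size: int = 10
    max_term_size: int = 500

    # pivots
    pivot_p_cutoff: float = 0.01
    min_pairs: int = 2
    interaction_min_score: float = 0.5

    # differential expression / reversal
    control_group: str = "healthy"
    model_group: str = "model"
    drug_groups: tuple[str, ...] | None = None  # None = every other group
    fc_cut: float = 1.0
    de_q_cut: float = 0.05
    de_method: str = "moderated"  # moderated | student | welch

    # PPI
    ppi_min_score: float = 950.0
    min_cluster_size: int = 3


def validate_config(raw: dict | PipelineConfig) -> PipelineConfig:
    """Check ranges and keys; aggregate every violation into one error."""
    if isinstance(raw, PipelineConfig):
        config, errors = raw, []
    else:
        known = {f.name for f in fields(PipelineConfig)}
        errors = []
        clean = {}
        for key, value in raw.items():
            if key not in known:
                hint = difflib.get_close_matches(key, known, n=1)
                suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
                errors.append(f"unknown key {key!r}{suffix}")
                continue
            clean[key] = value
        if "drug_groups" in clean and clean["drug_groups"] is not None:
            clean["drug_groups"] = tuple(clean["drug_groups"])
        config = PipelineConfig(**clean)

    for name in ("enrich_p_cutoff", "enrich_q_cutoff", "pivot_p_cutoff",
                 "de_q_cut", "r2_cutoff"):
        v = getattr(config, name)
        if not 0.0 < v <= 1.0:
            errors.append(f"{name}={v} out of range (0, 1]")
    if not 0.0 < config.cut_height <= 1.0:
        errors.append(f"cut_height={config.cut_height} out of range (0, 1]")
    for name in ("min_module_size", "max_module_size", "min_pairs",
                 "min_term_size", "max_term_size", "min_cluster_size"):
        if getattr(config, name) < 1:
            errors.append(f"{name} must be >= 1")
    if config.power is not None and config.power != "scalefree":
        if not isinstance(config.power, int) or config.power < 1:
            errors.append(
                "power must be an integer >= 1, 'scalefree', or null "
                "for the sample-size default"
            )
    if config.fc_cut < 0:
        errors.append("fc_cut must be >= 0")
    if config.de_method not in ("moderated", "student", "welch"):
        errors.append(
            f"de_method {config.de_method!r} not one of moderated/student/welch"
        )
    if errors:
        raise ConfigError(errors)
    logger.info("config validated: %s", config_to_dict(config))
    return config


def config_to_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("drug_groups") is not None:
        d["drug_groups"] = list(d["drug_groups"])
    return d


def load_config_file(path: str | Path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(["config file must hold a mapping"])
    return validate_config(raw)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def linkage_to_newick(dendrogram: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string (heights as
    branch lengths), iteratively so deep trees do not hit recursion limits."""
    root = to_tree(dendrogram)
    parts: dict[int, str] = {}
    stack = [(root, False)]
    while stack:
        node, expanded = stack.pop()
        if node.is_leaf():
            parts[node.id] = f"{leaf_names[node.id]}:0"
            continue
        if not expanded:
            stack.append((node, True))
            stack.append((node.left, False))
            stack.append((node.right, False))
        else:
            left, right = parts.pop(node.left.id), parts.pop(node.right.id)
            parts[node.id] = f"({left},{right}):{node.dist:.10g}"
    return parts[root.id] + ";"


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage in order and return the output manifest.

    Stages needing an input path that was not configured are skipped (and
    recorded as skipped in the manifest); a stage that starts and fails
    aborts the run with the stage name and cause.
    """
    config = validate_config(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "files": {}}

    config_path = out / "config.yaml"
    with open(config_path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)
    _register(manifest, "config", [config_path], out)

    stage_state: dict = {}
    stage_plan = [
        ("modules", _stage_modules, config.expression is not None),
        ("enrich", _stage_enrich, config.gmt is not None),
        ("pivots", _stage_pivots, config.interactions is not None),
        ("targets", _stage_targets, config.expression is not None),
        ("ppi", _stage_ppi, config.ppi_edges is not None),
    ]
    for name, fn, enabled in stage_plan:
        if not enabled:
            manifest["stages"][name] = "skipped (no input configured)"
            logger.info("stage %s skipped: input not configured", name)
            continue
        t0 = time.perf_counter()
        try:
            outputs = fn(config, stage_state, out)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            manifest["stages"][name] = f"failed: {exc}"
            _write_manifest(manifest, out, partial=True)
            raise PipelineError(name, exc) from exc
        _register(manifest, name, outputs, out)
        logger.info("stage %s done in %.2fs (%d files)",
                    name, time.perf_counter() - t0, len(outputs))
    _write_manifest(manifest, out, partial=False)
    return manifest


def _register(manifest: dict, stage: str, paths: list[Path], out: Path) -> None:
    manifest["stages"][stage] = "ok"
    for p in paths:
        manifest["files"][str(p.relative_to(out))] = _sha256(p)


def _write_manifest(manifest: dict, out: Path, partial: bool) -> None:
    manifest["partial"] = partial
    with open(out / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_modules(config: PipelineConfig, state: dict, out: Path) -> list[Path]:
    study = read_expression(config.expression, config.design)
    partition, scan, tree = coexpression.detect_modules(
        study,
        power=config.power,
        signed=config.signed,
        r2_cutoff=config.r2_cutoff,
        cut_height=config.cut_height,
        min_module_size=config.min_module_size,
        max_module_size=config.max_module_size,
    )
    state["study"], state["partition"] = study, partition
    outputs = []
    p = out / "partition.tsv"
    write_table(partition.to_frame(), p, sort_by=["gene"])
    outputs.append(p)
    if scan is not None:
        p = out / "soft_threshold_scan.tsv"
        write_table(scan.scan, p, sort_by=["power"])
        outputs.append(p)
    p = out / "dendrogram.nwk"
    with open(p, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(linkage_to_newick(tree, study.genes) + "\n")
    outputs.append(p)
    sizes = partition.sizes
    logger.info("modules: %d detected (%s)", len(partition.labels),
                ", ".join(f"{m}={sizes[m]}" for m in partition.labels))
    return outputs


def _stage_enrich(config: PipelineConfig, state: dict, out: Path) -> list[Path]:
    collection = read_gmt(config.gmt)
    rows = enrich_module(
        state["partition"], collection,
        p_cutoff=config.enrich_p_cutoff, q_cutoff=config.enrich_q_cutoff,
        min_term_size=config.min_term_size, max_term_size=config.max_term_size,
    )
    counts = cross_module_term_counts(rows)
    p1, p2 = out / "enrichment.tsv", out / "term_module_counts.tsv"
    write_table(rows, p1, sort_by=["module", "p_value", "term"])
    write_table(counts, p2, sort_by=["term"])
    return [p1, p2]


def _stage_pivots(config: PipelineConfig, state: dict, out: Path) -> list[Path]:
    interactions = read_interactions(
        config.interactions, min_score=config.interaction_min_score
    )
    rows = pivot_scan(
        interactions, state["partition"],
        p_cutoff=config.pivot_p_cutoff, min_pairs=config.min_pairs,
    )
    state["pivots"] = rows
    summary = core_regulators(rows)
    p1, p2 = out / "pivots.tsv", out / "core_regulators.tsv"
    write_table(rows, p1, sort_by=["regulator_class", "regulator", "module"])
    write_table(summary, p2, sort_by=["regulator"])
    return [p1, p2]


def _stage_targets(config: PipelineConfig, state: dict, out: Path) -> list[Path]:
    study = state["study"]
    groups = study.groups
    drug_groups = config.drug_groups
    if drug_groups is None:
        drug_groups = tuple(
            g for g in groups if g not in (config.control_group, config.model_group)
        )
    disease = drug_response.differential_expression(
        study, config.model_group, config.control_group,
        fc_cut=config.fc_cut, q_cut=config.de_q_cut, method=config.de_method,
    )
    outputs = []
    p = out / "de_disease.tsv"
    write_table(disease, p, sort_by=["feature"])
    outputs.append(p)

    target_frames, report_frames = [], []
    for drug in drug_groups:
        treatment = drug_response.differential_expression(
            study, drug, config.model_group,
            fc_cut=config.fc_cut, q_cut=config.de_q_cut, method=config.de_method,
        )
        p = out / f"de_{drug}.tsv"
        write_table(treatment, p, sort_by=["feature"])
        outputs.append(p)
        targets = drug_response.reversal_targets(disease, treatment, drug)
        target_frames.append(targets.to_frame())
        report = drug_response.map_targets_to_modules(
            targets, state["partition"], state.get("pivots")
        )
        report_frames.append(report.to_frame())
        state.setdefault("targets", {})[drug] = targets

    all_targets = (
        pd.concat(target_frames, ignore_index=True)
        if target_frames
        else pd.DataFrame(columns=["feature", "drug", "class"])
    )
    p = out / "targets.tsv"
    write_table(all_targets, p, sort_by=["drug", "class", "feature"])
    outputs.append(p)
    all_reports = (
        pd.concat(report_frames, ignore_index=True)
        if report_frames
        else pd.DataFrame(columns=["drug", "module", "targets"])
    )
    p = out / "target_module_report.tsv"
    write_table(all_reports, p, sort_by=["drug", "module"])
    outputs.append(p)
    return outputs


def _stage_ppi(config: PipelineConfig, state: dict, out: Path) -> list[Path]:
    edge_table = read_ppi_edges(config.ppi_edges)
    node_subset = None
    if config.ppi_nodes:
        with open(config.ppi_nodes, encoding="utf-8") as fh:
            node_subset = {line.strip() for line in fh if line.strip()}
    graph = ppi_mod.build_graph(
        edge_table, node_subset=node_subset, min_score=config.ppi_min_score
    )
    degrees = ppi_mod.hub_ranking(graph)
    clusters = ppi_mod.connected_clusters(
        graph, min_cluster_size=config.min_cluster_size
    )
    p1, p2, p3 = out / "degrees.tsv", out / "clusters.tsv", out / "network.sif"
    write_table(degrees, p1, sort_by=["node"])
    write_table(ppi_mod.clusters_to_frame(clusters), p2, sort_by=["cluster"])
    write_sif(graph.edges(), p3)
    return [p1, p2, p3]
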