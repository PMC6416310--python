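"""Synthetic study generator with planted, recoverable structure.

Emulates the statistical shape of a case/control/treatment expression study
of the kind used to dissect acute liver injury: a few thousand genes measured
in a handful of samples per group, with

* planted co-expression modules — each module's genes share one latent
  factor, so the expected within-module Pearson correlation is controlled
  exactly by the factor-model identity ``r = loading^2 / (loading^2 + sd^2)``;
* planted disease genes shifted by ``±disease_log2fc`` in every diseased
  group, with a configurable fraction of that shift cancelled in each
  drug-treated group (the reversal signature);
* planted module-specific regulators (ncRNA and TF) in a bipartite
  regulator→target table, alongside optional null regulators;
* planted high-degree hubs in an otherwise sparse random PPI network.

Every generator is a pure function of ``(config, seed)``; the ground truth
is returned alongside each artifact so recovery can be scored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import (
    ExpressionStudy,
    GeneSetCollection,
    InteractionTable,
    PPIEdgeTable,
    write_table,
)

UNASSIGNED = "unassigned"

# sub-stream tags so each generator has an independent, reproducible stream
_STREAM_EXPRESSION = 1
_STREAM_INTERACTIONS = 2
_STREAM_PPI = 3
_STREAM_GENESETS = 4


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Group semantics: ``groups[0]`` is the healthy control, ``groups[1]`` the
    untreated disease model, and any further groups are drug treatments.
    Disease shifts apply to all non-control groups; reversal only to drug
    groups.  ``module_size`` may be a single size or one size per module.
    """

    n_genes: int = 600
    n_modules: int = 5
    module_size: int | Sequence[int] = 100
    within_module_correlation: float = 0.7
    n_samples_per_group: int = 5
    groups: tuple[str, ...] = ("healthy", "model", "drug_A", "drug_B")
    n_disease_genes: int = 50
    disease_log2fc: float = 2.0
    reversal_fraction: float = 0.6
    noise_sd: float = 0.5
    baseline: float = 8.0
    # fraction of disease genes drawn from module members rather than the
    # background pool; at 0 the per-gene DE signal-to-noise is exactly
    # disease_log2fc / noise_sd, untangled from the co-expression factors
    disease_in_module_fraction: float = 0.0
    n_regulators: int = 20
    targets_per_regulator: int = 20
    regulator_module_specificity: float = 0.8
    n_null_regulators: int = 0
    interaction_score_min: float = 0.5
    ppi_n_nodes: int = 200
    ppi_n_hubs: int = 5
    hub_neighbors: int = 50
    ppi_background_mean_degree: float = 4.0
    ppi_score_min: float = 951.0
    ppi_score_max: float = 1000.0
    seed: int = 0

    def module_sizes(self) -> list[int]:
        if isinstance(self.module_size, int):
            return [self.module_size] * self.n_modules
        sizes = [int(s) for s in self.module_size]
        if len(sizes) != self.n_modules:
            raise ValueError(
                f"module_size lists {len(sizes)} sizes for {self.n_modules} modules"
            )
        return sizes

    def validate(self) -> None:
        sizes = self.module_sizes()
        if self.n_genes <= 0 or self.n_modules <= 0:
            raise ValueError("n_genes and n_modules must be positive")
        if any(s <= 0 for s in sizes):
            raise ValueError("module sizes must be positive")
        if sum(sizes) > self.n_genes:
            raise ValueError("module sizes sum past n_genes")
        if not 0.0 < self.within_module_correlation < 1.0:
            raise ValueError("within_module_correlation must lie in (0, 1)")
        if self.n_samples_per_group <= 0:
            raise ValueError("n_samples_per_group must be positive")
        if len(self.groups) < 2:
            raise ValueError("need at least control and model groups")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("duplicate group labels")
        if not 0.0 <= self.reversal_fraction <= 1.0:
            raise ValueError("reversal_fraction must lie in [0, 1]")
        if not 0.0 <= self.regulator_module_specificity <= 1.0:
            raise ValueError("regulator_module_specificity must lie in [0, 1]")
        if not 0.0 <= self.disease_in_module_fraction <= 1.0:
            raise ValueError("disease_in_module_fraction must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for name in ("n_disease_genes", "n_regulators", "n_null_regulators",
                     "ppi_n_hubs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_regulators and self.targets_per_regulator <= 0:
            raise ValueError("targets_per_regulator must be positive")
        if self.ppi_n_nodes <= 1:
            raise ValueError("ppi_n_nodes must exceed 1")
        if self.ppi_n_hubs and self.hub_neighbors >= self.ppi_n_nodes:
            raise ValueError("hub_neighbors must be below ppi_n_nodes")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated study, for scoring recovery."""

    true_module_of: dict[str, str] = field(default_factory=dict)
    true_disease_genes_up: frozenset[str] = frozenset()
    true_disease_genes_down: frozenset[str] = frozenset()
    true_reversed_genes: dict[str, frozenset[str]] = field(default_factory=dict)
    true_pivot_regulators: dict[str, str] = field(default_factory=dict)
    true_hubs: frozenset[str] = frozenset()

    def module_labels(self) -> list[str]:
        labels: dict[str, None] = {}
        for lab in self.true_module_of.values():
            if lab != UNASSIGNED:
                labels.setdefault(lab, None)
        return list(labels)

    def genes_in_module(self, label: str) -> list[str]:
        return [g for g, m in self.true_module_of.items() if m == label]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionStudy, SyntheticTruth]:
    """Draw the expression matrix and plant disease/reversal effects.

    Module genes follow ``x = baseline + loading * f_m + eps`` with a latent
    factor ``f_m ~ N(0,1)`` per sample and ``eps ~ N(0, noise_sd)``; the
    loading is solved from the target within-module correlation.  Background
    genes are ``baseline + eps``.  Disease genes gain ``±disease_log2fc`` in
    every non-control group; in each drug group a ``reversal_fraction`` of
    them has that shift cancelled.
    """
    config.validate()
    rng = _rng(config, _STREAM_EXPRESSION)

    sizes = config.module_sizes()
    width = max(4, len(str(config.n_genes)))
    genes = [f"g{i:0{width}d}" for i in range(1, config.n_genes + 1)]
    samples = [
        f"{grp}_{i}"
        for grp in config.groups
        for i in range(1, config.n_samples_per_group + 1)
    ]
    group_of = {s: s.rsplit("_", 1)[0] for s in samples}
    n_samples = len(samples)

    r = config.within_module_correlation
    loading = config.noise_sd * np.sqrt(r / (1.0 - r))

    values = config.baseline + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, n_samples)
    )
    truth = SyntheticTruth(true_module_of={g: UNASSIGNED for g in genes})
    start = 0
    for m, size in enumerate(sizes, start=1):
        label = f"M{m}"
        factor = rng.normal(0.0, 1.0, size=n_samples)
        values[start : start + size, :] += loading * factor
        for g in genes[start : start + size]:
            truth.true_module_of[g] = label
        start += size

    module_genes = np.array(genes[:start])
    background_genes = np.array(genes[start:])

    n_in_mod = int(round(config.disease_in_module_fraction * config.n_disease_genes))
    n_in_bg = config.n_disease_genes - n_in_mod
    if n_in_bg > len(background_genes) or n_in_mod > len(module_genes):
        raise ValueError("not enough genes to place the requested disease genes")
    disease = np.concatenate(
        [
            rng.choice(module_genes, size=n_in_mod, replace=False),
            rng.choice(background_genes, size=n_in_bg, replace=False),
        ]
    )
    n_up = config.n_disease_genes - config.n_disease_genes // 2
    up, down = disease[:n_up], disease[n_up:]
    truth.true_disease_genes_up = frozenset(up)
    truth.true_disease_genes_down = frozenset(down)

    frame = pd.DataFrame(values, index=genes, columns=samples)
    diseased_groups = config.groups[1:]  # model + drugs
    drug_groups = config.groups[2:]
    for grp in diseased_groups:
        cols = [s for s in samples if group_of[s] == grp]
        frame.loc[up, cols] += config.disease_log2fc
        frame.loc[down, cols] -= config.disease_log2fc

    n_rev = int(round(config.reversal_fraction * config.n_disease_genes))
    for drug in drug_groups:
        reversed_genes = rng.choice(disease, size=n_rev, replace=False)
        cols = [s for s in samples if group_of[s] == drug]
        rev_up = [g for g in reversed_genes if g in truth.true_disease_genes_up]
        rev_down = [g for g in reversed_genes if g in truth.true_disease_genes_down]
        frame.loc[rev_up, cols] -= config.disease_log2fc
        frame.loc[rev_down, cols] += config.disease_log2fc
        truth.true_reversed_genes[drug] = frozenset(reversed_genes)

    study = ExpressionStudy(values=frame, group_of=group_of)
    return study, truth


# ---------------------------------------------------------------------------
# regulator→target interactions
# ---------------------------------------------------------------------------

def simulate_interactions(
    config: SimulationConfig, truth: SyntheticTruth
) -> tuple[InteractionTable, SyntheticTruth]:
    """Draw the bipartite regulator→target table.

    Planted regulators are assigned to modules round-robin and draw a
    ``regulator_module_specificity`` fraction of their targets from their
    module, the rest uniformly from all genes; null regulators draw uniformly.
    Regulator classes alternate ncRNA/TF.  Scores are drawn at or above
    ``interaction_score_min`` so default score filtering keeps every row.
    """
    config.validate()
    rng = _rng(config, _STREAM_INTERACTIONS)
    genes = np.array(sorted(truth.true_module_of))
    labels = truth.module_labels()
    if config.n_regulators and not labels:
        raise ValueError("truth has no modules to assign regulators to")

    n_specific = int(round(
        config.regulator_module_specificity * config.targets_per_regulator
    ))
    rows: list[dict[str, object]] = []
    truth.true_pivot_regulators = {}

    def _draw_uniform(n: int, exclude: set[str]) -> list[str]:
        pool = np.array([g for g in genes if g not in exclude])
        return list(rng.choice(pool, size=n, replace=False))

    for i in range(config.n_regulators):
        cls = "ncRNA" if i % 2 == 0 else "TF"
        name = f"{cls}_reg{i + 1:02d}"
        module = labels[i % len(labels)]
        members = truth.genes_in_module(module)
        if n_specific > len(members):
            raise ValueError(
                f"module {module} has {len(members)} genes; "
                f"cannot draw {n_specific} specific targets"
            )
        targets = list(rng.choice(np.array(members), size=n_specific, replace=False))
        targets += _draw_uniform(
            config.targets_per_regulator - n_specific, set(targets)
        )
        truth.true_pivot_regulators[name] = module
        for t in targets:
            rows.append({"regulator": name, "target": t})

    for i in range(config.n_null_regulators):
        cls = "ncRNA" if i % 2 == 0 else "TF"
        name = f"{cls}_null{i + 1:03d}"
        for t in _draw_uniform(config.targets_per_regulator, set()):
            rows.append({"regulator": name, "target": t})

    frame = pd.DataFrame(rows, columns=["regulator", "target"])
    span = 1.0 - config.interaction_score_min
    frame["score"] = config.interaction_score_min + span * rng.random(len(frame))
    frame["regulator_class"] = [
        "ncRNA" if reg.startswith("ncRNA") else "TF" for reg in frame["regulator"]
    ]
    frame = frame.sort_values(["regulator", "target"]).reset_index(drop=True)
    return InteractionTable(frame), truth


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------

def simulate_ppi(config: SimulationConfig) -> tuple[PPIEdgeTable, SyntheticTruth]:
    """Draw a sparse PPI edge list with planted high-degree hubs.

    Background edges are Erdős–Rényi at ``ppi_background_mean_degree``;
    each hub additionally wires to ``hub_neighbors`` random partners.
    Scores are drawn above the strict default threshold (950 on the usual
    0-1000 database scale) so graph construction keeps every edge.
    """
    config.validate()
    rng = _rng(config, _STREAM_PPI)
    n = config.ppi_n_nodes
    width = max(4, len(str(n)))
    nodes = [f"P{i:0{width}d}" for i in range(1, n + 1)]
    hubs = nodes[: config.ppi_n_hubs]

    pairs: set[tuple[str, str]] = set()
    p_bg = min(1.0, config.ppi_background_mean_degree / (n - 1))
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(len(iu)) < p_bg
    for i, j in zip(iu[keep], ju[keep]):
        pairs.add((nodes[i], nodes[j]))

    for hub in hubs:
        others = np.array([v for v in nodes if v != hub])
        for v in rng.choice(others, size=config.hub_neighbors, replace=False):
            pairs.add((min(hub, v), max(hub, v)))

    edges = sorted(pairs)
    scores = rng.uniform(config.ppi_score_min, config.ppi_score_max, size=len(edges))
    frame = pd.DataFrame(
        {
            "protein_a": [a for a, _ in edges],
            "protein_b": [b for _, b in edges],
            "score": np.round(scores, 1),
        }
    )
    truth = SyntheticTruth(true_hubs=frozenset(hubs))
    return PPIEdgeTable(frame), truth


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def simulate_gene_sets(
    config: SimulationConfig,
    truth: SyntheticTruth,
    pad_per_module: int = 20,
    n_null_terms: int = 20,
) -> GeneSetCollection:
    """Build a GMT-style collection with one term per planted module.

    Each module term holds the module's genes padded with ``pad_per_module``
    random background genes (so enrichment is strong but not degenerate);
    null terms are random draws and should not enrich anywhere.
    """
    config.validate()
    rng = _rng(config, _STREAM_GENESETS)
    genes = np.array(sorted(truth.true_module_of))
    background = np.array(
        [g for g in genes if truth.true_module_of[g] == UNASSIGNED]
    )
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for label in truth.module_labels():
        members = set(truth.genes_in_module(label))
        n_pad = min(pad_per_module, len(background))
        if n_pad:
            members |= set(rng.choice(background, size=n_pad, replace=False))
        sets[f"SET_{label}"] = (f"planted term for module {label}", frozenset(members))
    for i in range(1, n_null_terms + 1):
        size = int(rng.integers(10, 51))
        members = frozenset(rng.choice(genes, size=size, replace=False))
        sets[f"NULL{i:02d}"] = ("random null term", members)
    return GeneSetCollection(sets=sets)


# ---------------------------------------------------------------------------
# fixture writer
# ---------------------------------------------------------------------------

def write_fixture(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate everything and write the study to ``out_dir`` as flat files.

    Writes ``expression.tsv``, ``design.tsv``, ``interactions.tsv``,
    ``ppi.tsv``, ``sets.gmt`` and ``truth.json``; returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study, truth = simulate_expression(config)
    interactions, truth = simulate_interactions(config, truth)
    ppi, ppi_truth = simulate_ppi(config)
    truth.true_hubs = ppi_truth.true_hubs
    sets = simulate_gene_sets(config, truth)

    paths = {name: out / fname for name, fname in [
        ("expression", "expression.tsv"),
        ("design", "design.tsv"),
        ("interactions", "interactions.tsv"),
        ("ppi", "ppi.tsv"),
        ("gmt", "sets.gmt"),
        ("truth", "truth.json"),
    ]}

    expr = study.values.copy()
    expr.insert(0, "gene", expr.index)
    expr.to_csv(paths["expression"], sep="\t", index=False,
                lineterminator="\n", float_format="%.6f")
    write_table(
        pd.DataFrame(
            {"sample": study.samples,
             "group": [study.group_of[s] for s in study.samples]}
        ),
        paths["design"],
        sort_by=["sample"],
    )
    write_table(interactions.frame, paths["interactions"],
                sort_by=["regulator", "target"])
    write_table(ppi.frame, paths["ppi"], sort_by=["protein_a", "protein_b"])
    with open(paths["gmt"], "w", encoding="utf-8", newline="\n") as fh:
        for term in sorted(sets.sets):
            desc, members = sets.sets[term]
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")
    with open(paths["truth"], "w", encoding="utf-8", newline="\n") as fh:
        json.dump(truth_to_json(truth), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def truth_to_json(truth: SyntheticTruth) -> dict[str, object]:
    return {
        "true_module_of": dict(sorted(truth.true_module_of.items())),
        "true_disease_genes_up": sorted(truth.true_disease_genes_up),
        "true_disease_genes_down": sorted(truth.true_disease_genes_down),
        "true_reversed_genes": {
            d: sorted(g) for d, g in sorted(truth.true_reversed_genes.items())
        },
        "true_pivot_regulators": dict(sorted(truth.true_pivot_regulators.items())),
        "true_hubs": sorted(truth.true_hubs),
    }


def truth_from_json(payload: dict[str, object]) -> SyntheticTruth:
    return SyntheticTruth(
        true_module_of=dict(payload["true_module_of"]),
        true_disease_genes_up=frozenset(payload["true_disease_genes_up"]),
        true_disease_genes_down=frozenset(payload["true_disease_genes_down"]),
        true_reversed_genes={
            d: frozenset(g) for d, g in payload["true_reversed_genes"].items()
        },
        true_pivot_regulators=dict(payload["true_pivot_regulators"]),
        true_hubs=frozenset(payload["true_hubs"]),
    )


def config_to_dict(config: SimulationConfig) -> dict[str, object]:
    d = dataclasses.asdict(config)
    d["groups"] = list(config.groups)
    if not isinstance(config.module_size, int):
        d["module_size"] = list(config.module_size)
    return d
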