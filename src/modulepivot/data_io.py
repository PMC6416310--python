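"""Reading and writing the flat-file formats the pipeline consumes.

All tables are plain TSV (UTF-8, ``\\n`` line endings); gene-set collections
use the standard GMT format.  Every reader enforces the container invariants
up front so downstream stages can assume clean inputs, and every writer is
deterministic so repeated runs are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REGULATOR_CLASSES = ("ncRNA", "TF")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionStudy:
    """A gene-by-sample abundance matrix with per-sample group labels.

    Values are assumed to already be on a log-like scale (e.g. log2 of
    normalized counts); no normalization is performed here.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with sample IDs as columns.
    group_of
        Mapping from every sample ID to its group label
        (e.g. ``healthy``, ``model``, ``drug_A``).
    """

    values: pd.DataFrame
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        genes = self.values.index
        samples = self.values.columns
        _check_unique(genes, "gene")
        _check_unique(samples, "sample")
        missing = [s for s in samples if s not in self.group_of]
        if missing:
            raise ValueError(f"sample {missing[0]!r} has no group label in the design")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.group_of[s], None)
        return list(seen)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.samples if self.group_of[s] == group]

    def group_matrix(self, group: str) -> pd.DataFrame:
        cols = self.samples_in_group(group)
        if not cols:
            raise KeyError(f"no samples in group {group!r}")
        return self.values[cols]


@dataclass
class GeneSetCollection:
    """Named gene sets (GO terms, KEGG pathways, ...) as flat sets.

    ``sets`` maps term ID to ``(description, frozenset of member genes)``.
    ``universe`` is an optional explicit background; when absent the
    enrichment stage derives one from the partition under test.
    """

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for term, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {term!r} is empty")
            if any(not isinstance(m, str) or not m for m in members):
                raise ValueError(f"gene set {term!r} has an empty member ID")

    def annotated_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for _, members in self.sets.values():
            out |= members
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class InteractionTable:
    """Scored regulator→target pairs with a regulator class (ncRNA or TF)."""

    frame: pd.DataFrame = field(repr=False)

    COLUMNS = ("regulator", "target", "score", "regulator_class")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"interaction table lacks columns {missing}")
        if not np.isfinite(self.frame["score"].to_numpy(dtype=float)).all():
            raise ValueError("interaction table has non-finite scores")
        bad = set(self.frame["regulator_class"]) - set(REGULATOR_CLASSES)
        if bad:
            raise ValueError(f"unknown regulator class {sorted(bad)[0]!r}")
        if self.frame.duplicated(subset=["regulator", "target"]).any():
            raise ValueError("duplicate (regulator, target) rows")
        self.frame = self.frame.reset_index(drop=True)

    def targets_of(self, regulator: str) -> frozenset[str]:
        rows = self.frame[self.frame["regulator"] == regulator]
        return frozenset(rows["target"])

    def subset_class(self, regulator_class: str) -> "InteractionTable":
        if regulator_class not in REGULATOR_CLASSES:
            raise ValueError(f"unknown regulator class {regulator_class!r}")
        sub = self.frame[self.frame["regulator_class"] == regulator_class]
        return InteractionTable(sub.copy())

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class PPIEdgeTable:
    """Undirected scored protein-protein edges, deduplicated, no self-loops."""

    frame: pd.DataFrame = field(repr=False)

    COLUMNS = ("protein_a", "protein_b", "score")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"PPI edge table lacks columns {missing}")
        self.frame = _canonicalize_edges(self.frame)

    def __len__(self) -> int:
        return len(self.frame)


def _canonicalize_edges(frame: pd.DataFrame) -> pd.DataFrame:
    """Order endpoints, drop self-loops, keep max score per undirected pair."""
    df = frame.copy()
    if not np.isfinite(df["score"].to_numpy(dtype=float)).all():
        raise ValueError("PPI edge table has non-finite scores")
    df = df[df["protein_a"] != df["protein_b"]]
    a = df[["protein_a", "protein_b"]].min(axis=1)
    b = df[["protein_a", "protein_b"]].max(axis=1)
    df = pd.DataFrame({"protein_a": a, "protein_b": b, "score": df["score"]})
    df = (
        df.groupby(["protein_a", "protein_b"], as_index=False)["score"]
        .max()
        .sort_values(["protein_a", "protein_b"])
        .reset_index(drop=True)
    )
    return df


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} ID {i!r}")
        seen.add(i)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, design_path: str | Path) -> ExpressionStudy:
    """Read an expression matrix TSV plus a sample design TSV.

    The matrix has a header row of sample IDs and gene IDs in the first
    column; the design has columns ``sample`` and ``group``.  Genes with any
    missing value are dropped (a count is logged); duplicate gene or sample
    IDs and samples absent from the design are hard errors.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    _check_unique(values.index, "gene")
    _check_unique(values.columns, "sample")

    design = pd.read_csv(design_path, sep="\t", dtype=str)
    for col in ("sample", "group"):
        if col not in design.columns:
            raise ValueError(f"design file lacks column {col!r}")
    _check_unique(design["sample"], "design sample")
    group_of = dict(zip(design["sample"], design["group"]))
    for s in values.columns:
        if s not in group_of:
            raise ValueError(f"sample {s!r} in matrix is absent from design")

    n_before = len(values)
    values = values.dropna(axis=0, how="any")
    dropped = n_before - len(values)
    if dropped:
        logger.info("dropped %d gene(s) with missing values", dropped)
    values = values.astype(float)
    group_of = {s: group_of[s] for s in values.columns}
    return ExpressionStudy(values=values, group_of=group_of)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``term TAB description TAB member TAB member ...``."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: fewer than 3 fields")
            term, desc = fields[0], fields[1]
            if term in sets:
                raise ValueError(f"GMT line {lineno}: duplicate term ID {term!r}")
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise ValueError(f"GMT line {lineno}: term {term!r} has no members")
            sets[term] = (desc, members)
    return GeneSetCollection(sets=sets)


def read_interactions(
    path: str | Path,
    min_score: float = 0.5,
    regulator_class: str | None = None,
) -> InteractionTable:
    """Read a regulator→target TSV, keeping rows with ``score >= min_score``.

    The threshold is inclusive, matching the convention of interaction
    databases that publish "score >= 0.5" cutoffs on their native scale.
    If the file has no ``regulator_class`` column, ``regulator_class`` must
    be given and is applied to every row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("regulator", "target", "score"):
        if col not in df.columns:
            raise ValueError(f"interaction file lacks column {col!r}")
    scores = pd.to_numeric(df["score"], errors="coerce")
    if scores.isna().any():
        bad = int(scores.index[scores.isna()][0])
        # +2: header line plus 1-based numbering
        raise ValueError(f"non-numeric score at line {bad + 2}")
    df["score"] = scores.astype(float)
    if "regulator_class" not in df.columns:
        if regulator_class is None:
            raise ValueError(
                "file has no regulator_class column and none was supplied"
            )
        df["regulator_class"] = regulator_class
    elif regulator_class is not None:
        df = df[df["regulator_class"] == regulator_class]

    n_before = len(df)
    df = df[df["score"] >= min_score]
    df = df.drop_duplicates(subset=["regulator", "target"])
    logger.info(
        "interactions: kept %d of %d rows at min_score=%g", len(df), n_before, min_score
    )
    df = df.sort_values(["regulator", "target"]).reset_index(drop=True)
    return InteractionTable(df[list(InteractionTable.COLUMNS)])


def read_ppi_edges(path: str | Path) -> PPIEdgeTable:
    """Read a PPI edge TSV (``protein_a``, ``protein_b``, ``score``).

    Self-loops are dropped; duplicate undirected pairs keep the max score.
    Score filtering happens later, at graph construction, because PPI
    databases use a strict threshold on their native 0-1000 scale.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str})
    for col in PPIEdgeTable.COLUMNS:
        if col not in df.columns:
            raise ValueError(f"PPI file lacks column {col!r}")
    df["score"] = pd.to_numeric(df["score"], errors="raise").astype(float)
    return PPIEdgeTable(df)


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------

def write_table(
    rows: pd.DataFrame | Sequence[Mapping[str, object]],
    path: str | Path,
    sort_by: Sequence[str] | None = None,
) -> None:
    """Write rows as a deterministic TSV (UTF-8, ``\\n`` endings).

    Rows are sorted by ``sort_by`` (default: all columns, left to right) so
    identical content always yields byte-identical files.  An empty input
    still writes the header line.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        rows = list(rows)
        df = pd.DataFrame(rows)
    if df.columns.empty:
        raise ValueError("cannot write a table with no columns")
    keys = list(sort_by) if sort_by else list(df.columns)
    if len(df):
        df = df.sort_values(keys, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")


def write_sif(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write an undirected network as SIF (``node TAB pp TAB node``)."""
    canon = sorted({(min(a, b), max(a, b)) for a, b in edges})
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for a, b in canon:
            fh.write(f"{a}\tpp\t{b}\n")
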