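"""WGCNA-style co-expression module detection.

The stage runs: Pearson correlation → soft-thresholded adjacency (power
chosen by scale-free topology fit) → topological overlap matrix (TOM) →
average-linkage clustering of 1−TOM → static height cut with a minimum
module size → removal of oversized modules.

The soft power is the smallest candidate whose signed scale-free fit R²
reaches the cutoff (default 0.85), the convention of weighted co-expression
network analysis; the TOM is the standard unsigned topological overlap

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    L_ij = Σ_u a_iu a_uj,   k_i = Σ_u a_iu.

Modules are labeled ``M1, M2, ...`` in decreasing size order; genes in
clusters below the minimum size, or in modules removed by the size filter,
carry the reserved label ``unassigned``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .data_io import ExpressionStudy

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

DEFAULT_CANDIDATE_POWERS = tuple(range(1, 21))
DEFAULT_R2_CUTOFF = 0.85
DEFAULT_CUT_HEIGHT = 0.95
DEFAULT_MIN_MODULE_SIZE = 30
DEFAULT_MAX_MODULE_SIZE = 500


def default_soft_power(n_samples: int, signed: bool = False) -> int:
    """Sample-size-based default soft power (the WGCNA FAQ table).

    With few samples, correlation noise makes the scale-free fit criterion
    unreliable — it drifts toward degenerate high powers where all
    adjacencies are near zero — so the field's standing recommendation is a
    fixed power keyed to sample count: unsigned 10/9/8/6 (signed doubled)
    for <20, <30, <40 and >=40 samples.
    """
    if n_samples < 20:
        p = 10
    elif n_samples < 30:
        p = 9
    elif n_samples < 40:
        p = 8
    else:
        p = 6
    return 2 * p if signed else p


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    genes: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.genes), len(self.genes)):
            raise ValueError("correlation matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix not symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("correlation diagonal must be 1")


@dataclass
class SoftThresholdScan:
    """Scale-free fit per candidate power, plus the chosen power."""

    scan: pd.DataFrame  # columns: power, scale_free_r2, mean_connectivity
    chosen_power: int

    def __post_init__(self) -> None:
        if self.chosen_power not in set(self.scan["power"]):
            raise ValueError("chosen_power absent from the scan")


@dataclass
class TOMatrix:
    genes: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("TOM not symmetric")
        if v.min() < -1e-12 or v.max() > 1.0 + 1e-12:
            raise ValueError("TOM values outside [0, 1]")


@dataclass
class ModulePartition:
    """Gene → module assignment with a reserved ``unassigned`` label."""

    module_of: dict[str, str]

    @property
    def labels(self) -> list[str]:
        labs = sorted(
            {m for m in self.module_of.values() if m != UNASSIGNED},
            key=_module_sort_key,
        )
        return labs

    @property
    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.module_of.values():
            out[m] = out.get(m, 0) + 1
        return out

    def genes_in(self, label: str) -> frozenset[str]:
        return frozenset(g for g, m in self.module_of.items() if m == label)

    @property
    def genes(self) -> list[str]:
        return list(self.module_of)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": list(self.module_of), "module": list(self.module_of.values())}
        ).sort_values(["gene"]).reset_index(drop=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ModulePartition":
        return cls(module_of=dict(zip(frame["gene"].astype(str),
                                      frame["module"].astype(str))))


def _module_sort_key(label: str) -> tuple[int, str]:
    if label.startswith("M") and label[1:].isdigit():
        return (int(label[1:]), "")
    return (1 << 30, label)


# ---------------------------------------------------------------------------
# correlation and adjacency
# ---------------------------------------------------------------------------

def correlation_matrix(study: ExpressionStudy) -> CorrelationMatrix:
    """Pearson correlation between every pair of gene profiles."""
    x = study.values.to_numpy(dtype=float)
    if x.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    sd = x.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(
            f"gene {study.genes[flat[0]]!r} has zero variance; remove it first"
        )
    r = np.corrcoef(x)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(genes=study.genes, values=r)


def adjacency(corr: CorrelationMatrix, power: int, signed: bool = False) -> np.ndarray:
    """Soft-threshold the correlation into a weighted adjacency.

    Unsigned: ``a_ij = |r_ij|^power``; signed: ``a_ij = ((1+r_ij)/2)^power``.
    The diagonal is zeroed (no self-connectivity).
    """
    if int(power) < 1:
        raise ValueError("power must be >= 1")
    r = corr.values
    a = np.abs(r) ** power if not signed else ((1.0 + r) / 2.0) ** power
    np.fill_diagonal(a, 0.0)
    return a


def scale_free_fit(adj: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit of the connectivity distribution.

    Bins the connectivities ``k_i = Σ_j a_ij`` into ``n_bins`` equal-width
    bins and regresses log10(bin frequency) on log10(bin mean k) over
    occupied bins; returns ``(signed_r2, slope)`` where the R² is negated
    when the slope is positive (the usual sign convention, so that only
    decreasing power-law-like distributions score highly).
    """
    k = adj.sum(axis=1)
    if np.allclose(k, k[0]):
        raise ValueError("degenerate connectivity: all k identical")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        mean_k = k[mask].mean()
        freq = mask.mean()
        if mean_k <= 0 or freq <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(freq))
    if len(xs) < 2:
        raise ValueError("fewer than 2 occupied connectivity bins")
    slope, intercept = np.polyfit(xs, ys, 1)
    yhat = slope * np.asarray(xs) + intercept
    ss_res = float(np.sum((np.asarray(ys) - yhat) ** 2))
    ss_tot = float(np.sum((np.asarray(ys) - np.mean(ys)) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    if slope > 0:
        r2 = -abs(r2)
    return float(r2), float(slope)


def select_soft_power(
    corr: CorrelationMatrix,
    candidate_powers: tuple[int, ...] = DEFAULT_CANDIDATE_POWERS,
    r2_cutoff: float = DEFAULT_R2_CUTOFF,
    signed: bool = False,
    n_bins: int = 10,
) -> SoftThresholdScan:
    """Scan candidate powers; choose the smallest reaching the R² cutoff.

    If no candidate reaches the cutoff, the power maximizing the signed R²
    is chosen and a warning is issued.
    """
    if not candidate_powers:
        raise ValueError("candidate_powers is empty")
    powers = sorted(int(p) for p in candidate_powers)
    rows = []
    for p in powers:
        a = adjacency(corr, p, signed=signed)
        r2, slope = scale_free_fit(a, n_bins=n_bins)
        rows.append(
            {"power": p, "scale_free_r2": r2, "slope": slope,
             "mean_connectivity": float(a.sum(axis=1).mean())}
        )
    scan = pd.DataFrame(rows)
    ok = scan[scan["scale_free_r2"] >= r2_cutoff]
    if len(ok):
        chosen = int(ok["power"].iloc[0])
    else:
        chosen = int(scan.loc[scan["scale_free_r2"].idxmax(), "power"])
        warnings.warn(
            f"no candidate power reached scale-free R^2 >= {r2_cutoff}; "
            f"using power {chosen} with the best fit",
            stacklevel=2,
        )
    logger.info("soft power chosen: %d", chosen)
    return SoftThresholdScan(scan=scan, chosen_power=chosen)


# ---------------------------------------------------------------------------
# topological overlap and clustering
# ---------------------------------------------------------------------------

def tom_similarity(adj: np.ndarray, genes: list[str] | None = None) -> TOMatrix:
    """Topological overlap similarity of a weighted adjacency.

    Requires a symmetric adjacency in [0, 1] with a zero diagonal; the
    result has unit diagonal by convention.
    """
    a = np.asarray(adj, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if a.min() < 0 or a.max() > 1:
        raise ValueError("adjacency values must lie in [0, 1]")
    if not np.allclose(np.diag(a), 0.0):
        raise ValueError("adjacency diagonal must be zero")
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    if genes is None:
        genes = [f"g{i}" for i in range(a.shape[0])]
    return TOMatrix(genes=genes, values=tom)


def cluster_dendrogram(tom: TOMatrix) -> np.ndarray:
    """Average-linkage clustering of the dissimilarity 1 − TOM.

    Returns a scipy linkage matrix; merge heights are non-decreasing.
    """
    n = len(tom.genes)
    if n < 2:
        raise ValueError("need at least 2 genes to cluster")
    d = 1.0 - tom.values
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    return linkage(condensed, method="average")


def cut_modules(
    dendrogram: np.ndarray,
    genes: list[str],
    cut_height: float = DEFAULT_CUT_HEIGHT,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
) -> ModulePartition:
    """Cut the tree at a fixed height and drop undersized clusters.

    ``cut_height`` is a fraction in (0, 1] of the merge-height range (the
    static-cut convention of the standard tree-cutting tools): the tree is
    cut at ``h_min + cut_height * (h_max − h_min)``, which keeps the cut
    meaningful whatever the absolute TOM scale the soft power produced.
    Surviving clusters are labeled ``M1, M2, ...`` in decreasing size order
    (ties broken by the lexicographically smallest member gene ID); genes in
    clusters below ``min_module_size`` become ``unassigned``.
    """
    if not 0.0 < cut_height <= 1.0:
        raise ValueError("cut_height must lie in (0, 1]")
    if min_module_size < 1:
        raise ValueError("min_module_size must be >= 1")
    heights = dendrogram[:, 2]
    threshold = heights.min() + cut_height * (heights.max() - heights.min())
    flat = fcluster(dendrogram, t=threshold, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for gene, c in zip(genes, flat):
        clusters.setdefault(int(c), []).append(gene)
    surviving = [
        members for members in clusters.values() if len(members) >= min_module_size
    ]
    surviving.sort(key=lambda ms: (-len(ms), min(ms)))
    module_of = {g: UNASSIGNED for g in genes}
    for rank, members in enumerate(surviving, start=1):
        for g in members:
            module_of[g] = f"M{rank}"
    return ModulePartition(module_of=module_of)


def filter_modules(
    partition: ModulePartition,
    max_module_size: int = DEFAULT_MAX_MODULE_SIZE,
) -> ModulePartition:
    """Remove oversized modules (size ≥ ``max_module_size``) to unassigned.

    Remaining modules are relabeled ``M1, M2, ...`` preserving their
    original order; removed modules are logged.
    """
    sizes = partition.sizes
    keep = [lab for lab in partition.labels if sizes[lab] < max_module_size]
    removed = [lab for lab in partition.labels if lab not in keep]
    if removed:
        logger.info(
            "size filter removed module(s): %s",
            ", ".join(f"{lab} (n={sizes[lab]})" for lab in removed),
        )
    relabel = {old: f"M{i}" for i, old in enumerate(keep, start=1)}
    module_of = {
        g: relabel.get(m, UNASSIGNED) for g, m in partition.module_of.items()
    }
    return ModulePartition(module_of=module_of)


def detect_modules(
    study: ExpressionStudy,
    power: int | str | None = None,
    signed: bool = False,
    candidate_powers: tuple[int, ...] = DEFAULT_CANDIDATE_POWERS,
    r2_cutoff: float = DEFAULT_R2_CUTOFF,
    cut_height: float = DEFAULT_CUT_HEIGHT,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    max_module_size: int = DEFAULT_MAX_MODULE_SIZE,
) -> tuple[ModulePartition, SoftThresholdScan | None, np.ndarray]:
    """Run the whole co-expression stage on one study.

    ``power=None`` uses the sample-size default (see ``default_soft_power``)
    while still computing the soft-threshold scan as a diagnostic;
    ``power="scalefree"`` adopts the scan's scale-free choice; an integer
    fixes the power by hand (no scan).  Returns the size-filtered partition,
    the scan (None when the power was fixed by hand) and the linkage matrix.
    """
    corr = correlation_matrix(study)
    scan: SoftThresholdScan | None = None
    if power is None or power == "scalefree":
        scan = select_soft_power(
            corr, candidate_powers=candidate_powers, r2_cutoff=r2_cutoff,
            signed=signed,
        )
        if power == "scalefree":
            power = scan.chosen_power
        else:
            power = default_soft_power(len(study.samples), signed=signed)
            logger.info(
                "using sample-size default power %d (scale-free scan chose %d)",
                power, scan.chosen_power,
            )
    a = adjacency(corr, power, signed=signed)
    tom = tom_similarity(a, genes=corr.genes)
    tree = cluster_dendrogram(tom)
    partition = cut_modules(
        tree, corr.genes, cut_height=cut_height, min_module_size=min_module_size
    )
    partition = filter_modules(partition, max_module_size=max_module_size)
    return partition, scan, tree
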