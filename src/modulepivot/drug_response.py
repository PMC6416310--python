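"""Differential expression and directional drug-reversal target calling.

The reversal signature of drug action: features up-regulated in disease
(model vs healthy) and down-regulated by treatment (treated vs model) are
*inhibited* targets; the mirror case gives *promoted* targets.  The same
machinery applies unchanged to transcript and protein abundance tables —
anything shaped as features × samples on a log-like scale.

Per-feature testing defaults to an empirical-Bayes moderated t-statistic:
the pooled per-feature variance is shrunk toward a prior fitted across all
features (the scaled-F model of the moderated t-test familiar from limma),
which buys substantial power at the tiny group sizes (n ≈ 5) these designs
use while falling back gracefully when features are heteroscedastic.
Plain Welch or Student t-tests are available via ``method``.  Calls combine
BH-adjusted significance with a fold-change floor (defaults |log2FC| >= 1,
q <= 0.05); all knobs are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .coexpression import ModulePartition
from .data_io import ExpressionStudy
from .enrichment import bh_adjust

logger = logging.getLogger(__name__)

DE_COLUMNS = ["feature", "log2_fold_change", "p_value", "q_value", "direction"]


@dataclass
class TargetSets:
    """Inhibited and promoted reversal targets of one drug."""

    drug: str
    inhibited: frozenset[str]
    promoted: frozenset[str]

    def __post_init__(self) -> None:
        if self.inhibited & self.promoted:
            raise ValueError("a feature cannot be both inhibited and promoted")

    @property
    def total(self) -> int:
        return len(self.inhibited) + len(self.promoted)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"feature": f, "drug": self.drug, "class": "inhibited"}
            for f in sorted(self.inhibited)
        ] + [
            {"feature": f, "drug": self.drug, "class": "promoted"}
            for f in sorted(self.promoted)
        ]
        return pd.DataFrame(rows, columns=["feature", "drug", "class"])


@dataclass
class TargetModuleReport:
    """Where a drug's reversal targets sit in the module landscape."""

    drug: str
    targets_in_modules: dict[str, frozenset[str]] = field(default_factory=dict)
    pivot_overlap: frozenset[str] = frozenset()

    @property
    def modules_hit(self) -> int:
        return sum(1 for v in self.targets_in_modules.values() if v)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"drug": self.drug, "module": m, "targets": ",".join(sorted(ts))}
            for m, ts in sorted(self.targets_in_modules.items())
            if ts
        ]
        return pd.DataFrame(rows, columns=["drug", "module", "targets"])


def _trigamma_inverse(z: float, iterations: int = 25) -> float:
    """Solve trigamma(x) = z by Newton iteration (x > 0, z > 0)."""
    x = 0.5 + 1.0 / z
    for _ in range(iterations):
        tri = special.polygamma(1, x)
        x = x + tri * (1.0 - tri / z) / special.polygamma(2, x)
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Fit the scaled-F prior ``s2 ~ s0^2 * F(df, d0)`` across features.

    Method-of-moments on log s2 (digamma/trigamma identities); returns
    ``(d0, s0^2)`` with ``d0 = inf`` when the observed spread of log s2 is
    no larger than pure chi-square sampling noise (homoscedastic features).
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(s2[ok].mean()) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(e.mean()))
    d0 = 2.0 * _trigamma_inverse(evar)
    s02 = float(np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


def differential_expression(
    study: ExpressionStudy,
    group_a: str,
    group_b: str,
    fc_cut: float = 1.0,
    q_cut: float = 0.05,
    method: str = "moderated",
) -> pd.DataFrame:
    """Per-feature two-group test of ``group_a`` vs ``group_b``.

    ``log2_fold_change = mean(a) − mean(b)`` (values taken as log2-like).
    ``method`` is ``"moderated"`` (empirical-Bayes shrunken pooled variance,
    the default), ``"student"`` (pooled t) or ``"welch"``.  A feature is
    ``up`` when q <= q_cut and log2FC >= fc_cut, ``down`` in the mirror
    case, otherwise ``ns``.  Features constant within both groups at equal
    means get p = 1 by convention.
    """
    a = study.group_matrix(group_a).to_numpy(dtype=float)
    b = study.group_matrix(group_b).to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("both groups need at least 2 samples")

    lfc = a.mean(axis=1) - b.mean(axis=1)
    if method == "moderated":
        # residual variance from the one-way fit over ALL groups in the
        # study (the usual linear-model workflow), then contrast a vs b
        mats = [
            study.group_matrix(g).to_numpy(dtype=float)
            for g in study.groups
            if len(study.samples_in_group(g)) >= 2
        ]
        df = sum(m.shape[1] - 1 for m in mats)
        s2 = sum(m.var(axis=1, ddof=1) * (m.shape[1] - 1) for m in mats) / df
        d0, s02 = _fit_variance_prior(s2, df)
        if np.isinf(d0):
            s2_post, df_total = np.full_like(s2, s02), np.inf
        else:
            s2_post = (d0 * s02 + df * s2) / (d0 + df)
            df_total = df + d0
        logger.info("moderated t: prior df %.2f, prior variance %.4g", d0, s02)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = lfc / np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
    elif method in ("student", "welch"):
        with np.errstate(divide="ignore", invalid="ignore"):
            _, p = stats.ttest_ind(a, b, axis=1, equal_var=(method == "student"))
    else:
        raise ValueError(f"unknown method {method!r}")

    degenerate = ~np.isfinite(p)
    if degenerate.any():
        # zero variance in both groups: identical means are a non-result
        # (p=1); different constant means are an arbitrarily strong call
        equal = np.isclose(lfc, 0.0)
        p = np.where(degenerate & equal, 1.0, p)
        p = np.where(degenerate & ~equal, np.finfo(float).tiny, p)
        logger.info("%d degenerate zero-variance feature(s) handled",
                    int(degenerate.sum()))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q = bh_adjust(p)

    direction = np.where(
        (q <= q_cut) & (lfc >= fc_cut), "up",
        np.where((q <= q_cut) & (lfc <= -fc_cut), "down", "ns"),
    )
    return pd.DataFrame(
        {"feature": study.genes, "log2_fold_change": lfc,
         "p_value": p, "q_value": q, "direction": direction},
        columns=DE_COLUMNS,
    )


def _directional(rows: pd.DataFrame, direction: str) -> frozenset[str]:
    return frozenset(rows.loc[rows["direction"] == direction, "feature"])


def reversal_targets(
    disease_rows: pd.DataFrame,
    treatment_rows: pd.DataFrame,
    drug_label: str,
) -> TargetSets:
    """Intersect disease and treatment calls into directional target sets.

    inhibited = up in disease ∩ down under treatment;
    promoted  = down in disease ∩ up under treatment.
    The two sets are disjoint by construction and their sizes add up to the
    drug's total target count.
    """
    inhibited = _directional(disease_rows, "up") & _directional(
        treatment_rows, "down"
    )
    promoted = _directional(disease_rows, "down") & _directional(
        treatment_rows, "up"
    )
    targets = TargetSets(drug=drug_label, inhibited=inhibited, promoted=promoted)
    assert targets.total == len(inhibited) + len(promoted)
    logger.info(
        "%s: %d inhibited + %d promoted = %d targets",
        drug_label, len(inhibited), len(promoted), targets.total,
    )
    return targets


def map_targets_to_modules(
    targets: TargetSets,
    partition: ModulePartition,
    pivots: pd.DataFrame | None = None,
) -> TargetModuleReport:
    """Locate a drug's targets in the module partition and the pivot list.

    ``unassigned`` never counts as a hit module.  ``pivot_overlap`` collects
    target IDs that also appear as reported pivot regulators (drug targets
    that are themselves module drivers).
    """
    all_targets = targets.inhibited | targets.promoted
    in_modules = {
        m: partition.genes_in(m) & all_targets for m in partition.labels
    }
    overlap: frozenset[str] = frozenset()
    if pivots is not None and len(pivots):
        overlap = frozenset(pivots["regulator"]) & all_targets
    return TargetModuleReport(
        drug=targets.drug, targets_in_modules=in_modules, pivot_overlap=overlap
    )
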