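"""Pivot analysis: ncRNA and TF drivers of co-expression modules.

A regulator "drives" a module when it has at least ``min_pairs`` (default 2)
interaction targets inside the module and the overlap is hypergeometrically
significant (raw p < 0.01 by default — no multiple-testing correction, the
convention of the original pivot procedure; BH is available behind a flag).

The background universe is the set of distinct target genes present in the
loaded interaction table for the regulator class under test — the database's
target space, not the whole genome — so each class (ncRNA, TF) is scanned
separately against its own background.
"""

from __future__ import annotations

import logging

import pandas as pd

from .coexpression import ModulePartition
from .data_io import InteractionTable, REGULATOR_CLASSES
from .enrichment import bh_adjust, hypergeometric_tail

logger = logging.getLogger(__name__)

PIVOT_COLUMNS = [
    "regulator", "regulator_class", "module", "k", "n_reg", "K_mod", "N_bg",
    "p_value",
]


def pivot_scan(
    interactions: InteractionTable,
    partition: ModulePartition,
    p_cutoff: float = 0.01,
    min_pairs: int = 2,
    adjust: bool = False,
) -> pd.DataFrame:
    """Test every (regulator, module) pair within each regulator class.

    For a regulator with target set T (restricted to the class background
    B = all distinct targets of that class) and a module with member overlap
    M = module ∩ B: ``k = |T ∩ M|``, tested as the upper hypergeometric tail
    of drawing ``|T|`` targets from ``|B|``.  Rows with ``k >= min_pairs``
    and ``p < p_cutoff`` are reported.  Self-targeting rows (regulator
    listed as its own target) are dropped first.  With ``adjust=True`` the
    cutoff is applied to BH-adjusted p-values within the class scan instead.
    """
    if len(interactions) == 0:
        raise ValueError("interaction table is empty")
    if not partition.labels:
        raise ValueError("partition has no modules")

    all_rows: list[dict[str, object]] = []
    frame = interactions.frame
    frame = frame[frame["regulator"] != frame["target"]]
    for cls in REGULATOR_CLASSES:
        sub = frame[frame["regulator_class"] == cls]
        if len(sub) == 0:
            continue
        background = frozenset(sub["target"])
        N_bg = len(background)
        module_overlap = {
            m: partition.genes_in(m) & background for m in partition.labels
        }
        if not any(module_overlap.values()):
            raise ValueError(
                f"no mappable targets: {cls} background and partition are disjoint"
            )
        tested: list[dict[str, object]] = []
        for regulator, tgt in sorted(sub.groupby("regulator")["target"]):
            targets = frozenset(tgt) & background
            n_reg = len(targets)
            for module in partition.labels:
                K_mod = len(module_overlap[module])
                if K_mod == 0:
                    continue
                k = len(targets & module_overlap[module])
                if k < min_pairs:
                    continue
                p = hypergeometric_tail(k, K_mod, n_reg, N_bg)
                tested.append(
                    {"regulator": regulator, "regulator_class": cls,
                     "module": module, "k": k, "n_reg": n_reg,
                     "K_mod": K_mod, "N_bg": N_bg, "p_value": p}
                )
        if not tested:
            continue
        if adjust:
            q = bh_adjust([row["p_value"] for row in tested])
            kept = [row for row, qv in zip(tested, q) if qv < p_cutoff]
        else:
            kept = [row for row in tested if row["p_value"] < p_cutoff]
        all_rows.extend(kept)
        logger.info("%s pivot scan: %d significant of %d tested pairs",
                    cls, len(kept), len(tested))

    result = pd.DataFrame(all_rows, columns=PIVOT_COLUMNS)
    if len(result):
        result = result.sort_values(
            ["regulator_class", "p_value", "regulator", "module"],
            kind="mergesort",
        ).reset_index(drop=True)
    return result


def core_regulators(rows: pd.DataFrame, top_n: int | None = None) -> pd.DataFrame:
    """Rank regulators by the number of distinct modules they drive.

    Returns columns ``regulator, regulator_class, modules_driven, modules``
    sorted by modules_driven descending, ties by regulator ID.
    """
    if len(rows) == 0:
        return pd.DataFrame(
            columns=["regulator", "regulator_class", "modules_driven", "modules"]
        )
    grouped = (
        rows.groupby(["regulator", "regulator_class"])["module"]
        .agg(lambda ms: sorted(set(ms)))
        .reset_index()
        .rename(columns={"module": "modules"})
    )
    grouped["modules_driven"] = grouped["modules"].map(len)
    grouped["modules"] = grouped["modules"].map(",".join)
    grouped = grouped.sort_values(
        ["modules_driven", "regulator"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    grouped = grouped[["regulator", "regulator_class", "modules_driven", "modules"]]
    if top_n is not None:
        grouped = grouped.head(int(top_n)).reset_index(drop=True)
    return grouped
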