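"""Per-module gene-set over-representation with BH correction.

Each (module, term) pair with at least one overlapping gene is tested with
an exact hypergeometric upper tail; p-values are BH-adjusted within each
module's family of tested terms, and rows survive when both the raw p and
the adjusted q pass their cutoffs (defaults match the usual GO practice,
p = q = 0.01; KEGG-style runs use p = 0.05, q = 0.2).

The universe defaults to the genes of the partition (assigned and
unassigned alike) intersected with the collection's annotated genes —
the dominant convention of over-representation tools; an explicit universe
can be supplied instead.  Terms are taken as flat sets: no ontology
propagation is attempted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .coexpression import ModulePartition
from .data_io import GeneSetCollection

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = [
    "module", "term", "description", "k", "K", "n", "N",
    "p_value", "q_value", "overlap_genes",
]

DEFAULT_MIN_TERM_SIZE = 10
DEFAULT_MAX_TERM_SIZE = 500


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeom(N, K, n).

    ``N`` is the universe size, ``K`` the number of marked elements
    (term size), ``n`` the draw size (module size), ``k`` the observed
    overlap.
    """
    k, K, n, N = int(k), int(K), int(n), int(N)
    if N < 0 or not (0 <= K <= N) or not (0 <= n <= N):
        raise ValueError(f"impossible hypergeometric counts K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def enrich_module(
    partition: ModulePartition,
    collection: GeneSetCollection,
    p_cutoff: float = 0.01,
    q_cutoff: float = 0.01,
    universe_policy: str = "partition",
    explicit_universe: frozenset[str] | None = None,
    min_term_size: int = DEFAULT_MIN_TERM_SIZE,
    max_term_size: int = DEFAULT_MAX_TERM_SIZE,
) -> pd.DataFrame:
    """Over-representation of every term in every module.

    Returns a DataFrame with columns ``module, term, description, k, K, n,
    N, p_value, q_value, overlap_genes`` (overlap genes comma-joined,
    sorted), one row per surviving (module, term) pair, sorted by module
    then p-value then term.  Term sizes are measured inside the universe
    and must fall within ``[min_term_size, max_term_size]`` to be tested;
    the ``unassigned`` label is never tested.
    """
    if not partition.labels:
        raise ValueError("partition has no modules")
    if not collection.sets:
        raise ValueError("gene-set collection is empty")
    if universe_policy == "partition":
        universe = frozenset(partition.genes) & collection.annotated_genes()
    elif universe_policy == "explicit":
        if explicit_universe is None and collection.universe is None:
            raise ValueError("explicit universe policy but no universe given")
        universe = frozenset(explicit_universe or collection.universe)
    else:
        raise ValueError(f"unknown universe_policy {universe_policy!r}")
    if not universe:
        raise ValueError("empty universe")
    N = len(universe)
    logger.info("enrichment universe: %d genes; term size bounds [%d, %d]",
                N, min_term_size, max_term_size)

    rows: list[dict[str, object]] = []
    for module in partition.labels:
        module_genes = partition.genes_in(module) & universe
        n = len(module_genes)
        if n == 0:
            continue
        tested: list[dict[str, object]] = []
        for term in sorted(collection.sets):
            desc, members = collection.sets[term]
            term_genes = members & universe
            K = len(term_genes)
            if not min_term_size <= K <= max_term_size:
                continue
            overlap = module_genes & term_genes
            k = len(overlap)
            if k < 1:
                continue
            p = hypergeometric_tail(k, K, n, N)
            tested.append(
                {"module": module, "term": term, "description": desc,
                 "k": k, "K": K, "n": n, "N": N, "p_value": p,
                 "overlap_genes": ",".join(sorted(overlap))}
            )
        if not tested:
            continue
        q = bh_adjust([row["p_value"] for row in tested])
        for row, qv in zip(tested, q):
            row["q_value"] = float(qv)
            if row["p_value"] <= p_cutoff and row["q_value"] <= q_cutoff:
                rows.append(row)

    frame = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)
    if len(frame):
        frame = frame.sort_values(
            ["module", "p_value", "term"], kind="mergesort"
        ).reset_index(drop=True)
    return frame


def cross_module_term_counts(rows: pd.DataFrame) -> pd.DataFrame:
    """How many distinct modules each term is enriched in, sorted descending.

    Mirrors summaries of the form "term X is significant in 16 modules".
    """
    if len(rows) == 0:
        return pd.DataFrame(columns=["term", "n_modules", "modules"])
    grouped = (
        rows.groupby("term")["module"]
        .agg(lambda ms: sorted(set(ms)))
        .reset_index()
        .rename(columns={"module": "modules"})
    )
    grouped["n_modules"] = grouped["modules"].map(len)
    grouped["modules"] = grouped["modules"].map(",".join)
    grouped = grouped.sort_values(
        ["n_modules", "term"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return grouped[["term", "n_modules", "modules"]]
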