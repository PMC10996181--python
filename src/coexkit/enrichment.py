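"""Over-representation analysis of gene lists against gene-set collections.

For a query of n genes drawn from a universe of N, overlap k with a term of
K genes is scored by the hypergeometric upper tail P[X >= k]; p-values are
Benjamini-Hochberg adjusted within each namespace (GO_BP separately from
KEGG and so on). This is the discrete-list flavour of gene-set enrichment —
rank-based weighted GSEA is deliberately out of scope.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = ("term_id", "name", "namespace", "k", "K", "n", "N",
                      "p_value", "q_value")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in the input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora(
    query: Iterable[str],
    genesets: GeneSetCollection,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in each gene set.

    The query is deduplicated and intersected with the universe (defaults to
    the collection's own universe); genes outside it are dropped with a
    logged count. One record per term with at least one universe gene;
    results are sorted by ascending p-value with BH q-values computed within
    each namespace.
    """
    if universe is None:
        universe = genesets.universe
    if not universe:
        raise InputError("a non-empty universe is required")
    universe = frozenset(universe)
    query_set = set(query)
    dropped = len(query_set - universe)
    if dropped:
        logger.info("dropping %d query genes outside the universe", dropped)
    query_set &= universe
    if not query_set:
        raise InputError("query is empty after intersecting with the universe")
    n, N = len(query_set), len(universe)

    rows = []
    for s in genesets:
        term_genes = s.genes & universe
        if not term_genes:
            continue
        K = len(term_genes)
        k = len(term_genes & query_set)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((s.term_id, s.name, s.namespace, k, K, n, N, min(p, 1.0)))
    if not rows:
        return pd.DataFrame(columns=list(ENRICHMENT_COLUMNS))
    df = pd.DataFrame(rows, columns=[c for c in ENRICHMENT_COLUMNS if c != "q_value"])
    df["q_value"] = np.nan
    for _, idx in df.groupby("namespace").groups.items():
        df.loc[idx, "q_value"] = bh_adjust(df.loc[idx, "p_value"].to_numpy())
    df = df.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    return df[list(ENRICHMENT_COLUMNS)]
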