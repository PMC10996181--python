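"""Two-group differential expression: Student's t-test plus fold-change filter.

A gene is called differentially expressed when the two-sided equal-variance
t-test on its per-sample values gives p < 0.05 and the log2 fold change of
the (pseudocounted) group means exceeds 1 in magnitude. Fold change is
group_b relative to group_a, so "up" means higher in group_b. No
multiple-testing correction is applied by default; a Benjamini-Hochberg
option exists for users who want FDR control.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

DEG_COLUMNS = ("gene_id", "mean_a", "mean_b", "log2fc", "p_value", "status")

UP = "up"
DOWN = "down"
NS = "ns"


def call_degs(
    expr: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    p_max: float = 0.05,
    fc_min: float = 1.0,
    pseudocount: float = 1.0,
    equal_var: bool = True,
    transform: str = "identity",
    adjust: str = "none",
) -> pd.DataFrame:
    """Call DEGs between two disjoint sample groups.

    Parameters
    ----------
    group_a, group_b
        Sample ids of the two groups (each >= 2 samples, disjoint).
    p_max, fc_min
        Significance and |log2 fold change| cutoffs (defaults 0.05 and 1).
    pseudocount
        Added to both group means before the log2 ratio so zero-TPM genes
        stay finite.
    equal_var
        Classic Student's t-test when True (default); Welch's when False.
    transform
        ``identity`` tests raw TPM; ``log2_plus_one`` tests log2(TPM + 1).
    adjust
        ``none`` (default, matching the raw p < 0.05 rule) or ``bh``; with
        ``bh`` a ``q_value`` column is added and status uses q < p_max.

    Returns a DataFrame with columns ``gene_id, mean_a, mean_b, log2fc,
    p_value, status`` (plus ``q_value`` under BH), one row per gene in input
    order. Means are always reported on the raw TPM scale.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise InputError("each group needs >= 2 samples")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise InputError(f"groups overlap: {sorted(overlap)}")
    missing = (set(group_a) | set(group_b)) - set(expr.sample_ids)
    if missing:
        raise InputError(f"samples not in the expression matrix: {sorted(missing)}")
    if transform not in ("identity", "log2_plus_one"):
        raise InputError(f"unknown transform {transform!r}")
    if adjust not in ("none", "bh"):
        raise InputError(f"unknown adjust {adjust!r}")

    col = {s: j for j, s in enumerate(expr.sample_ids)}
    xa = expr.values[:, [col[s] for s in group_a]]
    xb = expr.values[:, [col[s] for s in group_b]]
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))

    ta, tb = (np.log2(xa + 1), np.log2(xb + 1)) if transform == "log2_plus_one" else (xa, xb)
    with np.errstate(divide="ignore", invalid="ignore"):
        result = stats.ttest_ind(ta, tb, axis=1, equal_var=equal_var)
    p = np.asarray(result.pvalue, dtype=float)
    # zero variance in both groups: equal means are trivially non-significant
    p = np.where(np.isnan(p), 1.0, p)

    df = pd.DataFrame({
        "gene_id": expr.gene_ids,
        "mean_a": mean_a,
        "mean_b": mean_b,
        "log2fc": log2fc,
        "p_value": p,
    })
    if adjust == "bh":
        from .enrichment import bh_adjust

        df["q_value"] = bh_adjust(p)
        sig = df["q_value"] < p_max
    else:
        sig = df["p_value"] < p_max
    df["status"] = np.select(
        [sig & (df["log2fc"] > fc_min), sig & (df["log2fc"] < -fc_min)],
        [UP, DOWN],
        default=NS,
    )
    counts = df["status"].value_counts()
    logger.info("DEG call: %d up, %d down of %d genes (p<%g, |log2fc|>%g)",
                counts.get(UP, 0), counts.get(DOWN, 0), len(df), p_max, fc_min)
    return df


def count_by_family(
    genes: Sequence[str],
    families: GeneSetCollection,
    unclassified_label: str = "unclassified",
) -> pd.DataFrame:
    """Census of a gene list by family (e.g. transcription-factor families).

    Each query gene is counted once per family that contains it; genes
    belonging to no family are tallied under ``unclassified``. Rows are
    ordered by descending count then family name.
    """
    if not families.sets:
        raise InputError("empty family collection")
    unique_genes = list(dict.fromkeys(genes))
    counts: dict[str, int] = {}
    for g in unique_genes:
        hit = False
        for fam in families:
            if g in fam.genes:
                counts[fam.term_id] = counts.get(fam.term_id, 0) + 1
                hit = True
        if not hit:
            counts[unclassified_label] = counts.get(unclassified_label, 0) + 1
    if not unique_genes:
        return pd.DataFrame(columns=["family", "count"])
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["family", "count"])
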