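"""Network validation by guilt-by-association GO prediction and ROC/AUC.

A co-expression network is trusted to the extent that a gene's functional
annotations can be predicted from its neighbors. Evaluation terms are GO
biological-process sets with 4-20 member genes (small enough to be specific,
large enough to be learnable). For every annotated gene with at least one
annotated neighbor, each candidate term is scored by the fraction of the
gene's annotated neighbors carrying that term — the gene's own annotations
never enter its score. Treating (gene, term) pairs as a binary classification
problem (label = the gene truly carries the term) gives an ROC curve whose
AUC summarizes the network's functional coherence; 0.5 is chance.

Scanning a grid of (PCC bound, MR ceiling) threshold pairs and comparing
AUCs selects the working thresholds: the maximal-AUC point, with near-ties
resolved toward the more inclusive network (lower |PCC| bound, higher MR
ceiling) so more genes stay connected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .coexpression import (
    POSITIVE,
    CoexpressionNetwork,
    NetworkThresholds,
    build_network,
    compute_mutual_rank,
    compute_pcc_matrix,
)
from .errors import InputError
from .io import ExpressionMatrix, GeneSet, GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_MIN_TERM_SIZE = 4
DEFAULT_MAX_TERM_SIZE = 20
DEFAULT_PCC_GRID = (0.6, 0.7, 0.8, 0.9)
DEFAULT_TIE_TOLERANCE = 0.01

#: Columns of a guilt-by-association prediction table.
GBA_COLUMNS = ("gene_id", "term_id", "score", "label")


def select_eval_terms(
    genesets: GeneSetCollection,
    min_size: int = DEFAULT_MIN_TERM_SIZE,
    max_size: int = DEFAULT_MAX_TERM_SIZE,
    namespace: str = "GO_BP",
) -> GeneSetCollection:
    """Filter to terms of the given namespace with min_size..max_size genes.

    When the collection has a universe set (normally the genes of the
    expression matrix), term size is measured after intersecting with it, and
    the returned sets are restricted to universe genes.
    """
    if not genesets.sets:
        raise InputError("empty gene-set collection")
    if min_size > max_size:
        raise InputError(f"min_size {min_size} exceeds max_size {max_size}")
    universe = genesets.universe
    selected: dict[str, GeneSet] = {}
    for s in genesets:
        if s.namespace != namespace:
            continue
        genes = s.genes & universe if universe is not None else s.genes
        if min_size <= len(genes) <= max_size:
            selected[s.term_id] = GeneSet(s.term_id, s.name, s.namespace, genes)
    if not selected:
        logger.warning("no terms of namespace %s with size in [%d, %d]",
                       namespace, min_size, max_size)
    else:
        logger.info("selected %d evaluation terms (size %d-%d, %s)",
                    len(selected), min_size, max_size, namespace)
    return GeneSetCollection(selected, universe)


def gba_scores(network: CoexpressionNetwork, genesets: GeneSetCollection) -> pd.DataFrame:
    """Guilt-by-association prediction records for every evaluable (gene, term).

    A gene is evaluable when it carries at least one selected term and has at
    least one network neighbor carrying a selected term. Its score for term t
    is the fraction of its annotated neighbors carrying t (leave-the-gene-out:
    only neighbor annotations are consulted). Returns a DataFrame with columns
    ``gene_id, term_id, score, label``.
    """
    if not network.edges:
        logger.warning("empty network: no guilt-by-association predictions")
        return pd.DataFrame(columns=list(GBA_COLUMNS))
    gene_terms = genesets.gene_to_terms()
    term_ids = sorted(genesets.sets)
    adjacency = network.adjacency()
    records: list[tuple[str, str, float, bool]] = []
    for gene in sorted(adjacency):
        own_terms = gene_terms.get(gene)
        if not own_terms:
            continue
        annotated_nbrs = [nb for nb in adjacency[gene] if gene_terms.get(nb)]
        if not annotated_nbrs:
            continue
        denom = len(annotated_nbrs)
        counts: dict[str, int] = {}
        for nb in annotated_nbrs:
            for t in gene_terms[nb]:
                counts[t] = counts.get(t, 0) + 1
        for t in term_ids:
            records.append((gene, t, counts.get(t, 0) / denom, t in own_terms))
    df = pd.DataFrame(records, columns=list(GBA_COLUMNS))
    logger.info("guilt-by-association: %d records over %d evaluable genes",
                len(df), df["gene_id"].nunique() if len(df) else 0)
    return df


@dataclass
class ROCCurve:
    """TPR/FPR points from (0,0) to (1,1) plus the trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


def roc_curve(predictions: pd.DataFrame) -> ROCCurve:
    """ROC over a prediction table, sweeping score thresholds descending.

    Tied scores are processed as one block, which makes the trapezoidal AUC
    equal the Mann-Whitney concordance statistic with ties counted half.
    """
    if len(predictions) == 0:
        raise InputError("empty prediction set")
    labels = predictions["label"].to_numpy(dtype=bool)
    scores = predictions["score"].to_numpy(dtype=float)
    if labels.all():
        raise InputError("degenerate prediction set: every label is positive")
    if not labels.any():
        raise InputError("degenerate prediction set: every label is negative")
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return ROCCurve(fpr=fpr, tpr=tpr, auc=float(_trapezoid_auc(fpr, tpr)))


@dataclass
class ThresholdGrid:
    """AUC and network size at every (pcc_bound, mr_max) grid point."""

    sign: str
    entries: pd.DataFrame  # pcc_bound, mr_max, auc, edge_count, evaluable_pairs, note


def threshold_grid_auc(
    expr: ExpressionMatrix,
    genesets: GeneSetCollection,
    pcc_grid: Sequence[float] = DEFAULT_PCC_GRID,
    mr_grid: Sequence[float] = (10.0, 30.0, 50.0, 100.0),
    sign: str = POSITIVE,
) -> ThresholdGrid:
    """Guilt-by-association AUC across a grid of threshold pairs.

    The PCC and Mutual Rank matrices are computed once and reused for every
    grid point. Grid points whose prediction set is degenerate (only one
    label class, or no evaluable genes) record a missing AUC with a reason
    instead of failing.
    """
    if not len(pcc_grid) or not len(mr_grid):
        raise InputError("pcc_grid and mr_grid must be non-empty")
    corr = compute_pcc_matrix(expr)
    mr = compute_mutual_rank(corr, mode=sign)
    rows = []
    for pcc_bound in pcc_grid:
        for mr_max in mr_grid:
            thresholds = NetworkThresholds(sign=sign, pcc_bound=pcc_bound, mr_max=mr_max)
            network = build_network(corr, mr, thresholds)
            auc_value, note = np.nan, ""
            pred = gba_scores(network, genesets) if network.edges else pd.DataFrame(
                columns=list(GBA_COLUMNS))
            if not len(pred):
                note = "no evaluable (gene, term) pairs"
            else:
                try:
                    auc_value = roc_curve(pred).auc
                except InputError as exc:
                    note = str(exc)
            rows.append((float(pcc_bound), float(mr_max), auc_value,
                         len(network), len(pred), note))
    entries = pd.DataFrame(
        rows, columns=["pcc_bound", "mr_max", "auc", "edge_count", "evaluable_pairs", "note"]
    )
    return ThresholdGrid(sign=sign, entries=entries)


def select_thresholds(
    grid: ThresholdGrid,
    tie_tolerance: float = DEFAULT_TIE_TOLERANCE,
) -> NetworkThresholds:
    """Pick the maximal-AUC grid point, breaking near-ties toward inclusiveness.

    Entries within ``tie_tolerance`` of the best AUC count as tied; among them
    the smallest |pcc_bound| wins (a looser correlation bound keeps more
    genes), then the largest mr_max. Deterministic and invariant to the order
    of grid entries.
    """
    entries = grid.entries.dropna(subset=["auc"])
    if entries.empty:
        raise InputError("every grid point has a missing AUC")
    best = entries["auc"].max()
    tied = entries[entries["auc"] >= best - tie_tolerance]
    tied = tied.sort_values(
        by=["pcc_bound", "mr_max"],
        key=lambda col: col.abs() if col.name == "pcc_bound" else -col,
    )
    row = tied.iloc[0]
    return NetworkThresholds(sign=grid.sign, pcc_bound=float(row["pcc_bound"]),
                             mr_max=float(row["mr_max"]))
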