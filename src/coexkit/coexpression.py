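"""Signed co-expression networks from Pearson correlation and Mutual Rank.

The pipeline is: compute the all-pairs Pearson correlation coefficient (PCC)
of gene expression profiles, convert each gene's correlation vector to ranks,
combine the two directional ranks of a pair into the Mutual Rank statistic

    MR(A, B) = sqrt(Rank(A, B) * Rank(B, A)),

and keep pairs passing both a PCC bound and an MR ceiling. Rank(A, B) is the
rank of gene B among all other genes ordered by correlation with gene A:
descending PCC for the positive network (strongest co-expression -> rank 1)
and ascending PCC for the negative network (strongest anti-correlation ->
rank 1), so a low MR always means a mutually top-ranked pair for the sign
under study. Ties receive average (fractional) ranks, which keeps every
gene's rank sum at G(G-1)/2 and makes MR well defined under duplicate PCCs.

Default thresholds: positive network PCC > 0.6 and MR < 30; negative network
PCC < -0.5 and MR < 30. All threshold inequalities are strict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.stats import rankdata

from .errors import InputError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
MODES = (POSITIVE, NEGATIVE)

#: Published default thresholds for the two signed networks.
DEFAULT_POSITIVE_PCC = 0.6
DEFAULT_NEGATIVE_PCC = -0.5
DEFAULT_MR_MAX = 30.0


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    """All-pairs PCC matrix over the genes that had non-zero sample variance."""

    gene_ids: list[str]
    pcc: np.ndarray
    excluded_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        g = len(self.gene_ids)
        if self.pcc.shape != (g, g):
            raise InputError(f"PCC matrix shape {self.pcc.shape} does not match {g} genes")


def compute_pcc_matrix(expr: ExpressionMatrix) -> CorrelationResult:
    """Pearson correlation between every pair of gene expression profiles.

    Genes whose TPM profile is constant across samples have an undefined PCC;
    they are moved to ``excluded_genes`` and absent from the matrix rather
    than silently dropped.
    """
    if expr.n_samples < 3:
        raise InputError(f"need >= 3 samples for correlation, got {expr.n_samples}")
    if expr.n_genes < 2:
        raise InputError(f"need >= 2 genes, got {expr.n_genes}")
    variances = expr.values.var(axis=1)
    keep = variances > 0
    excluded = [g for g, k in zip(expr.gene_ids, keep) if not k]
    if excluded:
        logger.warning("excluding %d zero-variance genes from correlation", len(excluded))
    if keep.sum() < 2:
        raise InputError("fewer than 2 genes with non-zero variance")
    pcc = np.corrcoef(expr.values[keep])
    np.clip(pcc, -1.0, 1.0, out=pcc)
    np.fill_diagonal(pcc, 1.0)
    gene_ids = [g for g, k in zip(expr.gene_ids, keep) if k]
    return CorrelationResult(gene_ids=gene_ids, pcc=pcc, excluded_genes=excluded)


# ---------------------------------------------------------------------------
# Mutual Rank
# ---------------------------------------------------------------------------

@dataclass
class MutualRankResult:
    """Directional rank matrix and the symmetric Mutual Rank matrix.

    ``rank[i, j]`` is Rank(gene_i, gene_j): the rank of gene j among the other
    G-1 genes ordered by PCC with gene i (direction set by ``mode``); the
    diagonal is NaN. ``mr`` is the elementwise geometric mean of ``rank`` and
    its transpose.
    """

    gene_ids: list[str]
    rank: np.ndarray
    mr: np.ndarray
    mode: str


def compute_mutual_rank(corr: CorrelationResult, mode: str = POSITIVE) -> MutualRankResult:
    """Mutual Rank of every gene pair from the PCC matrix.

    Positive mode ranks each gene's partners by descending PCC (largest PCC
    -> rank 1); negative mode by ascending PCC (most negative -> rank 1).
    Self-correlation is excluded from every ranking; ties are averaged.
    """
    if mode not in MODES:
        raise InputError(f"mode must be one of {MODES}, got {mode!r}")
    g = len(corr.gene_ids)
    if g < 3:
        raise InputError(f"need >= 3 genes for Mutual Rank, got {g}")
    # Rank along each row with the self-entry forced to sort strictly last,
    # leaving the G-1 partners with ranks 1..G-1 (average ties).
    key = -corr.pcc if mode == POSITIVE else corr.pcc.copy()
    np.fill_diagonal(key, np.inf)
    rank = rankdata(key, method="average", axis=1)
    np.fill_diagonal(rank, np.nan)
    mr = np.sqrt(rank * rank.T)
    return MutualRankResult(gene_ids=list(corr.gene_ids), rank=rank, mr=mr, mode=mode)


# ---------------------------------------------------------------------------
# Network extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkThresholds:
    """PCC bound plus MR ceiling for one signed network; inequalities are strict.

    Positive sign keeps PCC > ``pcc_bound`` (default 0.6); negative sign keeps
    PCC < ``pcc_bound`` (default -0.5). Both keep MR < ``mr_max`` (default 30).
    """

    sign: str = POSITIVE
    pcc_bound: float = DEFAULT_POSITIVE_PCC
    mr_max: float = DEFAULT_MR_MAX

    def __post_init__(self) -> None:
        if self.sign not in MODES:
            raise InputError(f"sign must be one of {MODES}, got {self.sign!r}")
        if self.sign == POSITIVE and not (0 <= self.pcc_bound < 1):
            raise InputError(f"positive pcc_bound must lie in [0, 1), got {self.pcc_bound}")
        if self.sign == NEGATIVE and not (-1 < self.pcc_bound <= 0):
            raise InputError(f"negative pcc_bound must lie in (-1, 0], got {self.pcc_bound}")
        if not self.mr_max > 1:
            raise InputError(f"mr_max must exceed 1, got {self.mr_max}")

    @classmethod
    def negative_default(cls) -> "NetworkThresholds":
        return cls(sign=NEGATIVE, pcc_bound=DEFAULT_NEGATIVE_PCC, mr_max=DEFAULT_MR_MAX)


class Edge(NamedTuple):
    """One undirected, signed co-expression edge; gene_a < gene_b lexicographically."""

    gene_a: str
    gene_b: str
    pcc: float
    mr: float
    sign: str


@dataclass
class CoexpressionNetwork:
    """Undirected edge set surviving the (PCC, MR) thresholds; no self-loops."""

    edges: list[Edge]
    thresholds: NetworkThresholds | None = None
    weighted = True  # edge rows carry pcc/mr/sign when serialised

    def __post_init__(self) -> None:
        canonical = []
        seen: set[tuple[str, str, str]] = set()
        for e in self.edges:
            if e.gene_a == e.gene_b:
                raise InputError(f"self-loop on {e.gene_a!r}")
            a, b = sorted((e.gene_a, e.gene_b))
            key = (a, b, e.sign)
            if key in seen:
                raise InputError(f"duplicate edge {a!r}-{b!r} ({e.sign})")
            seen.add(key)
            canonical.append(Edge(a, b, e.pcc, e.mr, e.sign))
        self.edges = sorted(canonical)

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def genes(self) -> set[str]:
        return {g for e in self.edges for g in (e.gene_a, e.gene_b)}

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(e.gene_a, e.gene_b) for e in self.edges}

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {}
        for e in self.edges:
            adj.setdefault(e.gene_a, set()).add(e.gene_b)
            adj.setdefault(e.gene_b, set()).add(e.gene_a)
        return adj


def build_network(
    corr: CorrelationResult,
    mr: MutualRankResult,
    thresholds: NetworkThresholds,
) -> CoexpressionNetwork:
    """Extract the signed network of pairs passing both thresholds strictly."""
    if corr.gene_ids != mr.gene_ids:
        raise InputError("correlation and mutual-rank results cover different gene sets")
    if thresholds.sign != mr.mode:
        raise InputError(
            f"threshold sign {thresholds.sign!r} does not match MR mode {mr.mode!r}"
        )
    if thresholds.sign == POSITIVE:
        pcc_ok = corr.pcc > thresholds.pcc_bound
    else:
        pcc_ok = corr.pcc < thresholds.pcc_bound
    with np.errstate(invalid="ignore"):
        keep = pcc_ok & (mr.mr < thresholds.mr_max)
    keep &= np.triu(np.ones_like(keep, dtype=bool), k=1)
    ii, jj = np.nonzero(keep)
    ids = corr.gene_ids
    edges = [
        Edge(*sorted((ids[i], ids[j])), float(corr.pcc[i, j]), float(mr.mr[i, j]),
             thresholds.sign)
        for i, j in zip(ii, jj)
    ]
    logger.info(
        "%s network: %d edges over %d genes (thresholds pcc %s, mr < %s)",
        thresholds.sign, len(edges), len({g for e in edges for g in e[:2]}),
        thresholds.pcc_bound, thresholds.mr_max,
    )
    return CoexpressionNetwork(edges=edges, thresholds=thresholds)


def neighbors(network: CoexpressionNetwork, gene: str, limit: int | None = None) -> list[Edge]:
    """Edges incident to ``gene``, most tightly co-expressed first.

    Ordering: ascending MR, then descending \\|PCC\\|, then lexicographic
    partner id. A gene absent from the network yields an empty list.
    """
    if limit is not None and limit <= 0:
        raise InputError(f"limit must be positive, got {limit}")
    incident = [e for e in network.edges if gene in (e.gene_a, e.gene_b)]
    if not incident:
        logger.info("gene %r has no edges in the network", gene)
        return []
    incident.sort(key=lambda e: (e.mr, -abs(e.pcc),
                                 e.gene_b if e.gene_a == gene else e.gene_a))
    return incident if limit is None else incident[:limit]
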