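"""Interolog projection: transfer a reference PPI network through orthologs.

An interaction (a1, a2) observed in a well-studied reference species (here,
Arabidopsis) is transferred to every target-species pair (d1, d2) with d1
orthologous to a1 and d2 orthologous to a2. Many-to-many ortholog relations
fan out over the full cross-product; self-pairs arising from shared
orthologs are dropped and duplicates across source edges are collapsed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import InputError
from .io import OrthologMap

logger = logging.getLogger(__name__)


@dataclass
class PPINetwork:
    """Undirected protein-protein interaction edges; no self-loops or duplicates."""

    edges: frozenset[tuple[str, str]]
    species: str = "unknown"
    weighted = False  # serialised as bare gene pairs

    def __post_init__(self) -> None:
        canonical = set()
        for a, b in self.edges:
            if a == b:
                raise InputError(f"self-interaction on {a!r}")
            canonical.add((min(a, b), max(a, b)))
        self.edges = frozenset(canonical)

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def genes(self) -> set[str]:
        return {g for e in self.edges for g in e}


def project_ppi(
    reference: PPINetwork,
    orthologs: OrthologMap,
    species: str = "target",
) -> PPINetwork:
    """Project every reference edge through the ortholog map (interolog transfer).

    Reference endpoints without orthologs contribute nothing; the result
    contains each projected unordered pair once and never a self-loop.
    """
    if not orthologs.pairs:
        raise InputError("empty ortholog map")
    mapping = orthologs.as_dict()
    projected: set[tuple[str, str]] = set()
    for a1, a2 in reference.edges:
        for d1 in mapping.get(a1, ()):
            for d2 in mapping.get(a2, ()):
                if d1 != d2:
                    projected.add((min(d1, d2), max(d1, d2)))
    network = PPINetwork(edges=frozenset(projected), species=species)
    logger.info("projected %d reference edges to %d edges over %d genes",
                len(reference), len(network), len(network.genes))
    return network
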