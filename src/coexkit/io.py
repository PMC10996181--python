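"""Readers, writers and core domain containers.

All tabular formats are plain TSV; gene sets use the de-facto standard GMT
layout (term, description, member genes). Readers validate strictly and never
silently drop records: anything malformed raises :class:`~coexkit.errors.FormatError`
with enough context to locate the offending line or cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, InputError

if TYPE_CHECKING:  # pragma: no cover - type-only imports
    from .coexpression import CoexpressionNetwork
    from .ppi import PPINetwork

logger = logging.getLogger(__name__)

#: Recognised gene-set namespaces.
NAMESPACES = ("GO_BP", "GO_MF", "GO_CC", "KEGG", "TF_FAMILY", "CUSTOM")

EXPRESSION_TRANSFORMS = ("identity", "log2_plus_one")


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A gene x sample matrix of non-negative TPM values.

    Parameters
    ----------
    gene_ids, sample_ids
        Ordered, duplicate-free identifier lists.
    values
        Dense ``(len(gene_ids), len(sample_ids))`` float array; every entry
        must be finite and >= 0 (TPM semantics).
    condition_of
        Optional map from sample id to condition label, used by the
        differential-expression caller.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    condition_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise FormatError(f"duplicate {name} id: {i!r}")
                seen.add(i)
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value at gene {self.gene_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )
        if np.any(self.values < 0):
            r, c = np.argwhere(self.values < 0)[0]
            raise FormatError(
                f"negative value {self.values[r, c]} at gene "
                f"{self.gene_ids[r]!r}, sample {self.sample_ids[c]!r}"
            )
        if self.condition_of is not None:
            unknown = set(self.condition_of) - set(self.sample_ids)
            if unknown:
                raise FormatError(f"condition labels for unknown samples: {sorted(unknown)}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class GeneSet:
    """One named gene set (a GO term, KEGG pathway, TF family...)."""

    term_id: str
    name: str
    namespace: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise FormatError(f"unknown namespace {self.namespace!r}")
        if not self.genes:
            raise FormatError(f"gene set {self.term_id!r} is empty")

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """A term-id keyed collection of gene sets with an optional analysis universe."""

    sets: dict[str, GeneSet]
    universe: frozenset[str] | None = None

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, term_id: str) -> GeneSet:
        return self.sets[term_id]

    def terms_of(self, gene: str) -> set[str]:
        return {s.term_id for s in self.sets.values() if gene in s.genes}

    def gene_to_terms(self) -> dict[str, set[str]]:
        """Invert the collection: gene id -> set of term ids carrying it."""
        out: dict[str, set[str]] = {}
        for s in self.sets.values():
            for g in s.genes:
                out.setdefault(g, set()).add(s.term_id)
        return out


@dataclass
class OrthologMap:
    """Unordered collection of (source_gene, target_gene) ortholog pairs.

    Many-to-many relations are allowed; duplicates are collapsed.
    """

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        self.pairs = frozenset(tuple(p) for p in self.pairs)

    def targets_of(self, source_gene: str) -> set[str]:
        return {t for s, t in self.pairs if s == source_gene}

    def as_dict(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for s, t in self.pairs:
            out.setdefault(s, set()).add(t)
        return out


@dataclass(frozen=True)
class GeneRecord:
    """A gene feature with 1-based inclusive coordinates."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str


@dataclass
class GenomeAnnotation:
    """Chromosome lengths plus gene features, 1-based inclusive, strand in {+,-}."""

    chromosomes: dict[str, int]
    genes: dict[str, GeneRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g in self.genes.values():
            if g.strand not in ("+", "-"):
                raise FormatError(f"gene {g.gene_id!r}: strand must be + or -, got {g.strand!r}")
            if g.chromosome not in self.chromosomes:
                raise FormatError(f"gene {g.gene_id!r} on unknown chromosome {g.chromosome!r}")
            clen = self.chromosomes[g.chromosome]
            if not (1 <= g.start <= g.end <= clen):
                raise FormatError(
                    f"gene {g.gene_id!r}: interval [{g.start}, {g.end}] outside "
                    f"chromosome {g.chromosome!r} of length {clen}"
                )


# ---------------------------------------------------------------------------
# Expression matrix I/O
# ---------------------------------------------------------------------------

def read_expression_matrix(
    path,
    transform: str = "identity",
    conditions: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a TSV expression matrix (header = sample ids, first column = gene id).

    ``transform="log2_plus_one"`` applies log2(x + 1) element-wise; the default
    leaves the TPM values untouched, which is also what the correlation stage
    consumes.
    """
    if transform not in EXPRESSION_TRANSFORMS:
        raise InputError(f"unknown transform {transform!r}; choose from {EXPRESSION_TRANSFORMS}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate gene id: {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"duplicate sample id: {dup!r}")
    try:
        values = df.astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"non-numeric expression value: {exc}") from exc
    mat = ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=values,
        condition_of=dict(conditions) if conditions else None,
    )
    if transform == "log2_plus_one":
        mat = ExpressionMatrix(mat.gene_ids, mat.sample_ids, np.log2(mat.values + 1.0),
                               mat.condition_of)
    logger.info("read expression matrix: %d genes x %d samples", mat.n_genes, mat.n_samples)
    return mat


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_design(path) -> dict[str, str]:
    """Read a two-column sample-to-condition table (sample_id TAB condition)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("design table needs at least two columns (sample_id, condition)")
    sample_col, cond_col = df.columns[:2]
    if df[sample_col].duplicated().any():
        dup = df[sample_col][df[sample_col].duplicated()].iloc[0]
        raise FormatError(f"duplicate sample id in design table: {dup!r}")
    return dict(zip(df[sample_col], df[cond_col]))


def write_design(condition_of: Mapping[str, str], path) -> None:
    pd.DataFrame(
        {"sample_id": list(condition_of), "condition": list(condition_of.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene-set (GMT) I/O
# ---------------------------------------------------------------------------

def read_gene_sets(path, namespace: str = "CUSTOM",
                   universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read a GMT file: ``term_id TAB description TAB gene1 TAB gene2 ...``.

    Duplicate gene ids within a line are collapsed; a line with no genes is a
    format error.
    """
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            term_id, name, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {term_id!r} has no genes")
            if term_id in sets:
                raise FormatError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            sets[term_id] = GeneSet(term_id, name, namespace, frozenset(genes))
    return GeneSetCollection(sets, frozenset(universe) if universe is not None else None)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.term_id, s.name, *sorted(s.genes)]) + "\n")


# ---------------------------------------------------------------------------
# Edge-list I/O
# ---------------------------------------------------------------------------

EDGE_COLUMNS = ("geneA", "geneB", "pcc", "mr", "sign")


def write_edge_list(network, path) -> None:
    """Write a co-expression network (or projected PPI) as TSV.

    Each undirected edge is written once with geneA < geneB lexicographically,
    rows sorted, so write -> read round-trips are byte-stable. Co-expression
    edges carry pcc/mr/sign columns; PPI networks only the two gene columns.
    """
    rows = []
    is_weighted = getattr(network, "weighted", False)
    for e in network.edges:
        if is_weighted:
            a, b = sorted((e.gene_a, e.gene_b))
            rows.append((a, b, e.pcc, e.mr, e.sign))
        else:
            a, b = sorted(e)
            rows.append((a, b))
    rows.sort()
    with open(path, "w") as fh:
        if is_weighted:
            fh.write("\t".join(EDGE_COLUMNS) + "\n")
            for a, b, pcc, mr, sign in rows:
                fh.write(f"{a}\t{b}\t{pcc:.10g}\t{mr:.10g}\t{sign}\n")
        else:
            fh.write("geneA\tgeneB\n")
            for a, b in rows:
                fh.write(f"{a}\t{b}\n")


def read_edge_list(path) -> "CoexpressionNetwork":
    """Read a co-expression edge list written by :func:`write_edge_list`."""
    from .coexpression import CoexpressionNetwork, Edge

    df = pd.read_csv(path, sep="\t")
    missing = set(EDGE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"edge list missing columns: {sorted(missing)}")
    edges = [
        Edge(row.geneA, row.geneB, float(row.pcc), float(row.mr), str(row.sign))
        for row in df.itertuples(index=False)
    ]
    return CoexpressionNetwork(edges=edges)


def read_ortholog_pairs(path) -> OrthologMap:
    """Read a two-column TSV of (source_gene, target_gene) pairs, header optional."""
    pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: ortholog line needs 2 columns")
            if lineno == 1 and fields[0].lower() in ("source", "source_gene", "genea"):
                continue
            pairs.add((fields[0], fields[1]))
    return OrthologMap(frozenset(pairs))


def write_ortholog_pairs(orthologs: OrthologMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("source_gene\ttarget_gene\n")
        for s, t in sorted(orthologs.pairs):
            fh.write(f"{s}\t{t}\n")


def read_ppi_edges(path, species: str = "unknown") -> "PPINetwork":
    """Read a two-column TSV of undirected PPI edges."""
    from .ppi import PPINetwork

    edges: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: PPI line needs 2 columns")
            if lineno == 1 and fields[0].lower() in ("genea", "protein_a", "a"):
                continue
            a, b = fields[0], fields[1]
            if a == b:
                raise FormatError(f"{path}:{lineno}: self-interaction {a!r}")
            edges.add((min(a, b), max(a, b)))
    return PPINetwork(edges=frozenset(edges), species=species)


def write_ppi_edges(network: "PPINetwork", path) -> None:
    with open(path, "w") as fh:
        fh.write("geneA\tgeneB\n")
        for a, b in sorted(network.edges):
            fh.write(f"{a}\t{b}\n")
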