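"""Coordinate-based sequence retrieval and strand-aware promoter extraction.

All coordinates are GFF3-style: 1-based, inclusive at both ends. Minus-strand
extractions return the reverse complement. Promoters are fixed-length windows
immediately 5' of a gene's start (a TSS approximation from gene features):
``[start-L, start-1]`` for plus-strand genes and ``[end+1, end+L]`` reverse
complemented for minus-strand genes, clipped at chromosome bounds with a flag
rather than an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import gffutils
from pyfaidx import Fasta

from .errors import CoordinateError, InputError, UnknownIDError
from .io import GeneRecord, GenomeAnnotation

logger = logging.getLogger(__name__)

DEFAULT_PROMOTER_LENGTH = 3000

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def open_genome(path) -> Fasta:
    """Open (and index, if needed) a FASTA genome."""
    return Fasta(str(path))


def _chromosome_length(genome, chromosome: str) -> int:
    if chromosome not in genome.keys():
        raise UnknownIDError(f"unknown chromosome {chromosome!r}")
    return len(genome[chromosome])


def extract_sequence(genome, chromosome: str, start: int, end: int,
                     strand: str = "+") -> str:
    """Fetch the sequence of a 1-based inclusive interval, strand-aware.

    ``genome`` is a :class:`pyfaidx.Fasta` (or any mapping of chromosome id
    to sequence). Minus strand returns the reverse complement; the returned
    length is always ``end - start + 1``.
    """
    if strand not in ("+", "-"):
        raise InputError(f"strand must be + or -, got {strand!r}")
    clen = _chromosome_length(genome, chromosome)
    if not (1 <= start <= end <= clen):
        raise CoordinateError(
            f"interval [{start}, {end}] outside chromosome {chromosome!r} (length {clen})"
        )
    seq = str(genome[chromosome][start - 1:end])
    return reverse_complement(seq) if strand == "-" else seq


@dataclass(frozen=True)
class PromoterRecord:
    """One extracted promoter window; ``end < start`` encodes an empty window."""

    gene_id: str
    sequence: str
    chromosome: str
    start: int
    end: int
    strand: str
    clipped: bool


def extract_promoters(
    annotation: GenomeAnnotation,
    genome,
    length: int = DEFAULT_PROMOTER_LENGTH,
    gene_ids: Iterable[str] | None = None,
) -> list[PromoterRecord]:
    """Extract fixed-length promoter windows upstream of gene starts.

    Windows truncated by a chromosome edge carry ``clipped=True``; a gene
    whose 5' end sits at the chromosome boundary yields an empty sequence
    (still flagged) rather than an error.
    """
    if length <= 0:
        raise InputError(f"promoter length must be positive, got {length}")
    if gene_ids is None:
        gene_ids = sorted(annotation.genes)
    records = []
    for gid in gene_ids:
        gene = annotation.genes.get(gid)
        if gene is None:
            raise UnknownIDError(f"unknown gene id {gid!r}")
        clen = annotation.chromosomes[gene.chromosome]
        if gene.strand == "+":
            start, end = max(1, gene.start - length), gene.start - 1
        else:
            start, end = gene.end + 1, min(clen, gene.end + length)
        if end < start:  # gene flush against the chromosome edge
            records.append(PromoterRecord(gid, "", gene.chromosome,
                                          min(start, clen), min(start, clen) - 1,
                                          gene.strand, True))
            continue
        seq = extract_sequence(genome, gene.chromosome, start, end, gene.strand)
        clipped = (end - start + 1) < length
        records.append(PromoterRecord(gid, seq, gene.chromosome, start, end,
                                      gene.strand, clipped))
    n_clipped = sum(r.clipped for r in records)
    if n_clipped:
        logger.info("%d of %d promoter windows clipped at chromosome bounds",
                    n_clipped, len(records))
    return records


# ---------------------------------------------------------------------------
# FASTA / GFF3 I/O
# ---------------------------------------------------------------------------

def read_genome_annotation(gff3_path, fasta_path=None) -> GenomeAnnotation:
    """Parse gene features (and chromosome lengths) from a GFF3 file.

    Chromosome lengths come from ``##sequence-region`` directives, or from
    the FASTA index when ``fasta_path`` is given (which takes precedence).
    """
    chromosomes: dict[str, int] = {}
    with open(gff3_path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                fields = line.split()
                if len(fields) >= 4:
                    chromosomes[fields[1]] = int(fields[3])
            elif not line.startswith("#"):
                break
    if fasta_path is not None:
        fa = Fasta(str(fasta_path))
        chromosomes = {name: len(fa[name]) for name in fa.keys()}
    if not chromosomes:
        raise InputError(
            "no chromosome lengths: GFF3 lacks ##sequence-region directives "
            "and no FASTA was given"
        )
    db = gffutils.create_db(str(gff3_path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="error")
    genes: dict[str, GeneRecord] = {}
    for feat in db.features_of_type("gene"):
        genes[feat.id] = GeneRecord(feat.id, feat.seqid, feat.start, feat.end, feat.strand)
    return GenomeAnnotation(chromosomes=chromosomes, genes=genes)


def write_gff3(annotation: GenomeAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, clen in sorted(annotation.chromosomes.items()):
            fh.write(f"##sequence-region {chrom} 1 {clen}\n")
        for gene in sorted(annotation.genes.values(),
                           key=lambda g: (g.chromosome, g.start, g.gene_id)):
            fh.write("\t".join([
                gene.chromosome, "coexkit", "gene", str(gene.start), str(gene.end),
                ".", gene.strand, ".", f"ID={gene.gene_id}",
            ]) + "\n")


def write_genome_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_promoters_fasta(records: Iterable[PromoterRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            flag = " clipped" if r.clipped else ""
            fh.write(f">{r.gene_id} {r.chromosome}:{r.start}-{r.end}({r.strand}){flag}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i:i + 60] + "\n")
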