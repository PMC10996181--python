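"""Seeded synthetic fixtures: expression with planted modules, gene sets,
two-condition designs, and toy genome/ortholog/PPI inputs.

Expression follows a latent-factor model. Each planted module m has one
standard-normal factor f_m per sample; a member gene g gets

    x[g, s] = baseline + s(g) * loading * f_m(s) + eps,   eps ~ N(0, noise_sd)

with s(g) = -1 for a configurable fraction of members (so each module plants
both positively and negatively co-expressed pairs), truncated at 0 to keep
TPM semantics. Background genes are baseline + noise only. With the default
loading 0.9 and noise sd 0.3 the population correlation of a same-sign
module pair is 0.81 / 0.90 = 0.9, comfortably above the working PCC
threshold; cross-sign pairs sit near -0.9.

Each module emits one gene set containing exactly its members; decoy terms
of realistic size are drawn from the background genes so planted labels stay
unambiguous. An optional two-condition design multiplies the baseline of
chosen background genes by 2**effect in the second condition. All randomness
flows from a single integer seed through one generator, so identical seeds
give identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as ckio
from .errors import InputError
from .io import (
    ExpressionMatrix,
    GeneRecord,
    GeneSet,
    GeneSetCollection,
    GenomeAnnotation,
    OrthologMap,
)
from .ppi import PPINetwork

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults are the documented study conditions."""

    n_genes: int = 300
    n_samples: int = 30
    n_modules: int = 8
    module_size_range: tuple[int, int] = (6, 20)
    loading: float = 0.9
    negative_fraction: float = 0.3
    noise_sd: float = 0.3
    baseline: float = 5.0
    n_background_terms: int = 20
    background_term_size_range: tuple[int, int] = (4, 20)
    deg_n_affected: int = 0
    deg_log2fc: float = 2.0
    conditions: tuple[str, str] = ("control", "treated")
    gene_length: int = 400
    intergenic_gap: int = 800
    n_reference_genes: int = 30
    n_reference_edges: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_samples < 3:
            raise InputError("need n_genes >= 2 and n_samples >= 3")
        if self.n_modules < 0 or self.noise_sd <= 0:
            raise InputError("n_modules must be >= 0 and noise_sd > 0")
        lo, hi = self.module_size_range
        if not (2 <= lo <= hi):
            raise InputError(f"bad module_size_range {self.module_size_range}")
        if not (0 <= self.negative_fraction <= 1):
            raise InputError("negative_fraction must lie in [0, 1]")
        if self.n_modules * hi > self.n_genes:
            raise InputError(
                f"{self.n_modules} modules of up to {hi} genes exceed n_genes={self.n_genes}"
            )

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        for key in ("module_size_range", "background_term_size_range", "conditions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticBundle:
    """Everything one generator run produces, plus the ground truth."""

    config: SyntheticConfig
    expression: ExpressionMatrix
    gene_sets: GeneSetCollection
    module_table: pd.DataFrame          # gene_id, module_id, sign
    positive_pairs: set[tuple[str, str]]  # planted same-sign within-module pairs
    negative_pairs: set[tuple[str, str]]  # planted cross-sign within-module pairs
    deg_table: pd.DataFrame             # gene_id, planted_log2fc
    annotation: GenomeAnnotation
    genome: dict[str, str]
    orthologs: OrthologMap
    reference_ppi: PPINetwork


def generate_dataset(config: SyntheticConfig) -> SyntheticBundle:
    """Generate one fully-deterministic synthetic bundle from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    width = max(4, len(str(config.n_genes)))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]
    sample_ids = [f"S{j + 1:02d}" for j in range(config.n_samples)]

    # --- planted modules -------------------------------------------------
    lo, hi = config.module_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_modules)
    module_of: dict[str, int] = {}
    sign_of: dict[str, int] = {}
    cursor = 0
    module_rows = []
    for m, size in enumerate(sizes):
        members = gene_ids[cursor:cursor + size]
        cursor += size
        n_neg = int(round(config.negative_fraction * size))
        flips = rng.permutation(size) < n_neg
        for g, neg in zip(members, flips):
            module_of[g] = m
            sign_of[g] = -1 if neg else 1
            module_rows.append((g, m, sign_of[g]))
    module_table = pd.DataFrame(module_rows, columns=["gene_id", "module_id", "sign"])
    background_genes = gene_ids[cursor:]

    positive_pairs: set[tuple[str, str]] = set()
    negative_pairs: set[tuple[str, str]] = set()
    for m in range(config.n_modules):
        members = [g for g in gene_ids[:cursor] if module_of[g] == m]
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                pair = (min(a, b), max(a, b))
                (positive_pairs if sign_of[a] == sign_of[b] else negative_pairs).add(pair)

    # --- expression ------------------------------------------------------
    factors = rng.standard_normal((max(config.n_modules, 1), config.n_samples))
    values = np.full((config.n_genes, config.n_samples), config.baseline)
    for g, i in ((g, gene_ids.index(g)) for g in module_of):
        values[i] += sign_of[g] * config.loading * factors[module_of[g]]

    # --- two-condition design and planted DEGs ---------------------------
    half = config.n_samples // 2
    condition_of = {
        s: (config.conditions[0] if j < half else config.conditions[1])
        for j, s in enumerate(sample_ids)
    }
    deg_rows = []
    if config.deg_n_affected:
        if config.deg_n_affected > len(background_genes):
            raise InputError(
                f"deg_n_affected={config.deg_n_affected} exceeds the "
                f"{len(background_genes)} background genes available"
            )
        affected = rng.choice(background_genes, size=config.deg_n_affected, replace=False)
        treated_cols = np.arange(half, config.n_samples)
        for g in affected:
            i = gene_ids.index(g)
            values[i, treated_cols] *= 2.0 ** config.deg_log2fc
            deg_rows.append((g, config.deg_log2fc))
    deg_table = pd.DataFrame(deg_rows, columns=["gene_id", "planted_log2fc"])

    values = np.maximum(values + rng.normal(0.0, config.noise_sd, values.shape), 0.0)
    expression = ExpressionMatrix(gene_ids, sample_ids, values, condition_of)

    # --- gene sets: one term per module plus background decoys -----------
    sets: dict[str, GeneSet] = {}
    for m in range(config.n_modules):
        members = frozenset(g for g in module_of if module_of[g] == m)
        tid = f"MOD:{m + 1:03d}"
        sets[tid] = GeneSet(tid, f"planted module {m + 1}", "GO_BP", members)
    blo, bhi = config.background_term_size_range
    for t in range(config.n_background_terms):
        size = int(rng.integers(blo, bhi + 1))
        if size > len(background_genes):
            raise InputError("background terms larger than the background gene pool")
        members = frozenset(rng.choice(background_genes, size=size, replace=False))
        tid = f"BG:{t + 1:03d}"
        sets[tid] = GeneSet(tid, f"decoy term {t + 1}", "GO_BP", members)
    gene_sets = GeneSetCollection(sets, universe=frozenset(gene_ids))

    # --- toy genome ------------------------------------------------------
    spacing = config.gene_length + config.intergenic_gap
    per_chrom = (config.n_genes + 1) // 2
    genes: dict[str, GeneRecord] = {}
    chrom_needs: dict[str, int] = {}
    for i, g in enumerate(gene_ids):
        chrom = "chr1" if i < per_chrom else "chr2"
        k = i if i < per_chrom else i - per_chrom
        start = config.intergenic_gap + 1 + k * spacing
        end = start + config.gene_length - 1
        strand = "+" if i % 2 == 0 else "-"
        genes[g] = GeneRecord(g, chrom, start, end, strand)
        chrom_needs[chrom] = end + config.intergenic_gap
    genome = {
        chrom: "".join(rng.choice(BASES, size=length))
        for chrom, length in sorted(chrom_needs.items())
    }
    annotation = GenomeAnnotation(
        chromosomes={c: len(s) for c, s in genome.items()}, genes=genes
    )

    # --- toy ortholog map and reference PPI -------------------------------
    ref_genes = [f"At{i + 1:03d}" for i in range(config.n_reference_genes)]
    pairs: set[tuple[str, str]] = set()
    for a in ref_genes:
        fanout = int(rng.choice([0, 1, 2], p=[0.2, 0.6, 0.2]))
        for t in rng.choice(gene_ids, size=fanout, replace=False):
            pairs.add((a, str(t)))
    orthologs = OrthologMap(frozenset(pairs))
    ref_edges: set[tuple[str, str]] = set()
    while len(ref_edges) < min(config.n_reference_edges,
                               config.n_reference_genes * (config.n_reference_genes - 1) // 2):
        a, b = rng.choice(ref_genes, size=2, replace=False)
        ref_edges.add((min(a, b), max(a, b)))
    reference_ppi = PPINetwork(edges=frozenset(ref_edges), species="reference")

    return SyntheticBundle(
        config=config,
        expression=expression,
        gene_sets=gene_sets,
        module_table=module_table,
        positive_pairs=positive_pairs,
        negative_pairs=negative_pairs,
        deg_table=deg_table,
        annotation=annotation,
        genome=genome,
        orthologs=orthologs,
        reference_ppi=reference_ppi,
    )


def shuffle_labels(genesets: GeneSetCollection, seed: int) -> GeneSetCollection:
    """Permute gene memberships across genes, preserving every term's size.

    A single random bijection over the annotated universe is applied to every
    set, which destroys the association between network structure and labels
    while keeping sizes and overlap structure — the null control for AUC = 0.5.
    """
    if not genesets.sets:
        raise InputError("empty gene-set collection")
    pool = sorted(genesets.universe) if genesets.universe is not None else sorted(
        {g for s in genesets for g in s.genes}
    )
    rng = np.random.default_rng(seed)
    shuffled_pool = list(rng.permutation(pool))
    mapping = dict(zip(pool, shuffled_pool))
    new_sets = {
        s.term_id: GeneSet(s.term_id, s.name, s.namespace,
                           frozenset(mapping[g] for g in s.genes))
        for s in genesets
    }
    return GeneSetCollection(new_sets, universe=genesets.universe)


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, Path]:
    """Write every bundle component in the toolkit's interchange formats."""
    from .seqtools import write_genome_fasta, write_gff3

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "design": outdir / "design.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "genome": outdir / "genome.fa",
        "annotation": outdir / "genes.gff3",
        "orthologs": outdir / "orthologs.tsv",
        "reference_ppi": outdir / "reference_ppi.tsv",
        "truth_modules": outdir / "truth_modules.tsv",
        "truth_positive_pairs": outdir / "truth_positive_pairs.tsv",
        "truth_negative_pairs": outdir / "truth_negative_pairs.tsv",
        "truth_degs": outdir / "truth_degs.tsv",
    }
    ckio.write_expression_matrix(bundle.expression, paths["expression"])
    ckio.write_design(bundle.expression.condition_of or {}, paths["design"])
    ckio.write_gene_sets(bundle.gene_sets, paths["gene_sets"])
    write_genome_fasta(bundle.genome, paths["genome"])
    write_gff3(bundle.annotation, paths["annotation"])
    ckio.write_ortholog_pairs(bundle.orthologs, paths["orthologs"])
    ckio.write_ppi_edges(bundle.reference_ppi, paths["reference_ppi"])
    bundle.module_table.to_csv(paths["truth_modules"], sep="\t", index=False)
    for key, pairs in (("truth_positive_pairs", bundle.positive_pairs),
                       ("truth_negative_pairs", bundle.negative_pairs)):
        pd.DataFrame(sorted(pairs), columns=["gene_a", "gene_b"]).to_csv(
            paths[key], sep="\t", index=False)
    bundle.deg_table.to_csv(paths["truth_degs"], sep="\t", index=False)
    return paths
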