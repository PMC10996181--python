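# Methods

This note documents the models, parameter choices and numerical decisions
behind coexkit, in the order the pipeline runs.

## Correlation and Mutual Rank

The correlation stage computes the full gene×gene Pearson matrix on raw TPM
values. No normalization beyond TPM is applied by default; a
`log2_plus_one` transform is available behind an explicit flag for users
who prefer variance-stabilized profiles, but the default keeps the
correlation substrate identical to what the thresholds were defined on.
Genes with zero sample variance have an undefined correlation; they are
removed before ranking and reported in `CorrelationResult.excluded_genes`
rather than silently dropped. At least 3 samples and 2 variable genes are
required. Computation is dense (`numpy.corrcoef`), which is comfortable to
roughly 25k genes on a workstation; values are clipped into [−1, 1] to
absorb last-ulp overshoot and the diagonal is forced to 1.

Mutual Rank converts each gene's correlation vector to ranks and combines
the two directions of a pair as MR(A,B) = √(Rank(A,B)·Rank(B,A)). Design
choices:

- **Tie handling is average (fractional) ranks.** This keeps every gene's
  rank sum at exactly G(G−1)/2, which makes MR well defined when duplicate
  PCC values occur and gives the suite a sharp invariant to test.
- **Self-correlation is excluded from every ranking**, so ranks run 1..G−1.
- **The negative network re-ranks by ascending PCC** instead of reusing
  positive-mode ranks. An MR ceiling is only meaningful if the strongest
  pairs of the sign under study rank near 1; for anti-correlated pairs that
  requires ascending order. With this convention "MR < 30" selects mutually
  top-anti-correlated pairs exactly as it selects mutually top-correlated
  ones in the positive network.
- The directional definition of Rank(A,B) vs Rank(B,A) is ambiguous in
  words, but the geometric mean makes the two readings equivalent, so the
  ambiguity is harmless.

Network extraction applies both thresholds **strictly** (PCC > 0.6 and
MR < 30 positive; PCC < −0.5 and MR < 30 negative, the defaults). One
numerical caveat: whether a mathematically-exact boundary pair (say PCC =
3/5) falls on or off the threshold depends on floating-point rounding of
the correlation; the strictness contract is therefore exercised in tests on
fixtures whose *computed* values land exactly on the bound.

## Guilt-by-association validation

Evaluation terms are GO biological-process sets with 4–20 members
(inclusive), sizes measured against the analysis universe (the genes of the
expression matrix) when one is set — small enough to be specific, large
enough that a gene's neighbors can vote. For each gene that carries at
least one selected term and has at least one annotated network neighbor,
every selected term is scored by the fraction of the gene's *annotated*
neighbors carrying it. Restricting the denominator to annotated neighbors
stops sparse GO coverage from diluting all scores; leaving the gene's own
annotations out of its score keeps the evaluation honest. The (gene, term)
records form a two-class problem (label = the gene truly carries the term);
ROC is computed with a block sweep over tied scores and trapezoidal AUC,
which equals the Mann–Whitney concordance statistic with ties counted half
— the suite checks this equivalence against a brute-force oracle.

Threshold selection scans a (PCC bound, MR ceiling) grid, computing PCC and
MR once and re-thresholding. AUCs within a tie tolerance of the maximum
(default 0.01, configurable) count as equivalent, and ties resolve toward
the more inclusive network: smaller |PCC bound| first, then larger MR
ceiling. Degenerate grid points (single-class labels, empty networks)
record a missing AUC with a reason instead of failing the scan. The scoring
scheme is a deliberate, documented choice — the simplest classifier
consistent with neighbor-vote prediction — not the only possible one.

## Differential expression

DEGs are called by a two-sided equal-variance Student's t-test per gene
with p < 0.05, plus a |log2 fold change| > 1 filter; Welch's test is a
flag. Fold change is group_b relative to group_a ("up" = higher in
group_b), computed from group means with a pseudocount of 1.0 so zero-TPM
genes stay finite. Genes with zero variance in both groups and equal means
get p = 1. No multiple-testing correction is applied by default, matching
the raw-p definition of the DEG rule; Benjamini–Hochberg is available via
`adjust="bh"`. The test runs on raw TPM by default with a log2(TPM+1)
option; means are always reported on the TPM scale.

## Over-representation analysis

The enrichment tool is over-representation analysis: hypergeometric upper
tail P[X ≥ k] for a query of n universe genes overlapping a K-gene term by
k in a universe of N, with BH adjustment applied within each namespace
(GO_BP separately from KEGG, etc.) since those tables are reported
separately. Rank-based, weighted GSEA is intentionally out of scope; the
exercised use case is enrichment of discrete up/down DEG lists. The
universe defaults to the gene-set collection's declared universe (normally
the expression matrix genes) and is always logged.

## Interolog PPI projection

A reference interaction (a1, a2) is transferred to every pair (d1, d2)
with d1 ∈ orthologs(a1), d2 ∈ orthologs(a2) — the full cross-product over
many-to-many ortholog relations, the standard interolog convention.
Self-pairs arising from shared orthologs are dropped; duplicates across
source edges are collapsed. Ortholog inference itself (e.g. OrthoFinder) is
consumed as a two-column table, never re-implemented.

## Sequence tools

All coordinates are GFF3-style 1-based inclusive, end-to-end, including the
CLI. Promoters are windows of a requested length (default 3000 bp)
immediately 5′ of the gene feature's start — a TSS approximation, since
gene models rarely annotate the true TSS: [start−L, start−1] on the plus
strand, [end+1, end+L] reverse-complemented on the minus strand. Windows
are clipped at chromosome bounds and flagged rather than erroring; a gene
flush against the edge yields an empty, flagged record.

## Synthetic data

The generator is first-class, tested code; every fixture the suite uses
flows from one integer seed through one `numpy` Generator. Expression
follows a latent-factor model: module m has a standard-normal factor per
sample, member genes load on it with magnitude 0.9 (a configurable fraction
— default 0.3 — with negated sign, planting anti-correlated pairs for the
negative network), plus Gaussian noise (sd 0.3) on a +5 TPM baseline,
truncated at 0. Under these defaults a same-sign module pair has population
correlation 0.81/0.90 = 0.9. Defaults: 300 genes, 30 samples, 8 modules of
6–20 genes — chosen as the documented study conditions for all benchmark
properties.

Each module emits one gene set containing exactly its members. Decoy terms
(default 20, sizes 4–20) are drawn from the *background* genes only: decoys
then exercise term selection and add annotation bulk without relabeling
module genes, keeping the planted ground truth unambiguous. The
label-shuffling null applies one random bijection over the universe to
every set, preserving sizes and overlap structure.

The optional two-condition design splits samples half/half and multiplies
the baseline of a chosen number of background genes by 2^effect in the
second condition; it is off by default so the network benchmarks measure
module structure alone, and DEG benchmarks enable it explicitly.

What the generator does **not** emulate: heavy-tailed TPM marginals,
mean–variance coupling, batch effects, correlated noise across modules,
and hierarchically overlapping GO terms. Passing benchmarks therefore shows
the machinery is correct and calibrated under the stated model, not that
real tissue panels will reach the same precision/recall or AUC.

## Problem sizes and runtime choices

The test-suite and acceptance benchmarks run at 300 genes × 30 samples
(networks/GBA, 10–20 replicates), 2,000 genes for DEG null calibration, and
a 500-gene end-to-end CLI run — sizes chosen so the whole suite completes
in well under a minute while leaving the statistical properties (type-I
error 5% ± 2%, AUC calibration within 0.05) clearly testable. The dense
G×G path is the contract; blocked computation would be an internal
optimization, not an interface change.

## Known limitations

- Correlation on raw TPM is sensitive to outlier samples; no robust
  correlation option is provided.
- The GBA classifier is one documented choice among several reasonable
  ones (e.g. weighted neighbor votes, label propagation).
- DEG calling is a two-group t-test on normalized values, not a count
  model; it is not appropriate for n < 2 per group or paired designs.
- Interolog projection carries no confidence scoring; dense ortholog
  fan-outs can inflate projected degree.
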