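# Methods

This note documents the procedures `consensustx` implements, the defaults it
ships, the numerical choices behind them, and what the synthetic benchmark
does and does not demonstrate.

## Greedy identity clustering

Pooled contigs are clustered incrementally, longest first (ties broken by
input order).  Each contig is compared against existing cluster
representatives in creation order and joins the first one it matches at
identity ≥ *c* (`assign_mode="first_match"`, the classic greedy behaviour;
`best_match` is available for comparison).  Otherwise it founds a new
cluster.  Because the scan is length-descending, representatives are always
the longest member of their cluster; the alternative convention of choosing
"the member that best matches the others" would require all-vs-all alignment
within each cluster and is not what incremental clustering tools actually
compute, so we deliberately use longest-member representatives.

**Identity** between two contigs is the number of identical aligned bases
divided by the length of the *shorter* sequence, maximized over both strands.
The alignment is end-gap-free (the longer sequence's overhangs are
unpenalized), i.e. the shorter sequence is aligned as an infix of the longer
one.  This containment semantics is what makes fragment collapse work: an
exact substring has identity 1.0.  The implementation computes the optimal
infix alignment with `edlib` (banded Myers bit-vector edit distance) and
counts the `=` runs of its extended CIGAR; positions where an `N` aligns are
never counted as matches.  Identity comparisons against the threshold use an
absolute epsilon of 1e-9 so that, e.g., a 30/1000-substitution pair sits
exactly at 0.970 regardless of float representation.

**Word prescreen.**  Two sequences at identity ≥ *c* over shorter length
`Ls` have at most `ceil((1-c)·Ls)` non-matching columns, each destroying at
most `n` of the `Ls − n + 1` length-`n` windows of the shorter sequence, so
the pair shares at least `Ls − n + 1 − n·ceil((1−c)·Ls)` words.  Shared
words are counted *with multiplicity* (sum of per-word minimum counts), which
upper-bounds the number of matching aligned windows even for repetitive
sequences; the filter rejects a candidate only when both strands fall below
the bound.  It is therefore conservative by construction, and the test suite
verifies that clustering with and without the prescreen produces identical
partitions.  Default word length: 9.

**Default threshold 0.97.**  The threshold must sit above the identity of
real isoform pairs (~0.96) and below that of cultivar alleles (≥ 0.99).
0.97 merges alleles differing by a few SNPs while keeping 96%-identity
isoform pairs in distinct clusters; `cluster_threshold_scan` re-runs the
clustering over a threshold grid for choosing *c* on new data.

## The 2-of-3 cluster filter

Each cluster is scored on (i) representative length, (ii) number of member
contigs, (iii) FPKM summed over all members and all samples.  Pass
conditions are `length ≥ 500`, `n_contigs > 10`, `sum_fpkm > 50` — the
length bound inclusive (a *minimal* length), the other two strictly
exclusive, matching how the cut-offs are stated; all three are
config-exposed.  A cluster is discarded only when **≥ 2** criteria fail
(`max_failures = 1`).  The disjunction protects genuinely short genes and
weakly expressed rare isoforms that any single hard threshold would remove;
the filter is monotone (improving one metric can never cause a discard),
which the suite checks property-based.

Cluster length is the *representative's* length, since the representative is
the sequence retained in the output FASTA.  `sum_fpkm` sums over member
contigs (not just the representative), consistent with the contig-to-cluster
expression procedure below.  Without an abundance table the filter degrades
to the two structural criteria (discard iff both fail) with a warning.

Composition analysis: `participation_matrix` counts members per (cluster,
source assembly); `assembly_correlation` is the Pearson correlation of those
per-assembly vectors, by default over true clusters only (size ≥ 2), since
singletons carry no co-occurrence signal; `breadth_histogram` tabulates
clusters by the number of distinct source assemblies, with a core set at
breadth > 10.

## Reconstruction quality by self-normalized bitscore ratio

For a reference gene *g* and an assembly, every contig is aligned locally
(Smith–Waterman, both strands; scikit-bio's `pair_align`) and the best raw
score *S* is converted to bits with the Karlin–Altschul transform
`bits = (λ·S − ln K)/ln 2`.  The **ratio** is best-hit bits divided by the
gene's self-alignment bits (`λ·m·|g| − ln K` over ln 2, since the optimal
self local alignment is the full-length exact match).  Properties:

* verbatim copy ⇒ ratio 1.0 exactly, for any scheme (self-normalization);
* ratio ∈ [0, 1] always — no local alignment against anything can out-score
  the self alignment under positive-match scoring;
* exact half-length fragment of a kb-scale gene ⇒
  `(λ·S/2 − ln K)/(λ·S − ln K)` ≈ 0.5.

Default scheme: match +1, mismatch −2, gap open 5, gap extend 2 (a length-k
gap costs `open + k·extend`), with λ = 1.28, K = 0.46 from the standard
nucleotide parameter table.  Because the ratio is self-normalized it is
largely insensitive to these constants, which is why we do not chase
bit-exact parity with any particular aligner version; other schemes require
λ and K explicitly (`ungapped_lambda` solves the ungapped score equation for
uniform base composition).  E-values are not computed for ratios; they only
appear as a pre-filter on externally supplied hit tables
(`hit_coverage_table`, default cutoff 1e-20).

An exact-word prescreen (11-mers, both strands) skips contigs sharing no
seed with the gene; such contigs can only produce noise-level local scores,
and the suite checks prescreened scores equal exhaustive ones on contigs
with any real similarity.

**Isoform prediction** counts distinct contigs whose individual ratio
exceeds 0.8 — a deliberately permissive empirical threshold: a full-length
97%-identity partner scores ≈ 0.88 ratio under the default scheme
(0.97·1 − 0.03·2 = 0.91 of the self raw score, slightly less in bits), so
both members of a real isoform pair are counted, while fragments below ~80%
of the gene are not.  Hit granularity is the contig, not the cluster: the
question is how many distinct high-quality sequences an assembly holds.

## Cluster-level expression and concordance

Contig-level FPKM (`fragments × 10⁹ / (length × library size)`) is attributed
to clusters by summing member contigs per sample — the transcript-to-gene-map
idea applied to the contig-to-cluster map.  Aggregation conserves per-sample
totals over mapped contigs exactly.  Multi-mapping resolution (the EM
estimator of external quantifiers) is deliberately *not* re-implemented; the
module consumes per-contig abundance tables, because the contribution here is
the cluster-level attribution, not fragment assignment.

Expression is normalized by dividing by a reference (housekeeping) cluster
per sample; a zero reference value is an error naming the sample.
Concordance with qPCR is the adjusted r² of ordinary least squares of
log2(RNA-seq) on log2(qPCR) over matched (gene, sample) pairs,
`adj r² = 1 − (1 − r²)(n − 1)/(n − 2)` (one predictor).  Pairs with a zero on
either side are excluded and counted; an optional additive `log_floor`
retains them instead.  Zero-handling is a genuine design choice (the measure
is undefined at zero); exclusion is the default because a floor biases slopes
at the low end.

## Digital read normalization

Single pass over the read stream in input order.  A read is retained iff the
median count of its canonical k-mers (k = 25), looked up in a counter built
from *previously retained* reads only, is < `max_cov`; its k-mers are then
committed.  Hence copy *m* of a duplicated read is admitted iff m − 1 <
max_cov, the output is a subsequence of the input, and the operation is
idempotent.  Streaming admission was chosen over two-pass filtering because
it is deterministic, order-stable and directly expresses the goal of capping
per-transcript coverage; the coin-flip variant used by some tools is
intentionally out of scope.  Pair-aware mode admits a pair iff the mean of
the two median coverages is below the cap, so mates are never orphaned.
The default cap is 30 (the value used when normalizing individual samples);
50, reported for the same tooling in another context, is available through
`NormalizeConfig(max_cov=50)` — the two appear interchangeably in practice
and the choice is config-level, not structural.

## Synthetic truth sets

The generator emulates the statistical structure the pipeline must resolve,
at the study's design points: 19 single assemblies and 42 expression samples
by default, kb-scale genes (900–1500 nt), isoform pairs at 0.96 identity,
SNP-level cultivar alleles, fragmentation into 1–3 pieces of ≥ 100 nt with
probability 0.3 per (gene, assembly), 10% dropout.  Specifics:

* **Isoforms** are substitution-only mutants at exactly
  `round((1 − target)·L)` distinct positions, so the realized identity is
  the target up to rounding.  Alleles are substitution-only too; small
  within-cluster variation in real data is SNP-like, and indel robustness is
  exercised separately through fragmentation.
* **`allele_rate` is a per-allele cap** (substitutions per kb): each allele
  draws uniformly between 0 and `floor(rate·L/1000)` substitutions (also
  ≤ 1% of length).  Two alleles of one gene therefore diverge by at most
  `2·rate/1000`, guaranteeing pairwise identity ≥ 0.99 for rates ≤ 5/kb —
  a hard guarantee a mean-rate (binomial) model cannot give, and the property
  the allele/isoform discrimination benchmark depends on.
* **Expression** is log-normal per gene per sample (μ = 3, σ = 1 on the log
  scale), the housekeeping reference held constant at exp(μ), and gene FPKM
  split over the gene's contigs proportionally to contig length, so contig
  values sum back to gene truth exactly.
* **Reads** are uniform tilings with optional per-gene duplication — enough
  to exercise the normalizer's cap, with no sequencing-error or quality
  model, no insert-size model.
* A single top-level seed fans out to per-stage child seeds via
  `seed·7919 + crc32(stage tag) mod 2³¹`; all generators are byte-identical
  across runs for a fixed seed.

What passing on this benchmark shows: the clustering/filtering/scoring logic
behaves as specified under SNP-level allelic variation, fragmentation and
uneven expression.  What it does not show: robustness to sequencing error,
chimeric contigs, alternative splicing (isoforms here differ by substitutions
only, not exon structure), or quantifier noise — real corpora add all four.

## Problem sizes

The test suite and the acceptance script run on deliberately small instances
chosen to exercise every code path while completing in seconds on one CPU:
corpora of 6–12 genes across 3–19 assemblies (≈ 30–250 contigs of 0.3–1.5 kb),
20-seed replications for the stochastic claims, and a 543,979-row metric
census (records only, no sequences) for the filter bookkeeping.  The
clustering and alignment kernels are the same at any scale; only the corpus
sizes are scaled down.

## Known limitations

* Greedy first-match clustering is order-dependent by design (it reproduces
  the behaviour of the standard tools); `best_match` reduces but does not
  remove that dependence.
* The end-gap-free identity is computed from a minimum-edit-distance infix
  alignment; for pairs whose optimal match-maximizing alignment differs from
  the edit-distance optimum (heavily indel-ridden pairs far below any usable
  threshold), the reported identity can be marginally conservative.  At and
  above clustering thresholds (≥ 0.90) the two coincide on substitution-and-
  fragment structured data.
* Karlin–Altschul constants are tabulated for the default scheme only;
  exotic schemes need explicit λ and K.
* `hit_coverage_table` trusts the supplied hit table; it does not re-align.
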