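# Methods

This note documents the models and procedures implemented in `cnvrkit`,
the conventions and parameter choices behind them, what the synthetic-data
generator does and does not emulate, and known limitations.

## Coordinates and formats

All internal coordinates are 0-based half-open, so interval length is
`end - start` and abutting intervals share no base. GFF3/GTF input
(1-based inclusive) is shifted on read; report TSVs display 1-based
inclusive coordinates to match Ensembl-style tables, and every writer
states its convention in a header comment. Chromosome names are matched as
exact text — no "chr"-prefix normalization — because silent renaming hides
data errors. Strand is carried on gene models but ignored by all overlap
computations: CNVRs are unstranded genomic events.

## CNVR construction

Two intervals A, B with shared length *o* have reciprocal overlap
`min(o/|A|, o/|B|)`. Merging is an iterated fixed point: starting from the
calls sorted by (chrom, start, end, sample), the first pair of current
regions (in that sorted order) with reciprocal overlap ≥ the threshold
(default 0.5) is merged into a region spanning their joint extent, and the
scan repeats until no pair qualifies. Two notes on this definition:

* **The fixed point is not unique in general.** When a region B qualifies
  with both A and C but A and C do not qualify with each other, the merge
  order decides the outcome (e.g. [0,100), [50,150), [100,200) at
  threshold 0.5). The first-qualifying-pair-in-sorted-order rule is
  therefore part of the operation's definition, making the result
  deterministic and independent of input order. In realistic data — calls
  jittered around well-separated true regions — such ambiguous chains are
  rare and the rule is immaterial.
* **Threshold comparisons are exact.** Overlap fractions are compared with
  rational arithmetic on integer lengths (`Fraction(o, max(|A|,|B|)) >=
  Fraction(threshold)`), so a pair at exactly 50% always merges and no
  floating-point boundary flakiness is possible.

At the fixed point no two emitted regions qualify, so re-merging the
emitted extents is the identity (idempotence), and every input call
belongs to exactly one region (partition property). Both are enforced by
property tests, along with equivalence to a from-scratch brute-force
fixed-point oracle on random instances.

Frequency filtering counts **distinct samples**, not calls (a sample
contributing two calls counts once); the default of 3 reflects a
rare-variant screen of roughly 2% in a population of ~175. State
classification compares each member's copy number with its chromosome's
expected copy number — default 2 for autosomes and 1 for X, the baseline
for male samples; both are configurable per chromosome. A member exactly
at baseline is rejected as malformed input: a no-change call does not
belong in a CNV list.

Cross-study comparison (`compare_cnvr_sets`) deliberately uses the loose
any-shared-base criterion rather than reciprocal overlap, since published
CNVR maps differ strongly in resolution.

## Gene annotation

A gene is a CNV gene when it shares at least one base with at least one
CNVR. Overlap is *complete* when the union of the gene's overlapping CNVRs
covers the gene interval, else *partial*. Gene classes derive from CNVR
states: only-gain → duplication, only-loss → deletion, anything else →
mixed. A gene overlapped by one pure-gain and one pure-loss CNVR is
classed mixed — it genuinely experiences both directions. Classes are
assigned from CNVR state rather than from individual member calls, so a
gene under a mixed region is mixed even if one particular carrier only
lost it. All biotypes are annotated; the enrichment stage restricts the
query to protein-coding genes.

## GO over-representation

The universe is the set of genes with at least one annotation in the
reference table (not all genome genes), and the query is intersected with
it before testing. With query size *n*, universe size *N* and *K* universe
genes on a term, the expected query count is `n·K/N` and the observed *k*
is referred to Binomial(n, K/N): `P(X ≥ k)` when *k* exceeds the
expectation (direction "+"), `P(X ≤ k)` otherwise ("−"). Tails come from
`scipy.stats.binom`, which computes them in log space internally. The
Bonferroni multiplier is the number of terms with K ≥ 1 in the annotation
set in use; full-ontology and slim-subset analyses are simply separate
runs with separate multipliers. Annotations are taken as given
(pre-propagated); no ontology-graph propagation is applied.

## Selective constraint (dN/dS)

Per ortholog pair, the classic pairwise protocol: standard-genetic-code
translation (codons containing N → X; terminal stop trimmed; internal stop
is an error naming the codon), global protein alignment under BLOSUM50
with affine gaps, gap projection onto codons (one amino-acid gap → `---`),
then the Nei–Gojobori (1986) proportion method:

* Synonymous site count per codon: at each position, the fraction of the
  three alternative nucleotides whose substitution preserves the amino
  acid; substitutions creating stop codons count as nonsynonymous. Sites
  are averaged between the two sequences; `S + N = 3 ×` (ungapped,
  stop-free codon columns) always holds.
* Differences: codons differing at d positions are averaged over all d!
  minimal mutational pathways; pathways through stop codons are discarded,
  and in the rare case every pathway is blocked, all pathways are used
  with stop-entering steps counted as nonsynonymous (this keeps the site
  bookkeeping intact).
* Jukes–Cantor correction `d = -(3/4)·ln(1 - (4/3)p)` applied to
  pS = Sd/S and pN = Nd/N. When `p ≥ 3/4` the logarithm is undefined: the
  pair is flagged **saturated** and removed from all contrasts. ω with
  dS = 0 but dN > 0 is reported infinite and excluded from rank tests; a
  pair with no substitutions at all has undefined ω.

Gap penalties are not dictated by the protocol itself; the defaults
(open 10, extend 1 on BLOSUM50) are fixed for determinism and configurable
(`--gap-open/--gap-extend`). For genuine orthologs the alignment — and
hence the estimate — is insensitive to these within reasonable ranges.
Tie-breaking among co-optimal alignments follows Biopython's canonical
traceback order, which is deterministic for fixed inputs.

## Expression breadth and tissue specificity

A gene is expressed in a tissue when **any one sample** of that tissue
strictly exceeds the platform threshold: UPC > 0.5 for microarray (UPC is
a 0–1 score interpretable as the probability the gene is active),
FPKM/RPKM > 1.0 for RNA-seq. The inequality is strict: a value exactly at
threshold does not qualify. Tissues assayed by more than one experiment
use the union rule — expressed in either experiment counts. Tissue labels
can be harmonized through a user-supplied synonym table; unmapped labels
are an error listing the offenders, never silently dropped.

Breadth is the number of expressed tissues over the full analyzed panel
(not only tissues with usable data for the gene), and **tissue-specific is
defined as breadth exactly 1** — the natural reading of "specific", made
explicit here because looser definitions (e.g. dominant-tissue fractions)
exist. The breadth contrast includes only genes expressed in ≥ 1 tissue on
both sides.

## Network centrality

Edge lists are symmetrized and deduplicated; self-loops are dropped;
confidence scores, if present, are ignored (no score threshold is applied,
as the analysis this mirrors used none). Degree is the number of distinct
partners; genes absent from the edge list have degree 0 and are excluded
from contrasts by the ≥ 1-interaction restriction.

## The rank-sum test

All three contrasts use a one-tailed Wilcoxon rank-sum (Mann–Whitney)
test with `U = R₁ − n₁(n₁+1)/2` (midranks for ties). When the pooled size
is ≤ 12 the p-value is exact: a permutation null over every assignment of
the pooled **values** to the two groups, which handles tied values exactly
(tied pairs contribute ½ to U). Beyond that, the normal approximation with
tie-corrected variance and a 0.5 continuity correction is used; it agrees
with the exact computation to < 0.01 absolute at n₁ = n₂ = 10 and is
calibrated to 5% ± 1% empirical size at α = 0.05 over 10⁴ null
replicates (both verified in the test suite). The switch point is
configurable; 12 keeps the enumeration below C(12,6) = 924 subsets.

## Synthetic data: what it emulates, and what it does not

The generator plants ground truth for every stage under one master seed,
with an independent spawned stream per sub-generator so stages never
perturb one another and output files are byte-identical across runs.

* **Genome.** 29 autosomes (ploidy 2) plus X (ploidy 1) of 3 Mb each — a
  scaled-down stand-in for a ~2.7 Gb mammalian assembly chosen so whole
  pipeline runs complete in seconds while exercising identical coordinate
  arithmetic. Consequence: genome-fraction numbers from synthetic runs are
  ~30× larger than a full-genome study would report.
* **CNV calls.** Planted regions are non-overlapping (truth stays
  unambiguous), log-uniform in size (2–200 kb), with a 1/f carrier
  spectrum capped at 36% of samples and a loss/gain/mixed mix of
  0.53/0.28/0.19. Carrier calls jitter both endpoints by a truncated
  normal (absolute SD in bases, or a fraction of region length); the
  jitter is clamped at one sixth of the region length, which guarantees
  ≥ 50% reciprocal overlap between every call and its region **and**
  between sibling calls, so merging provably reunites each region.
* **Ortholog pairs.** Ancestors are uniform sense codons; one lineage
  receives Poisson(μ) proposal events per nucleotide site, accepting
  synonymous changes always, nonsynonymous with probability ω, and
  stop-creating changes never. At low divergence the accepted synonymous
  rate per site approaches μ, so μ doubles as the target dS (default
  0.43, kept below the 0.5 saturation guard). Two known estimator-level
  effects, both visible in the tests: pathway averaging attributes a
  sliver of dN to multi-hit codons even at ω = 0, and the generator's
  refusal to create stops (which NG86 site counting treats as available
  nonsynonymous changes) biases ω estimates at ω = 1 about 10–13% low —
  within the 15% recovery band the suite enforces.
* **Expression.** Planted breadths are `1 + Binomial(21, p)` with p set so
  medians land at 2 (CNV genes) and 10 (neutral genes) over a 22-tissue
  panel split across one microarray and two RNA-seq experiments, six
  tissues assayed twice. Expressed (gene, tissue) pairs get one clearly
  supra-threshold sample in at least one covering experiment; everything
  else stays sub-threshold, so calling recovers the planted sets exactly.
* **Network.** Target degrees are Poisson with class means (duplication 5,
  others 10), realized by a configuration model then simplified; realized
  degrees sit slightly below target, which is why truth records targets.
* **Annotations.** Background terms annotate genes class-blind; planted
  enriched terms annotate CNV genes at 30% vs 1%.

What passing tests on this data do **not** show: robustness to overlapping
true regions, to correlated noise in read-depth calls, to cross-platform
expression batch effects beyond binary calling, to annotation bias, or to
any property of real genomes (GC structure, segmental duplications,
assembly gaps). The generator validates the *arithmetic and inference
chain*, not the upstream calling.

## Numerical and degenerate-input choices

* Merging threshold comparison in exact rationals; ties in region ordering
  broken by the smallest member (start, end, sample) tuple.
* Jukes–Cantor at p = 0 returns exactly 0; the saturated flag is raised
  exactly when the log argument is ≤ 0.
* Exact rank-sum p includes the observed arrangement, so p ∈ (0, 1];
  approximate p is floored at the smallest positive float.
* Zero-length intervals, empty groups, empty queries, unknown platforms,
  unmapped tissues, baseline-equal copy numbers and malformed rows all
  raise immediately with the offending item named; no silent repair.

## Limitations

* dN/dS is the pairwise counting estimate; no maximum-likelihood codon
  models, no transition/transversion or codon-frequency corrections.
* No ontology-graph propagation and no FDR alternative in the default
  enrichment path (Bonferroni only).
* Gene classes resolve at gene level; no transcript- or exon-level overlap.
* Degree is the only centrality; no betweenness/closeness/eigenvector.
* The pipeline consumes caller output; it neither calls CNVs from reads
  nor models read depth.
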