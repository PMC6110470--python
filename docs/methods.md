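# Methods

`exodel` implements an exome read-depth deletion-discovery and
interpretation pipeline over synthetic cohorts: depth simulation →
PCA-normalized depth + 3-state HMM deletion calling → quality and case-only
filtering → case-control burden permutation testing, alongside a small-variant
deleteriousness classifier, a compound-heterozygote screen on a brain-specific
protein-interaction network, and hypergeometric gene-set over-representation.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic data does and does not establish.

## Depth model and the synthetic cohort

Per-target mean read depth for sample *s* at target *t* is drawn
negative-binomially around

μ_st = depth_mean · g_t · f_s · exp(Σ_k a_sk b_tk) · c_st

with

* `depth_mean` — cohort-wide coverage, default 100×;
* g_t — per-target capture efficiency, lognormal with log-sd
  `target_log_sd = 0.3` (capture kits vary severalfold across targets);
* f_s — per-sample library-size factor, lognormal with log-sd
  `sample_log_sd = 0.2` (library depth commonly varies ±40%);
* a low-rank multiplicative batch term (`batch_rank = 2` latent factors,
  loading sd `batch_sd = 0.1`) — the systematic structure the PCA
  normalization exists to remove;
* c_st — copy ratio, 1 everywhere except targets spanned by an embedded
  deletion in a carrier, where it is 0.5 (heterozygous loss);
* NB dispersion `depth_dispersion = 200` (variance μ + μ²/200, ≈12%
  coefficient of variation at 100×; the Poisson floor dominates at this
  depth).

Batch magnitude matters at desk scale: with much stronger multiplicative
factors (loading sd ≳0.15) the exponential generates a ladder of harmonic
components that the variance criterion also removes, and on a 5,000-target
matrix those extra components absorb a visible fraction of any localized
single-sample deviation. The defaults keep the systematic structure to the
3–4 genuine components (size factor + batch factors), which is the regime the
normalization operates in on full-size exomes, where components spread over
~200k targets and absorption of a 10–20-target signal is negligible.

Targets are laid out on 5 synthetic chromosomes with exponential inter-target
gaps (mean 1 kb; the analysis drivers use 3 kb so that a >400 kb deletion
spans ~140 targets rather than most of a chromosome) and Gaussian target
lengths (150 ± 50 bp, floor 50). Coordinates are 1-based with exclusive ends,
so length = end − start everywhere; BED (0-based half-open) and GFF3
(1-based inclusive) are converted exactly at the file boundary.

Deletion loci are placed on non-overlapping target runs (with a 2-target
margin) and carriers are drawn without replacement from the eligible
phenotype groups at the configured fraction. One global seed drives
independent named child streams (layout / depth / variants / network / maps /
gene sets), so adding or re-running one generator never perturbs another and
identical seeds give byte-identical outputs.

What the generator does **not** model: GC-content or mappability bias,
target-level dropout, duplications, related individuals, ancestry structure,
and genotype-level linkage between deletions and small variants. Passing the
recovery tests therefore shows the caller handles overdispersed counts with
low-rank structure and rare embedded signal — not that it is robust to every
bias of real capture data.

## Deletion calling

**Coverage QC.** A sample is excluded iff its mean depth is <30× or fewer
than 70% of targets reach 20×; survivors pass through unchanged.

**PCA normalization.** The depth matrix is target-mean-centred; principal
components whose variance exceeds `rel_var_threshold` (default 0.7) times
the mean component variance are subtracted; each residual row is divided by
its own standard deviation, giving per-sample z-scores with unit row sd.
Two numerical guards: (i) at most half of the sample dimensions may be
removed — in tiny cohorts the noise eigenvalue bulk is so wide that the
variance criterion would otherwise select every component and null the
matrix; (ii) residual rows with zero variance (a sample identical to the
target means) are dropped with a warning, per the degenerate-input contract.

**HMM.** States diploid/deletion/duplication with Gaussian emissions on z
(means 0 / −3 / +3, sd 1). Transitions depend on the distance d between
adjacent target midpoints: with attrition factor f = exp(−d/D), a CNV state
persists with probability f and otherwise reverts to the quasi-stationary
distribution (1−2p, p, p); the diploid row is (1−2p, p, p) throughout.
Defaults p = 1e−8 and D = 70 kb follow the published defaults of the
read-depth caller this reimplements; both are configurable. Adjacent targets
on different chromosomes are treated as infinitely distant, which resets the
chain. Viterbi runs vectorized across samples in log space; back-pointer
ties resolve to the lowest state index (DIP < DEL < DUP) for determinism.
Maximal non-diploid runs become calls spanning the first to last target.

**Scoring.** Q_SOME is the phred-scaled posterior that ≥1 target in the
segment occupies the call's CNV state, capped at 99:
`min(99, round(−10·log10(P(no such target))))`. P(none) comes from a forward
recursion restricted to the complement states, run in the same scaled space
as the standard forward-backward pass (scaling plays the role of log-space
arithmetic; nothing non-finite can be returned — total underflow of the
"none" mass simply hits the 99 cap). The per-call z-score is the arithmetic
mean of z over the call's targets. Both quantities are verified against
exhaustive 3^n path enumeration on small instances.

## Filtering and matching

Deletion calls survive the quality filter iff z_mean < −3 (strict) and
Q_SOME ≥ 60; duplications are discarded outright (their false-positive rate
makes them uninterpretable in this design). The case-only screen then keeps a
call iff no control call matches it, at most 2 distinct case samples carry a
matching call, and no reference-map interval with frequency >1% matches it —
"matches" meaning reciprocal overlap min(|a∩b|/|a|, |a∩b|/|b|) ≥ 0.7
throughout. The overlap fraction and carrier ceiling are configurable; the
reciprocal (rather than one-way) reading of the 70% rule is a design choice
applied consistently to call-call and call-map matching. Gene annotation
reports every gene model whose span shares ≥1 bp with the call, via
per-chromosome interval trees.

## Burden test

Input: quality-filtered deletions from cases and controls. Selection keeps
deletions with length >400 kb whose internal carrier frequency — the
fraction of all samples carrying a ≥70%-reciprocal-overlap match — is
<0.5%. Four statistics per group: deletions per person, fraction of samples
with ≥1 deletion, total deleted bp per person, and mean deletion length
(0 by convention for a group without calls). Significance is one-sided
(cases > controls) on the case-minus-control difference, by label
permutation. With sampling, the estimator is add-one-corrected,
p = (1 + #{Δ* ≥ Δ})/(1 + n_perm), so p ∈ [1/(n_perm+1), 1]; when the number
of distinct labelings C(n, n_cases) is at most `exhaustive_max_labelings`
(default 2·10⁵), exact enumeration replaces sampling and p is the exact tail
fraction (the observed labeling is part of the enumeration, so p ≥
1/#labelings). Ties count toward the tail (with a 1e−12 float guard), which
keeps the test valid though mildly conservative for the count-valued
statistics.

## Variant pipeline

Genotypes with DP < 10 or GQ < 20 are set to missing (alleles and site
fields untouched; site missingness is recomputed). Site-level hard filters
follow the standard SNV/INDEL threshold sets (QD, FS, MQ, rank-sums, DP,
mean GQ, missingness >5%, ABHet outside [0.25, 0.75], Hardy-Weinberg
phred > 20 meaning p < 0.01, and a VQSLOD cut-off). A missing annotation
passes by default (filter only on evidence present); `strict_missing`
inverts that. The VQSLOD directionality for indels is genuinely ambiguous in
the upstream convention this mirrors, so it is an explicit config field
(`vqslod_fail_below`, default 0 for both modes) rather than a guess baked
into code.

Multi-allelic records are decomposed one alt at a time and left-normalized
(right-trim shared suffix, extending left from the reference when an allele
would empty; then left-trim shared prefix). The operation is idempotent and
haplotype-preserving, both property-tested.

Rarity: allele frequency <0.005 (strict) in every database present; absence
counts as 0. The deleteriousness verdict fires on any of: (1) non-synonymous
effect with ≥5 of the 9 missense predictors calling deleterious, or CADD
>4.5, or ≥2 of {GERP >3, PhyloP >0.95, SiPhy >10}; (2) splicing, stop-gain
or stop-loss; (3) any insertion or deletion. Synonymous variants never
qualify via scores. The quoted rule says "5 out of 8" while listing nine
predictors; the panel defaults to all nine listed scores with a quorum of 5,
and both are configurable. Missing predictor calls never count toward the
quorum. The CADD threshold applies to whichever CADD column the input
carries (raw vs phred is not disambiguated upstream; the threshold is
configurable for either convention).

## Compound-heterozygote screen

The interaction network is restricted to nomenclature-valid, brain-expressed
genes; edges survive only if both endpoints do (no transitive closure).
For each sample, a hit pairs a case-only deletion with a rare deleterious
variant in the same gene (`same_gene`) or in a first-order network partner
of a deleted gene (`first_order`). Phasing is unavailable, so "a deleterious
variant on the other allele" is operationalized as any passing deleterious
variant in the deletion carrier; genotype state is recorded but not filtered
on. Symbol matching is exact and case-sensitive. Output ordering is
deterministic (sample, variant gene, position, relation).

## Enrichment statistics

Over-representation is the exact upper-tail hypergeometric probability
P(X ≥ k) for overlap k between an n-gene query and a K-gene set in an
N-gene background (evaluated via the survival function, stable in the deep
tail). The published analyses this reproduces used a brain-expressed
background of N = 14,177; the three printed p-values are reproduced within
±0.002 before rounding (the exact tail gives 0.0114 / 0.0080 / 0.2171
against printed 0.012 / 0.009 / 0.217 — the source's rounding convention or
resampling noise is not recoverable, hence the tolerance). Score
comparisons use the two-sided Wilcoxon/Mann-Whitney rank-sum test: exact
when both groups have ≤20 observations without ties, otherwise the normal
approximation with mid-rank tie correction; identical pooled values return
p = 1 by convention.

## Problem sizes and verification

The test suite verifies: Viterbi log-probability, forward-backward
posteriors and segment Q_SOME probabilities against enumeration of all 3^n
paths (200 random instances, n ≤ 8); the classifier against an independent
truth-table sweep of effect × predictor-quorum × CADD × conservation; the
burden test against exact enumeration (the 4-case/4-control instance gives
p = 1/70), a 500-replicate null calibration at 200 permutations (rejection
at α = 0.05 within [0.03, 0.07]), and an enriched 15%-vs-5% design
(p < 0.01 at 1000 permutations); rank-sum p-values against exhaustive
rank-split enumeration for all group sizes ≤7; the compound-het screen
against a brute-force triple loop; and end-to-end recovery on a seeded
200-sample × 5,000-target cohort at 100× with 15-target heterozygous
deletions (≥90% sensitivity at ≥70% reciprocal overlap, ≤10% false
discovery after the z/Q_SOME filter). These sizes were chosen as the
smallest at which the checks are statistically meaningful; the published
cohort-scale results (carrier counts, burden p-values) are functions of the
unavailable patient exomes and are out of reach by construction.

## Known limitations

* Duplications are segmented by the HMM but deliberately unsupported
  downstream.
* The caller's resolution is the target grid; breakpoints within a target
  are not refined.
* The internal-frequency and carrier-count rules depend on the 70% matching
  convention; highly fragmented calls at the same locus can evade matching.
* The per-gene CNV-tolerance comparison consumes fixture-supplied scores;
  no attempt is made to reconstruct the external score tables.
* VQSR, alignment, genotype calling, ancestry and relatedness exclusions are
  upstream concerns consumed as annotations, not reimplemented.
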