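# Methods

This note documents the models, conventions and numerical choices behind
each stage of `isomirflow`, and what the synthetic-data generators do and do
not emulate.

## Sequence handling

All sequences are normalised at ingest to the DNA alphabet (upper case,
U→T), so RNA-style mature/precursor references and DNA sequencing reads
share one alphabet. FASTQ qualities are fixed to Sanger encoding (Phred+33);
no autodetection is attempted. `N` matches no base, including another `N`:
a read containing `N` can never be assigned to a family, which is the
conservative choice and makes classifier counts deterministic.

## Read QC and contaminant screening

Reads are kept iff 16 ≤ length ≤ 35 (inclusive) and the arithmetic mean of
the raw integer Phred scores is ≥ 30 (inclusive). The mean is taken on the
score scale, not on error probabilities, matching the stated "average phred
score" rule. Screening against coding-exon and other-small-RNA references is
exact substring matching on either strand with zero mismatches: no mismatch
tolerance is defined for this step upstream, so the fully specified,
conservative choice is exact matching (the tolerance is configurable in
principle by supplying shorter reference windows). Rules apply in a fixed
order — length → quality → coding exon → other small RNA — so each removed
read has exactly one reason and the filter report is additive.

## isomiR classification

Categories and precedence are described in the README. Conventions worth
recording:

* **Families.** Byte-identical mature sequences are collapsed into one
  family before matching; uniqueness is evaluated over families, so
  duplicate database entries cannot void uniqueness.
* **Precedence.** C1 > C2 > C3 > C4, and within C3: end substitution > end
  addition > internal mismatch. The category is decided before uniqueness: a
  read identical to one family and one substitution away from another is C1
  and uniquely assigned. Families matching only at worse categories do not
  void uniqueness (best-hit semantics, as in standard aligners).
* **Trims and additions across both ends.** C2 allows the 1–5 missing bases
  to be split over both ends, and C3 end addition allows the 1–2 extra bases
  to be split; both are the permissive reading of "either ends".
* **Non-templated additions.** Added bases are arbitrary and are not checked
  against the precursor flanks; templated extensions are the business of C4.
* **Substitutions.** The single allowed difference in C3 must be a definite
  read base (A/C/G/T) differing from the reference base; an `N` at the
  difference position does not qualify.
* **Strand.** Reads are classified sense-strand only; small-RNA libraries
  are stranded.
* **Precursor matches.** C4 requires zero mismatches. A precursor's matches
  are attributed to the family of the mature with the same identifier, so a
  hairpin fragment counts toward its own miRNA's merged total.
* **Multi-mapped reads** are tallied and discarded, never fractionally
  allocated.
* **Ambiguous offsets.** When a trim or addition is consistent with several
  placements (repetitive sequence), the smallest 5' offset is recorded in
  the edit detail; the category and family are unaffected.

The brute-force oracle enumerates, per family, every legal variant string
(all trims to total 5, all single end/internal substitutions over A/C/G/T,
all 1–2-base additions over all base combinations) into per-stage hash
tables and classifies by lookup under the same precedence and uniqueness
rules. It is feasible for miRNA-scale references and is the ground truth for
the equivalence property (10,000 randomized reads in the test suite).

## Differential expression engine

The engine re-implements the classical TMM + conditional-likelihood + exact
NB test workflow from the published formulas rather than wrapping an
existing package, so that every step is inspectable and property-tested.
The test suite nevertheless cross-checks it against the Bioconductor
reference implementation on a small matrix: TMM factors agree to 1e-8 and
exact-test p-values to well under 2 %.

* **Filters.** mRNA: a gene is kept iff CPM ≥ 1 in at least one sample
  (boundary inclusive: "less than 1 CPM" fails only below 1). miRNA: kept
  iff raw count ≥ 5 in at least ⌈n/3⌉ of the n samples pooled over the two
  compared groups; the pooled reading of "1/3rd of samples (treatment vs
  control)" is adopted and the fraction is a parameter.
* **TMM.** Reference sample: upper-quartile CPM closest to the mean
  upper-quartile. Per sample, M = log2 relative-abundance ratio and
  A = mean log2 abundance are computed over features positive in both sample
  and reference; 30 % of each M tail and 5 % of each A tail are trimmed by
  rank; the factor is the inverse-binomial-variance weighted mean of the
  kept M values; factors are rescaled to geometric mean 1. A sample sharing
  no positive features with the reference gets factor 1 with a warning.
* **Quantile adjustment.** Effective library sizes (library × factor) are
  equalised to their geometric mean by mapping each count
  quantile-to-quantile between NB distributions with the current dispersion,
  averaging normal and gamma approximations and computing in the
  numerically favourable tail.
* **Common dispersion (qCML).** The conditional NB log-likelihood given the
  per-group totals of the pseudo-counts (groups with a single sample carry
  no information and are skipped) is maximised over δ = φ/(1+φ) ∈
  (1e-6, 100/101) by bounded search with tolerance 1e-6; the
  adjust-then-maximise cycle runs twice, starting from φ = 0.01. Tagwise or
  trended dispersion is deliberately not implemented: a single common
  dispersion is what the two-group exact test needs and keeps the estimator
  testable. Note that conditioning on group totals is not exactly invariant
  to duplicating the data; the reference implementation shows the same
  ≈ 20 % shrink on a doubled matrix, and the consistency test asserts this
  neighbourhood rather than exact invariance.
* **Exact test.** Group sums of the pseudo-counts (rounded to integers) are
  modelled as NB with means n_g·μ and dispersions φ/n_g; conditional on the
  total z, the two-sided p-value sums the probabilities of all splits whose
  probability is at most the observed split's (tie guard 1+1e-7). Doubling
  of the smaller tail is *not* used. At φ = 0 the conditional distribution
  is Binomial(z, n₁/(n₁+n₂)), which is the closed-form oracle used in tests.
  For z > 10,000 the enumeration is restricted to a ±50-SD window around the
  conditional mean (always containing the observed split); the neglected
  tail mass is far below double precision.
* **Fold changes.** log2 FC uses normalized group means with a prior count
  of 0.125 per sample, so zero-count groups are defined.
* **BH.** Step-up with monotonicity enforcement, capped at 1; p-values must
  lie in (0, 1].
* **Call rules.** miRNA: FDR ≤ 0.15 (inclusive) and |FC| > 1.5 (strict,
  evaluated as |log2FC| > log2 1.5 so the boundary is exact in floating
  point). mRNA: FDR < 0.05 (strict).

## Comparative analyses

* **Chemotype subtraction.** Feature universes are intersected; `shared` =
  DE under both the active compound and its inactive analogue, flagged
  concordant iff the log2 FCs have equal sign; `specific` = active DE minus
  shared. Pure set algebra: idempotent and conserved.
* **Reversal set.** Significance is required in *both* contrasts, with
  strictly opposite log2 FC signs (zero never qualifies). Opposite point
  estimates without significance in both lists do not count; the reversal
  set is an intersection of DE lists.
* **Sample flagging.** Score = mean log2(CPM+1) over the marker features;
  flag iff score > median + k·MAD (MAD scaled by 1.4826, k = 3 by default).
  With identical samples the MAD is 0 and nothing can exceed the median, so
  nothing is flagged. Flagging is advisory: the function never drops
  samples, mirroring a manual-exclusion workflow, because MAD rules at n ≈ 6
  are fragile.
* **Summaries.** Fold-change bins use |log2FC| < 1, 1–2, > 2 (2-fold and
  4-fold boundaries); percentages are computed from their integer
  numerators/denominators and rounded half-away-from-zero to one decimal,
  which reproduces printed-table values exactly.

## ddPCR quantification

λ = −ln(1 − f) per droplet, concentration λ/V with V = 0.85 nL by default —
an instrument-typical droplet volume, declared (not inferred) and
configurable. Replicate wells are averaged on the concentration scale
*before* the target/reference ratio is taken. Group-relative expression
divides by the arithmetic (not geometric) mean of the reference group, so
that group's mean is exactly 1 after the transform. Saturated wells are
rejected; wells under 10,000 droplets warn.

## Survival and motor-function statistics

Kaplan–Meier uses the standard product-limit conventions: all events at a
time t are processed in one risk-step and subjects censored at t remain at
risk at t (daily-resolution data make ties common). The log-rank statistic
is Σw(d₁ − E₁) with hypergeometric variance, w = 1 (Mantel-Cox) or w = total
at risk (Gehan–Breslow–Wilcoxon); p comes from χ² with 1 df, and a
group-label permutation mode exists purely as a verification oracle.
Fisher's exact test is two-sided by ≤-probability summation over the
hypergeometric support (the convention of the commonly used analysis
software), with an accumulated-round-off snap to 1 when every table is as
probable as the observed one; it matches an independent implementation to
1e-9 over exhaustive margin grids. `fisher_power` estimates power by
simulating binomial outcomes per arm and reports a 95 % binomial CI.

## Synthetic data

Generators are pure functions of (parameters, seed); one named stream per
generator is derived from the single seed, so fixtures do not change when
tests are reordered.

* **References.** Mature sequences are drawn pairwise distinct and pairwise
  non-substring (rejection sampling with a bounded retry budget); each
  precursor embeds its mature with 25 random bases of flank on each side and
  shares its identifier. Default mature lengths are 21–24 nt — typical for
  miRNAs and chosen so that a maximal 5-base trim still satisfies the 16-nt
  read-length floor. Screening references are random 300-mers.
* **Reads.** Each class applies exactly its defining edit. Every
  miRNA-derived read is verified against the classifier's own rules and
  resampled (bounded retries) until its call matches its truth label
  uniquely — without this, a randomly trimmed read can coincide with a
  different category or family and the truth table would lie. The
  verification is not circular: the classifier itself is independently
  pinned by the brute-force oracle equivalence property. Junk reads are
  verified unassignable and unscreened. The quality model gives a
  configurable fraction of reads a mean Phred below 30 (default 5 %), and a
  fraction of *junk* reads a length outside 16–35 (default 5 %); length
  outliers live in the unassignable class because the miRNA-derived classes
  have edit-determined lengths.
* **Counts.** Per-feature baseline abundances are log-normal (σ = 1.5),
  normalised to sum to 1; library sizes are log-uniform over 0.5–2 M
  (mRNA-like defaults; deep enough to be realistic, small enough for fast
  tests). Genotype and treatment effects are additive on the log2 scale,
  spiked independently per contrast with random sign and fixed magnitude.
  Counts are gamma-Poisson draws, which are exactly NB and remain correct in
  the dispersion → 0 limit.
* **Survival.** Exponential event times per group with fixed-time
  administrative censoring at the study end.
* **Droplets.** Each droplet is positive with probability 1 − e^(−λ).

What the generators do **not** emulate: sequencing-error profiles (adapter
read-through, homopolymer errors), UMIs, positional quality decay, GC or
length biases in counting, correlated library composition, informative
censoring, or droplet volume variation. Passing tests therefore demonstrate
the correctness of the algorithms under their stated models, not robustness
to every artefact of real instruments.

## Problem sizes

The test suite and the acceptance script use 10,000 reads × 20 families for
the oracle-equivalence check, 50,000 reads × 40 families for end-to-end
count recovery, 2,000-feature matrices at 4 v 4 or 6 v 6 for DE calibration,
20,000 droplets per ddPCR well, and cohorts of ~20 animals per arm for the
survival statistics — sizes representative of the target experiments while
keeping a full run to seconds.
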