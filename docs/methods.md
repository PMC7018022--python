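# Methods

`codonstab` implements a pipeline connecting coding-sequence composition to
mRNA decay in mammalian cells: per-transcript codon/amino-acid frequencies,
stability coefficients against half-life tables, tRNA-seq-based codon
optimality, metabolic-labeling half-life estimation, synonymous reporter
design, and the downstream association models. This note documents the models,
conventions, defaults, and the limits of what the synthetic validation shows.

## Composition statistics

Codonization is non-overlapping (width 3, step 3); frames +1/+2 skip one/two
leading nucleotides; a trailing partial codon is dropped. Codon frequencies
are fractions over counted codons, with stop codons and N-containing triplets
excluded from numerator *and* denominator, so every profile lives on the same
61-codon simplex and profiles are comparable across transcripts regardless of
N content. The initiator ATG is included in the denominator. Translation uses
the standard genetic code; internal stops are retained as `*` (translation is
not aborted, so frameshifted translations remain well defined) and any
N-containing codon maps to `X`. Amino-acid frequencies exclude `*` entirely
and track `X` as a separate fraction; the 20 canonical frequencies plus the
`X` fraction sum to 1.

GC content is (G+C)/(A+C+G+T) over the whole ORF; GC3 is the fraction of
frame-0 *sense* codons whose third (wobble) base is G or C — stop codons are
excluded so the GC3 universe matches the 61-codon universe used everywhere
else.

FASTA reading keeps, per identifier, the longest sequence (ties broken by the
lexicographically smallest sequence, for deterministic output) and optionally
drops records not starting with ATG, reporting the dropped count. Homopolymer
detection returns all maximal runs of at least 5 identical residues with
1-based inclusive coordinates; a reducer keeps the longest run per gene and
amino acid (ties keep the first occurrence).

## tRNA adaptation index (tAI)

Per-gene tRNA-seq read counts are aggregated by anticodon after excluding
selenocysteine and initiator-methionine genes (matched by substring on the
gene identifier) and converted to reads per million. Each codon's weight is

    W(c) = sum over decoding anticodons a of (1 - s[pairing]) * RPM(a)
    tAI(c) = W(c) / max W

with the classical selective-constraint wobble penalties: G:U 0.41, I:C 0.28,
I:A 0.9999, U:G 0.68 (anticodons with genomic A34 are treated as
inosine-modified). ATG and TGG are decoded only by their Watson–Crick
anticodons: the generic wobble rule would credit Ile-TAT reads to ATG, which
no elongator tRNA does. The penalty table is a plain mapping and fully
overridable, so alternative wobble conventions are reproducible.

Isodecoder aggregation happens by anticodon after per-gene counting; because
W is linear in the aggregated RPMs, splitting or pooling isodecoder genes
does not change the result (asserted in tests), and the whole table is
invariant to sequencing depth.

A codon is **optimal** when its tAI is *strictly greater* than the median of
the 61 values; a codon exactly at the median is non-optimal. Percent-optimal
of an ORF is 100 × optimal sense codons / total sense codons.

## Reporter design by synonymous flipping

Variable-optimality reporters are designed by flipping synonymous codons
across the optimality boundary rather than re-encoding from scratch, which
maximizes sequence similarity between variants. Candidate positions (codons
whose amino acid has synonyms on the needed side of the median) are shuffled
once with the seeded generator and consumed until the realized percent
crosses the target; the walk stops on whichever side of the target is nearer,
so the result is within one codon of the request. Replacement synonyms are
drawn uniformly from the desired side; non-flipped codons are never altered,
and the translation is asserted unchanged. Amino acids whose synonyms are all
on one side (including single-codon Met and Trp) bound the feasible range;
requests outside it raise an error reporting the theoretical min/max.

## Stability coefficients (CSC / AASC)

The codon stability coefficient is the Pearson correlation, across
transcripts, between a codon's frequency and half-life; the amino-acid
analogue (AASC) uses amino-acid frequencies. Joins between profiles and
half-life tables are inner joins on transcript id with the attrition count
logged — silent mismatch is the most common reproduction bug. Each
coefficient carries a two-sided p-value and a 95% confidence interval from
the Fisher z-transform (z = atanh r, se = 1/sqrt(n-3)); the CI method on the
Pearson estimate is a package convention chosen for reproducibility.
Significance tiers: stabilizing/destabilizing at p < 0.01 for codons and
p < 0.001 for amino acids by default (both configurable), plus a genome-wide
flag at p < 5e-8. A covariate with zero variance yields an NA coefficient,
never a silent zero.

Transcript-level scores are frequency-weighted sums of the coefficients over
a transcript's frame-0 profile. NA coefficients are excluded with the
remaining weights renormalized (rather than treated as zero), so transcripts
rich in NA-coefficient codons are not biased toward 0; the number of excluded
nonzero-weight terms is reported.

The *extreme* amino-acid partition is |AASC| > 0.10 with p < 1e-30; codons
inherit their amino acid's class. The exclusive-amino-acid summary counts
multi-codon amino acids whose synonymous CSCs all share a strict sign; any NA
or exactly-zero CSC disqualifies the family.

## Half-life estimation from decay timecourses

The timecourse model assumes constant spike-in amounts per sample: the
per-timepoint factor is mean(spike-in reads)/total reads, expressed relative
to t0, and each column is divided by it, undoing the apparent amplification
from the shrinking mRNA pool late in the chase. Rows are then rescaled to 100
at t0; transcripts with raw t0 FPKM < 1 are flagged and skipped rather than
aborting the run.

Decay is fitted per transcript as

    y(t) = 100 * exp(-(k + ln2/Td) * t),   k >= 0

minimizing the sum of absolute deviations (LAD). The ln2/Td term removes the
apparent decay contributed by growth dilution (doubling time Td, default
15 h; Td = inf disables it). Conventions, each configurable or at least
explicit:

* the fit is in **linear abundance space** on the percent-remaining scale —
  a log-space LAD would be a different estimator;
* the intercept is pinned at y(0) = 100 (the t0 point contributes a zero
  residual and is included in n for the mean absolute residual, so residual
  thresholds are comparable across transcripts);
* optimization is a deterministic 200-point grid on k in [0, 10·ln2] h⁻¹
  (0 plus log-spaced points) followed by bounded scalar refinement between
  the grid optimum's neighbors — reproducible without a stochastic optimizer,
  and within 1e-6 h of truth on noiseless input;
* a boundary solution k = 0 (no decay beyond dilution) is flagged
  non-decaying with infinite half-life;
* fewer than 4 finite timepoints flags the transcript unfit.

Filters retain half-life ≤ 18 h and mean absolute residual ≤ 20. The residual
threshold is interpreted on the t0 = 100 percent-remaining scale — the only
scale on which 20 is a sensible magnitude; both cutoffs are parameters. A
rejection report counts each reason separately.

For gene-group analyses, very stable transcripts that pass depth filters but
fail decay fitting can be assigned a ceiling half-life (default 24 h) by an
explicit imputation helper, so the stable tail (e.g. cytoplasmic ribosomal
proteins) is not silently missing.

## Association statistics

* **GC3 vs optimality**: two-sided Fisher exact test on the 2×2 table of the
  61 codons (GC3/AT3 × optimal/non-optimal); tests cross-check the p-value
  against full hypergeometric enumeration.
* **Half-life model**: half-lives are mapped through −1/x (monotone,
  all-negative), the transform that symmetrizes a right-skewed half-life
  distribution; OLS of the transformed values on transcript average CSC and
  GC3 frequency reports per-term β, 95% CI, p, adjusted R², and the overall
  F-test p. Constant or collinear regressors raise an error naming the term.
* **Codon-level CSC model**: OLS of CSC on tAI and relative free amino-acid
  concentration, with each codon carrying its amino acid's concentration.
  Cys and Glu codons are excluded (assay NA/outlier status for those free
  amino-acid measurements), giving 57 rows for all codons and 38/19 for the
  moderate/extreme partitions when the extreme set has six amino acids.
  Repeated use of one amino acid's concentration across synonymous codons
  violates strict independence; the model is reported as printed, with that
  caveat.
* **Stratification**: half-lives binned by a covariate (default: fixed-width
  bins over its observed range, edges configurable) with per-bin n/median/
  quartiles and a Kruskal–Wallis omnibus test.
* **Group comparisons**: two-sided Wilcoxon rank-sum; exact enumeration for
  tie-free groups up to n = 20 per side, tie-corrected normal approximation
  otherwise. All tests are two-sided at the 95% level unless a caller
  overrides a threshold.

## Synthetic data and what it does (not) show

The generator emulates the statistical structure the analysis assumes, not
real biology:

* **Transcriptome**: ATG-initiated ORFs of lognormal length (default median
  350 codons, σ = 0.45, minimum 30), codons drawn i.i.d. from per-transcript
  compositions sampled from a symmetric Dirichlet (default concentration 2.0,
  giving realistic between-transcript usage variability). Only sense codons
  are drawn, so internal stops are absent by construction.
* **Half-lives**: log half-life = planted linear effects of observed codon
  and amino-acid frequencies + N(0, σ = 0.3), scaled to a median of 4 h —
  positive and right-skewed by construction. The log-linear form is an
  artifact choice: the simplest generative model under which CSC sign
  recovery is well defined.
* **Timecourse**: 10 timepoints over a 12 h chase (0, 0.5, 1, 2, 3, 4, 6, 8,
  10, 12 h), 15 h doubling time, lognormal spike-factor distortion (σ = 0.2)
  applied inversely so normalization can undo it exactly, multiplicative
  lognormal measurement noise (σ = 0.1) applied last.
* **tRNA counts**: anticodon abundances reproducing a requested tAI vector
  are solved by nonnegative least squares under the wobble model (vectors
  with no nonnegative solution raise a feasibility error); counts are drawn
  multinomially and split across two isodecoder genes per anticodon, with
  Sec/iMet decoy genes included to exercise the exclusion path.

All streams derive from a single seed via NumPy's PCG64
(`default_rng([seed, stream])` with a fixed stream id per generator), so
fixtures are byte-reproducible.

What passing tests show: the estimators are numerically correct (agreement
with independent oracles), unbiased enough to recover planted effects at
realistic noise (CSC signs at n = 2,000; median half-life error < 10% at
σ = 0.1), and the pipeline's plumbing (normalization, joins, filters,
partitions) is exact. What they do not show: performance under real codon
usage and GC isochore structure, correlated measurement noise, isoform
ambiguity, or tRNA modification biases — none of which the generator
attempts to mimic.

## Problem sizes

Defaults used by the test suite and the acceptance script: 2,000 transcripts
for planted-effect recovery and the transcript-level model, 500 noisy
trajectories for half-life recovery, and 10⁷ reads for the tRNA round trip.
The infinite-depth tAI limit is checked exactly by feeding the solved
anticodon abundances directly as counts, since multinomial noise at any
finite depth dominates a 1e-6 tolerance.

## Known limitations

* Wobble penalties are a convention, not a measurement; published tAI vectors
  built with different penalties or modification-aware weighting will differ.
* The LAD fit assumes a single exponential with a pinned intercept; biphasic
  decay or labeling chase-in artifacts at early timepoints are not modeled
  (a free-amplitude option exists on the fitting routine).
* The extreme/moderate partition thresholds (0.10, 1e-30) are sharp cutoffs
  on continuous quantities; borderline amino acids flip class under
  resampling.
* One printed reference result for the codon-level model (the extreme-subset
  intercept's CI in the literature this pipeline reproduces) is inconsistent
  with its own point estimate — an apparent sign typo; this implementation
  reports its computed CI.
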