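# Methods

## Scientific model

Elements of extreme C+G content (roughly >= 70% over >= 500 bp) can fail to
denature under standard melting conditions. An un-melted element tethers its
melted flanks, which re-anneal by zero-order kinetics as soon as
non-denaturing conditions return, blocking primer and probe access
throughout the surrounding domain. Two observable consequences are modelled:

1. **Array intensity suppression.** The expected log R ratio (LRR) of a
   probe at distance `d` (bp) from the nearest intact element carries a
   deficit `A * exp(-rho * d)` for `d <= D_max`. The exponential arises from
   the physics of tethering: if single-strand nicks occur as a Poisson
   process with density `rho` per bp, `exp(-rho d)` is the probability that
   no nick separates the probe target from the element. `A` (LRR units) is
   the deficit of a fully tethered probe; `rho` encodes sample quality
   (intact DNA: small `rho`, strong suppression — degraded DNA: large `rho`,
   little suppression).
2. **PRT ratio suppression.** A paralogue ratio test co-amplifying a test
   amplicon (distance `d` from an element) and an unaffected reference
   yields `ratio = R_eq * (1 - min(A, 1) * exp(-rho * d))`, where `R_eq` is
   the equal-efficiency ratio (1.43 for the classical chromosome-2 design,
   treated strictly as an input constant). Physical separation
   (`d -> infinity`) restores `R_eq`.

Sample-level GC *waves* — smooth intensity fluctuations correlated with
regional GC/CpG content at many scales, of sample-specific sign and
amplitude — are superimposed on this mechanism and are what the wave
correction removes.

## Wave correction

Per sample, after quantile normalization across the cohort (reference =
mean of sorted sample vectors; ties receive the average of the reference
values they span), LRR is regressed by OLS on:

- centered polynomial terms `(x_w - mean x_w)^p`, `p = 1..degree`, for each
  window size `w` and each metric (GC fraction, CpG dinucleotide fraction);
- chip-stratum indicator offsets (first stratum as reference), standing in
  for within-chip signal re-scaling;
- an intercept.

Defaults: degree 2 (waves are smooth and low-order; configurable), window
list {50, 100, 500, 1k, 10k, 50k, 100k, 250k, 1M} bp. Covariates are
centered before polynomial expansion to limit collinearity. Rank-deficient
designs are handled by dropping aliased columns (greedy rank-preserving
scan, warned and recorded). The model is estimated per sample because the
wave phenotype is sample-specific. The fit itself is delegated to
statsmodels OLS; an independent normal-equations oracle checks it in the
tests to 1e-10.

Corrected LRR = residual + the sample's pre-correction mean, so corrected
variance never exceeds the input variance. Extreme samples are labelled by
the maximum-|Z| GC term (any window) against a threshold of |Z| > 30; the
selector is configurable since no single canonical term is privileged.
A minimum of `n_terms + 2` probes is enforced as a hard error, with an
advisory warning below 10 probes per term.

Window content conventions: a window of size `w` centered at 1-based
position `c` spans `c - (w-1)//2 .. c + w//2`; windows overhanging a contig
end are clipped and the effective length used as denominator (keeps the
manifest row count stable); ambiguous bases are excluded from numerator and
denominator (unbiased under masking); the CpG denominator is the number of
valid dinucleotide slots (effective length - 1 when nothing is masked).
All user-facing coordinates are 1-based fully closed; BED I/O converts
losslessly to 0-based half-open.

## High-GC element discovery

No canonical detection procedure exists for these elements, so the finder
is deliberately simple: windows of `min_length` (default 500 bp) are scored
every `step` (50 bp); windows with GC >= `min_gc` (0.70) merge into maximal
runs; boundaries are trimmed to the outermost G/C base and greedily extended
through contiguous G/C. Elements closer than one step merge naturally
because their qualifying windows overlap. A reported element's recomputed
GC may fall below `min_gc` by at most `step/min_length`. The 0.70/500 bp
defaults are calibrated so that an 1100 bp, 73%-GC element — the scale of
the classical restriction-mapping example — is detected with boundaries
within one step.

## Nick-rate estimation

Per-probe suppression `delta_i` (baseline median of unsusceptible probes
minus corrected LRR) is reduced to 10 equal-count distance-bin means
(fewer distinct distances fall back to exact grouping), then
`A * exp(-rho d)` is fitted by bounded trust-region least squares
(scipy `curve_fit`), initialized from a log-linear regression on the
positive bins. Binning stabilises the heavy noise of single probes; exactly
zero suppression short-circuits to `A = 0` with an undefined-rate flag.

## Association analysis

For each (metric, window) the per-sample statistic is that content term's
degree-1 Z score (signed variance-explained available as an alternative);
it is correlated against per-sample PRT ratios with Pearson (t
approximation) and Spearman p-values reported side by side, rows ordered
from the largest window down. Spearman uses exact permutation enumeration
for n <= 8 (all n! rank permutations scored in one matrix product) because
the t approximation can deviate by up to ~0.08 at n = 5; a Monte-Carlo
permutation test is also available. Raw p-values are reported without
multiple-testing correction, matching the classical presentation.

## Fragmentation advice

For a target amplicon and its nearest high-GC element, an in-silico digest
marks an enzyme *separating* when at least one cut falls strictly between
the proximal boundaries and no cut lands inside the target; a cut inside
the target is a distinct "assay destroyed" verdict. This rule is provably
equivalent to assembling fragments from the cut positions and testing
co-membership, and the tests verify that equivalence on random instances.
Predicted ratios: `R_eq` when separated, the suppression law otherwise.
Sonication to mean fragment `L` retains linkage with probability
`exp(-d/L)`, giving the expected ratio
`R_eq (1 - min(A,1) exp(-rho d) exp(-d/L))`. Only the nearest element is
considered (multi-element suppression is capped at 1 in total); coordinates
are linear — circular molecules are unsupported. Restriction matching is
forward-strand only; the common type II enzymes are palindromic, for which
this is exhaustive.

## Synthetic cohort generator

The generator emulates the study conditions end to end with full ground
truth: an i.i.d. background genome (40% GC) with planted i.i.d. high-GC
elements (six of 1100 bp at 73% GC per 2 Mb by default), probes every
500 bp, and 54 samples split 24 extreme-positive / 19 extreme-negative / 11
null. Positive and negative classes carry GC waves of opposite sign at the
100 bp window (default coefficients 4.0 for degrees 1 and 2, calibrated so
an affected sample's extreme Z is ~60, i.e. twice the classification
threshold). Nick rates: 1e-4/bp for the positive class (intact DNA, fully
TUF-vulnerable) and 2e-3/bp for negative and null samples — the
negative-wave phenotype models a non-TUF, concentration-type artifact on
ordinary-quality DNA, which is what makes the wave statistic monotone with
PRT performance. Suppression amplitude 0.6 LRR units (a free parameter: no
published value exists on the LRR scale), `D_max` 50 kb, homoscedastic
Gaussian noise (sd 0.1), four chip strata with offsets ~ N(0, 0.05), PRT
test-element distance 1 kb, `R_eq` 1.43 with readout noise sd 0.05.

Fragmentation acts on the truth: sonication draws Poisson breakpoints at
rate 1/mean_fragment; digestion breaks deterministically at cut sites; any
break strictly between a probe and its nearest element boundary sets that
probe's distance to infinity.

What the generator does *not* emulate: genotype-cluster structure and
B-allele frequencies, heteroscedastic or heavy-tailed intensity noise,
repeat structure and realistic GC autocorrelation of real genomes,
melting-curve thermodynamics, and WGA branching kinetics. Passing tests
therefore demonstrate correctness of the estimators under the stated
mechanism, not performance on real arrays.

## Numerical and reproducibility choices

- Content queries use integer prefix sums per contig, exactly equal to
  substring counting (verified against a brute-force oracle), making 1 Mb
  windows as cheap as 50 bp ones.
- One global seed fans out to per-stage streams via
  `numpy.random.SeedSequence.spawn`; identical config + seed reproduce
  byte-identical pipeline outputs (checksummed in the run manifest).
- Variances are sample variances (ddof 1); the pre/post ratio is invariant
  to that choice because the model nests the intercept.
- Copy-number inference is a single LRR threshold (default -0.3, a free
  parameter: no published LRR value corresponds to the weak-signal level);
  weak regions are maximal runs of >= 5 probes where >= 50% of affected
  samples call CN 1.
- Test and acceptance experiments run at reduced scale chosen to keep the
  statistics meaningful: a fixed 1 Mb / 5000-probe design with cohorts
  redrawn per seed for recovery experiments (as on a real array, the design
  is fixed across samples), 800 kb / 2000 probes x 54 samples x 20 seeds
  for the association study, and 2000 replicates for type-I calibration.

## Known limitations

- The window-scale term set is treated as fully configurable; no canonical
  eight- or nine-window list is privileged beyond the default.
- The suppression amplitude, D_max and the CN-1 threshold are free
  parameters documented above, not published constants.
- Distances are measured to element boundaries, not centers, on the
  rationale that suppression propagates outward from the anchored duplex.
- The advisor assumes the reference locus of a PRT is unaffected by the
  treatments.
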