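# Methods

`rhythmdiff` implements a differential-rhythmicity analysis for
around-the-clock expression profiles of two conditions (e.g. two
genotypes within one sex): per-condition rhythm detection, a per-gene
between-condition rhythm test, a five-category decision table, circular
summaries of peak phases, and a ground-truthed simulator of the whole
design. This note records the models, the numerical choices, and what
the synthetic data can and cannot demonstrate.

## Rank-based rhythm detection

Each gene's profile is compared against cosine reference waveforms by
Kendall correlation, in the JTK_CYCLE family of tests.

**Period grid.** Candidate periods are the integer multiples of the
sampling interval inside a 20–28 h window; with 3 h sampling this gives
{21, 24, 27} h. Lags step at the sampling interval across one period
(7 + 8 + 9 = 24 waveforms for the default design).

**Statistic.** For a reference waveform the cosine values at the sample
times are rounded to 10 decimal places and converted to tie-grouped
ranks. Kendall's S is the number of concordant minus discordant pairs;
pairs tied in the reference are excluded and pairs tied in the data
contribute zero. τ normalises S by the maximum attainable given the
reference's tie structure.

**Exact null.** Under exchangeability of tie-free data the distribution
of S against a tied reference follows from the inversion-generating
function of multiset permutations: the convolution of Gaussian-binomial
(q-binomial) polynomials, one per tie group, computed in exact integer
arithmetic (Harding-style). Tail tables are cached per tie structure.
Tests verify agreement with exhaustive enumeration of all n!
orderings to 1e-12. Beyond n = 25 a normal approximation with the
standard tie-corrected variance and a continuity correction is used
(never reached by the default design).

**Selection and multiplicity.** For each waveform the one-sided
upper-tail p of S ranks the alternatives (this keeps a peak distinct
from its antiphase trough); the reported p is the exact two-sided tail
at the best waveform, and the within-gene `adj_p` is Bonferroni over
the full set of tested (period × lag) waveforms — the convention of the
original JTK ADJ.P. `bonferroni_periods` (×3) and `none` are available
as config options. A Benjamini–Hochberg q across genes (`q_bh`) is also
emitted; the classifier consumes `adj_p` by default and the column is
configurable, since published "adjP" criteria are ambiguous between the
two.

**Concatenation.** By default each single-cycle series is duplicated to
a 48 h two-cycle series before rank testing, which sharply reduces the
rank test's false negatives on 8-point profiles. Duplicated data
violate the exchangeability the exact null assumes, so the empirical
false-positive rate at adjP < 0.05 on arrhythmic profiles is inflated
(~0.13 measured by `scripts/acceptance.py`, versus ~0.01 without
concatenation). This trade — fewer false negatives at the cost of a
permissive rhythm call — is intentional and mirrors how two-cycle
duplication is used in practice; the classification step compensates by
requiring concordant evidence from several statistics. The no-concat
analysis is one switch away and yields proportional category counts.

**Constant series** carry no ordering information: p = adj_p = 1, phase
undefined, flagged in a warning channel.

**Lomb–Scargle (optional).** A floating-mean harmonic periodogram on
the same period grid: the normalised power is the cosinor R², whose
null tail for Gaussian noise is exactly (1 − z)^((n−3)/2); the minimum
over periods is Šidák-corrected. Fisher's method can combine it with
the rank-test p for a meta2d-style ensemble. It is off by default and
not used by the classifier.

## Between-condition comparison

Each gene is fit with a fixed-period (24 h) cosinor
y = M + a·cos(ωt) + b·sin(ωt). The null hypothesis is equality of
(a, b) across conditions — rhythm shape, not expression level; mesor
differences are excluded from H0 by default (`include_mesor` adds
them). Two tests are computed:

- **Parametric:** nested-model F-test with condition-specific
  intercepts and shared error variance (2 numerator df).
- **Robust:** Huber M-estimation (tuning constant 1.345, ≤ 50 IRLS
  iterations, tolerance 1e-8) of the stacked model with
  difference-coded harmonic columns; Wald χ²₂ on the two difference
  coefficients with the robust covariance. Degenerate scale
  (near-perfect fits) or non-convergence falls back to the parametric
  p, flagged.

The two p-values are Fisher-combined into `meta_p`. This plays the role
of a published differential-rhythmicity meta p but is an explicit
approximation assembled from standard components, not a re-derivation
of any specific package's internals. The comparison runs on the
single-cycle series: duplicated residuals would destroy the F-test's
exact null, and the comparison has no false-negative problem that
concatenation would fix (a config option enables it regardless).
Type-I error at α = 0.05 is calibrated to within Monte-Carlo error
under the simulator's pooled log-normal noise.

## Classification

The decision table uses four statistics per gene — rhythm adjP in the
test condition (group 1, e.g. knockout) and in the reference (group 2),
`meta_p`, and the circular phase difference of the two rank-test peak
lags — with thresholds 0.05 / 0.1 / 0.01 / 6 h. All inequalities are
strict: adjP = 0.05 exactly, or Δφ = 6.0 h exactly, match no rhythmic
rule. Rules are evaluated in order, first match wins, and a terminal
`unclassified` catch-all guarantees that categories partition the gene
list (the printed criteria are not exhaustive: both conditions
arrhythmic, or both adjP in (0.05, 0.1], fall through).

Two orientations of the meta-p inequalities are shipped because the
published criteria admit two readings: `as_printed` reproduces the
table verbatim ("unchanged" ⇒ meta p < 0.01, change categories ⇒
meta p > 0.01), while `difference_consistent` flips those four rows so
that categories asserting a difference require a small meta p. The
pipeline defaults to `difference_consistent`, the orientation implied
by a difference-detecting null; the truth-table tests cover both. The
gained/lost rows carry no phase predicate (one condition has no defined
peak), and the asymmetric thresholds are applied exactly as printed,
including the lost row where the strict 0.05 sits on the reference
group.

## Circular statistics

Phases enter in ZT hours and are converted to angles θ = 2πφ/24. The
mean vector gives the population peak time and resultant length R;
uniformity is tested with the Rayleigh statistic Z = nR² and the
classical second-order series tail. The 95% CI of the mean direction is
the large-sample dispersion-based interval, half-width
asin(z₀.₉₇₅·√(δ̂/n)) with δ̂ = (1 − ρ̂₂)/(2R²); simulation shows 95% ± 2%
coverage at κ = 4, n = 200, and the expected √n width scaling. Samples
too dispersed for the asin argument are flagged rather than given a
fake interval. Histograms use half-open bins partitioning [0, 24).

Rhythmic-gene enrichment against a fixed background expectation
(default 16%, the mouse-liver circadian-database convention) uses the
exact binomial two-sided test with the minimum-likelihood convention;
an explicit background set (K of N) switches to a 2×2 Fisher exact
test. The choice matters at the margins: for k = 0 the minlike p
exceeds the pure lower tail (1 − rate)^n because improbable upper-tail
outcomes are included.

## Synthetic data

The simulator emulates a pooled around-the-clock liver RNA-seq design:
8 timepoints at 3 h spacing over one 12:12 LD cycle, two conditions,
one pooled sample per condition × timepoint averaging 3 independent
noisy animal profiles (equal-mass RNA pooling ≈ averaging).

**Waveform** is a single-harmonic cosine with multiplicative relative
amplitude, m·(1 + A·cos(2π(t − φ)/24)); A ∈ [0, 1] keeps abundances
non-negative and the peak/trough ratio is (1 + A)/(1 − A). A cosine
matches the detector's reference family, which makes recovery tests
well-posed.

**Defaults (the simulated study conditions).** Category mix 60%
arrhythmic / 20% rhythmic-unchanged / 10% phase-shifted (exact 12 h
flips) / 7% gained in the test condition / 3% lost; relative amplitude
0.5; per-animal CV 0.10; mesor log-uniform between 10 and 1000
(FPKM-like); reference-condition peak phases von Mises around ZT20.5
with κ = 2 (the night-peaking wild-type population), gained-rhythm
phases von Mises around ZT6 with κ = 4 (strong mid-day clustering);
"other difference" keeps the phase and drops the amplitude to 0.2.
Counts per category are exact by largest-remainder rounding.

**Noise.** Log-normal mode multiplies the profile by a mean-preserving
log-normal with the given CV (pool = arithmetic mean of the animal
draws; CV → 0 reproduces the noiseless profile exactly). The
negative-binomial mode draws the pooled library directly as an
integer-valued NB with mean equal to the profile and dispersion divided
by the pool size; it exists because whether pooled-then-sequenced
samples behave as means of abundances or of counts is not knowable from
the design, and both behaviours are provided.

**Reproducibility.** One master seed; each gene's parameters and noise
come from a dedicated `SeedSequence((seed, stream, gene_index))`
substream, so enlarging a simulation leaves the RNG streams of existing
genes untouched. (The category *layout* of a prefix can still change,
because per-category counts are re-rounded for the new total.)

**What passing tests do and do not show.** The simulator shares the
detector's waveform family, uses independent noise across timepoints,
and programs clean effect categories. Real data have non-sinusoidal
shapes, autocorrelated and heteroskedastic noise, partial effects, and
library-level artefacts; recovery rates measured here (sensitivity
≥ 0.8, specificity ≥ 0.9 per category at amplitude 0.5 and CV 10%) are
an upper bound on what comparable real data would give, and the type-I
calibration of the comparison holds exactly only under the simulator's
noise.

## Pipeline conventions

Stage order: (simulate | read) → optional low-count filter → per-group
detection → comparison → classification → circular summaries. The
low-count filter drops genes whose raw-count sum across the timepoints
of all groups combined is strictly below 100 (a sum of exactly 100 is
retained); a per-group reading is available as an option. The
2^-ΔΔCt helper implements relative qPCR quantification against a
reference gene and calibrator condition. All tabular I/O is TSV with
`<GROUP>_ZT<hh>` sample columns; floats are written with `%.10g` so
reruns are byte-identical, and the manifest records the config echo
(every effective parameter), seed, version, per-stage gene counts, and
a SHA-256 per output file.

## Problem sizes used by the test suite and acceptance script

Simulation-based checks use 2000 genes for end-to-end recovery, 5000
replicates for type-I calibration, and exhaustive enumeration up to
n = 6 (720 permutations) for the exact-null oracle; these sizes give
Monte-Carlo standard errors comfortably below the tolerances they are
checked against while keeping a full run in tens of seconds.

## Known limitations

- Fixed 24 h period in the comparison; per-gene fitted periods are out
  of scope, and lags are reported modulo 24 h even when the best rank
  period is 21 or 27 h.
- The rank test's amplitude estimate is a crude half peak-to-trough
  range, emitted for convenience and excluded from any quantitative
  claim.
- No multi-way (> 2 group) classification; the 2 × 2 genotype × sex
  design is analysed as separate pairwise comparisons.
- The exact null assumes tie-free data; concatenation deliberately
  violates this (see above) and genuinely tied data make the test
  conservative.
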