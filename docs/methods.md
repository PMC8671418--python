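# Methods

This note documents the models, estimators and numerical conventions
implemented in `circamark`, the design choices made where several
conventions were defensible, and what the synthetic-data generator does and
does not emulate.

## Rest–activity segmentation and indices

### Hidden Markov model

Activity counts are log1p-transformed and modelled as a homogeneous 3-state
Gaussian HMM (states IA < MA < HA, ordered by emission mean after fitting).
Estimation is Baum–Welch EM (via `hmmlearn`) with up to 500 iterations and a
log-likelihood tolerance of 1e-4; `n_restarts` runs (default 10) are started
from the 10%/50%/90% count quantiles — the first unperturbed, the rest with
seeded Gaussian jitter — and the best log-likelihood is kept. Quantile
initialisation makes the IA/MA/HA basin the typical attractor, so a handful
of restarts suffices in practice.

Two numerical guards matter:

* **Emission-variance floor** (0.01 on the log1p scale, configurable).
  Integer counts put a point mass at exactly zero during rest; without a
  floor, maximum likelihood prefers a degenerate solution with one state
  collapsed onto that spike (and MA/HA merged). The floor is far below any
  realistic emission variance, so it is inactive except in that degenerate
  regime.
* **Degenerate-input rejection.** Series with fewer than three distinct
  transformed levels (e.g. constant zero) cannot identify three states and
  are rejected with an error rather than fitted. Non-convergence of the
  winning run is reported through `HmmModel.converged` plus a warning.

Transitions are homogeneous; p₁₋₁ is the single IA self-transition
probability of the fitted matrix. A time-inhomogeneous (harmonically
modulated) transition model would refine this but is not implemented; the
indices below capture the clock-time structure through the posterior
profile instead.

### Fingerprint and derived indices

Forward–backward posterior state probabilities are averaged within
clock-time bins (10 min by default) across all recorded days, giving a 24-h
"fingerprint" whose rows sum to one. From the IA profile P_IA(t):

* rest duration a = ∫₀²⁴ P_IA(t) dt (hours);
* centre of rest c = circular mean clock time weighted by P_IA;
* Rhythm Index RI = (W − a²/24)/(a − a²/24), clipped to [0, 1] and reported
  in percent, where W is the P_IA mass inside the a-hour window centred at
  c (computed with exact fractional bin coverage on the circle). RI is
  100% for a square-wave profile (regular bedtimes, uninterrupted rest) and
  0% for a flat profile; a flat profile has no defined centre, and RI is
  set to 0 in that case by the limit law. RI is undefined (missing) when
  a = 0 or a = 24.

The dichotomy index I<O pools all epochs of the recording: the out-of-bed
median is computed once, and I<O is the percentage of in-bed epochs
(diary-defined, strict `<`) below it. Pooling, rather than averaging
per-day values, uses all epochs symmetrically and is stable for short
recordings; because only ranks matter, I<O is invariant to monotone
transforms of the counts. r24 is the Pearson autocorrelation at a lag of
24 h using all overlapping pairs (≥ 48 h of data required; undefined for a
constant series).

### Dominant period

The point estimate is the peak, in a 16–32 h band, of a Hann-windowed
periodogram zero-padded 32× and lightly smoothed (3-bin moving average),
with parabolic interpolation of the peak on the frequency grid; for a
5-day, 1-min recording this resolves a sinusoid's period to well under half
an hour. The confidence interval resamples whole recording days with
replacement (default 100 resamples) and takes the 2.5th/97.5th percentiles
of the resampled peaks. Day-block resampling preserves within-day structure
while perturbing day-to-day composition; for noise-dominated series the
interval is correspondingly wide, which is the diagnostic purpose.

## Cosinor rhythmometry

The fixed-period two-component model (periods 12 h and 24 h) is fitted to
natural-log concentrations. With fixed periods the model is linear in
(cos, sin) pairs, so the fit is one OLS solve — exact, convex, and free of
starting-value issues; amplitudes and acrophases are recovered by
A = √(β_c² + β_s²), θ = atan2(−β_s, β_c). Samples at the same clock time on
consecutive days enter at t and t + 24 h; the model is 24-h periodic, so
they act as replicates and day effects are absorbed in the error.

Reporting back-transforms to the measurement scale: mesor = exp(M), overall
amplitude = half the range of the exponentiated fitted curve on a 1-min
clock grid, relative amplitude = overall amplitude / mesor (a fraction),
and overall acrophase = clock time of the curve maximum (earliest tie).
This convention keeps mesor and amplitude mutually consistent on the
reported scale.

**Rhythm detection.** A component is rhythmic when its amplitude differs
from zero at α = 0.1 (liberal by design for ~10-sample series); a series is
rhythmic when either component is. The test is the classical cosinor
zero-amplitude test: A = 0 iff the component's cos and sin coefficients
both vanish, so the test is F(2, n−5) on that pair. A t statistic built on
the non-negative amplitude estimate is not used for the decision because
the acrophase is unidentified at A = 0, which inflates the small-sample
type-I error well above nominal (≈ 0.19 at n = 10 in simulation, versus
0.10 for the F form); delta-method standard errors are still reported for
interpretation. Degrees of freedom are n − 5 (five mean parameters). An
exact fit (residual variance at roundoff level) short-circuits the test:
zero amplitudes get p = 1, nonzero ones p = 0.

Eligibility: at least seven valid (finite, strictly positive) timed samples
spanning ≥ 24 h; non-positive concentrations are an error on the log scale.
Designs that do not identify all five parameters (e.g. a single clock time)
are rejected as singular.

Cohort summaries report, per nucleoside, the count of rhythmic patients and
mean/range/median/quartiles of mesor, amplitude and relative amplitude,
plus the coefficient of variation of the mesor; acrophase summaries are
circular (weighted circular mean; circular median defined as the midpoint
of the arc minimising summed circular distances, so {23:00, 01:00} → 00:00;
quantiles computed after centring at the circular median).

## Association analysis

Spearman correlations use pairwise deletion and require ≥ 4 complete pairs;
p-values come from the t approximation for n ≥ 10 and from the exact
permutation distribution below that. Constant variables yield a missing
correlation rather than an error. Significance tiers (0.1/0.05/0.01/0.001)
and the three-level grid classification (significant / trend / ns) follow
the usual correlation-diagram conventions.

**Residual-bootstrap uncertainty check.** Rhythm-parameter estimates from
~10 samples are noisy, so a plain Spearman p-value understates uncertainty.
For each of B = 1000 trials, every patient's own cosinor residuals are
resampled with replacement (within patient — residual distributions are
patient-specific), the response is rebuilt around the fitted values, the
linear cosinor is re-solved, the derived parameter (e.g. relative
amplitude, on a 5-min curve grid) recomputed, and the cross-patient
Spearman p re-evaluated. The association is confirmed only if the 90th
percentile of the B p-values is ≤ 0.1. This criterion is strictly harsher
than p ≤ 0.1 on the observed data and in simulation never flags a pair
whose plain p exceeds the threshold. The refit is vectorised across trials
(one matrix product per patient), so B = 1000 over a 29-patient cohort
takes well under a second.

**Stepwise covariate models.** Bidirectional stepwise OLS by AIC, starting
from the full main-effects model; at each step all single-term deletions
and additions are scored and the best strictly-improving move taken
(deletions preferred on ties, then alphabetical — making the search
order-invariant when AIC differences exceed 1e-10). Because the search
starts at the full model and only accepts improvements, the selected AIC
never exceeds the full model's. Categorical covariates move as whole
terms. Rank-deficient designs are rejected with the aliased columns named
(QR with column pivoting).

Group contrasts use Welch's t-test by default (no equal-variance
assumption), with an optional log transform for right-skewed excretion
values; labels are ordered alphabetically so swapping groups negates t and
leaves p unchanged.

## Chemotherapy-response classification

Trend: OLS of log excretion on day (≥ 5 points), category by slope sign if
p ≤ 0.05 else `no_change`; the log scale makes the category invariant to
assay rescaling. An exactly collinear series is handled explicitly (p = 0
for a nonzero slope, p = 1 for a flat one).

CEA change: baseline is the last value at or before the course start,
follow-up the last value 30–61 days after. "Changed by more than 50%" is
read multiplicatively and symmetrically — increase if the ratio exceeds
1.5, decrease if below 2/3 — because a multiplicative rule treats increases
and decreases symmetrically on a positive marker; the additive reading
(±50% of baseline) is available via `mode="additive"`. A patient counts as
"trend" if any monitored nucleoside (default: 1-methylguanosine,
4-acetylcytidine, adenosine, cytidine) shows a significant slope.

The 2×3 trend × CEA table is tested with the Freeman–Halton exact test:
all tables sharing the observed margins are enumerated recursively, each
weighted by its multivariate hypergeometric probability, and the p-value
sums the probabilities of tables no more probable than the observed one
(relative tie tolerance 1e-12). Zero-margin rows/columns are dropped first;
a table reduced to one row or column returns p = 1. On 2×2 tables the
procedure coincides with Fisher's exact test. Survival is compared between
trend and no-trend patients with the Welch t-test.

## Synthetic cohorts

The generator produces the four data streams with controllable ground
truth; all randomness flows from a single seed through spawned
sub-streams, so outputs are bitwise reproducible and every zero-noise
output is an exact closed form of its parameters.

**Actigraphy.** Recordings default to 5 × 24 h starting at 15:00 with a
nightly 23:00–07:00 bed window (so all five windows are complete), each
end jittered independently (default SD 10 min). In bed the latent state is
IA except during a Poisson number (default mean 1/night) of brief wake
excursions that resume the day-time activity chain; out of bed the state
alternates MA/HA as a Markov chain with self-transition 0.9. Emissions are
Gaussian on the log1p scale, exponentiated and rounded to integer counts —
default means (1.3, 3.2, 4.8), i.e. median counts of roughly 3, 24 and 120
per minute. The IA level is deliberately a few counts per minute: real
rest epochs are rarely all-zero, and an all-zero rest state would make the
integer rounding dominate the emission distribution. The diary records the
jittered windows (the generator emulates a compliant diary; diary
misreporting is not modelled). Not emulated: device non-wear, missing
epochs, naps, seasonal/weekday structure.

**Urine.** Concentrations follow the two-component cosinor on the log
scale with Gaussian noise, sampled at the ten study clock times (07:00,
11:00, 15:00, 19:00, 23:00 on two consecutive days). Cohort baselines use
typical median mesors per nucleoside (64.3 µg/g creatinine for
pseudouridine down to 0.58 for cytidine) with between-patient log-SD 0.3,
within the coefficient-of-variation range reported for such cohorts;
within-patient noise SD defaults to 0.2–0.35 depending on scenario. The
generator is the fitted model plus lognormal noise — it does not emulate
assay limits of detection, creatinine-normalisation error, or
day-to-day mesor drift, so estimator performance on real data will be
somewhat worse than on these simulations.

**Treatment courses.** Daily overnight excretions for 3 days before and 14
days after a course follow a log-linear trend with lognormal noise; CEA is
generated as a baseline/follow-up pair whose ratio realises a chosen
category (increase: 1.6–3.0; stable: 0.8–1.25; decrease: 0.35–0.6);
survival is lognormal with a shorter location for trending patients.

**Scenarios.** `robust-rhythm`, `disrupted` and `mixed` interpolate a
per-patient disruption score into bedtime jitter (2–82 min SD), night
interruptions (0.2–8.2 per night) and excretion rhythm amplitude. Rest
duration is drawn per patient (6–10 h in `mixed`), and an optional
coupling adds `coupling × (rest_hours − 8)` to each nucleoside's 24-h
log-amplitude, creating a true rest-duration/amplitude association for
power studies of the bootstrap check. Covariates (sex, age, WHO
performance status, primary site, comorbidities, prior surgery,
chemotherapy lines) are drawn from frequencies typical of a metastatic
colorectal cancer cohort; they are carried for the regression machinery
but do not causally influence the generated signals.

## Problem sizes in the test and acceptance suites

The suites use sizes chosen to give stable Monte-Carlo estimates while
keeping a full run short: 2000 replicates for null-calibration rates
(Monte-Carlo SE ≈ 0.007), 500 for acrophase recovery, 200 random tables
for the exact-test oracle comparison, 20 seeds × 5-day recordings for HMM
decoding, and 20 cohorts of 29 patients (B = 1000) per condition for the
bootstrap check's discrimination rates.

## Known limitations

* Homogeneous HMM transitions: p₁₋₁ is a single scalar; clock-dependent
  transition modulation is not modelled.
* The Rhythm Index formula reproduces the defining limit behaviours
  (100% square-wave, 0% flat) but other implementations of a rhythm index
  may scale intermediate values differently; compare values only within
  this package.
* No multiplicity correction across the correlation grid or across
  nucleosides (deliberate, matching the exploratory design); the bootstrap
  check is the guard against over-interpretation.
* Fixed periods (12/24 h) for excretion rhythms; period estimation is only
  performed for actigraphy.
* The exact r×c enumeration is exponential in table size; it is intended
  for the small patient-count tables of this design (totals of a few
  dozen).
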