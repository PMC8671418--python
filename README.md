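# circamark

Circadian biomarker analytics for oncology cohorts: rest–activity rhythm
quantification from wrist actigraphy, cosinor rhythmometry of timed urinary
modified-nucleoside excretions, bootstrap-verified correlation analysis, and
chemotherapy-response trend tests — with a synthetic-cohort generator so the
whole pipeline is testable end to end without clinical data.

## Who this is for

Urinary modified nucleosides (pseudouridine, 1-methylguanosine,
1-methyladenosine, N2-N2-dimethylguanosine, 4-acetylcytidine,
1-methylinosine, adenosine, cytidine) are non-invasive readouts of nucleic
acid turnover and candidate markers of tumour dynamics in metastatic
colorectal cancer. Their excretion varies along the 24 h and after
chemotherapy, and those dynamics relate to the robustness of the patient's
rest–activity circadian rhythm. `circamark` packages the statistical
machinery needed to study these links: chronobiologists and biostatisticians
analysing timed urine collections, actigraphy recordings, treatment-course
excretion series and plasma CEA follow-up.

## What it computes

**Rest–activity indices** (module `circamark.actigraphy`). A 3-state
Gaussian hidden Markov model on log1p-transformed 1-min activity counts
segments each recording into inactive/rest (IA), moderately active (MA) and
highly active (HA) states. Derived indices: the IA self-transition
probability p₁₋₁; median HA activity; rest duration *a* = ∫ P_IA(t) dt over
24 h; centre of rest *c* (circular gravity centre of the IA profile); the
Rhythm Index

    RI = (W − a²/24) / (a − a²/24) × 100%,   W = ∫ P_IA over the a-hour window centred at c,

which is 100% for regular square-wave rest and 0% for a flat IA profile;
the dichotomy index I<O (% of in-bed epochs with activity below the median
out-of-bed activity, from the sleep diary); the 24-h autocorrelation r24;
the dominant period from a smoothed periodogram in a 16–32 h band with a
day-resampling confidence interval; and a 24-h cosinor amplitude/acrophase
of the counts.

**Cosinor rhythmometry** (module `circamark.cosinor`). The two-component
fixed-period model on log concentrations

    y(t) = M + A₁₂ cos(2πt/12 + θ₁₂) + A₂₄ cos(2πt/24 + θ₂₄) + e(t)

is fitted by (exactly equivalent) linear least squares on cos/sin pairs.
Reported per patient and nucleoside: back-transformed mesor exp(M), overall
amplitude (half-range of the exponentiated fitted curve), relative amplitude
(fraction of mesor), overall acrophase (clock time of the fitted maximum),
and per-component zero-amplitude tests — exact F(2, n−5) on each cos/sin
coefficient pair, flagged rhythmic at p ≤ 0.1. Patients with fewer than
seven valid timed samples are excluded. Cohort summaries use circular
statistics for acrophases.

**Association analysis** (module `circamark.association`). Spearman rank
correlations between any pair of per-patient parameters (exact permutation
p-values below n = 10), a residual-bootstrap uncertainty check (1000 trials
resampling each patient's cosinor residuals, refitting, and re-testing; a
correlation is confirmed only if the 90th percentile of bootstrap p-values
is ≤ 0.1), bidirectional stepwise OLS covariate selection by AIC, and
Welch two-sample comparisons.

**Chemotherapy response** (module `circamark.chemo`). Daily overnight
excretions around a course are classified as increasing / decreasing /
unchanged by OLS regression of log excretion on day (trend iff slope
p ≤ 0.05); plasma CEA changes 1–2 months after the course are categorised
by a symmetric ±50% multiplicative rule; the patient-level trend × CEA
table is tested with the Freeman–Halton exact test for r×c contingency
tables (full enumeration of margin-consistent tables); survival is compared
between trend and no-trend patients.

**Synthetic cohorts** (module `circamark.synthetic`). Deterministic,
seed-controlled generators for all four data streams with known ground
truth, including scenario presets (`robust-rhythm`, `disrupted`, `mixed`)
and an optional coupling between rest duration and excretion rhythm
amplitude for power studies.

## Worked example

```python
import numpy as np
from circamark import fit_multicomponent_cosinor, fisher_exact_rxc
from circamark.synthetic import UrineSimParams, generate_urine_series

# a strongly 24-h-rhythmic nucleoside sampled at the 10 study clock times
params = UrineSimParams(mesor_log=np.log(60.0), amp12_log=0.1, amp24_log=0.4,
                        phase24=-2 * np.pi * 13 / 24, noise_sd_log=0.1)
samples = generate_urine_series(params, seed=42)
fit = fit_multicomponent_cosinor(samples["time_h"], samples["concentration"])
```

This prints (via the fields of `fit`):

```
mesor        =   56.7 ug/g creatinine
amplitude    =   29.8 ug/g creatinine
rel. ampl.   =   0.52  (fraction of mesor)
acrophase    =  12:49
p(24 h)      = 0.0007   p(12 h) = 0.4378
rhythmic     = True
```

The generating curve peaked at 13:00 with a 24-h log-amplitude of 0.4; from
ten noisy samples the fit recovers an acrophase of 12:49, a clearly
significant 24-h component and a non-significant 12-h component. And the
exact test on a 2×3 trend-by-CEA contingency table with rows (1, 8, 0) and
(0, 2, 3):

```python
fisher_exact_rxc([[1, 8, 0], [0, 2, 3]])   # -> 0.0275
```

A full simulated study (actigraphy → cosinor → correlations → chemo
response, with report tables and a reproducibility manifest) runs from the
command line:

```bash
circamark -v run-all --scenario mixed --n-patients 29 --seed 1 --outdir report/
```

Other subcommands (`simulate`, `actigraphy-metrics`, `cosinor-fit`,
`associate`, `chemo-trends`) expose the individual stages on CSV inputs; see
`circamark --help`.

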