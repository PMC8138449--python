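# Methods

## Signal model and preprocessing

The pipeline operates on single-channel blood-volume-pulse (PPG) signals
sampled at 64 Hz by a wrist band, with an optional 3-axis accelerometer at
32 Hz. Recordings are cubic-spline interpolated to 128 Hz to double the
time resolution available to the pulse detector, then lowpass filtered
with a windowed-sinc FIR (Hamming window, order 256 = 257 taps, 4 Hz
cutoff). The filter is linear phase and is applied in a single pass with
its constant group delay (128 samples) compensated exactly, so the net
phase shift is zero; edges are reflect-padded by one filter length to keep
transients out of the analysis window. The measured response has < 0.5 dB
passband ripple below 2 Hz and > 40 dB stopband attenuation above 8 Hz.

"Order 256" is read as polynomial order, i.e. 257 taps; with an odd-length
symmetric kernel the delay compensation is exact at the sample level.

## Quality-window selection

Analysis uses exactly one 60 s window per recording: scanning left to
right in 1 s steps, the earliest window with at least 55 good seconds is
accepted and the rest of the recording is discarded; if none exists, the
recording is excluded with a machine-parseable reason. A second is good
iff

* the accelerometer-magnitude standard deviation within the second is
  ≤ 0.05 g (skipped with a warning when no accelerometer is present), and
* the local peak-to-peak PPG amplitude (2 s window centred on the second)
  is within a factor 1 + `amp_var_tol` (default 2.0, i.e. a factor of 3)
  of the recording's median peak-to-peak, in either direction.

The amplitude criterion is deliberately a symmetric fold-ratio rather
than a tight relative deviation: AF itself produces beat-to-beat amplitude
variability that a tight threshold misclassifies as artifact, whereas
genuine motion excursions exceed the pulse amplitude many-fold and
dropouts fall far below it. Both thresholds are configuration entries.
Under these defaults every clean synthetic record is accepted in full and
every injected motion segment is flagged.

A consequence of the 55/60 rule worth noting: an artifact covering
0–70 s admits a window starting at 65 s (exactly 5 bad seconds), so the
accepted start lands at 65–66 s, not at 70 s.

## Pulse detection and derived series

Pulses are local maxima of the filtered window with minimum separation
0.3 s; a candidate is kept if its prominence reaches 0.4 × the median
prominence of candidates within a centred 10 s neighbourhood. Times are
reported at the apex. The pulse-interval (PIN) series is the sequence of
successive differences gated to (0.25, 3.0) s — covering 20–240 bpm —
with out-of-range intervals removed as gaps, never merged. The amplitude
(AMP) of each pulse is max − min of the signal within ±0.25 s of the
detection, clipped at window edges. Windows with fewer than 10 detected
pulses are treated as pulse-detection failures: interval and amplitude
features become undefined while the autocorrelation feature is still
computed.

On clean synthetic sinus-rhythm windows at default noise the detector
reaches ≥ 95 % beat sensitivity within ±100 ms of ground truth with ≤ 2
false detections per minute; sensitivity is measurably lower for AF
signals at matched noise, because low-amplitude beats fall under the
adaptive threshold.

## Features

Ten features per window; undefined values propagate as NaN and the window
is dropped from model fitting (complete-case analysis).

| feature | definition | units / scale |
|---|---|---|
| PIN_mean, AMP_mean | arithmetic mean | s, signal units |
| PIN_RMSSD, AMP_RMSSD | √mean(Δx²) of successive differences | s, signal units |
| PIN_TPR, AMP_TPR | share of interior strict local extrema, ties non-turning | ×100 (0–100) |
| AMP_SampEn | sample entropy, m = 2, r = 0.2 × SD of the series | nats |
| PIN_COSEn | SampEn(m = 1, r = 30 ms) + ln 2r − ln mean(PIN) | nats |
| PIN_AFE | Lorenz-plot irregularity score (below) | unitless |
| AC | 100 × mean |R_l| over lags 0.3–10 s | ×100 (0–100) |

Sample entropy uses Chebyshev distance, excludes self-matches, and counts
N − m templates at both lengths; A = 0 yields NaN rather than an infinite
estimate. COSEn's tolerance and mean-rate corrections make short interval
series comparable across heart rates; its constants (m = 1, r = 30 ms) are
the values conventional for AF detection from interval series.

**AFEvidence.** Successive interval differences are paired into Lorenz
points (δ_i, δ_{i−1}) and binned into a 40 ms grid spanning ±600 ms
(outliers clamped to edge bins). The score is
`IrregularityEvidence − OriginCount − 2 × PACEvidence`, with
IrregularityEvidence the number of populated bins outside the ±80 ms
origin region, OriginCount the number of points inside it, and
PACEvidence the excess of points in the opposite-sign quadrants over the
same-sign quadrants (floored at zero) — the alternating short-long
signature of bigeminal/trigeminal ectopy. The segment map (origin, four
quadrants, four axis arms) is documented as a lookup table in
`ppgaf.afevidence`. This is a simplified geometry: published
segment-based scores use a finer 13-segment partition whose exact map is
not reproduced here, so absolute AFE magnitudes are not comparable with
published cohort tables, but the score's structure — strongly negative for
regular rhythms, strongly positive for uncorrelated irregular intervals,
penalized for patterned alternation — is preserved and is what the models
consume.

**Autocorrelation.** R_l keeps the 1/N normalization of the truncated
sum, so R_l carries a triangular taper (for a pure period-P sinusoid,
R_P = 1 − P/N exactly). The signal is mean-centered before correlation —
without centering, any DC offset drives all |R_l| toward 1 and destroys
discrimination; centering is exposed as a config switch (`ac_center`).
The lag grid 0.3–10 s skips the trivially high short-lag correlation and
spans at least seven cardiac cycles at 40 bpm; both bounds are
configurable. AC needs no pulse detections, which the test suite enforces
by injecting a null detector and asserting AC is unchanged.

## Predictor models and validation

Logistic models are fit by Newton–Raphson IRLS (convergence when the
largest coefficient update < 1e-8, cap 100 iterations). Standard errors
come from the inverse observed information at the optimum; p-values are
two-sided Wald. Perfect separation is not fatal: the iteration cap bounds
the coefficients and the model carries a `converged=False` flag with a
warning. The fitter is validated in tests against an independent
numerical optimizer of the log-likelihood and against statsmodels.

Backward selection starts from all ten features and repeatedly removes
the feature with the largest Wald p exceeding α (default 0.157), refitting
after each removal, until all remaining p ≤ α. Ties break toward the
larger p, then the lexically larger name; the intercept is exempt.
Removing every feature returns a flagged intercept-only model.

Cross-validation partitions windows into k = 10 seeded folds, stratified
by label by default (configurable) so folds essentially never lack a
class; a fold that still does is excluded from the averages with a
warning. Per-fold AUC (trapezoid over the threshold sweep, equal to the
Mann–Whitney statistic with ties counted ½), sensitivity, specificity,
PPV, NPV and accuracy at cutoff 0.5 are averaged arithmetically, and the
averaged ROC curve is the vertical mean of per-fold TPR on a fixed
101-point FPR grid — the standard reading of "averaging true and false
positive rates" across folds. The 0.5 cutoff presumes a roughly balanced
cohort and is configurable.

A caveat observed repeatedly on well-separated synthetic cohorts: under
quasi-complete separation the Wald statistic collapses (Hauck–Donner
effect), so backward selection can eliminate the *strongest* feature
first. This is a property of Wald-based elimination itself, visible in
`examples/backward_selection.py` on smaller cohorts, and is one reason
the synthetic cohort defaults keep group separability in a realistic
range rather than at ceiling.

## Synthetic data: what it emulates and what it does not

`simulate_record` draws beat times as a renewal process. Sinus rhythm
uses a respiratory-sinus-arrhythmia sinusoid (0.25 Hz) of amplitude
`hrv_sd_s` plus a white component of 0.4 × `hrv_sd_s`, floored at 0.25 s —
serially correlated variability, as real sinus rhythm has; purely IID
jitter would make the interval turning-point ratio indistinguishable from
AF's. AF intervals are IID truncated Gaussian (SD `af_irregularity_s`,
floor 0.3 s) with no serial correlation, deliberately agnostic of atrial
electrophysiology. Each beat emits an asymmetric pulse: a fast Gaussian
upstroke (σ ≈ 0.045 + 0.025·L s for local interval L), a slow Gaussian
decay (σ ≈ 0.10 + 0.12·L s), and a dicrotic bump of 0.20 relative
amplitude at 0.35·L riding on the decay as a shoulder. The dicrotic wave
is a shoulder, not an isolated peak, matching wrist-PPG morphology — an
isolated dicrotic Gaussian would present a second prominence that any
apex detector reports as a spurious pulse. Per-beat amplitude factors are
LogNormal(0, `amp_cv`) marginally, AR(1) with ρ = 0.7 in log scale for SR
(slow perfusion drift) and IID for AF; `morph_var` jitters the width,
dicrotic delay and dicrotic amplitude per beat, so autocorrelation
degrades as pulse shape varies. Respiratory baseline wander (4 % of base
amplitude) and white sensor noise are added. Motion artifacts inject a
smoothed random-walk excursion of 4 × base amplitude into the PPG and a
0.35 g noise burst into the accelerometer over the configured segments.

`simulate_cohort` samples per-record parameters reproducibly from
documented laws: mean heart rate from Normal(84.4, 15.0) bpm for AF and
Normal(69.8, 13.6) bpm for SR (the clinically observed group laws), the
remaining parameters from overlapping uniform ranges
(`DEFAULT_COHORT_PARAMS`) chosen once so that group separability is
realistic — univariate AUCs near but below 1 — rather than degenerate.
Cohort records default to 90 s (comfortably above the 60 s window with
headroom for the quality scan); single-record simulations default to
300 s, matching a ≥ 5 min recording protocol.

The generator makes no claim to hemodynamic realism: no pulse-wave
velocity, no PAC/PVC ectopy (AFEvidence's ectopy term is exercised with
constructed alternating series only), no sensor-contact physics, no
skin-tone or perfusion effects. Passing tests demonstrate that the
pipeline recovers known effect directions and orderings under this model,
not clinical-grade accuracy on real wrist data.

## Numerical and design choices

* Interpolation is cubic spline; values at original instants are
  preserved and the derivative is smooth for apex localization.
* The AC oracle comparisons and feature computations use direct dot
  products (not FFT), keeping results bit-comparable with brute-force
  reference sums.
* Undefined features (short series, zero variance, no entropy template
  matches) are NaN, never imputed; model fitting is complete-case.
* TPR's denominator is n − 2 (interior points), ties count as
  non-turning.
* Fold assignment, cohort parameters and record noise all derive from
  explicit integer seeds; identical seeds give bit-identical cohorts,
  fold maps and report files.
* Problem sizes used by the test-suite and the reproduction script —
  169 + 190 records of 90 s, 50 selection replicates at n = 350, 30
  permutation replicates — were chosen as the package's standard
  experiment sizes; the full suite runs in well under a minute of
  compute per experiment.

## Known limitations

* The pulse detector is validated only against the simulator's ground
  truth, not against an annotated clinical pulse database.
* AFE magnitudes are not comparable with 13-segment published scores
  (structure preserved, geometry simplified).
* Backward selection inherits the Wald test's separation pathology; a
  likelihood-ratio-based variant would be more robust on small,
  well-separated cohorts.
* The quality algorithm accepts or rejects; it never repairs artifacts.
* Absolute feature magnitudes on synthetic cohorts (AC scale, AFE scale,
  amplitude units) are simulator-dependent; only directions, orderings
  and cross-validated discrimination transfer to real data.
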