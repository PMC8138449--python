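# ppgaf — atrial-fibrillation detection from wrist-band photoplethysmography

Atrial fibrillation (AF) is frequently asymptomatic and paroxysmal, and the
irregular, variable pulse waves it produces defeat PPG rhythm analyses that
depend on detecting every individual pulse. `ppgaf` implements a 1-minute
wrist-band PPG analysis built around a morphology feature that needs **no
pulse detection at all**: the mean absolute autocorrelation of the signal
over a grid of delays. Regular rhythms with stable pulse shape keep high
autocorrelation at multiples of the cardiac period; AF's varying intervals
and pulse shapes collapse it.

The package is aimed at physiological-signal researchers prototyping
arrhythmia-screening algorithms. Because clinical recordings with
adjudicated rhythm labels are rarely shareable, it ships a first-class
synthetic PPG generator with exact ground truth (beat times, per-beat
amplitudes, rhythm labels, motion-artifact segments co-registered with a
simulated accelerometer), so every pipeline stage is testable end to end.

## Method

For a 1-min window `x_1..x_N` (64 Hz wrist-band signal interpolated to
128 Hz and lowpass filtered with a zero-phase FIR, order 256, 4 Hz cutoff),
the normalized autocorrelation at delay `l` is

```
R_l = (1/N · Σ_{t=1}^{N−l} x_t x_{t+l}) / R_0 ,    R_0 = (1/N) Σ x_t²
```

and the **AC** feature is `100 × mean_l |R_l|` over delays from 0.3 s to
10 s. Alongside AC, nine conventional features are computed from detected
pulses: the pulse-interval (PIN) series yields mean, RMSSD, AFEvidence
(Lorenz-plot irregularity score of successive interval differences), COSEn
(`SampEn(m=1, r=30 ms) + ln 2r − ln mean(PIN)`), and turning-point ratio;
the pulse-amplitude (AMP) series yields mean, RMSSD, sample entropy and
turning-point ratio. Each feature serves as a univariate logistic
predictor of AF (cutoff 0.5); a multivariate model is built by backward
elimination of Wald-insignificant features at the 0.157 level. Performance
is estimated by stratified, seeded 10-fold cross-validation with
vertically averaged ROC curves.

A quality algorithm selects the first 1-min section with at least 55 s
free of wrist movement (accelerometer criterion) and PPG amplitude
artifacts; recordings without such a section are excluded, with
machine-readable reasons.

## Worked example

```
$ python examples/cohort_classification.py
79 analyzable windows (40 AF)
AC univariate  AUC 0.954  sens 90.0%  spec 90.0%  acc 89.8%
multivariate   AUC 0.963  sens 95.0%  spec 95.0%  acc 94.8%
```

A synthetic cohort of 40 AF + 40 SR recordings is simulated, one quality
window per recording is selected and featurized, and two logistic models
are 10-fold cross-validated. The AC feature alone — computed without any
pulse detection — separates the rhythms with AUC 0.954; combining it with
pulse-interval features raises accuracy to ~95 %. On single recordings
(`examples/simulate_and_extract.py`) the contrast behind this is direct:
AC = 51.0 for a sinus-rhythm window versus 11.3 for an AF window, while
the AF interval series shows PIN_RMSSD 0.249 s versus 0.032 s.

`examples/backward_selection.py` prints the elimination trace and the
Estimate / SE / OR / p table of the retained multivariate model.

The same pipeline is scriptable from the shell:

```
ppgaf simulate --n-af 5 --n-sr 5 --seed 1 --out cohort/
ppgaf extract --in cohort/ --out features.csv
ppgaf cv --features features.csv --feature AC --k 10 --seed 42 --out-prefix cv_ac
ppgaf train --features features.csv --select-backward --out model.txt
ppgaf predict --model model.txt --features features.csv --out calls.csv
```

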