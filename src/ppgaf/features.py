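"""The ten discriminative features of one 1-min PPG window.

Five pulse-interval (PIN) features — mean, RMSSD, AFEvidence, COSEn and
turning-point ratio — four pulse-amplitude (AMP) features — mean, RMSSD,
sample entropy and turning-point ratio — and the autocorrelation morphology
feature AC, which is computed directly from the signal and needs no pulse
detection.  TPR and AC are reported on a 0–100 scale (values used 100-fold).

Undefined features (too few pulses, degenerate input) are reported as NaN
and the affected window is excluded from model fitting downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .afevidence import af_evidence
from .pulses import PulseSeries, analyze_pulses
from .records import PpgRecord

FEATURE_NAMES = (
    "PIN_mean", "PIN_RMSSD", "PIN_AFE", "PIN_COSEn", "PIN_TPR",
    "AMP_mean", "AMP_RMSSD", "AMP_SampEn", "AMP_TPR", "AC",
)


@dataclass
class FeatureVector:
    """The ten named features of one window (NaN = undefined)."""

    PIN_mean: float
    PIN_RMSSD: float
    PIN_AFE: float
    PIN_COSEn: float
    PIN_TPR: float
    AMP_mean: float
    AMP_RMSSD: float
    AMP_SampEn: float
    AMP_TPR: float
    AC: float
    label: str | None = None
    analyzable: bool = True

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class AcProfile:
    """Normalized autocorrelation r_l over a lag grid; r[0] = 1."""

    lags: np.ndarray  # sample counts
    r: np.ndarray     # values in [-1, 1]


def mean_of(series) -> float:
    """Arithmetic mean; NaN on empty input."""
    x = np.asarray(series, dtype=float)
    return float(x.mean()) if x.size else float("nan")


def rmssd(series) -> float:
    """Root mean square of successive differences; NaN if < 2 elements."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        return float("nan")
    d = np.diff(x)
    return float(np.sqrt(np.mean(d * d)))


def turning_point_ratio(series) -> float:
    """Share of interior points that are strict local extrema, x100.

    Equal neighbours never count as turning points; NaN if < 3 elements.
    For an IID continuous sequence the expectation is 200/3 ~ 66.7.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        return float("nan")
    a, b, c = x[:-2], x[1:-1], x[2:]
    turns = ((b > a) & (b > c)) | ((b < a) & (b < c))
    return float(100.0 * np.count_nonzero(turns) / (x.size - 2))


def sample_entropy(series, m: int = 2, r: float | None = None) -> float:
    """Sample entropy −ln(A/B) with Chebyshev distance, self-matches
    excluded and the conventional N−m templates at both lengths.

    ``r`` is the absolute match tolerance.  Returns NaN for degenerate
    input (too short, r <= 0, or no matches at length m+1)."""
    x = np.asarray(series, dtype=float)
    n = x.size
    if r is None or r <= 0 or n <= m + 1:
        return float("nan")

    def pair_matches(length: int) -> int:
        nt = n - m  # same template count for both lengths
        tpl = np.lib.stride_tricks.sliding_window_view(x, length)[:nt]
        d = np.abs(tpl[:, None, :] - tpl[None, :, :]).max(axis=-1)
        iu = np.triu_indices(nt, k=1)
        return int(np.count_nonzero(d[iu] <= r))

    b = pair_matches(m)
    a = pair_matches(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return float(-math.log(a / b))


def cosen(pin_s, m: int = 1, r_s: float = 0.03) -> float:
    """Coefficient of sample entropy: SampEn(m, r) + ln(2r) − ln(mean PIN).

    The tolerance correction removes the dependence on the (fixed, absolute)
    match tolerance and the mean-rate term normalizes for heart rate,
    making short interval series comparable across subjects.  NaN if fewer
    than 10 intervals or SampEn is undefined."""
    pin = np.asarray(pin_s, dtype=float)
    if pin.size < 10:
        return float("nan")
    mu = pin.mean()
    if mu <= 0:
        return float("nan")
    se = sample_entropy(pin, m=m, r=r_s)
    return float(se + math.log(2 * r_s) - math.log(mu))


def ac_profile(samples, max_lag: int, center: bool = True) -> AcProfile:
    """Normalized autocorrelation r_l = (1/N · Σ_{t} x_t x_{t+l}) / R_0 for
    l = 0..max_lag, with R_0 = (1/N) Σ x_t².

    The 1/N normalization (rather than 1/(N−l)) is deliberate, so r_l
    carries the triangular taper of the truncated sum.  The signal is
    mean-centered first by default; a zero-variance signal raises."""
    x = np.asarray(samples, dtype=float)
    n = x.size
    if not 1 <= max_lag < n:
        raise ValueError("need N > max_lag >= 1")
    if center:
        x = x - x.mean()
    r0 = float(x @ x) / n
    if r0 <= 0:
        raise ValueError("zero-variance signal: autocorrelation undefined")
    r = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        r[lag] = (x[: n - lag] @ x[lag:]) / n / r0
    return AcProfile(lags=np.arange(max_lag + 1), r=r)


def ac_feature(window, fs_hz: float | None = None, min_lag_s: float = 0.3,
               max_lag_s: float = 10.0, center: bool = True) -> float:
    """Mean absolute autocorrelation over the lag grid, x100.

    ``window`` may be a :class:`PpgRecord` or a plain sample array with
    ``fs_hz`` given.  The default lag grid runs from 0.3 s (skipping the
    trivially high short-lag correlation) to 10 s (several cardiac cycles
    even at low rates).  Needs no pulse detection; NaN on zero variance."""
    if isinstance(window, PpgRecord):
        x, fs = window.samples, window.fs_hz
    else:
        if fs_hz is None:
            raise ValueError("fs_hz required when passing raw samples")
        x, fs = np.asarray(window, dtype=float), fs_hz
    lo = max(int(round(min_lag_s * fs)), 1)
    hi = min(int(round(max_lag_s * fs)), x.size - 1)
    if hi < lo:
        return float("nan")
    try:
        prof = ac_profile(x, max_lag=hi, center=center)
    except ValueError:
        return float("nan")
    return float(100.0 * np.mean(np.abs(prof.r[lo:hi + 1])))


def extract_features(window: PpgRecord, *, label: str | None = None,
                     detector=None, min_pulses: int = 10,
                     min_separation_s: float = 0.3, rel_prominence: float = 0.4,
                     neighborhood_s: float = 10.0, pin_min_s: float = 0.25,
                     pin_max_s: float = 3.0, amp_halfwidth_s: float = 0.25,
                     cosen_m: int = 1, cosen_r_s: float = 0.03,
                     sampen_m: int = 2, sampen_r_factor: float = 0.2,
                     ac_min_lag_s: float = 0.3, ac_max_lag_s: float = 10.0,
                     ac_center: bool = True) -> FeatureVector:
    """Compute all ten features for an accepted, preprocessed 1-min window.

    ``detector`` allows injecting an alternative pulse detector (signature
    ``detector(window) -> pulse times``); the AC feature is computed from
    the raw window samples regardless and is unaffected by detection.
    PIN/AMP features are NaN when fewer than ``min_pulses`` pulses are
    found; the window is flagged unanalyzable when, in addition, AC is
    undefined."""
    if detector is None:
        times = None
    else:
        times = np.asarray(detector(window), dtype=float)
    if times is None:
        ps = analyze_pulses(window, min_separation_s, rel_prominence,
                            neighborhood_s, pin_min_s, pin_max_s,
                            amp_halfwidth_s)
    else:
        from .pulses import compute_amp_series, compute_pin_series
        pin = (compute_pin_series(times, pin_min_s, pin_max_s)
               if times.size >= 2 else np.empty(0))
        amp = compute_amp_series(window, times, amp_halfwidth_s)
        ps = PulseSeries(times, pin, amp)

    nan = float("nan")
    if ps.n_pulses >= min_pulses and ps.pin_s.size >= 2:
        pin, amp = ps.pin_s, ps.amp
        amp_sd = float(np.std(amp))
        fv_pin = dict(
            PIN_mean=mean_of(pin),
            PIN_RMSSD=rmssd(pin),
            PIN_AFE=af_evidence(pin),
            PIN_COSEn=cosen(pin, m=cosen_m, r_s=cosen_r_s),
            PIN_TPR=turning_point_ratio(pin),
            AMP_mean=mean_of(amp),
            AMP_RMSSD=rmssd(amp),
            AMP_SampEn=sample_entropy(amp, m=sampen_m,
                                      r=sampen_r_factor * amp_sd if amp_sd > 0 else None),
            AMP_TPR=turning_point_ratio(amp),
        )
    else:
        fv_pin = {k: nan for k in FEATURE_NAMES[:-1]}

    ac = ac_feature(window, min_lag_s=ac_min_lag_s, max_lag_s=ac_max_lag_s,
                    center=ac_center)
    analyzable = not (math.isnan(ac) and ps.n_pulses < min_pulses)
    return FeatureVector(**fv_pin, AC=ac, label=label or window.label,
                         analyzable=analyzable)
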