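"""Pulse detection and the derived pulse-interval / amplitude series.

Pulses are picked at the apex of local maxima of the filtered signal with a
physiologic minimum separation (0.3 s) and an adaptive prominence
threshold: a candidate peak survives if its prominence reaches 40 % of the
median prominence of candidates within a centred 10 s neighbourhood.  The
successive differences of the detected pulse times form the pulse-interval
(PIN) series, gated to the physiologic band (0.25, 3.0) s; the pulse
amplitude (AMP) is the max-minus-min signal excursion in a 0.5 s window
around each detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .records import PpgRecord


@dataclass
class PulseSeries:
    """Detected pulses of one 1-min window."""

    pulse_times_s: np.ndarray  # strictly increasing, seconds from window start
    pin_s: np.ndarray          # gated successive differences, seconds
    amp: np.ndarray            # per-pulse amplitude, signal units

    @property
    def n_pulses(self) -> int:
        return int(self.pulse_times_s.size)


def detect_pulses(window: PpgRecord, min_separation_s: float = 0.3,
                  rel_prominence: float = 0.4,
                  neighborhood_s: float = 10.0) -> np.ndarray:
    """Detect pulse apex times (seconds from window start).

    Returns an empty array when no peaks qualify; the caller decides
    whether the window is analyzable (fewer than ~10 pulses per minute is
    treated as detection failure downstream).
    """
    x, fs = window.samples, window.fs_hz
    dist = max(int(round(min_separation_s * fs)), 1)
    peaks, props = find_peaks(x, distance=dist, prominence=1e-12)
    if peaks.size == 0:
        return np.empty(0)
    prom = props["prominences"]
    times = peaks / fs
    half = neighborhood_s / 2.0
    keep = np.zeros(peaks.size, dtype=bool)
    for i, t in enumerate(times):
        nb = (times >= t - half) & (times <= t + half)
        keep[i] = prom[i] >= rel_prominence * np.median(prom[nb])
    return times[keep]


def compute_pin_series(pulse_times_s: np.ndarray, min_s: float = 0.25,
                       max_s: float = 3.0) -> np.ndarray:
    """Successive pulse differences, with intervals outside (min_s, max_s)
    removed; removal leaves a gap — neighbouring intervals are never
    merged."""
    t = np.asarray(pulse_times_s, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 pulses to form intervals")
    d = np.diff(t)
    return d[(d > min_s) & (d < max_s)]


def compute_amp_series(window: PpgRecord, pulse_times_s: np.ndarray,
                       halfwidth_s: float = 0.25) -> np.ndarray:
    """Max-minus-min signal excursion in ±``halfwidth_s`` around each
    pulse, clipped to window edges."""
    x, fs = window.samples, window.fs_hz
    amps = np.empty(len(pulse_times_s))
    for i, t in enumerate(pulse_times_s):
        lo = max(int(round((t - halfwidth_s) * fs)), 0)
        hi = min(int(round((t + halfwidth_s) * fs)) + 1, x.size)
        seg = x[lo:hi]
        amps[i] = seg.max() - seg.min() if seg.size else 0.0
    return amps


def analyze_pulses(window: PpgRecord, min_separation_s: float = 0.3,
                   rel_prominence: float = 0.4, neighborhood_s: float = 10.0,
                   pin_min_s: float = 0.25, pin_max_s: float = 3.0,
                   amp_halfwidth_s: float = 0.25) -> PulseSeries:
    """Detect pulses and derive both series in one call."""
    times = detect_pulses(window, min_separation_s, rel_prominence, neighborhood_s)
    pin = compute_pin_series(times, pin_min_s, pin_max_s) if times.size >= 2 else np.empty(0)
    amp = compute_amp_series(window, times, amp_halfwidth_s)
    return PulseSeries(times, pin, amp)
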