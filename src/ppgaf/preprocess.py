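"""Interpolation, zero-phase lowpass filtering and quality-window selection.

The raw 64 Hz wrist-band signal is first interpolated to 128 Hz (cubic
spline) to double the time resolution for beat detection, then lowpass
filtered with a linear-phase FIR (order 256, i.e. 257 taps, Hamming window,
4 Hz cutoff) applied in a single pass with group-delay compensation so the
net phase shift is zero.  A quality algorithm then scans for the first
continuous 1-min section in which at least 55 s are free of wrist movement
(accelerometer criterion) and of PPG amplitude artifacts; only that first
eligible window is analysed and the rest of the recording is discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .records import PpgRecord

log = logging.getLogger(__name__)


@dataclass
class QualityWindow:
    """Outcome of the quality scan for one recording."""

    start_s: float
    end_s: float
    good_fraction: float
    accepted: bool
    reason: str = "ok"  # machine-parseable: ok | too_short | no_good_window


def interpolate_to(record: PpgRecord, target_fs: float) -> PpgRecord:
    """Resample the PPG channel to ``target_fs`` with a cubic spline.

    Values at the original sample instants are preserved to interpolation
    accuracy; record duration is unchanged up to one output sample.
    """
    if record.n_samples < 2:
        raise ValueError("record must contain at least 2 samples")
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    t_old = np.arange(record.n_samples) / record.fs_hz
    n_new = int(round(record.duration_s * target_fs))
    t_new = np.arange(n_new) / target_fs
    spline = CubicSpline(t_old, record.samples)
    y = spline(np.clip(t_new, 0.0, t_old[-1]))
    return replace(record, samples=y, fs_hz=float(target_fs))


def zero_phase_lowpass(record: PpgRecord, order: int = 256,
                       cutoff_hz: float = 4.0) -> PpgRecord:
    """Zero-phase FIR lowpass (windowed-sinc, ``order``+1 taps, Hamming).

    The linear-phase filter is applied once; the constant group delay of
    ``order/2`` samples is compensated exactly, so the net phase shift is
    zero.  Edges are reflect-padded to avoid transients inside the window.
    """
    n = record.n_samples
    ntaps = order + 1
    if n <= ntaps:
        raise ValueError("record shorter than filter length")
    if record.fs_hz <= 2 * cutoff_hz:
        raise ValueError("sampling rate must exceed twice the cutoff")
    taps = signal.firwin(ntaps, cutoff_hz, fs=record.fs_hz, window="hamming")
    xp = np.pad(record.samples, ntaps, mode="reflect")
    # odd-length symmetric kernel + mode="same" centres the output: delay
    # order/2 is removed and the result is zero phase.
    y = np.convolve(xp, taps, mode="same")[ntaps:ntaps + n]
    return replace(record, samples=y)


def _per_second_accel_ok(record: PpgRecord, n_sec: int, sd_thresh: float) -> np.ndarray:
    if record.accel is None or record.accel_fs_hz is None:
        log.warning("no accelerometer channel: movement criterion skipped")
        return np.ones(n_sec, dtype=bool)
    mag = np.linalg.norm(record.accel, axis=1)
    fs = record.accel_fs_hz
    ok = np.ones(n_sec, dtype=bool)
    for s in range(n_sec):
        seg = mag[int(s * fs):int((s + 1) * fs)]
        ok[s] = seg.size == 0 or seg.std() <= sd_thresh
    return ok


def _per_second_amplitude_ok(record: PpgRecord, n_sec: int, tol: float) -> np.ndarray:
    """Flag seconds whose local peak-to-peak amplitude deviates from the
    recording's median by more than a factor of ``1 + tol`` in either
    direction (so both large excursions and dropouts fail).

    The symmetric fold-ratio keeps the statistic insensitive to the
    beat-to-beat amplitude variability that characterises AF itself while
    still failing motion artifacts, whose excursions exceed the pulse
    amplitude several-fold."""
    x, fs = record.samples, record.fs_hz
    p2p = np.empty(n_sec)
    for s in range(n_sec):
        # 2 s window centred on the epoch
        lo = max(int((s - 0.5) * fs), 0)
        hi = min(int((s + 1.5) * fs), x.size)
        seg = x[lo:hi]
        p2p[s] = seg.max() - seg.min() if seg.size else 0.0
    med = np.median(p2p)
    if med <= 0:
        return p2p == med
    fold = np.maximum(p2p / med, np.divide(med, p2p, out=np.full(n_sec, np.inf),
                                           where=p2p > 0))
    return fold <= 1.0 + tol


def good_seconds(record: PpgRecord, accel_sd_g: float = 0.05,
                 amp_var_tol: float = 2.0) -> np.ndarray:
    """Per-second quality flags: a second is good iff the wrist is still
    (accelerometer-magnitude SD below threshold) and the local PPG
    amplitude variation is within tolerance of the recording median."""
    n_sec = int(record.duration_s)
    return (_per_second_accel_ok(record, n_sec, accel_sd_g)
            & _per_second_amplitude_ok(record, n_sec, amp_var_tol))


def select_quality_window(record: PpgRecord, window_s: float = 60.0,
                          min_good_s: float = 55.0, accel_sd_g: float = 0.05,
                          amp_var_tol: float = 2.0) -> QualityWindow:
    """Return the earliest 1-min window with at least ``min_good_s`` good
    seconds, scanning left to right; ``accepted=False`` if none exists."""
    if record.duration_s < window_s:
        raise ValueError("record shorter than the analysis window")
    flags = good_seconds(record, accel_sd_g, amp_var_tol)
    w = int(window_s)
    counts = np.convolve(flags.astype(int), np.ones(w, dtype=int), mode="valid")
    for start, c in enumerate(counts):
        if c >= min_good_s:
            gf = c / w
            log.info("accepted window [%d, %d) s, good fraction %.3f",
                     start, start + w, gf)
            return QualityWindow(float(start), float(start + w), gf, True)
    best = float(counts.max()) / w if counts.size else 0.0
    log.warning("no eligible 1-min window (best good fraction %.3f)", best)
    return QualityWindow(0.0, float(w), best, False, reason="no_good_window")
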