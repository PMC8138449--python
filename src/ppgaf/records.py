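"""Core signal container shared by the whole pipeline."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass
class PpgRecord:
    """A uniformly sampled blood-volume-pulse (PPG) signal.

    Parameters
    ----------
    samples : ndarray
        PPG signal values, arbitrary device units.
    fs_hz : float
        Sampling rate of ``samples`` in Hz.
    accel : ndarray of shape (n, 3), optional
        Co-registered 3-axis accelerometer trace in g.
    accel_fs_hz : float, optional
        Sampling rate of the accelerometer channel.
    truth_beats_s : ndarray, optional
        Ground-truth beat times in seconds (synthetic records only).
    truth_amps : ndarray, optional
        Ground-truth per-beat amplitude factors (synthetic records only).
    label : {"AF", "SR"}, optional
        Rhythm label when known.
    """

    samples: np.ndarray
    fs_hz: float
    accel: np.ndarray | None = None
    accel_fs_hz: float | None = None
    truth_beats_s: np.ndarray | None = None
    truth_amps: np.ndarray | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.accel is not None:
            self.accel = np.asarray(self.accel, dtype=float)
            if self.accel.ndim != 2 or self.accel.shape[1] != 3:
                raise ValueError("accel must have shape (n, 3)")
        if self.truth_beats_s is not None:
            self.truth_beats_s = np.asarray(self.truth_beats_s, dtype=float)
            if np.any(np.diff(self.truth_beats_s) <= 0):
                raise ValueError("truth_beats_s must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def slice(self, start_s: float, end_s: float) -> "PpgRecord":
        """Extract a sub-record on [start_s, end_s); truth beat times are
        re-expressed relative to the new origin."""
        if not 0 <= start_s < end_s <= self.duration_s + 1e-9:
            raise ValueError("slice bounds outside record")
        i0 = int(round(start_s * self.fs_hz))
        i1 = int(round(end_s * self.fs_hz))
        out = replace(self, samples=self.samples[i0:i1])
        if self.accel is not None and self.accel_fs_hz:
            j0 = int(round(start_s * self.accel_fs_hz))
            j1 = int(round(end_s * self.accel_fs_hz))
            out.accel = self.accel[j0:j1]
        if self.truth_beats_s is not None:
            m = (self.truth_beats_s >= start_s) & (self.truth_beats_s < end_s)
            out.truth_beats_s = self.truth_beats_s[m] - start_s
            if self.truth_amps is not None:
                out.truth_amps = self.truth_amps[m]
        return out
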