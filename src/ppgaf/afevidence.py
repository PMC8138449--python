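"""AFEvidence: irregularity scoring on the Lorenz plot of successive
interval differences.

For a pulse-interval series ``pin`` the successive differences
``d_i = pin_i − pin_{i−1}`` are paired into Lorenz-plot points
``(d_i, d_{i−1})``.  Sinus rhythm concentrates the points at the origin;
atrial fibrillation scatters them widely; ectopy in bigeminy/trigeminy
patterns loads the opposite-sign quadrants in a structured way.

Geometry (segment lookup):

======  =================================================  ==========
seg id  region (half-width h = 80 ms, range clamp 600 ms)  meaning
======  =================================================  ==========
0       |dx| < h and |dy| < h                              origin (regular)
1       dx >= h, dy >= h                                   quadrant + +
2       dx <= −h, dy >= h                                  quadrant − +
3       dx <= −h, dy <= −h                                 quadrant − −
4       dx >= h, dy <= −h                                  quadrant + −
5..8    one coordinate inside ±h, the other beyond         axis arms E/N/W/S
======  =================================================  ==========

The histogram uses 40 ms square bins spanning ±600 ms; points beyond the
range are clamped into the edge bins.  The score is

``AFEvidence = IrregularityEvidence − OriginCount − 2 × PACEvidence``

where *IrregularityEvidence* is the number of populated non-origin bins,
*OriginCount* the number of points in segment 0, and *PACEvidence* the
excess of points in the opposite-sign quadrants (2 and 4, the
bigeminy/trigeminy alternation signature) over the same-sign quadrants
(1 and 3), floored at zero.
"""

from __future__ import annotations

import numpy as np

BIN_WIDTH_S = 0.040
HIST_RANGE_S = 0.600
ORIGIN_HALFWIDTH_S = 0.080
MIN_INTERVALS = 12


def lorenz_points(pin_s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Points (d_i, d_{i−1}) of successive interval differences."""
    d = np.diff(np.asarray(pin_s, dtype=float))
    return d[1:], d[:-1]


def segment_of(dx: float, dy: float, h: float = ORIGIN_HALFWIDTH_S) -> int:
    """Segment id of one Lorenz point (see module docstring table)."""
    in_x, in_y = abs(dx) < h, abs(dy) < h
    if in_x and in_y:
        return 0
    if not in_x and not in_y:
        if dx >= h and dy >= h:
            return 1
        if dx <= -h and dy >= h:
            return 2
        if dx <= -h and dy <= -h:
            return 3
        return 4
    if in_y:  # arm along x
        return 5 if dx >= h else 7
    return 6 if dy >= h else 8


def _bin_index(v: np.ndarray) -> np.ndarray:
    n_bins = int(round(2 * HIST_RANGE_S / BIN_WIDTH_S))  # 30
    idx = np.floor((v + HIST_RANGE_S) / BIN_WIDTH_S).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def af_evidence(pin_s: np.ndarray) -> float:
    """AFEvidence score of a pulse-interval series (NaN if < 12 intervals)."""
    pin = np.asarray(pin_s, dtype=float)
    if pin.size < MIN_INTERVALS:
        return float("nan")
    dx, dy = lorenz_points(pin)
    segs = np.array([segment_of(a, b) for a, b in zip(dx, dy)])
    origin_count = int(np.sum(segs == 0))
    out = segs != 0
    bx, by = _bin_index(dx[out]), _bin_index(dy[out])
    irregularity = len(set(zip(bx.tolist(), by.tolist())))
    n_opposite = int(np.sum((segs == 2) | (segs == 4)))
    n_same = int(np.sum((segs == 1) | (segs == 3)))
    pac = max(n_opposite - n_same, 0)
    return float(irregularity - origin_count - 2 * pac)
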