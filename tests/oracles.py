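"""Independent brute-force oracles used to validate the feature and
classifier implementations.  Everything here is deliberately written as
plain double loops over the defining formulas, sharing no code with the
package."""

from __future__ import annotations

import math

import numpy as np


def mean_oracle(x):
    s = 0.0
    for v in x:
        s += v
    return s / len(x)


def rmssd_oracle(x):
    s = 0.0
    for i in range(len(x) - 1):
        s += (x[i + 1] - x[i]) ** 2
    return math.sqrt(s / (len(x) - 1))


def tpr_oracle(x):
    turns = 0
    for i in range(1, len(x) - 1):
        if (x[i] > x[i - 1] and x[i] > x[i + 1]) or (x[i] < x[i - 1] and x[i] < x[i + 1]):
            turns += 1
    return 100.0 * turns / (len(x) - 2)


def sampen_oracle(x, m, r):
    """Template-counting sample entropy, Chebyshev distance, no
    self-matches, N−m templates at both lengths."""
    n = len(x)
    nt = n - m

    def count(length):
        c = 0
        for i in range(nt):
            for j in range(i + 1, nt):
                if max(abs(x[i + k] - x[j + k]) for k in range(length)) <= r:
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def cosen_oracle(pin, m=1, r=0.03):
    return sampen_oracle(list(pin), m, r) + math.log(2 * r) - math.log(mean_oracle(pin))


def afe_oracle(pin, h=0.08, bin_w=0.04, rng_s=0.6):
    """Brute-force Lorenz-plot scoring from the documented geometry."""
    d = [pin[i + 1] - pin[i] for i in range(len(pin) - 1)]
    pts = [(d[i], d[i - 1]) for i in range(1, len(d))]
    origin = 0
    bins = set()
    n_same = n_opp = 0
    n_bins = int(round(2 * rng_s / bin_w))
    for (dx, dy) in pts:
        if abs(dx) < h and abs(dy) < h:
            origin += 1
            continue
        bx = min(max(int(math.floor((dx + rng_s) / bin_w)), 0), n_bins - 1)
        by = min(max(int(math.floor((dy + rng_s) / bin_w)), 0), n_bins - 1)
        bins.add((bx, by))
        if abs(dx) >= h and abs(dy) >= h:
            if dx * dy > 0:
                n_same += 1
            else:
                n_opp += 1
    pac = max(n_opp - n_same, 0)
    return len(bins) - origin - 2 * pac


def ac_profile_oracle(x, max_lag):
    n = len(x)
    mu = mean_oracle(x)
    xc = [v - mu for v in x]
    r0 = sum(v * v for v in xc) / n
    out = []
    for lag in range(max_lag + 1):
        s = 0.0
        for t in range(n - lag):
            s += xc[t] * xc[t + lag]
        out.append(s / n / r0)
    return out


def ac_feature_oracle(x, fs, min_lag_s=0.3, max_lag_s=10.0):
    lo = max(int(round(min_lag_s * fs)), 1)
    hi = min(int(round(max_lag_s * fs)), len(x) - 1)
    prof = ac_profile_oracle(x, hi)
    vals = [abs(v) for v in prof[lo:hi + 1]]
    return 100.0 * sum(vals) / len(vals)


def auc_pair_oracle(scores, labels):
    """Mann–Whitney pair counting with ties counted 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def logistic_nll(beta, X, y):
    """Negative log-likelihood of a logistic model, intercept first.

    NLL = Σ [ log(1 + exp(η)) − y·η ], computed stably."""
    beta = np.asarray(beta, dtype=float)
    eta = beta[0] + np.asarray(X) @ beta[1:]
    return float(np.sum(np.log1p(np.exp(-np.abs(eta))) + np.maximum(eta, 0.0)
                        - np.asarray(y) * eta))
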