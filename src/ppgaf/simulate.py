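"""Synthetic wrist-band PPG generator with known ground truth.

Clinical PPG recordings with adjudicated rhythm labels are not freely
available, so every downstream stage of the pipeline is exercised against
simulated blood-volume-pulse signals whose beat times, per-beat amplitudes
and rhythm labels are known exactly.

Two rhythm regimes are modelled:

* **SR** (sinus rhythm): a quasi-regular renewal process.  Beat-to-beat
  variability is dominated by a respiratory-sinus-arrhythmia sinusoid
  (0.25 Hz) of amplitude ``hrv_sd_s`` plus a smaller white component, which
  makes successive intervals serially correlated, as real sinus-rhythm
  heart-rate variability is.  Pulse amplitudes drift slowly (AR(1) in log
  scale) around a stable morphology.
* **AF** (atrial fibrillation): beat intervals drawn IID from a truncated
  Gaussian with standard deviation ``af_irregularity_s`` (floor 0.3 s) and
  no serial correlation; amplitudes vary beat to beat (IID log-normal) and
  the pulse shape is perturbed per beat via ``morph_var``.

Each beat emits a stereotyped pulse template — a systolic Gaussian plus a
smaller dicrotic bump at ~55 % of the local interval — scaled by a per-beat
LogNormal(0, amp_cv) amplitude factor.  Motion artifacts inject large
low-frequency PPG baseline excursions together with accelerometer activity
in the configured segments, so the quality algorithm can be driven
realistically.  The accelerometer is simulated at 32 Hz in g units, flat at
(0, 0, 1 g) outside artifacts, mirroring a wrist-band export.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .records import PpgRecord

RHYTHMS = ("SR", "AF")

_RESP_HZ = 0.25  # respiratory modulation frequency for SR interval/baseline
_SR_WHITE_FRAC = 0.4  # white jitter as a fraction of hrv_sd_s
_SR_AMP_RHO = 0.7  # AR(1) coefficient of SR log-amplitudes
_DICROTIC_FRAC = 0.35  # dicrotic bump delay as a fraction of local interval
_DICROTIC_AMP = 0.20  # dicrotic amplitude relative to systolic peak


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated recording.

    Identical configurations (including ``seed``) produce bit-identical
    records.
    """

    rhythm: str = "SR"
    duration_s: float = 300.0
    mean_hr_bpm: float = 70.0
    hrv_sd_s: float = 0.03
    af_irregularity_s: float = 0.18
    amp_cv: float = 0.10
    morph_var: float = 0.15
    noise_sd: float = 0.02
    base_amp: float = 1.0
    artifact_segments: tuple = ()
    seed: int = 0
    fs_hz: float = 64.0
    accel_fs_hz: float = 32.0

    def __post_init__(self):
        if self.rhythm not in RHYTHMS:
            raise ValueError(f"rhythm must be one of {RHYTHMS}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not 30.0 <= self.mean_hr_bpm <= 220.0:
            raise ValueError("mean_hr_bpm must lie in [30, 220]")
        if self.amp_cv < 0:
            raise ValueError("amp_cv must be non-negative")
        if not 0.0 <= self.morph_var <= 1.0:
            raise ValueError("morph_var must lie in [0, 1]")
        if self.noise_sd < 0 or self.fs_hz <= 0 or self.accel_fs_hz <= 0:
            raise ValueError("noise_sd must be >= 0 and rates positive")


def _beat_intervals(cfg: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw beat times (s) as a renewal process; returns (times, intervals)."""
    base = 60.0 / cfg.mean_hr_bpm
    phase = rng.uniform(0.0, 2.0 * math.pi)
    t = rng.uniform(0.2, 0.6)
    times, ivs = [], []
    while t < cfg.duration_s - 0.05:
        times.append(t)
        if cfg.rhythm == "SR":
            iv = (
                base
                + cfg.hrv_sd_s * math.sin(2.0 * math.pi * _RESP_HZ * t + phase)
                + rng.normal(0.0, _SR_WHITE_FRAC * cfg.hrv_sd_s)
            )
            iv = max(iv, 0.25)
        else:  # AF: IID, truncated below at 0.3 s
            iv = max(rng.normal(base, cfg.af_irregularity_s), 0.3)
        ivs.append(iv)
        t += iv
    return np.asarray(times), np.asarray(ivs)


def _amplitude_factors(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Per-beat amplitude factors, LogNormal(0, amp_cv) marginally.

    SR log-factors follow a stationary AR(1) (slow perfusion drift); AF
    log-factors are IID.
    """
    rho = _SR_AMP_RHO if cfg.rhythm == "SR" else 0.0
    a = np.empty(n)
    if n == 0:
        return a
    a[0] = rng.normal(0.0, cfg.amp_cv)
    innov = rng.normal(0.0, cfg.amp_cv, size=max(n - 1, 0))
    scale = math.sqrt(1.0 - rho * rho)
    for k in range(1, n):
        a[k] = rho * a[k - 1] + scale * innov[k - 1]
    return cfg.base_amp * np.exp(a)


def _add_pulse(x: np.ndarray, fs: float, t0: float, amp: float,
               sigma_rise: float, sigma_decay: float,
               dic_dt: float, dic_amp: float, sigma_dic: float) -> None:
    """Add one stereotyped pulse in place: an asymmetric systolic wave
    (fast Gaussian upstroke, slow Gaussian decay) with a smaller dicrotic
    bump riding on the decay as a shoulder rather than a separate peak."""
    lo = max(int((t0 - 4 * sigma_rise) * fs), 0)
    hi = min(int((t0 + dic_dt + 4 * (sigma_dic + sigma_decay)) * fs) + 1, x.size)
    if hi <= lo:
        return
    tt = np.arange(lo, hi) / fs
    sig = np.where(tt < t0, sigma_rise, sigma_decay)
    x[lo:hi] += amp * (
        np.exp(-0.5 * ((tt - t0) / sig) ** 2)
        + dic_amp * np.exp(-0.5 * ((tt - t0 - dic_dt) / sigma_dic) ** 2)
    )


def simulate_record(cfg: SimConfig) -> PpgRecord:
    """Generate one PPG record according to ``cfg``.

    Returns a :class:`~ppgaf.records.PpgRecord` with ``truth_beats_s``,
    ``truth_amps`` and ``label`` populated.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs_hz))
    t_axis = np.arange(n) / cfg.fs_hz
    x = np.zeros(n)

    beats, ivs = _beat_intervals(cfg, rng)
    amps = _amplitude_factors(cfg, beats.size, rng)
    base_iv = 60.0 / cfg.mean_hr_bpm

    # morphology jitter draws (one uniform 4-vector per beat, fixed order)
    jit = rng.uniform(-1.0, 1.0, size=(beats.size, 4))
    for k, t0 in enumerate(beats):
        local = min(ivs[k] if k < ivs.size else base_iv, 1.4)
        mv = cfg.morph_var
        sigma_rise = max((0.045 + 0.025 * local) * (1 + 0.4 * mv * jit[k, 0]), 0.02)
        sigma_decay = max((0.10 + 0.12 * local) * (1 + 0.4 * mv * jit[k, 1]), 0.05)
        dic_dt = _DICROTIC_FRAC * local * (1 + 0.2 * mv * jit[k, 2])
        dic_amp = max(_DICROTIC_AMP * (1 + mv * jit[k, 3]), 0.0)
        sigma_dic = max(0.05 + 0.04 * local, 0.03)
        _add_pulse(x, cfg.fs_hz, t0, amps[k], sigma_rise, sigma_decay,
                   dic_dt, dic_amp, sigma_dic)

    # respiratory baseline wander + sensor noise
    phase_b = rng.uniform(0.0, 2.0 * math.pi)
    x += 0.04 * cfg.base_amp * np.sin(2.0 * math.pi * _RESP_HZ * t_axis + phase_b)
    x += rng.normal(0.0, cfg.noise_sd, size=n)

    # accelerometer: gravity on z plus sensor noise
    na = int(round(cfg.duration_s * cfg.accel_fs_hz))
    accel = np.tile([0.0, 0.0, 1.0], (na, 1)) + rng.normal(0.0, 0.003, size=(na, 3))

    # motion artifacts: smoothed random-walk baseline excursion + accel burst
    for (s, e) in cfg.artifact_segments:
        i0, i1 = max(int(s * cfg.fs_hz), 0), min(int(e * cfg.fs_hz), n)
        if i1 > i0:
            w = rng.normal(0.0, 1.0, size=i1 - i0)
            box = max(int(0.5 * cfg.fs_hz), 1)
            w = np.convolve(w, np.ones(box) / box, mode="same")
            sd = w.std()
            if sd > 0:
                x[i0:i1] += 4.0 * cfg.base_amp * w / sd
        j0, j1 = max(int(s * cfg.accel_fs_hz), 0), min(int(e * cfg.accel_fs_hz), na)
        if j1 > j0:
            accel[j0:j1] += rng.normal(0.0, 0.35, size=(j1 - j0, 3))

    return PpgRecord(
        samples=x,
        fs_hz=cfg.fs_hz,
        accel=accel,
        accel_fs_hz=cfg.accel_fs_hz,
        truth_beats_s=beats,
        truth_amps=amps,
        label=cfg.rhythm,
    )


# Cohort-level parameter laws.  Mean heart rate is drawn from the normal laws
# observed clinically (AF 84.4 +/- 15.0 bpm, SR 69.8 +/- 13.6 bpm); remaining
# parameters are drawn uniformly from overlapping ranges so that group
# separation is realistic rather than trivial.
DEFAULT_COHORT_PARAMS: dict = {
    "AF": dict(
        mean_hr_bpm=(84.4, 15.0), hr_clip=(45.0, 160.0),
        af_irregularity_s=(0.04, 0.24),
        hrv_sd_s=(0.02, 0.05),
        amp_cv=(0.15, 0.50),
        morph_var=(0.25, 0.80),
        base_amp=(0.50, 1.00),
        noise_sd=(0.010, 0.080),
        duration_s=90.0,
    ),
    "SR": dict(
        mean_hr_bpm=(69.8, 13.6), hr_clip=(40.0, 140.0),
        af_irregularity_s=(0.04, 0.24),
        hrv_sd_s=(0.02, 0.10),
        amp_cv=(0.05, 0.30),
        morph_var=(0.05, 0.70),
        base_amp=(0.60, 1.20),
        noise_sd=(0.010, 0.080),
        duration_s=90.0,
    ),
}


def simulate_cohort(n_af: int, n_sr: int, seed: int = 0,
                    param_ranges: dict | None = None) -> list[PpgRecord]:
    """Generate a labelled cohort of AF and SR records.

    Per-record parameters are sampled reproducibly from ``param_ranges``
    (see :data:`DEFAULT_COHORT_PARAMS`); per-record seeds derive from the
    master ``seed``.  AF records come first in the returned list.
    """
    if n_af < 0 or n_sr < 0:
        raise ValueError("cohort counts must be non-negative")
    ranges = {k: dict(DEFAULT_COHORT_PARAMS[k]) for k in RHYTHMS}
    if param_ranges:
        for k, v in param_ranges.items():
            ranges[k].update(v)
    rng = np.random.default_rng(seed)
    records: list[PpgRecord] = []
    for label, count in (("AF", n_af), ("SR", n_sr)):
        r = ranges[label]
        for _ in range(count):
            hr_mu, hr_sd = r["mean_hr_bpm"]
            hr = float(np.clip(rng.normal(hr_mu, hr_sd), *r["hr_clip"]))
            cfg = SimConfig(
                rhythm=label,
                duration_s=float(r["duration_s"]),
                mean_hr_bpm=hr,
                hrv_sd_s=float(rng.uniform(*r["hrv_sd_s"])),
                af_irregularity_s=float(rng.uniform(*r["af_irregularity_s"])),
                amp_cv=float(rng.uniform(*r["amp_cv"])),
                morph_var=float(rng.uniform(*r["morph_var"])),
                base_amp=float(rng.uniform(*r["base_amp"])),
                noise_sd=float(rng.uniform(*r["noise_sd"])),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            records.append(simulate_record(cfg))
    return records
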