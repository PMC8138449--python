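"""End-to-end per-record analysis and cohort feature tables."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .features import FEATURE_NAMES, FeatureVector, extract_features
from .preprocess import QualityWindow, interpolate_to, select_quality_window, zero_phase_lowpass
from .records import PpgRecord

log = logging.getLogger(__name__)


def preprocess_record(record: PpgRecord, cfg: PipelineConfig = PipelineConfig()) -> PpgRecord:
    """Interpolate to the working rate and lowpass filter."""
    rec = interpolate_to(record, cfg.target_fs_hz)
    return zero_phase_lowpass(rec, cfg.filter_order, cfg.filter_cutoff_hz)


def analyze_record(record: PpgRecord, cfg: PipelineConfig = PipelineConfig(),
                   detector=None) -> tuple[FeatureVector | None, QualityWindow]:
    """Full per-record pipeline: preprocess, pick the first good 1-min
    window, extract the ten features.  Returns (None, window) when no
    eligible window exists."""
    rec = preprocess_record(record, cfg)
    qw = select_quality_window(rec, cfg.window_s, cfg.min_good_s,
                               cfg.accel_sd_g, cfg.amp_var_tol)
    if not qw.accepted:
        return None, qw
    window = rec.slice(qw.start_s, qw.end_s)
    fv = extract_features(
        window, detector=detector, min_pulses=cfg.min_pulses,
        min_separation_s=cfg.min_separation_s, rel_prominence=cfg.rel_prominence,
        neighborhood_s=cfg.prominence_neighborhood_s, pin_min_s=cfg.pin_min_s,
        pin_max_s=cfg.pin_max_s, amp_halfwidth_s=cfg.amp_halfwidth_s,
        cosen_m=cfg.cosen_m, cosen_r_s=cfg.cosen_r_s, sampen_m=cfg.sampen_m,
        sampen_r_factor=cfg.sampen_r_factor, ac_min_lag_s=cfg.ac_min_lag_s,
        ac_max_lag_s=cfg.ac_max_lag_s, ac_center=cfg.ac_center,
    )
    return fv, qw


def cohort_feature_table(records, cfg: PipelineConfig = PipelineConfig(),
                         detector=None) -> pd.DataFrame:
    """Run the pipeline over a cohort; one row per record with the ten
    features, label and window metadata.  Rejected records appear with
    NaN features and ``accepted=False`` so exclusions stay auditable."""
    rows = []
    for i, rec in enumerate(records):
        fv, qw = analyze_record(rec, cfg, detector=detector)
        row = {"record": i, "window_start_s": qw.start_s,
               "good_fraction": qw.good_fraction, "accepted": qw.accepted,
               "reason": qw.reason}
        if fv is None:
            row.update({k: np.nan for k in FEATURE_NAMES})
            row["label"] = rec.label
            row["analyzable"] = False
            log.warning("record %d rejected (%s)", i, qw.reason)
        else:
            d = fv.as_dict()
            row.update({k: d[k] for k in FEATURE_NAMES})
            row["label"] = d["label"]
            row["analyzable"] = d["analyzable"]
        rows.append(row)
    return pd.DataFrame(rows)


def modeling_frame(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Complete-case feature matrix and 0/1 labels (AF=1) for model
    fitting; windows with any undefined feature are excluded."""
    cols = list(FEATURE_NAMES)
    df = table.dropna(subset=cols)
    df = df[df["label"].isin(["AF", "SR"])]
    y = (df["label"] == "AF").to_numpy(dtype=int)
    return df[cols].reset_index(drop=True), y
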