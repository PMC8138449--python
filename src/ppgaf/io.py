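"""File formats: wrist-band CSV exports, feature tables, model files and
cross-validation reports.

Two PPG CSV dialects are supported.  The ``e4`` dialect mirrors the public
wrist-band export layout: first row the session start timestamp (UNIX
seconds), second row the sampling rate in Hz, then one sample per row (BVP:
one column; ACC: three columns, in g).  The ``plain`` dialect is a header
row followed by ``time,value`` rows; irregular time stamps are resampled to
the median rate with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import CvReport, PredictorModel
from .features import FEATURE_NAMES
from .records import PpgRecord

log = logging.getLogger(__name__)


@dataclass
class E4Export:
    """Paths of one exported recording."""

    bvp_path: Path
    acc_path: Path | None = None
    dialect: str = "e4"  # e4 | plain


class FormatError(ValueError):
    """Malformed input file; the message names the offending line."""


# ---------------------------------------------------------------- writers

def write_bvp_csv(path, samples, fs_hz: float, t0: float = 0.0) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{t0:.6f}\n{fs_hz:.6f}\n")
        fh.writelines(f"{v:.6f}\n" for v in np.asarray(samples, dtype=float))


def write_acc_csv(path, accel, fs_hz: float, t0: float = 0.0) -> None:
    path = Path(path)
    acc = np.asarray(accel, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"{t0:.6f},{t0:.6f},{t0:.6f}\n")
        fh.write(f"{fs_hz:.6f},{fs_hz:.6f},{fs_hz:.6f}\n")
        fh.writelines(",".join(f"{v:.6f}" for v in row) + "\n" for row in acc)


def write_record(directory, record: PpgRecord) -> E4Export:
    """Write one record in the e4 dialect (BVP.csv + optional ACC.csv)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bvp = directory / "BVP.csv"
    write_bvp_csv(bvp, record.samples, record.fs_hz)
    acc = None
    if record.accel is not None:
        acc = directory / "ACC.csv"
        write_acc_csv(acc, record.accel, record.accel_fs_hz or 32.0)
    return E4Export(bvp, acc)


def write_cohort(directory, records) -> Path:
    """Write a cohort as ``rec_NNNN/`` subdirectories plus labels.csv;
    returns the labels path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(records):
        sub = directory / f"rec_{i:04d}"
        write_record(sub, rec)
        rows.append({"record_id": sub.name, "label": rec.label or ""})
    labels = directory / "labels.csv"
    pd.DataFrame(rows).to_csv(labels, index=False)
    return labels


# ---------------------------------------------------------------- readers

def _read_header_float(lines, idx: int, path) -> float:
    try:
        return float(lines[idx].split(",")[0])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: malformed header at line {idx + 1}: "
                          f"{lines[idx]!r}" if idx < len(lines)
                          else f"{path}: missing header line {idx + 1}") from exc


def _read_e4_matrix(path, n_cols: int):
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise FormatError(f"{path}: file too short for the e4 dialect")
    t0 = _read_header_float(lines, 0, path)
    fs = _read_header_float(lines, 1, path)
    if fs <= 0:
        raise FormatError(f"{path}: non-positive sampling rate at line 2")
    try:
        data = np.array([[float(v) for v in ln.split(",")] for ln in lines[2:] if ln],
                        dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: malformed sample row") from exc
    if data.ndim != 2 or data.shape[1] != n_cols:
        raise FormatError(f"{path}: expected {n_cols} column(s)")
    return t0, fs, data


def read_ppg(export: E4Export) -> PpgRecord:
    """Read a PPG recording (and optional accelerometer) into a record."""
    if export.dialect == "e4":
        _, fs, data = _read_e4_matrix(export.bvp_path, 1)
        samples = data[:, 0]
        accel = accel_fs = None
        if export.acc_path is not None:
            _, accel_fs, accel = _read_e4_matrix(export.acc_path, 3)
        log.info("read %d samples at %.1f Hz (%.1f s)", samples.size, fs,
                 samples.size / fs)
        return PpgRecord(samples, fs, accel=accel, accel_fs_hz=accel_fs)
    if export.dialect == "plain":
        df = pd.read_csv(export.bvp_path)
        if df.shape[1] < 2 or df.shape[0] < 2:
            raise FormatError(f"{export.bvp_path}: need a time,value table")
        t = df.iloc[:, 0].to_numpy(dtype=float)
        v = df.iloc[:, 1].to_numpy(dtype=float)
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise FormatError(f"{export.bvp_path}: time stamps not increasing")
        med = float(np.median(dt))
        fs = 1.0 / med
        if np.max(np.abs(dt - med)) > 0.01 * med:
            warnings.warn(f"{export.bvp_path}: irregular time stamps; "
                          f"resampling to the median rate {fs:.3f} Hz",
                          stacklevel=2)
            n = int(round((t[-1] - t[0]) * fs)) + 1
            tu = t[0] + np.arange(n) * med
            v = np.interp(tu, t, v)
        return PpgRecord(v, fs)
    raise ValueError(f"unknown dialect {export.dialect!r}")


def read_cohort(directory) -> tuple[list[PpgRecord], list[str]]:
    """Read a cohort directory written by :func:`write_cohort`."""
    directory = Path(directory)
    labels_df = pd.read_csv(directory / "labels.csv")
    records, labels = [], []
    for _, row in labels_df.iterrows():
        sub = directory / str(row["record_id"])
        acc = sub / "ACC.csv"
        rec = read_ppg(E4Export(sub / "BVP.csv", acc if acc.exists() else None))
        rec.label = str(row["label"]) or None
        records.append(rec)
        labels.append(rec.label)
    return records, labels


# ------------------------------------------------------- tables & models

def write_feature_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing feature columns {missing}")
    return df


def save_model(path, model: PredictorModel) -> None:
    """Serialize a model as a flat key=value text file."""
    with open(path, "w") as fh:
        fh.write(f"cutoff={model.cutoff:.17g}\n")
        fh.write(f"intercept={model.intercept:.17g}\n")
        fh.write("feature_names=" + ",".join(model.feature_names) + "\n")
        for name, coef in zip(model.feature_names, model.coefficients):
            fh.write(f"coef.{name}={coef:.17g}\n")
        for i, (name, p) in enumerate(model.selection_trace, start=1):
            fh.write(f"trace.{i}={name}:{p:.17g}\n")


def load_model(path) -> PredictorModel:
    kv = {}
    trace = []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        key, _, val = ln.partition("=")
        if key.startswith("trace."):
            name, _, p = val.partition(":")
            trace.append((name, float(p)))
        else:
            kv[key] = val
    names = [n for n in kv.get("feature_names", "").split(",") if n]
    coefs = np.array([float(kv[f"coef.{n}"]) for n in names])
    model = PredictorModel(
        intercept=float(kv["intercept"]), coefficients=coefs,
        feature_names=names, cutoff=float(kv["cutoff"]),
    )
    model.selection_trace = trace
    return model


def write_cv_report(prefix, report: CvReport) -> tuple[Path, Path]:
    """Write ``<prefix>_metrics.csv`` (per-fold rows + Mean/Min/Max) and
    ``<prefix>_roc.csv`` (averaged ROC points)."""
    prefix = Path(prefix)
    metrics_path = prefix.with_name(prefix.name + "_metrics.csv")
    roc_path = prefix.with_name(prefix.name + "_roc.csv")
    report.metric_table().to_csv(metrics_path, index=False, float_format="%.6f")
    fpr, tpr = report.roc
    pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(roc_path, index=False,
                                                  float_format="%.6f")
    return metrics_path, roc_path
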