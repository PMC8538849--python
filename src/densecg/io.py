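"""File formats: feature tables (CSV), ECG strips (CSV), YAML configs.

Feature CSVs use the registry names verbatim as header columns (e.g.
``PNN50%``, ``SD1/SD2``) plus a ``label`` column with the class strings
N/AF/O/X; columns are matched by name so order never matters.  ECG
strips are 2-column CSVs (time_s, mv); the sampling rate is inferred
from the time column and records are resampled to 300 Hz when needed.
All writers are locale-independent (period decimal separator, UTF-8).
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

from densecg.errors import FormatError
from densecg.features.registry import FeatureRegistry, default_registry
from densecg.types import CLASSES, ECGRecord

__all__ = [
    "read_feature_table", "write_feature_table",
    "read_ecg", "write_ecg", "read_config",
    "TARGET_FS",
]

TARGET_FS = 300.0


def read_feature_table(path, registry: FeatureRegistry | None = None):
    """Load a feature CSV into (values, labels, missing_mask).

    Columns are matched to the registry by canonical name or sanitized
    alias; unknown columns raise a listing of the offenders, unknown
    labels name the offending value.  Missing cells are accepted, masked
    and imputed as 0.
    """
    reg = registry if registry is not None else default_registry()
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse feature table {path}: {exc}") from exc
    if "label" not in df.columns:
        raise FormatError("feature table must contain a 'label' column")

    resolved = {}
    unknown = []
    for col in df.columns:
        if col == "label":
            continue
        try:
            resolved[reg.get(col).name] = col
        except KeyError:
            unknown.append(col)
    if unknown:
        raise FormatError(f"unknown feature columns: {unknown}")
    absent = [n for n in reg.names if n not in resolved]
    if absent:
        raise FormatError(f"feature table lacks columns: {absent[:5]}"
                          + ("..." if len(absent) > 5 else ""))

    bad = [v for v in df["label"] if v not in CLASSES]
    if bad:
        raise FormatError(f"unknown class label {bad[0]!r} "
                          f"(expected one of {list(CLASSES)})")
    labels = df["label"].to_numpy(dtype=object)

    X = np.empty((len(df), len(reg)), dtype=float)
    for j, name in enumerate(reg.names):
        col = pd.to_numeric(df[resolved[name]], errors="coerce")
        raw = df[resolved[name]]
        nonnum = col.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if nonnum.any():
            r = int(np.argmax(nonnum.to_numpy()))
            raise FormatError(
                f"non-numeric cell at row {r}, column {resolved[name]!r}: "
                f"{raw.iloc[r]!r}")
        X[:, j] = col.to_numpy(dtype=float)
    missing = ~np.isfinite(X)
    X[missing] = 0.0
    return X, labels, missing


def write_feature_table(path, X, labels, registry: FeatureRegistry | None = None,
                        missing_mask=None) -> None:
    """Write a feature CSV with registry-name headers and a label column."""
    reg = registry if registry is not None else default_registry()
    X = np.asarray(X, dtype=float)
    df = pd.DataFrame(X, columns=reg.names)
    if missing_mask is not None:
        df = df.mask(np.asarray(missing_mask, dtype=bool))
    df["label"] = list(labels)
    df.to_csv(path, index=False, float_format="%.17g")


def read_ecg(path, resample: bool = True) -> ECGRecord:
    """Load a 2-column (time_s, mv) ECG CSV; resamples to 300 Hz."""
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse ECG file {path}: {exc}") from exc
    if df.shape[1] < 2 or len(df) < 2:
        raise FormatError(f"{path}: expected >= 2 rows of (time_s, mv)")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    x = df.iloc[:, 1].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0) or not np.all(np.isfinite(x)):
        raise FormatError(f"{path}: time column must increase; samples finite")
    fs = 1.0 / float(np.median(dt))
    name = str(getattr(path, "stem", path))
    if resample and abs(fs - TARGET_FS) > 1e-6:
        frac = Fraction(TARGET_FS / fs).limit_denominator(1000)
        x = sps.resample_poly(x, frac.numerator, frac.denominator)
        fs = TARGET_FS
    return ECGRecord(samples=x, fs=fs, record_id=name)


def write_ecg(path, record: ECGRecord) -> None:
    """Write a record as a 2-column (time_s, mv) CSV."""
    df = pd.DataFrame({"time_s": record.times, "mv": record.samples})
    df.to_csv(path, index=False, float_format="%.9g")


def read_config(path) -> dict:
    """Load a YAML (or JSON, a YAML subset) configuration file."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
    except (OSError, yaml.YAMLError) as exc:
        raise FormatError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise FormatError(f"config {path} must be a mapping")
    return cfg
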