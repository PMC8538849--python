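"""Time-domain TQ-segment features (84-93).

The TQ stretches (T-end to next Q) expose atrial activity free of
ventricular overlap.  Conventions:

* ``Complexity_TQ`` — normalized Lempel-Ziv complexity of the
  median-binarized concatenation of all TQ segments;
* leakage — per segment, the residual power fraction after subtracting
  the best-fitting sinusoid at the segment's dominant frequency (0 for a
  pure tone, near 1 for broadband content);
* period T — 1000 / dominant frequency (ms) per segment;
* ``Median_TQamp`` — median over segments of half the peak-to-peak
  amplitude, an estimate of fibrillatory-wave amplitude.
"""

from __future__ import annotations

import numpy as np

from densecg.features._util import dominant_frequency, lz76_complexity
from densecg.features.pca import tq_segments
from densecg.types import AverageBeat, BeatSet, ECGRecord

__all__ = ["tq_time_features", "segment_leakage"]

_NAMES = ("Complexity_TQ",
          "MeanLeak_TQ", "MinLeak_TQ", "MaxLeak_TQ", "StdLeak_TQ",
          "MeanT_TQ", "MinT_TQ", "MaxT_TQ", "StdT_TQ",
          "Median_TQamp")


def segment_leakage(seg: np.ndarray, fs: float):
    """(leakage, period_ms) of one TQ segment.

    Fits a + b*sin + c*cos at the dominant frequency by least squares;
    leakage is the residual power over the total (mean-removed) power.
    """
    seg = np.asarray(seg, dtype=float)
    f0, _, _ = dominant_frequency(seg, fs, 1.0, 30.0)
    if f0 is None or f0 <= 0:
        return np.nan, np.nan
    t = np.arange(len(seg)) / fs
    A = np.column_stack([np.ones_like(t),
                         np.sin(2 * np.pi * f0 * t),
                         np.cos(2 * np.pi * f0 * t)])
    coef, *_ = np.linalg.lstsq(A, seg, rcond=None)
    resid = seg - A @ coef
    total = np.sum((seg - seg.mean()) ** 2)
    if total <= 0:
        return np.nan, 1000.0 / f0
    return float(np.sum(resid ** 2) / total), 1000.0 / f0


def tq_time_features(record: ECGRecord, beats: BeatSet,
                     avg: AverageBeat) -> dict:
    out = {k: np.nan for k in _NAMES}
    segs = tq_segments(record, beats, avg)
    if len(segs) < 2:
        return out

    concat = np.concatenate(segs)
    out["Complexity_TQ"] = lz76_complexity(concat > np.median(concat))

    leaks, periods = [], []
    for s in segs:
        lk, per = segment_leakage(s, record.fs)
        if np.isfinite(lk):
            leaks.append(lk)
        if np.isfinite(per):
            periods.append(per)
    if leaks:
        leaks = np.array(leaks)
        out["MeanLeak_TQ"] = float(leaks.mean())
        out["MinLeak_TQ"] = float(leaks.min())
        out["MaxLeak_TQ"] = float(leaks.max())
        out["StdLeak_TQ"] = float(leaks.std())
    if periods:
        periods = np.array(periods)
        out["MeanT_TQ"] = float(periods.mean())
        out["MinT_TQ"] = float(periods.min())
        out["MaxT_TQ"] = float(periods.max())
        out["StdT_TQ"] = float(periods.std())

    out["Median_TQamp"] = float(np.median([np.ptp(s) / 2.0 for s in segs]))
    return out
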