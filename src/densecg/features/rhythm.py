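"""Beat-class rhythm features (48-66).

Per-class amplitude and RR statistics over the ventricular and normal
beat populations, the normal-beat proportion, an AF likelihood from RR
irregularity, and a signal-complexity measure.

AF% maps two irregularity measures — the fraction of successive RR
differences exceeding 50 ms and the Poincare dispersion ratio SD1/SD2 —
through a logistic function into [0, 100]; a perfectly regular rhythm
sits at the map's minimum.  Complexity is the normalized Lempel-Ziv
complexity of the median-binarized signal.
"""

from __future__ import annotations

import numpy as np

from densecg.features._util import lz76_complexity
from densecg.features.beats import beat_amplitudes
from densecg.features.hrv import pnn50_fraction, poincare_sd
from densecg.types import BeatSet, ECGRecord

__all__ = ["rhythm_features", "af_probability"]

_NAMES = ("MeanAmpVB", "MinAmpVB", "MaxAmpVB", "StdAmpVB",
          "MeanAmpN", "MinAmpN", "MaxAmpN", "StdAmpN",
          "MeanRRVB", "MinRRVB", "MaxRRVB", "StdRRVB",
          "MeanRRN", "MinRRN", "MaxRRN", "StdRRN",
          "NBeats%", "AF%", "Complexity_ECG")


def _stats(x):
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        return (np.nan,) * 4
    return float(x.mean()), float(x.min()), float(x.max()), float(x.std())


def af_probability(rr_ms: np.ndarray) -> float:
    """Logistic AF likelihood (%) from RR irregularity."""
    frac = pnn50_fraction(rr_ms)
    sd1, sd2 = poincare_sd(rr_ms)
    ratio = sd1 / sd2 if (np.isfinite(sd1) and np.isfinite(sd2) and sd2 > 0) else 0.0
    frac = frac if np.isfinite(frac) else 0.0
    score = 6.0 * frac + 1.5 * min(ratio, 3.0) - 2.5
    return float(100.0 / (1.0 + np.exp(-score)))


def rhythm_features(record: ECGRecord, beats: BeatSet) -> dict:
    out = {k: np.nan for k in _NAMES}
    if len(beats) == 0:
        return out
    fs = record.fs
    amps = beat_amplitudes(record, beats)
    cls = beats.beat_class

    vb = cls == "ventricular"
    nb = cls == "normal"
    (out["MeanAmpVB"], out["MinAmpVB"], out["MaxAmpVB"],
     out["StdAmpVB"]) = _stats(amps[vb])
    (out["MeanAmpN"], out["MinAmpN"], out["MaxAmpN"],
     out["StdAmpN"]) = _stats(amps[nb])

    if len(beats) >= 2:
        rr = beats.rr_ms(fs)
        # the RR interval ending at beat i+1 belongs to beat i+1's class
        rr_cls = cls[1:]
        (out["MeanRRVB"], out["MinRRVB"], out["MaxRRVB"],
         out["StdRRVB"]) = _stats(rr[rr_cls == "ventricular"])
        # normal-to-normal intervals: both endpoints normal
        nn = (cls[:-1] == "normal") & (cls[1:] == "normal")
        (out["MeanRRN"], out["MinRRN"], out["MaxRRN"],
         out["StdRRN"]) = _stats(rr[nn])
        out["AF%"] = af_probability(rr)

    counted = vb.sum() + nb.sum()
    if counted:
        out["NBeats%"] = 100.0 * nb.sum() / counted
    out["Complexity_ECG"] = lz76_complexity(
        record.samples > np.median(record.samples))
    return out
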