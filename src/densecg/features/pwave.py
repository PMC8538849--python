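"""Time-domain P-wave features (72-83).

P-wave candidates are searched inside every RR interval between the end
of the ventricular complex of one beat and the PQ approach of the next
(T-end to next Q, the atrial observation window).  Local maxima of the
baseline-corrected signal exceeding an adaptive threshold (at least
0.04 mV and 2.5 median absolute deviations of the window) count as
P-wave candidates.  Amplitude statistics, PP-interval statistics,
per-interval counts, the share of intervals with multiple P-waves and
the overall P rate follow.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from densecg.types import AverageBeat, BeatSet, ECGRecord

__all__ = ["pwave_features", "detect_p_candidates"]

_NAMES = ("MeanAmpP", "MinAmpP", "MaxAmpP", "StdAmpP",
          "MeanPPint", "MinPPint", "MaxPPint", "StdPPint",
          "MeanPcountRRint", "StdPcountRRint", "DoubleP%", "ratePP")


def detect_p_candidates(record: ECGRecord, beats: BeatSet,
                        avg: AverageBeat):
    """(sample positions, amplitudes, per-RR counts) of P candidates."""
    fs = record.fs
    x = record.samples
    t_end = avg.fiducial_rel_r("T_end")
    q = avg.fiducial_rel_r("Q")
    if t_end is None:
        t_end = int(0.40 * fs)
    if q is None:
        q = -int(0.04 * fs)
    min_dist = max(1, int(0.10 * fs))
    positions, amplitudes, counts = [], [], []
    for r0, r1 in zip(beats.r_peaks[:-1], beats.r_peaks[1:]):
        lo, hi = r0 + t_end, r1 + q
        lo, hi = max(0, lo), min(len(x), hi)
        if hi - lo < min_dist:
            counts.append(0)
            continue
        seg = x[lo:hi]
        base = np.median(seg)
        dev = seg - base
        mad = np.median(np.abs(dev - np.median(dev)))
        thr = max(0.04, 2.5 * mad)
        pk, props = sps.find_peaks(dev, height=thr, distance=min_dist)
        counts.append(len(pk))
        for p, h in zip(pk, props["peak_heights"]):
            positions.append(lo + p)
            amplitudes.append(h)
    return (np.array(positions, dtype=int), np.array(amplitudes, dtype=float),
            np.array(counts, dtype=int))


def pwave_features(record: ECGRecord, beats: BeatSet,
                   avg: AverageBeat) -> dict:
    out = {k: np.nan for k in _NAMES}
    if len(beats) < 2:
        return out
    pos, amp, counts = detect_p_candidates(record, beats, avg)

    if len(amp):
        out["MeanAmpP"] = float(amp.mean())
        out["MinAmpP"] = float(amp.min())
        out["MaxAmpP"] = float(amp.max())
        out["StdAmpP"] = float(amp.std())
    if len(pos) >= 2:
        pp = np.diff(pos) / record.fs * 1000.0
        out["MeanPPint"] = float(pp.mean())
        out["MinPPint"] = float(pp.min())
        out["MaxPPint"] = float(pp.max())
        out["StdPPint"] = float(pp.std())
    if len(counts):
        out["MeanPcountRRint"] = float(counts.mean())
        out["StdPcountRRint"] = float(counts.std())
        out["DoubleP%"] = 100.0 * float(np.mean(counts >= 2))
    out["ratePP"] = 60.0 * len(pos) / record.duration_s
    return out
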