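"""Average-beat morphology features (23-47).

Amplitude statistics, per-beat template correlation, delineation-derived
amplitudes and durations, binary waveform tests (fragmentation, inverted
QRS-T, wide inverted QRS-T a.k.a. the bundle-branch-block pattern) and
maximal curvatures of the P, QRS and T waves.

Curvature is computed on the average beat as |z''| / (1 + z'^2)^(3/2)
with the sample index as abscissa and amplitude in mV, a unit convention
that keeps the quantity scale-comparable across records sampled at the
same rate.
"""

from __future__ import annotations

import numpy as np

from densecg.features._util import max_norm_xcorr
from densecg.features.beats import beat_amplitudes, _beat_windows
from densecg.types import AverageBeat, BeatSet, ECGRecord

__all__ = ["morphology_features"]

_NAMES = ("ECG_range", "stdAmp", "stdAmp%", "rejAmp%",
          "corBeat(mean)", "corBeat(50%)", "corBeat(25%)",
          "P-wave presence", "QRS-amp", "T-amp", "P-amp",
          "J-shift", "J-shift%", "QRS-width", "PQ-int", "TQ-int",
          "Fragmentation", "Inverted QRS-T", "LBBB",
          "maxc(QRS)", "maxc(P)", "maxc(T)",
          "maxc(QRS/P)", "maxc(QRS/T)", "maxc(T/P)")


def _safe_div(a, b):
    return a / b if b not in (0, 0.0) and np.isfinite(b) else np.nan


def _curvature_max(w: np.ndarray, lo: int, hi: int) -> float:
    if hi - lo < 5:
        return np.nan
    seg = w[lo:hi]
    d1 = np.gradient(seg)
    d2 = np.gradient(d1)
    kappa = np.abs(d2) / (1.0 + d1 ** 2) ** 1.5
    return float(np.max(kappa))


def morphology_features(record: ECGRecord, beats: BeatSet,
                        avg: AverageBeat) -> dict:
    out = {k: np.nan for k in _NAMES}
    fs = record.fs
    ms = lambda v: int(round(v / 1000.0 * fs))
    w = avg.waveform
    fid = avg.fiducials

    out["ECG_range"] = float(record.samples.max() - record.samples.min())

    amps = beat_amplitudes(record, beats)
    if len(amps):
        out["stdAmp"] = float(amps.std())
        out["stdAmp%"] = _safe_div(100.0 * amps.std(), amps.mean())
    out["rejAmp%"] = 100.0 * float(np.sum(~avg.included_mask)) / len(beats)

    # per-beat maximal normalized cross-correlation against the average
    pre, post, ok = _beat_windows(record, beats)
    lag = ms(50)
    cors = []
    for i, r in ok:
        c = max_norm_xcorr(record.samples[r - pre: r + post], w, lag)
        if np.isfinite(c):
            cors.append(c)
    if cors:
        cors = np.array(cors)
        out["corBeat(mean)"] = float(cors.mean())
        out["corBeat(50%)"] = float(np.percentile(cors, 50))
        out["corBeat(25%)"] = float(np.percentile(cors, 25))

    baseline = fid.get("baseline", 0.0)
    r = fid.get("R")
    q, s, j = fid.get("Q"), fid.get("S"), fid.get("J")
    t_pk, t_end, p_pk = fid.get("T_peak"), fid.get("T_end"), fid.get("P_peak")

    qrs_amp = np.nan
    if r is not None and s is not None:
        qrs_amp = float(w[r] - w[s])
        out["QRS-amp"] = qrs_amp
    if t_pk is not None and q is not None:
        out["T-amp"] = float(abs(w[t_pk] - w[q]))
    if p_pk is not None and q is not None:
        out["P-amp"] = float(abs(w[p_pk] - w[q]))
    if j is not None and q is not None:
        out["J-shift"] = float(abs(w[j] - w[q]))
        if r is not None and s is not None:
            lo = max(0, q - 2)
            qrspp = float(w[lo:min(len(w), s + 3)].max()
                          - w[lo:min(len(w), s + 3)].min())
            out["J-shift%"] = _safe_div(100.0 * out["J-shift"], qrspp)
    if j is not None and q is not None:
        out["QRS-width"] = (j - q) / fs * 1000.0
    if q is not None and p_pk is not None:
        out["PQ-int"] = (q - p_pk) / fs * 1000.0
    if t_end is not None and q is not None and len(beats) >= 2:
        rr_mean = float(np.mean(beats.rr_ms(fs)))
        out["TQ-int"] = max(rr_mean - (t_end - q) / fs * 1000.0, 0.0)

    # P-wave presence: positive deflection in [-250, -80] ms before R
    # exceeding 0.05 mV and 5% of the QRS amplitude
    if p_pk is not None:
        p_dev = w[p_pk] - baseline
        thr = max(0.05, 0.05 * qrs_amp) if np.isfinite(qrs_amp) else 0.05
        out["P-wave presence"] = float(p_dev > thr)

    # fragmentation: slope inversion within 80 ms left of R with a small
    # amplitude drop (< 30% of QRS-amp)
    if r is not None and np.isfinite(qrs_amp):
        frag = 0.0
        d = np.diff(w)
        lo = max(1, r - ms(80))
        for k in range(r - 2, lo, -1):
            if d[k - 1] < 0 <= d[k]:  # local dip on the upstroke
                if (w[r] - w[k]) < 0.3 * qrs_amp and (w[r] - w[k]) > 0:
                    frag = 1.0
                    break
        out["Fragmentation"] = frag

    if r is not None and t_pk is not None:
        inv = float(np.sign(w[r] - baseline) != np.sign(w[t_pk] - baseline)
                    and (w[t_pk] - baseline) != 0)
        out["Inverted QRS-T"] = inv
        if np.isfinite(out.get("QRS-width", np.nan)) \
                and np.isfinite(out.get("T-amp", np.nan)) \
                and np.isfinite(qrs_amp):
            out["LBBB"] = float(inv == 1.0 and out["QRS-width"] > 140.0
                                and out["T-amp"] > qrs_amp / 3.0)

    # maximal curvature within each wave's window
    if r is not None:
        if q is not None and s is not None:
            out["maxc(QRS)"] = _curvature_max(w, q, s + 1)
        if p_pk is not None:
            out["maxc(P)"] = _curvature_max(w, max(0, p_pk - ms(40)),
                                            min(len(w), p_pk + ms(40)))
        if t_pk is not None:
            out["maxc(T)"] = _curvature_max(w, max(0, t_pk - ms(80)),
                                            min(len(w), t_pk + ms(80)))
    out["maxc(QRS/P)"] = _safe_div(out["maxc(QRS)"], out["maxc(P)"])
    out["maxc(QRS/T)"] = _safe_div(out["maxc(QRS)"], out["maxc(T)"])
    out["maxc(T/P)"] = _safe_div(out["maxc(T)"], out["maxc(P)"])
    return out
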