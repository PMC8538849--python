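"""Spectral TQ-segment features (94-137).

Ventricular activity is suppressed by subtracting the average beat at
every detected R, leaving a residual dominated by atrial activity and
noise.  The residual is cut into non-overlapping 4 s windows and each
window gets a Hann-windowed periodogram zero-padded to 4096 points
(frequency step ~0.073 Hz at 300 Hz).  Per window, restricted to the
3-15 Hz atrial band:

* dominant frequency (DF) — location of the power maximum;
* regularity index (RI) — fraction of band power within +-0.75 Hz of
  the dominant peak (sharpness of the peak);
* first spectral normalized moment (FSNM) — power-weighted mean
  frequency;
* spectral width at levels 0.2/0.4/0.6/0.8 of the normalized maximum —
  span between the lowest and highest band frequency whose normalized
  power meets the level (the enclosing bandwidth);
* spectral area at the same levels — integral of normalized power in
  excess of the level.

Mean/Min/Max/Std over windows of each quantity yield the 44 features.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from densecg.types import AverageBeat, BeatSet, ECGRecord

__all__ = ["tq_frequency_features", "suppress_ventricular", "window_spectrum_stats"]

_LEVELS = (0.2, 0.4, 0.6, 0.8)
_LEVEL_TAGS = ("_02", "_04", "_06", "_08")
BAND = (3.0, 15.0)
NFFT = 4096


def _names():
    n = []
    for q in ("DF", "RI", "FSNM"):
        n += [f"{s}{q}" for s in ("Mean", "Min", "Max", "Std")]
    for kind in ("SpecWidth", "SpecArea"):
        for tag in _LEVEL_TAGS:
            n += [f"{s}{kind}{tag}" for s in ("Mean", "Min", "Max", "Std")]
    return n


_NAMES = _names()


def suppress_ventricular(record: ECGRecord, beats: BeatSet,
                         avg: AverageBeat) -> np.ndarray:
    """Residual signal after subtracting the average beat at each R."""
    resid = record.samples.copy()
    n = len(resid)
    for r in beats.r_peaks:
        lo = r - avg.pre
        hi = r + avg.post
        wlo = max(0, -lo)
        whi = len(avg.waveform) - max(0, hi - n)
        lo, hi = max(0, lo), min(n, hi)
        if whi > wlo:
            resid[lo:hi] -= avg.waveform[wlo:whi]
    return resid


def window_spectrum_stats(x: np.ndarray, fs: float) -> dict | None:
    """DF, RI, FSNM, widths and areas of one 4 s window (None if silent)."""
    if np.allclose(x, x[0]):
        return None
    f, p = sps.periodogram(x, fs=fs, window="hann", nfft=max(NFFT, len(x)))
    band = (f >= BAND[0]) & (f <= BAND[1])
    fb, pb = f[band], p[band]
    if pb.max() <= 0:
        return None
    df = float(fb[np.argmax(pb)])
    total = pb.sum()
    near = np.abs(fb - df) <= 0.75
    out = {
        "DF": df,
        "RI": float(pb[near].sum() / total),
        "FSNM": float((fb * pb).sum() / total),
    }
    pn = pb / pb.max()
    dfreq = fb[1] - fb[0]
    for lev, tag in zip(_LEVELS, _LEVEL_TAGS):
        above = np.where(pn >= lev)[0]
        out[f"SpecWidth{tag}"] = float(fb[above[-1]] - fb[above[0]]) \
            if len(above) else 0.0
        out[f"SpecArea{tag}"] = float(np.clip(pn - lev, 0, None).sum() * dfreq)
    return out


def tq_frequency_features(record: ECGRecord, beats: BeatSet,
                          avg: AverageBeat | None) -> dict:
    out = {k: np.nan for k in _NAMES}
    fs = record.fs
    wlen = int(4.0 * fs)
    if len(record.samples) < wlen:
        return out
    resid = (suppress_ventricular(record, beats, avg)
             if avg is not None and len(beats) else record.samples)

    per_window = []
    for start in range(0, len(resid) - wlen + 1, wlen):
        st = window_spectrum_stats(resid[start:start + wlen], fs)
        if st is not None:
            per_window.append(st)
    if not per_window:
        return out

    keys = per_window[0].keys()
    for q in keys:
        vals = np.array([w[q] for w in per_window])
        out[f"Mean{q}"] = float(vals.mean())
        out[f"Min{q}"] = float(vals.min())
        out[f"Max{q}"] = float(vals.max())
        out[f"Std{q}"] = float(vals.std())
    return out
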