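"""Shared signal-processing helpers for the feature suite."""

from __future__ import annotations

import numpy as np
from scipy import signal


def bandpass(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass."""
    nyq = fs / 2.0
    hi = min(hi, 0.99 * nyq)
    sos = signal.butter(order, [lo / nyq, hi / nyq], btype="band", output="sos")
    return signal.sosfiltfilt(sos, x)


def max_norm_xcorr(beat: np.ndarray, template: np.ndarray, max_lag: int) -> float:
    """Maximal normalized cross-correlation over lags in [-max_lag, max_lag].

    Both inputs must have equal length; each lagged overlap is correlated
    after mean removal (Pearson on the overlapping part).
    """
    n = len(beat)
    best = -1.0
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            a, b = beat[lag:], template[: n - lag]
        else:
            a, b = beat[: n + lag], template[-lag:]
        if len(a) < 4:
            continue
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt((a * a).sum() * (b * b).sum())
        if denom <= 0:
            continue
        best = max(best, float((a * b).sum() / denom))
    return best if best > -1.0 else np.nan


def resample_to(x: np.ndarray, n: int) -> np.ndarray:
    """Linear resampling of a segment to a fixed number of points."""
    if len(x) == n:
        return np.asarray(x, dtype=float)
    src = np.linspace(0.0, 1.0, len(x))
    dst = np.linspace(0.0, 1.0, n)
    return np.interp(dst, src, x)


def lz76_complexity(bits: np.ndarray) -> float:
    """Normalized Lempel-Ziv (1976) complexity of a binary sequence.

    Returns c(n) * log2(n) / n, which tends to 0 for constant sequences
    and to ~1 for i.i.d. fair-coin sequences.
    """
    s = "".join("1" if b else "0" for b in np.asarray(bits).astype(bool))
    n = len(s)
    if n < 2:
        return 0.0
    return _lz76_count(s) * np.log2(n) / n


def _lz76_count(s: str) -> int:
    """Number of distinct phrases in the LZ76 parsing of ``s``."""
    n = len(s)
    i = 0
    c = 1
    u = 1  # length of current prefix
    v = 1  # length of current comparison window
    vmax = v
    while u + v <= n:
        if s[i + v - 1] == s[u + v - 1]:
            v += 1
        else:
            vmax = max(v, vmax)
            i += 1
            if i == u:  # all positions tried: new phrase
                c += 1
                u += vmax
                v = 1
                i = 0
                vmax = v
            else:
                v = 1
    if v != 1:
        c += 1
    return c


def dominant_frequency(x: np.ndarray, fs: float, f_lo: float, f_hi: float,
                       nfft: int = 4096):
    """Dominant frequency of a segment by zero-padded Hann periodogram.

    Returns (frequency, power spectrum, frequency grid) with the search
    restricted to [f_lo, f_hi].  None frequency if the band is empty or
    the segment is silent.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 8 or np.allclose(x, x[0]):
        return None, None, None
    f, p = signal.periodogram(x, fs=fs, window="hann", nfft=max(nfft, len(x)))
    band = (f >= f_lo) & (f <= f_hi)
    if not np.any(band) or p[band].max() <= 0:
        return None, f, p
    fb, pb = f[band], p[band]
    return float(fb[np.argmax(pb)]), f, p
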