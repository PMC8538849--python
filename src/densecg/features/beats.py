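"""QRS detection, average-beat synthesis, delineation and beat typing.

The detector follows the classic band-pass / derivative / squaring /
moving-window-integration scheme: the signal is band-passed to the QRS
energy band (5-18 Hz), differentiated and squared, integrated over a
150 ms window, and candidate peaks above an adaptive threshold (with a
200 ms refractory distance) are refined to the extremum of the raw
signal.  A ``detector_failed`` flag is raised when the detected rate is
implausible (< 20 or > 300 bpm) or any 4 s stretch holds no beat; it
feeds the noise-correction feature.

The average beat is the sample-wise mean over beats on a fixed window
[-250, +450] ms around R, after rejecting beats whose peak absolute
amplitude falls outside meanAmp +- stdAmp.  Fiducial points (P, Q, R, S,
J, T-peak, T-end) are delineated on the average beat and re-used as
per-beat offsets.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from densecg.errors import InsufficientBeatsError, TooShortError
from densecg.features._util import bandpass, max_norm_xcorr
from densecg.types import AverageBeat, BeatSet, ECGRecord

__all__ = ["detect_beats", "build_average_beat", "classify_beats",
           "beat_amplitudes", "PRE_MS", "POST_MS"]

PRE_MS = 250    # averaging window before R
POST_MS = 450   # averaging window after R

MIN_BPM, MAX_BPM = 20.0, 300.0


def detect_beats(record: ECGRecord) -> BeatSet:
    """Locate R-peaks; flags ``detector_failed`` on implausible output."""
    fs = record.fs
    x = record.samples
    if record.duration_s < 2.0:
        raise TooShortError("QRS detection needs at least 2 s of signal")

    filt = bandpass(x, fs, 5.0, 18.0)
    deriv = np.gradient(filt)
    sq = deriv ** 2
    win = max(1, int(round(0.150 * fs)))
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    dist = max(1, int(round(0.25 * fs)))
    cand, _ = sps.find_peaks(integ, distance=dist)
    if len(cand):
        thr = 0.15 * np.percentile(integ[cand], 95)
        cand = cand[integ[cand] > max(thr, 1e-12)]

    # refine each candidate to the raw-signal extremum nearby
    half = int(round(0.075 * fs))
    peaks = []
    for c in cand:
        lo, hi = max(0, c - half), min(len(x), c + half + 1)
        peaks.append(lo + int(np.argmax(np.abs(x[lo:hi]))))
    peaks = np.unique(peaks)
    # collapse refinements closer than the refractory period
    if len(peaks) > 1:
        keep = [peaks[0]]
        for p in peaks[1:]:
            if p - keep[-1] < int(0.2 * fs):
                if np.abs(x[p]) > np.abs(x[keep[-1]]):
                    keep[-1] = p
            else:
                keep.append(p)
        peaks = np.array(keep)

    failed = False
    if len(peaks) < 2:
        failed = True
    else:
        bpm = 60.0 * (len(peaks) - 1) / ((peaks[-1] - peaks[0]) / fs)
        if not MIN_BPM <= bpm <= MAX_BPM:
            failed = True
        seg = int(4.0 * fs)
        for start in range(0, len(x) - seg + 1, seg):
            if not np.any((peaks >= start) & (peaks < start + seg)):
                failed = True
                break
    return BeatSet(r_peaks=peaks, detector_failed=failed)


def beat_amplitudes(record: ECGRecord, beats: BeatSet) -> np.ndarray:
    """Peak absolute amplitude of each detected beat (|signal| at R)."""
    return np.abs(record.samples[beats.r_peaks])


def _beat_windows(record: ECGRecord, beats: BeatSet):
    """Indices of beats whose full averaging window fits in the record."""
    fs = record.fs
    pre = int(round(PRE_MS / 1000.0 * fs))
    post = int(round(POST_MS / 1000.0 * fs))
    ok = [(i, r) for i, r in enumerate(beats.r_peaks)
          if r - pre >= 0 and r + post < len(record.samples)]
    return pre, post, ok


def build_average_beat(record: ECGRecord, beats: BeatSet) -> AverageBeat:
    """Amplitude-outlier-rejected average beat plus delineated fiducials."""
    if len(beats) < 3:
        raise InsufficientBeatsError("average beat needs >= 3 detected beats")
    fs = record.fs
    pre, post, ok = _beat_windows(record, beats)
    if len(ok) < 3:
        raise InsufficientBeatsError("fewer than 3 beats with a full window")

    amps = beat_amplitudes(record, beats)
    mean_a, std_a = amps.mean(), amps.std()
    included = np.zeros(len(beats), dtype=bool)
    window_ok = np.zeros(len(beats), dtype=bool)
    for i, _ in ok:
        window_ok[i] = True
        # reject only strict outliers; a zero-std band keeps every beat
        if np.abs(amps[i] - mean_a) <= std_a or std_a == 0:
            included[i] = True
    if included.sum() < 1:
        included = window_ok.copy()

    stack = np.stack([record.samples[r - pre: r + post]
                      for i, r in ok if included[i]])
    wave = stack.mean(axis=0)
    avg = AverageBeat(waveform=wave, fs=fs, pre=pre, post=post,
                      included_mask=included)
    avg.fiducials = _delineate(wave, fs, pre)
    return avg


def _delineate(w: np.ndarray, fs: float, r_idx: int) -> dict:
    """Fiducial offsets (window samples) on an average-beat waveform."""
    ms = lambda v: int(round(v / 1000.0 * fs))
    n = len(w)
    fid: dict = {}

    # R refined to the absolute extremum close to the nominal position
    lo, hi = max(0, r_idx - ms(30)), min(n, r_idx + ms(30))
    r = lo + int(np.argmax(np.abs(w[lo:hi])))
    fid["R"] = r
    baseline = float(np.median(w[max(0, r - ms(250)): max(1, r - ms(200))]))

    q_lo, q_hi = max(0, r - ms(100)), max(1, r - ms(8))
    if q_hi > q_lo:
        qi = int(np.argmin(w[q_lo:q_hi]))
        if qi == 0:
            # no genuine Q dip (wide monophasic QRS): fall back to the
            # onset where the waveform departs the baseline
            thr = 0.05 * abs(w[r] - baseline)
            q = q_lo
            for k in range(r, q_lo - 1, -1):
                if abs(w[k] - baseline) < thr:
                    q = k
                    break
            fid["Q"] = q
        else:
            fid["Q"] = q_lo + qi
    else:
        fid["Q"] = None

    s_lo, s_hi = min(n - 1, r + ms(8)), min(n, r + ms(100))
    fid["S"] = s_lo + int(np.argmin(w[s_lo:s_hi])) if s_hi > s_lo else None

    # J point: first sample after S where the slope has settled
    j = None
    if fid["S"] is not None:
        d = np.gradient(w)
        qs = slice(fid["Q"] if fid["Q"] is not None else q_lo, s_hi)
        dmax = np.max(np.abs(d[qs])) if qs.stop > qs.start else 0.0
        for k in range(fid["S"] + 1, min(n, fid["S"] + ms(100))):
            if np.abs(d[k]) < 0.05 * dmax:
                j = k
                break
        if j is None:
            j = min(n - 1, fid["S"] + ms(40))
    fid["J"] = j

    t_lo, t_hi = min(n - 1, r + ms(150)), min(n, r + ms(430))
    if t_hi > t_lo:
        t_pk = t_lo + int(np.argmax(np.abs(w[t_lo:t_hi] - baseline)))
        fid["T_peak"] = t_pk
        t_amp = abs(w[t_pk] - baseline)
        t_end = None
        for k in range(t_pk + 1, n):
            if abs(w[k] - baseline) < 0.15 * t_amp:
                t_end = k
                break
        fid["T_end"] = t_end if t_end is not None else n - 1
    else:
        fid["T_peak"] = fid["T_end"] = None

    p_hi = r - ms(80)
    if fid["Q"] is not None:
        p_hi = min(p_hi, fid["Q"] - ms(10))
    p_lo, p_hi = max(0, r - ms(250)), max(1, p_hi)
    if p_hi > p_lo:
        fid["P_peak"] = p_lo + int(np.argmax(w[p_lo:p_hi] - baseline))
    else:
        fid["P_peak"] = None

    fid["baseline"] = baseline
    # enforce P < Q <= R <= S < J < T_peak <= T_end; drop offenders
    last = -1
    for k in ("P_peak", "Q", "R", "S", "J", "T_peak", "T_end"):
        v = fid.get(k)
        if v is None:
            continue
        if v < last and k != "R":
            fid[k] = None
        else:
            last = max(last, v)
    return fid


def classify_beats(record: ECGRecord, beats: BeatSet, avg: AverageBeat,
                   corr_threshold: float = 0.8) -> BeatSet:
    """Label beats normal/ventricular by template correlation.

    A beat is called ventricular when its maximal normalized
    cross-correlation against the average beat (lag search +-50 ms)
    falls below ``corr_threshold``; beats without a full window are
    ``rejected``.
    """
    fs = record.fs
    pre, post, ok = _beat_windows(record, beats)
    lag = int(round(0.050 * fs))
    cls = np.array(["rejected"] * len(beats), dtype=object)
    for i, r in ok:
        beat = record.samples[r - pre: r + post]
        c = max_norm_xcorr(beat, avg.waveform, lag)
        cls[i] = "normal" if (np.isfinite(c) and c >= corr_threshold) \
            else "ventricular"
    return BeatSet(r_peaks=beats.r_peaks, beat_class=cls,
                   detector_failed=beats.detector_failed)
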