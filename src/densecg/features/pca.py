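"""Principal-component deviation features (67-71).

Fixed-length resampled PQRST segments (the averaging window around each
R) and TQ segments are stacked, the rank-1 reconstruction from the first
principal component is subtracted, and the per-segment standard
deviation of the residual quantifies how far each segment departs from
the dominant waveform shape.  Identical segments give zero deviations;
independent additive noise of standard deviation sigma gives deviations
close to sigma.
"""

from __future__ import annotations

import numpy as np

from densecg.features._util import resample_to
from densecg.features.beats import PRE_MS, POST_MS
from densecg.types import AverageBeat, BeatSet, ECGRecord

__all__ = ["pca_features", "pca_deviation_stds", "tq_segments"]

_PQRST_LEN = 128
_TQ_LEN = 64


def pca_deviation_stds(segments: list) -> np.ndarray:
    """Per-segment residual std after first-PC reconstruction."""
    A = np.stack(segments)
    mu = A.mean(axis=0)
    B = A - mu
    # economy SVD; first right-singular vector spans the dominant shape
    _, _, vt = np.linalg.svd(B, full_matrices=False)
    pc1 = vt[0]
    recon = mu + np.outer(B @ pc1, pc1)
    return (A - recon).std(axis=1)


def tq_segments(record: ECGRecord, beats: BeatSet, avg: AverageBeat) -> list:
    """Raw TQ stretches (T-end of beat i to Q of beat i+1)."""
    t_end = avg.fiducial_rel_r("T_end")
    q = avg.fiducial_rel_r("Q")
    if t_end is None or q is None:
        return []
    segs = []
    x = record.samples
    for r0, r1 in zip(beats.r_peaks[:-1], beats.r_peaks[1:]):
        lo, hi = r0 + t_end, r1 + q
        if hi - lo >= int(0.05 * record.fs) and lo >= 0 and hi <= len(x):
            segs.append(x[lo:hi])
    return segs


def pca_features(record: ECGRecord, beats: BeatSet, avg: AverageBeat) -> dict:
    out = {k: np.nan for k in ("MeanStd_PCA_PQRST", "MinStd_PCA_PQRST",
                               "MaxStd_PCA_PQRST", "RangeStd_PCA_PQRST",
                               "MeanStd_PCA_TQ")}
    fs = record.fs
    pre = int(round(PRE_MS / 1000.0 * fs))
    post = int(round(POST_MS / 1000.0 * fs))
    pqrst = [resample_to(record.samples[r - pre: r + post], _PQRST_LEN)
             for r in beats.r_peaks
             if r - pre >= 0 and r + post < len(record.samples)]
    if len(pqrst) >= 3:
        dev = pca_deviation_stds(pqrst)
        out["MeanStd_PCA_PQRST"] = float(dev.mean())
        out["MinStd_PCA_PQRST"] = float(dev.min())
        out["MaxStd_PCA_PQRST"] = float(dev.max())
        out["RangeStd_PCA_PQRST"] = float(dev.max() - dev.min())

    tq = [resample_to(s, _TQ_LEN) for s in tq_segments(record, beats, avg)]
    if len(tq) >= 3:
        out["MeanStd_PCA_TQ"] = float(pca_deviation_stds(tq).mean())
    return out
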