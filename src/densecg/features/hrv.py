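"""Heart-rate-variability statistics (features 2-22).

All statistics are computed on the RR tachogram (ms) and its first
difference dRR.  Conventions:

* ``RRmeand`` is the mean absolute deviation of RR around its mean;
* ``dRRmean``/``dRRmedian`` are mean/median of |dRR| ("deviations"),
  ``dRRstd`` the standard deviation of signed dRR;
* ``PNN50`` (min^-1) is the count of |dRR| > 50 ms divided by the total
  dRR magnitude sum expressed in minutes; ``PNN50%`` the plain count
  proportion;
* the HRV triangular index uses 7.8125 ms histogram bins;
* Poincare SD1/SD2 are the dispersions perpendicular/parallel to the
  identity line of the (RR_n, RR_{n-1}) scatter; CCM is the mean
  triangle area of consecutive point triples normalized by pi*SD1*SD2.

Ratios with zero denominators are reported missing (NaN), never +-inf.
"""

from __future__ import annotations

import numpy as np

__all__ = ["hrv_features", "poincare_sd", "pnn50_fraction"]


def _safe_div(a, b):
    return a / b if b not in (0, 0.0) and np.isfinite(b) else np.nan


def poincare_sd(rr: np.ndarray):
    """(SD1, SD2) of the Poincare scatter of consecutive RR intervals."""
    if len(rr) < 3:
        return np.nan, np.nan
    x, y = rr[1:], rr[:-1]
    sd1 = np.std((x - y) / np.sqrt(2))
    sd2 = np.std((x + y) / np.sqrt(2))
    return float(sd1), float(sd2)


def pnn50_fraction(rr: np.ndarray) -> float:
    """Plain proportion of |dRR| > 50 ms (0..1)."""
    drr = np.diff(rr)
    return float(np.mean(np.abs(drr) > 50.0)) if len(drr) else np.nan


def hrv_features(rr_ms: np.ndarray) -> dict:
    """Features 2-22 from an RR series in milliseconds."""
    rr = np.asarray(rr_ms, dtype=float)
    out = {k: np.nan for k in (
        "RRmean", "RRmedian", "RRstd", "RRmeand", "RRstd%", "RRmeand%", "RRrat",
        "dRRmean", "dRRstd", "dRRmedian", "dRRmean%", "dRRstd%", "dRRmedian%",
        "PNN50", "PNN50%", "RMSSD", "RMSSD%", "HRV TrIdx", "SD1/SD2", "CCM",
        "corRR")}
    if len(rr) < 2:
        return out

    rrmean = rr.mean()
    rrmedian = float(np.median(rr))
    out["RRmean"] = rrmean
    out["RRmedian"] = rrmedian
    out["RRstd"] = float(rr.std())
    out["RRmeand"] = float(np.mean(np.abs(rr - rrmean)))
    out["RRstd%"] = _safe_div(100.0 * out["RRstd"], rrmean)
    out["RRmeand%"] = _safe_div(100.0 * out["RRmeand"], rrmean)
    out["RRrat"] = _safe_div(rrmean, rrmedian)

    drr = np.diff(rr)
    if len(drr) >= 1:
        out["dRRmean"] = float(np.mean(np.abs(drr)))
        out["dRRstd"] = float(np.std(drr))
        out["dRRmedian"] = float(np.median(np.abs(drr)))
        out["dRRmean%"] = _safe_div(100.0 * out["dRRmean"], rrmean)
        out["dRRstd%"] = _safe_div(100.0 * out["dRRstd"], rrmean)
        out["dRRmedian%"] = _safe_div(100.0 * out["dRRmedian"], rrmean)
        n50 = int(np.sum(np.abs(drr) > 50.0))
        total_drr_min = np.sum(np.abs(drr)) / 60000.0  # ms -> minutes
        out["PNN50"] = _safe_div(n50, total_drr_min) if total_drr_min > 0 else (
            0.0 if n50 == 0 else np.nan)
        out["PNN50%"] = 100.0 * n50 / len(drr)
        out["RMSSD"] = float(np.sqrt(np.mean(drr ** 2)))
        out["RMSSD%"] = _safe_div(100.0 * out["RMSSD"], rrmean)

    # triangular index: total count over modal-bin count, 7.8125 ms bins
    if len(rr) >= 2:
        lo = np.floor(rr.min() / 7.8125) * 7.8125
        nbins = max(1, int(np.ceil((rr.max() - lo) / 7.8125)) + 1)
        hist, _ = np.histogram(rr, bins=nbins,
                               range=(lo, lo + nbins * 7.8125))
        out["HRV TrIdx"] = _safe_div(float(len(rr)), float(hist.max()))

    sd1, sd2 = poincare_sd(rr)
    out["SD1/SD2"] = _safe_div(sd1, sd2)
    if len(rr) >= 4 and np.isfinite(sd1) and np.isfinite(sd2) \
            and sd1 > 0 and sd2 > 0:
        x, y = rr[1:], rr[:-1]
        areas = []
        for i in range(len(x) - 2):
            p = np.array([[x[i], y[i]], [x[i + 1], y[i + 1]],
                          [x[i + 2], y[i + 2]]])
            areas.append(0.5 * abs(
                (p[1, 0] - p[0, 0]) * (p[2, 1] - p[0, 1])
                - (p[2, 0] - p[0, 0]) * (p[1, 1] - p[0, 1])))
        out["CCM"] = float(np.mean(areas) / (np.pi * sd1 * sd2))

    if len(rr) >= 3:
        x, y = rr[1:], rr[:-1]
        if x.std() > 0 and y.std() > 0:
            out["corRR"] = float(np.corrcoef(x, y)[0, 1])
    return out
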