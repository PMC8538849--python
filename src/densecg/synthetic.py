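"""Synthetic single-lead ECG strips, feature tables and fixture networks.

The ECG generator emulates the recording conditions of short hand-held
single-lead devices: 300 Hz sampling, 0.5-40 Hz analog bandwidth, +-5 mV
dynamic range, strips of 9-61 s.  Beats are synthesized as sums of
Gaussian bumps for the P, Q, R, S and T deflections on top of an RR
process chosen per rhythm class:

* ``N``  — near-constant RR (coefficient of variation ``rr_jitter``,
  default 0.03) with a P-wave before every QRS;
* ``AF`` — i.i.d. log-normal RR with CV >= 0.15 ("irregularly
  irregular"), no P deflection, and an additive sinusoidal fibrillatory
  f-wave of configurable amplitude and frequency (4-10 Hz);
* ``O``  — sinus rhythm with ectopic (wide, premature, P-less)
  ventricular beats inserted per pattern (bigeminy / trigeminy / random);
* ``X``  — beats buried under baseline wander and band-limited EMG noise
  whose amplitudes dominate the QRS amplitude.

Every generator is a pure function of its spec (including the seed), and
ground-truth beat and P-wave positions are returned alongside the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from densecg.errors import InvalidSpecError, ShapeError
from densecg.types import CLASSES, DYNAMIC_RANGE_MV, ECGRecord
from densecg.net import BNParams, DenseParams, Topology, TrainedModel, BN_EPS

__all__ = [
    "RhythmSpec", "TableSpec", "GroundTruth",
    "generate_ecg", "generate_feature_table", "fixture_network",
    "beat_template",
]

# Gaussian bump parameters of the normal beat template:
# (amplitude mV, center offset s relative to R, width s)
_NORMAL_WAVES = {
    "P": (0.15, -0.170, 0.025),
    "Q": (-0.08, -0.035, 0.010),
    "R": (1.00, 0.000, 0.012),
    "S": (-0.18, 0.030, 0.010),
    "T": (0.32, 0.270, 0.055),
}
# Ventricular ectopic template: wide, large, no P, discordant T.
_PVC_WAVES = {
    "R": (1.35, 0.000, 0.034),
    "S": (-0.35, 0.060, 0.025),
    "T": (-0.38, 0.300, 0.070),
}

_DEFAULT_JITTER = {"N": 0.03, "AF": 0.25, "O": 0.04, "X": 0.03}


@dataclass
class RhythmSpec:
    """Parameters of one synthetic rhythm strip."""

    rhythm_class: str = "N"
    duration_s: float = 30.0
    fs: float = 300.0
    mean_hr_bpm: float = 75.0
    rr_jitter: float | None = None   # CV of RR; per-class default if None
    p_wave: bool | None = None       # per-class default if None
    f_wave_amp_mv: float = 0.1       # AF only
    f_wave_freq_hz: float = 6.0      # in [4, 10]
    ectopy_pattern: str = "none"     # none | bigeminy | trigeminy | random_pvc
    baseline_wander_amp_mv: float = 0.0
    emg_noise_amp_mv: float = 0.0
    powerline_amp_mv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.rhythm_class not in CLASSES:
            raise InvalidSpecError(f"unknown rhythm class {self.rhythm_class!r}")
        if self.fs <= 0 or self.duration_s <= 0:
            raise InvalidSpecError("duration and sampling rate must be positive")
        if not (9.0 <= self.duration_s <= 61.0):
            raise InvalidSpecError("duration_s must lie in [9, 61] s")
        if self.rr_jitter is None:
            self.rr_jitter = _DEFAULT_JITTER[self.rhythm_class]
        if self.rr_jitter < 0:
            raise InvalidSpecError("rr_jitter must be >= 0")
        if self.rhythm_class == "AF" and self.rr_jitter < 0.15:
            raise InvalidSpecError("AF requires rr_jitter >= 0.15")
        for a in (self.f_wave_amp_mv, self.baseline_wander_amp_mv,
                  self.emg_noise_amp_mv, self.powerline_amp_mv):
            if a < 0:
                raise InvalidSpecError("amplitudes must be >= 0")
        if not (4.0 <= self.f_wave_freq_hz <= 10.0):
            raise InvalidSpecError("f_wave_freq_hz must lie in [4, 10] Hz")
        if self.p_wave is None:
            self.p_wave = self.rhythm_class != "AF"
        if self.ectopy_pattern not in ("none", "bigeminy", "trigeminy", "random_pvc"):
            raise InvalidSpecError(f"unknown ectopy pattern {self.ectopy_pattern!r}")
        if self.rhythm_class == "O" and self.ectopy_pattern == "none":
            self.ectopy_pattern = "random_pvc"
        if self.rhythm_class == "X" and self.baseline_wander_amp_mv == 0 \
                and self.emg_noise_amp_mv == 0:
            # noise dominates QRS: default 2x the R amplitude
            self.baseline_wander_amp_mv = 2.0
            self.emg_noise_amp_mv = 2.0


@dataclass
class GroundTruth:
    """Synthesis-time truth accompanying a generated strip."""

    r_peaks: np.ndarray          # sample index of every synthesized R
    p_peaks: np.ndarray          # sample index of every synthesized P
    beat_class: np.ndarray       # "normal" / "ventricular" per beat
    rr_s: np.ndarray             # RR intervals used (s)


def _rr_sequence(spec: RhythmSpec, rng: np.random.Generator) -> np.ndarray:
    mean_rr = 60.0 / spec.mean_hr_bpm
    n_max = int(np.ceil(spec.duration_s / mean_rr)) + 8
    cv = spec.rr_jitter
    if cv == 0:
        return np.full(n_max, mean_rr)
    if spec.rhythm_class == "AF":
        # i.i.d. log-normal with the requested CV of RR
        sigma = np.sqrt(np.log1p(cv ** 2))
        mu = np.log(mean_rr) - sigma ** 2 / 2.0
        rr = rng.lognormal(mu, sigma, size=n_max)
    else:
        rr = rng.normal(mean_rr, cv * mean_rr, size=n_max)
    return np.clip(rr, 0.3 * mean_rr, 2.5 * mean_rr)


def beat_template(t: np.ndarray, waves: dict, include_p: bool = True) -> np.ndarray:
    """Evaluate a sum-of-Gaussians beat template at times ``t`` (s rel. R)."""
    y = np.zeros_like(t, dtype=float)
    for name, (amp, mu, sd) in waves.items():
        if name == "P" and not include_p:
            continue
        y += amp * np.exp(-0.5 * ((t - mu) / sd) ** 2)
    return y


def generate_ecg(spec: RhythmSpec) -> tuple[ECGRecord, GroundTruth]:
    """Synthesize one strip; returns the record and ground-truth positions."""
    rng = np.random.default_rng(spec.seed)
    fs, dur = spec.fs, spec.duration_s
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    sig = np.zeros(n)

    rr = _rr_sequence(spec, rng)
    mean_rr = 60.0 / spec.mean_hr_bpm
    r_times = []
    beat_kind = []
    tcur = 0.45 * mean_rr
    i = 0
    while tcur < dur - 0.15 and i < len(rr):
        r_times.append(tcur)
        beat_kind.append("normal")
        tcur += rr[i]
        i += 1
    r_times = np.array(r_times)
    beat_kind = np.array(beat_kind, dtype=object)

    # ectopy: replace selected sinus beats by premature ventricular beats
    if spec.ectopy_pattern != "none" and len(r_times) > 3:
        idx = np.arange(1, len(r_times) - 1)
        if spec.ectopy_pattern == "bigeminy":
            pvc = idx[idx % 2 == 1]
        elif spec.ectopy_pattern == "trigeminy":
            pvc = idx[idx % 3 == 2]
        else:
            pvc = idx[rng.random(len(idx)) < 0.15]
        for k in pvc:
            beat_kind[k] = "ventricular"
            r_times[k] -= 0.18 * mean_rr  # prematurity

    p_times = []
    for rt, kind in zip(r_times, beat_kind):
        rel = t - rt
        m = np.abs(rel) < 0.6  # only evaluate near the beat
        if kind == "ventricular":
            sig[m] += beat_template(rel[m], _PVC_WAVES)
        else:
            sig[m] += beat_template(rel[m], _NORMAL_WAVES, include_p=spec.p_wave)
            if spec.p_wave:
                p_times.append(rt + _NORMAL_WAVES["P"][1])

    if spec.rhythm_class == "AF" and spec.f_wave_amp_mv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        sig += spec.f_wave_amp_mv * np.sin(2 * np.pi * spec.f_wave_freq_hz * t + phase)

    if spec.baseline_wander_amp_mv > 0:
        sig += spec.baseline_wander_amp_mv * np.sin(
            2 * np.pi * 0.33 * t + rng.uniform(0, 2 * np.pi))
    if spec.emg_noise_amp_mv > 0:
        emg = rng.normal(0.0, 1.0, n)
        emg = signal.sosfiltfilt(
            signal.butter(4, [15 / (fs / 2), min(45, 0.49 * fs) / (fs / 2)],
                          btype="band", output="sos"), emg)
        emg *= spec.emg_noise_amp_mv / max(emg.std(), 1e-12)
        sig += emg
    if spec.powerline_amp_mv > 0:
        sig += spec.powerline_amp_mv * np.sin(2 * np.pi * 50.0 * t)

    # device bandwidth and dynamic range
    sos = signal.butter(2, [0.5 / (fs / 2), min(40.0, 0.49 * fs) / (fs / 2)],
                        btype="band", output="sos")
    sig = signal.sosfiltfilt(sos, sig)
    sig = np.clip(sig, -DYNAMIC_RANGE_MV, DYNAMIC_RANGE_MV)

    rec = ECGRecord(sig, fs, record_id=f"syn-{spec.rhythm_class}-{spec.seed}")
    gt = GroundTruth(
        r_peaks=np.round(np.asarray(r_times) * fs).astype(int),
        p_peaks=np.round(np.asarray(p_times) * fs).astype(int),
        beat_class=beat_kind,
        rr_s=np.diff(r_times),
    )
    return rec, gt


# ---------------------------------------------------------------------------
# class-structured feature tables


@dataclass
class TableSpec:
    """Class-conditional Gaussian feature-table generator spec.

    ``informative_features`` maps a 0-based feature column to per-class
    mean shifts, e.g. ``{3: {"AF": 2.0}}`` shifts column 3 by +2 (in
    native units) for AF rows only.  ``feature_scales`` emulates the
    heterogeneous native units of real feature tables.
    """

    n_per_class: dict = field(default_factory=lambda: {c: 100 for c in CLASSES})
    n_features: int = 137
    informative_features: dict = field(default_factory=dict)
    noise_sd: float = 1.0
    baseline: float = 0.0
    feature_scales: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise InvalidSpecError("noise_sd must be > 0")
        if any(v < 0 for v in self.n_per_class.values()):
            raise InvalidSpecError("class counts must be >= 0")
        if sum(self.n_per_class.values()) == 0:
            raise InvalidSpecError("at least one class count must be positive")
        if self.informative_features and \
                max(self.informative_features) >= self.n_features:
            raise InvalidSpecError("informative feature index out of range")


def generate_feature_table(spec: TableSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw a stratified class-conditional Gaussian feature table.

    Returns ``(X, labels)`` with ``X`` of shape (sum n_per_class,
    n_features) and labels from ``CLASSES`` in contiguous class blocks.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    labels = []
    for c in CLASSES:
        nc = spec.n_per_class.get(c, 0)
        if nc == 0:
            continue
        mu = np.full(spec.n_features, spec.baseline, dtype=float)
        for j, shifts in spec.informative_features.items():
            mu[j] += shifts.get(c, 0.0)
        rows.append(rng.normal(mu, spec.noise_sd, size=(nc, spec.n_features)))
        labels += [c] * nc
    X = np.vstack(rows)
    if spec.feature_scales is not None:
        X = X * np.asarray(spec.feature_scales, dtype=float)
    return X, np.array(labels, dtype=object)


# ---------------------------------------------------------------------------
# fixture networks


def fixture_network(widths, weight_rule: str = "indexed",
                    weights=None, biases=None) -> TrainedModel:
    """Build a deterministic hand-set model for oracle tests.

    ``widths`` lists every layer size including input and output, e.g.
    ``[3, 4, 3, 2]`` is a net with 3 inputs, hidden layers of 4 and 3,
    and 2 outputs.  The batch-normalization layer is the identity
    (gamma=1, beta=0, mean=0, var chosen so that the scale factor is
    exactly 1) and dropout is disabled.

    weight_rule:
      ``all_ones``  — every weight 1, every bias 0;
      ``indexed``   — W_l[i, j] = (l+1) + (i+1)/10 + (j+1)/100, scaled to
        keep magnitudes small; distinct, reproducible values;
      ``explicit``  — caller-supplied ``weights`` (list of matrices) and
        optional ``biases``.
    """
    widths = [int(w) for w in widths]
    if len(widths) < 2:
        raise InvalidSpecError("need at least input and output widths")
    topo = Topology(n_inputs=widths[0], hidden_widths=tuple(widths[1:-1]),
                    n_classes=widths[-1])
    shapes = [(widths[i], widths[i + 1]) for i in range(len(widths) - 1)]

    if weight_rule == "all_ones":
        W = [np.ones(s) for s in shapes]
        b = [np.zeros(s[1]) for s in shapes]
    elif weight_rule == "indexed":
        W = []
        for li, (m, k) in enumerate(shapes):
            ii, jj = np.meshgrid(np.arange(m), np.arange(k), indexing="ij")
            W.append(0.1 * ((li + 1) + (ii + 1) / 10.0 + (jj + 1) / 100.0))
        b = [np.full(s[1], 0.01 * (i + 1)) for i, s in enumerate(shapes)]
    elif weight_rule == "explicit":
        if weights is None or len(weights) != len(shapes):
            raise ShapeError("explicit rule requires one matrix per dense layer")
        W = [np.asarray(w, dtype=float) for w in weights]
        for w, s in zip(W, shapes):
            if w.shape != s:
                raise ShapeError(f"weight shape {w.shape} != expected {s}")
        if biases is None:
            b = [np.zeros(s[1]) for s in shapes]
        else:
            b = [np.asarray(x, dtype=float) for x in biases]
            for bb, s in zip(b, shapes):
                if bb.shape != (s[1],):
                    raise ShapeError(f"bias shape {bb.shape} != expected ({s[1]},)")
    else:
        raise InvalidSpecError(f"unknown weight rule {weight_rule!r}")

    n_in = widths[0]
    bn = BNParams(gamma=np.ones(n_in), beta=np.zeros(n_in),
                  mean=np.zeros(n_in), var=np.full(n_in, 1.0 - BN_EPS))
    return TrainedModel(topology=topo, bn=bn, dense=DenseParams(W=W, b=b),
                        meta={"fixture": weight_rule})
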