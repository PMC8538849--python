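"""Core domain containers shared by the signal, feature and model layers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from densecg.errors import InvalidSpecError

#: Fixed rhythm-class ordering used everywhere in the package.
CLASSES = ("N", "AF", "O", "X")

#: Dynamic range of the recording device (mV).
DYNAMIC_RANGE_MV = 5.0


@dataclass
class ECGRecord:
    """A single-lead ECG strip in millivolt at a given sampling rate."""

    samples: np.ndarray
    fs: float
    record_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise InvalidSpecError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidSpecError("ECG samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


@dataclass
class BeatSet:
    """Detected R-peaks with per-beat class labels.

    ``beat_class`` entries are ``"normal"``, ``"ventricular"`` or
    ``"rejected"``.  ``detector_failed`` is raised when the detected rate
    is implausible or any 4 s stretch contains no beat; it feeds the
    noise-correction flag (feature 1).
    """

    r_peaks: np.ndarray
    beat_class: np.ndarray | None = None
    detector_failed: bool = False

    def __post_init__(self):
        self.r_peaks = np.asarray(self.r_peaks, dtype=int)
        if len(self.r_peaks) > 1 and np.any(np.diff(self.r_peaks) <= 0):
            raise InvalidSpecError("r_peaks must be strictly increasing")
        if self.beat_class is None:
            self.beat_class = np.array(["normal"] * len(self.r_peaks), dtype=object)
        else:
            self.beat_class = np.asarray(self.beat_class, dtype=object)

    def __len__(self):
        return len(self.r_peaks)

    def rr_ms(self, fs: float) -> np.ndarray:
        """RR intervals in milliseconds."""
        return np.diff(self.r_peaks) / fs * 1000.0


@dataclass
class AverageBeat:
    """Sample-wise mean of aligned beats after amplitude-outlier rejection.

    The waveform lives on a fixed window around the R-peak; fiducial
    offsets are expressed in samples relative to the start of the window.
    """

    waveform: np.ndarray
    fs: float
    pre: int    # samples before R in the window
    post: int   # samples after R
    included_mask: np.ndarray = None
    fiducials: dict = field(default_factory=dict)  # name -> window offset (samples)

    @property
    def r_index(self) -> int:
        return self.pre

    def fiducial_rel_r(self, name: str):
        """Offset of a fiducial relative to R, in samples (None if absent)."""
        if name not in self.fiducials or self.fiducials[name] is None:
            return None
        return int(self.fiducials[name]) - self.pre


@dataclass
class FeatureVector:
    """The 137 features of one record in canonical registry order."""

    values: np.ndarray
    missing_mask: np.ndarray
    record_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != self.missing_mask.shape:
            raise InvalidSpecError("values and missing_mask must align")
        if not np.all(np.isfinite(self.values[~self.missing_mask])):
            raise InvalidSpecError("non-missing feature values must be finite")
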