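"""The ordered registry of the 137 diagnostic ECG features.

Feature names follow the field's conventional labels (e.g. ``PNN50%``,
``SD1/SD2``, ``corBeat(50%)``).  Because several names contain characters
that many downstream tools reject, every entry also carries a sanitized
alias (``PNN50pct``, ``SD1_over_SD2`` ...) with a documented one-to-one
mapping.

Families
--------
noise        1        noise-correction trigger flag
hrv          2-22     heart-rate-variability statistics
morphology   23-47    average-beat morphology, delineation, curvature
rhythm       48-66    per-beat-class statistics, AF likelihood, complexity
pca          67-71    principal-component deviations of PQRST/TQ segments
pwave        72-83    time-domain P-wave analysis
tq_time      84-93    time-domain TQ-segment (atrial activity) analysis
tq_freq      94-137   spectral TQ-segment analysis over 4 s windows
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["FeatureEntry", "FeatureRegistry", "default_registry"]


@dataclass(frozen=True)
class FeatureEntry:
    index: int  # 1-based position in the canonical ordering
    name: str
    family: str
    units: str

    @property
    def alias(self) -> str:
        """Sanitized identifier safe for CSV headers / attribute access."""
        s = self.name
        s = s.replace("%", "pct").replace("/", "_over_")
        s = s.replace("(", "_").replace(")", "")
        s = re.sub(r"[ \-]", "_", s)
        return s


def _stats4(prefix: str, suffix: str, units: str, family: str, start: int):
    names = [f"{s}{prefix}{suffix}" for s in ("Mean", "Min", "Max", "Std")]
    return [(start + i, n, family, units) for i, n in enumerate(names)]


def _build_entries():
    e: list[tuple[int, str, str, str]] = []
    e.append((1, "Noise correction", "noise", "binary"))

    hrv = [
        ("RRmean", "ms"), ("RRmedian", "ms"), ("RRstd", "ms"), ("RRmeand", "ms"),
        ("RRstd%", "%"), ("RRmeand%", "%"), ("RRrat", ""),
        ("dRRmean", "ms"), ("dRRstd", "ms"), ("dRRmedian", "ms"),
        ("dRRmean%", "%"), ("dRRstd%", "%"), ("dRRmedian%", "%"),
        ("PNN50", "1/min"), ("PNN50%", "%"), ("RMSSD", "ms"), ("RMSSD%", "%"),
        ("HRV TrIdx", ""), ("SD1/SD2", ""), ("CCM", ""), ("corRR", ""),
    ]
    e += [(2 + i, n, "hrv", u) for i, (n, u) in enumerate(hrv)]

    morph = [
        ("ECG_range", "mV"), ("stdAmp", "mV"), ("stdAmp%", "%"), ("rejAmp%", "%"),
        ("corBeat(mean)", ""), ("corBeat(50%)", ""), ("corBeat(25%)", ""),
        ("P-wave presence", "binary"), ("QRS-amp", "mV"), ("T-amp", "mV"),
        ("P-amp", "mV"), ("J-shift", "mV"), ("J-shift%", "%"),
        ("QRS-width", "ms"), ("PQ-int", "ms"), ("TQ-int", "ms"),
        ("Fragmentation", "binary"), ("Inverted QRS-T", "binary"), ("LBBB", "binary"),
        ("maxc(QRS)", ""), ("maxc(P)", ""), ("maxc(T)", ""),
        ("maxc(QRS/P)", ""), ("maxc(QRS/T)", ""), ("maxc(T/P)", ""),
    ]
    e += [(23 + i, n, "morphology", u) for i, (n, u) in enumerate(morph)]

    e += _stats4("Amp", "VB", "mV", "rhythm", 48)
    e += _stats4("Amp", "N", "mV", "rhythm", 52)
    e += _stats4("RR", "VB", "ms", "rhythm", 56)
    e += _stats4("RR", "N", "ms", "rhythm", 60)
    e += [(64, "NBeats%", "rhythm", "%"), (65, "AF%", "rhythm", "%"),
          (66, "Complexity_ECG", "rhythm", "")]

    e += [(67, "MeanStd_PCA_PQRST", "pca", "mV"), (68, "MinStd_PCA_PQRST", "pca", "mV"),
          (69, "MaxStd_PCA_PQRST", "pca", "mV"), (70, "RangeStd_PCA_PQRST", "pca", "mV"),
          (71, "MeanStd_PCA_TQ", "pca", "mV")]

    e += _stats4("Amp", "P", "mV", "pwave", 72)
    e += _stats4("PPint", "", "ms", "pwave", 76)
    e += [(80, "MeanPcountRRint", "pwave", ""), (81, "StdPcountRRint", "pwave", ""),
          (82, "DoubleP%", "pwave", "%"), (83, "ratePP", "pwave", "1/min")]

    e += [(84, "Complexity_TQ", "tq_time", "")]
    e += _stats4("Leak", "_TQ", "", "tq_time", 85)
    e += _stats4("T", "_TQ", "ms", "tq_time", 89)
    e += [(93, "Median_TQamp", "tq_time", "mV")]

    e += _stats4("DF", "", "Hz", "tq_freq", 94)
    e += _stats4("RI", "", "", "tq_freq", 98)
    e += _stats4("FSNM", "", "Hz", "tq_freq", 102)
    idx = 106
    for lev in ("_02", "_04", "_06", "_08"):
        e += _stats4("SpecWidth", lev, "Hz", "tq_freq", idx)
        idx += 4
    for lev in ("_02", "_04", "_06", "_08"):
        e += _stats4("SpecArea", lev, "Hz", "tq_freq", idx)
        idx += 4
    return e


class FeatureRegistry:
    """Ordered, immutable collection of the 137 feature definitions."""

    def __init__(self, entries=None):
        raw = entries if entries is not None else _build_entries()
        self.entries = tuple(FeatureEntry(*t) if not isinstance(t, FeatureEntry) else t
                             for t in raw)
        names = [fe.name for fe in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in registry")
        idx = [fe.index for fe in self.entries]
        if idx != list(range(1, len(idx) + 1)):
            raise ValueError("registry indices must be contiguous from 1")
        self._by_name = {fe.name: fe for fe in self.entries}
        self._by_alias = {fe.alias: fe for fe in self.entries}

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def names(self) -> list[str]:
        return [fe.name for fe in self.entries]

    @property
    def aliases(self) -> list[str]:
        return [fe.alias for fe in self.entries]

    def get(self, key: str) -> FeatureEntry:
        """Look a feature up by canonical name or sanitized alias."""
        if key in self._by_name:
            return self._by_name[key]
        if key in self._by_alias:
            return self._by_alias[key]
        raise KeyError(key)

    def position(self, key: str) -> int:
        """0-based array position of a feature."""
        return self.get(key).index - 1

    def alias_map(self) -> dict:
        """Mapping canonical name -> sanitized alias."""
        return {fe.name: fe.alias for fe in self.entries}

    def binary_features(self) -> list[str]:
        return [fe.name for fe in self.entries if fe.units == "binary"]

    def percent_features(self) -> list[str]:
        return [fe.name for fe in self.entries if fe.units == "%"]


def default_registry() -> FeatureRegistry:
    """The canonical 137-entry registry."""
    return FeatureRegistry()
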