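"""End-to-end feature extraction: record in, 137-vector out.

The pipeline runs QRS detection, average-beat synthesis and delineation,
beat typing, and the seven feature families.  Stages that cannot run
(detector failure, too few beats, absent fiducials) leave their features
missing; missing values are imputed as 0 after being recorded in the
missing mask (the classifier's batch-normalization layer re-centers
inputs, and the mask is retained for audit).  Feature 1 is the
noise-correction trigger: 1 when QRS detection failed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from densecg.errors import InsufficientBeatsError
from densecg.features.beats import build_average_beat, classify_beats, detect_beats
from densecg.features.hrv import hrv_features
from densecg.features.morphology import morphology_features
from densecg.features.pca import pca_features
from densecg.features.pwave import pwave_features
from densecg.features.registry import FeatureRegistry, default_registry
from densecg.features.rhythm import rhythm_features
from densecg.features.tq_freq import tq_frequency_features
from densecg.features.tq_time import tq_time_features
from densecg.types import ECGRecord, FeatureVector

__all__ = ["extract_feature_vector", "extract_table"]


def extract_feature_vector(record: ECGRecord,
                           registry: FeatureRegistry | None = None) -> FeatureVector:
    """Compute all 137 features of one record in registry order."""
    reg = registry if registry is not None else default_registry()
    feats: dict = {}

    beats = detect_beats(record)
    feats["Noise correction"] = 1.0 if beats.detector_failed else 0.0

    avg = None
    if not beats.detector_failed and len(beats) >= 3:
        try:
            avg = build_average_beat(record, beats)
            beats = classify_beats(record, beats, avg)
        except InsufficientBeatsError:
            avg = None

    feats.update(hrv_features(beats.rr_ms(record.fs)))
    if avg is not None:
        feats.update(morphology_features(record, beats, avg))
        feats.update(pca_features(record, beats, avg))
        feats.update(pwave_features(record, beats, avg))
        feats.update(tq_time_features(record, beats, avg))
    feats.update(rhythm_features(record, beats))
    feats.update(tq_frequency_features(record, beats, avg))

    values = np.array([feats.get(name, np.nan) for name in reg.names],
                      dtype=float)
    missing = ~np.isfinite(values)
    values[missing] = 0.0  # imputation; the mask keeps the audit trail
    return FeatureVector(values=values, missing_mask=missing,
                         record_id=record.record_id)


def extract_table(records, registry: FeatureRegistry | None = None,
                  labels=None) -> pd.DataFrame:
    """Extract a feature table (one row per record, registry columns).

    ``labels``, when given, adds a ``label`` column; the row index is the
    record id.
    """
    reg = registry if registry is not None else default_registry()
    rows, ids = [], []
    for rec in records:
        fv = extract_feature_vector(rec, reg)
        rows.append(fv.values)
        ids.append(rec.record_id)
    df = pd.DataFrame(rows, columns=reg.names, index=ids)
    if labels is not None:
        df["label"] = list(labels)
    return df
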