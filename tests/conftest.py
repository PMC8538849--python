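"""Shared fixtures: synthetic records and fixture networks.

Signal-level fixtures are session-scoped because generation plus full
feature extraction is the expensive part of the suite.
"""

import numpy as np
import pytest

from densecg import synthetic
from densecg.features import default_registry, extract_feature_vector


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def normal_record():
    """Clean sinus-rhythm strip with ground truth."""
    return synthetic.generate_ecg(synthetic.RhythmSpec("N", seed=11))


@pytest.fixture(scope="session")
def af_record():
    """AF strip: irregular RR, no P-waves, 6 Hz f-waves."""
    return synthetic.generate_ecg(synthetic.RhythmSpec("AF", seed=12))


@pytest.fixture(scope="session")
def noise_record():
    return synthetic.generate_ecg(synthetic.RhythmSpec("X", seed=13))


@pytest.fixture(scope="session")
def normal_features(normal_record, registry):
    rec, _ = normal_record
    return extract_feature_vector(rec, registry)


@pytest.fixture(scope="session")
def af_features(af_record, registry):
    rec, _ = af_record
    return extract_feature_vector(rec, registry)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
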