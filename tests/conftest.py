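import numpy as np
import pytest

from neurofeat import EEGSegment, EffectConfig, generate_dataset, generate_segment
from neurofeat.segments import N_CHANNELS, N_SAMPLES


@pytest.fixture(scope="session")
def null_cfg() -> EffectConfig:
    """All-multipliers-1 baseline config (homogeneous subjects)."""
    return EffectConfig(subject_gain_sd=0.0)


@pytest.fixture(scope="session")
def segment(null_cfg) -> EEGSegment:
    return generate_segment(6, 1.0, null_cfg, seed=7)


@pytest.fixture(scope="session")
def zero_segment() -> EEGSegment:
    return EEGSegment(data=np.zeros((N_CHANNELS, N_SAMPLES)), label=6)


@pytest.fixture(scope="session")
def tiny_collection(null_cfg):
    """1 subject, 4 segments per class (24 segments)."""
    return generate_dataset(1, 4, null_cfg, seed=11)[0]


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
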