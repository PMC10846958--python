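import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import arterynano as an

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def tip() -> an.TipGeometry:
    return an.TipGeometry()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def study_noise() -> an.NoiseModel:
    """5% relative force noise plus modest baseline artefacts."""
    return an.NoiseModel(
        relative_force_noise=0.05,
        baseline_offset_nN=0.2,
        baseline_slope_nN_per_um=0.05,
        contact_jitter_sd_um=0.05,
    )
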