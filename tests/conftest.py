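import numpy as np
import pytest

from larvaquant.synthetic import FishGenParams, KinematicParams


@pytest.fixture
def noise_free_kin() -> KinematicParams:
    """Deterministic straight crawler: no draw noise, no heading change,
    walking rate equal to the net advance rate (zero wobble)."""
    return KinematicParams(
        walking_rate_mean=1.0, stride_length_mean=1.0, stride_length_sd=0.0,
        stride_duration_mean=1.0, stride_duration_sd=0.0, heading_sd=0.0,
        fps=5.0, duration=20.0, pause_prob=0.0,
    )


@pytest.fixture
def clean_fish() -> FishGenParams:
    """Small noise-free FISH condition with zero background."""
    return FishGenParams(
        n_nuclei=5, ratio_mean=2.2, ratio_sd=0.0, background_level=0.0,
        noise_model="none", stack_shape=(16, 128, 128),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
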