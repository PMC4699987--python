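import hypothesis
import numpy as np
import pytest

from stilltrain import TrainingConfig

hypothesis.settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=60,
)
hypothesis.settings.load_profile("default")


@pytest.fixture
def cfg():
    """A plain early-training configuration with the bonus feature disabled,
    so reward times follow the criterion schedule alone."""
    return TrainingConfig(
        set_start_s=5.0,
        set_max_s=95.0,
        n_periods=2,
        auto_delta_s=5.0,
        timeout_s=2.0,
        bonus_period_s=0.0,
        reward_duration_ms=500,
        read_every_ms=100,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
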