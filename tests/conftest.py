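import numpy as np
import pytest

from respondermi import (
    DropoutSpec,
    PROFILES,
    apply_dropout,
    generate_cv,
    mask_dataset,
    simulate_trial,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def linear_profile():
    return PROFILES["linear"]


@pytest.fixture
def complete_trial(linear_profile):
    data = simulate_trial(linear_profile, n=200, seed=101)
    return generate_cv(data, profile=linear_profile, seed=102)


@pytest.fixture
def masked_trial(complete_trial):
    spec = DropoutSpec(model_id=1, target_rate=0.30)
    mask = apply_dropout(complete_trial, spec, seed=103)
    return mask_dataset(complete_trial, mask), mask
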