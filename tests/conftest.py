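import numpy as np
import pytest

import hepatoscope as h
from hepatoscope.training import TrainConfig


@pytest.fixture(scope="session")
def small_cohort() -> h.CohortDataset:
    """4 + 4 subjects on the default geometry/grid — enough to train on."""
    return h.generate_cohort(n_healthy=4, n_nafld=4, seed=42)


@pytest.fixture(scope="session")
def tiny_net() -> h.NetworkConfig:
    """A deliberately small classifier for fast training tests."""
    return h.NetworkConfig(stem_channels=4, n_blocks=1, reduction_ratio=2, init_seed=7)


@pytest.fixture(scope="session")
def fast_train() -> TrainConfig:
    return TrainConfig(max_epochs=60, patience=60, min_delta=0.0)
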