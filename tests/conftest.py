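import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "misens",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("misens")

from misens import (BinaryPopulation, ContinuousPopulation, MissingnessModel,
                    apply_mnar, generate_binary, generate_continuous)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def continuous_incomplete():
    """A small continuous-outcome sample with roughly half the outcomes missing."""
    sample = generate_continuous(ContinuousPopulation(), 40, seed=11)
    inc = apply_mnar(sample, MissingnessModel(0.0, 1.0, 0.5), seed=12)
    assert inc.n_observed >= 6 and inc.n_missing >= 4
    return inc


@pytest.fixture
def binary_incomplete():
    """A binary-outcome sample with both classes observed and some missing."""
    sample = generate_binary(BinaryPopulation(), 80, seed=21)
    inc = apply_mnar(sample, MissingnessModel(-0.4, 1.0, 1.0), seed=22)
    obs = inc.y[inc.observed_index]
    assert inc.n_missing >= 5 and obs.min() == 0.0 and obs.max() == 1.0
    return inc
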