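import numpy as np
import pytest

from vischool import Arena, BehaviourParams, RunConfig


@pytest.fixture
def params():
    return BehaviourParams()


@pytest.fixture
def arena():
    return Arena()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_config():
    """A quick single-agent homogeneous run."""
    return RunConfig(n_agents=1, duration=30.0, seed=7)
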