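import numpy as np
import pytest

from transfercsp import SimConfig, simulate_session


def quick_config(**kw):
    """Small, fast session parameters for unit tests."""
    base = dict(n_channels=16, fs=160.0, trial_len_s=1.5,
                n_trials_per_class=20, classes=("LH", "RH"),
                snr_db=10.0, erd_depth=0.6, seed=0)
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def quick_session():
    """A small clean two-class session with strong planted structure."""
    return simulate_session(quick_config(background_rhythms=0.0))


@pytest.fixture(scope="session")
def quick_target_session():
    """Matching combined-task session for transfer tests."""
    return simulate_session(quick_config(classes=("LH&F", "RH&F"),
                                         background_rhythms=0.0, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
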