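import numpy as np
import pytest

from numact import (EffectSizes, build_session, enumerate_videos,
                    select_balanced_subset)


@pytest.fixture(scope="session")
def videos():
    return enumerate_videos()


@pytest.fixture(scope="session")
def subset72(videos):
    return select_balanced_subset(videos, seed=1)


@pytest.fixture(scope="session")
def schedules(subset72):
    return build_session(subset72, seed=2)


@pytest.fixture(scope="session")
def noiseless_effects():
    """Degenerate effect sizes: all parameter spread and noise switched off,
    so programmed amplitudes are exactly the configured means."""
    return EffectSizes(noise_sd=0.0, baseline_sd=0.0, gain_sd=0.0,
                      delta_sd=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
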