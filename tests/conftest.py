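import numpy as np
import pytest

from snbdecode import SynthConfig, generate_session


@pytest.fixture(scope="session")
def single_session():
    """Small 4-stimulus single-protocol session with a few injected bursts."""
    cfg = SynthConfig(
        protocol="single",
        n_stimuli=4,
        trials_per_stimulus=12,
        snb_prob={"pre_cue": 0.08, "cue": 0.04},
        seed=101,
    )
    return generate_session(cfg)


@pytest.fixture(scope="session")
def sequential_session():
    """Small 2-stimulus sequential session with bursts in every phase."""
    cfg = SynthConfig(
        protocol="sequential",
        n_stimuli=2,
        trials_per_stimulus=20,
        snb_prob={"pre_cue": 0.06, "cue": 0.06, "delay": 0.06, "probe": 0.06},
        seed=202,
    )
    return generate_session(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
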