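import numpy as np
import pytest

from alphaffr import synth
from alphaffr.montage import make_leadfield


@pytest.fixture(scope="session")
def leadfield():
    return make_leadfield()


@pytest.fixture(scope="session")
def small_spec():
    # 150 + 150 + 10 tokens over three blocks: the full schedule structure
    # at a size where simulation takes ~1 s
    return synth.StimulusSpec().scaled(0.05)


@pytest.fixture(scope="session")
def small_session(leadfield, small_spec):
    """One small coupled session at the analysis rate, noiseless source kept."""
    rng = np.random.default_rng(7)
    params = synth.draw_participant("NH", 0, rng, coupling=0.4)
    schedule = synth.make_event_schedule(small_spec, 7)
    return synth.simulate_session(
        params, leadfield, schedule, "clear", 7,
        spec=small_spec, fs=5000.0, keep_source=True,
    )


@pytest.fixture(scope="session")
def small_noiseless_session(leadfield, small_spec):
    """Same structure with sensor noise and cortical projection silenced."""
    rng = np.random.default_rng(3)
    params = synth.draw_participant("NH", 1, rng, coupling=0.4)
    params.noise_sd = 0.0
    params.alpha_base_power = 0.0
    schedule = synth.make_event_schedule(small_spec, 3)
    return synth.simulate_session(
        params, leadfield, schedule, "clear", 3,
        spec=small_spec, fs=5000.0, keep_source=True,
    )
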