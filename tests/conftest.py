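import numpy as np
import pytest

from physiograph import synthgen


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sim_config():
    """A small, fast 4-sensor / 2-state configuration for unit tests."""
    templates = np.zeros((2, 4, 3))
    for s in range(2):
        for k in range(4):
            templates[s, k] = (0.5 * s, 1.0 + 2.0 * s + 0.5 * k, 1.0)
    return synthgen.SimConfig(
        n_sensors=4,
        n_states=2,
        transition_matrix=np.array([[0.7, 0.3], [0.3, 0.7]]),
        emission_templates=templates,
        noise_sd=0.1,
        coupling_edges=((0, 1, 0.9),),
        sample_rate=32.0,
        duration=30.0,
        dwell_scale=64.0,
        seed=3,
    )


@pytest.fixture
def small_batch(small_sim_config):
    rec = synthgen.simulate_recording(small_sim_config)
    return synthgen.preprocess_and_window(rec, 32.0, 2.0)
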