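import numpy as np
import pytest

from scgate.synthetic_data import GeneratorConfig, generate_session


@pytest.fixture(scope="session")
def small_lgn_config():
    """A compact LGN-scenario session: enough neurons/trials for the
    statistics to behave, small enough to regenerate quickly."""
    return GeneratorConfig(
        seed=11,
        n_neurons_by_class={"visual": 12, "visual_movement": 5, "movement": 3},
        n_stim_trials_per_phase=100,
        n_behavior_trials_per_phase=20,
        n_map_trials_per_phase=49,
        n_saccade_trials_per_phase=25,
        n_mua_trials=60,
    )


@pytest.fixture(scope="session")
def small_lgn_bundle(small_lgn_config):
    return generate_session(small_lgn_config,
                            parts={"stimulus", "motor", "behavior"})


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
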