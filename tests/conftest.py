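import numpy as np
import pytest

from vta_memcode import behavior, synth


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic session shared by read-only tests: 6 units
    (half delay-modulated), 60 trials, light protocol and waveforms."""
    cfg = synth.SynthConfig(seed=42, n_trials=60, n_da=4, n_gaba=2,
                            n_untagged=0, fraction_traj_delay_da=0.5,
                            fraction_traj_delay_gaba=0.5,
                            fraction_reward_responsive=0.5)
    bundle, truth = synth.generate_cohort(cfg)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def small_linearized(small_cohort):
    _, bundle, _ = small_cohort
    return behavior.linearize_session(bundle)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
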