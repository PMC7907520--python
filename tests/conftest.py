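import numpy as np
import pytest

from radiomap.synthetic import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A quickly-generated separable cohort for unit tests."""
    cfg = SimConfig(n_patients=120, n_features=60, n_informative=8,
                    effect_size=2.0, block_size=6, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
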