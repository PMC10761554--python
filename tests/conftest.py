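import numpy as np
import pytest

from txdamage.motifs import PWM
from txdamage.simulate import SimConfig, simulate_genome


@pytest.fixture(scope="session")
def gg_pwm():
    """Near-deterministic 2-bp GG motif."""
    probs = np.array([[0.001, 0.001, 0.997, 0.001]] * 2)
    return PWM("GG", probs)


@pytest.fixture(scope="session")
def small_genome():
    cfg = SimConfig(n_genes=30, seed=11)
    sequences, genes = simulate_genome(cfg)
    return cfg, sequences, genes


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
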