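import numpy as np
import pytest

from tfbsload import pwm as pwm_mod
from tfbsload import synthetic as syn


@pytest.fixture
def toy_pwm() -> pwm_mod.PWM:
    """Deterministic 8-column PWM with mixed information content."""
    return syn.make_pwm(8, [0.5, 1.2, 1.8, 1.9, 1.6, 1.9, 1.0, 0.4],
                        seed=1)


@pytest.fixture
def flat_pwm() -> pwm_mod.PWM:
    """4-column PWM with simple hand-checkable probabilities."""
    probs = np.array([
        [0.7, 0.1, 0.1, 0.1],
        [0.1, 0.7, 0.1, 0.1],
        [0.25, 0.25, 0.25, 0.25],
        [0.4, 0.1, 0.4, 0.1],
    ])
    return pwm_mod.PWM.from_probabilities("toy", probs, threshold=None)


@pytest.fixture
def sharp_pwm() -> pwm_mod.PWM:
    """ACGT-consensus PWM whose columns are sharply distinguishable."""
    probs = np.full((4, 4), 0.05)
    for j in range(4):
        probs[j, j] = 0.85
    return pwm_mod.PWM.from_probabilities("sharp", probs)


@pytest.fixture(scope="session")
def fly_dataset():
    """Shared planted genome + population at isogenic-panel scale."""
    pwm = syn.make_pwm(8, [0.5, 1.2, 1.8, 1.9, 1.6, 1.9, 1.0, 0.4],
                       seed=1)
    genome = syn.make_genome(pwm, n_instances=80, n_decoys=10,
                             homotypic_pair_fraction=0.2,
                             length=100_000, seed=2)
    population = syn.make_population(genome, pwm, n_haplotypes=162,
                                     theta=0.03, selection_scale=1.0,
                                     seed=3)
    return pwm, genome, population
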