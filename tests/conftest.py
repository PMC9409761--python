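import numpy as np
import pytest

from phenodiv.simulate import (
    SimulationConfig,
    paper_like_fixture,
    simulate_augmented_trial,
)
from phenodiv.trial import TraitSpec


@pytest.fixture(scope="session")
def study(
):
    """Full-scale synthetic study: 103 genotypes, 17 traits, 17 descriptors."""
    return paper_like_fixture(seed=7)


@pytest.fixture(scope="session")
def study_trial(study):
    return study[0]


@pytest.fixture(scope="session")
def study_qualitative(study):
    return study[1]


def make_small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A fast 3-trait trial (b=3, c=2, n=12) for unit tests."""
    traits = [
        TraitSpec("T1", goal="increase"),
        TraitSpec("T2", goal="increase"),
        TraitSpec("T3", goal="decrease"),
    ]
    defaults = dict(
        b=3,
        c=2,
        n=12,
        traits=traits,
        trait_means=np.array([50.0, 10.0, 5.0]),
        genetic_cov=np.diag([16.0, 4.0, 1.0]),
        error_cov=np.diag([4.0, 1.0, 0.25]),
        block_sd=np.array([1.0, 0.5, 0.1]),
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture
def small_trial():
    trial, _ = simulate_augmented_trial(make_small_config(seed=3))
    return trial
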