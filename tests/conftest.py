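import numpy as np
import pytest

from vipermorph import SimulationConfig, generate_study
from vipermorph.simulate import dorsal_template


@pytest.fixture(scope="session")
def small_study():
    """A small nine-group synthetic study shared across read-only tests."""
    return generate_study(SimulationConfig(n_per_group=6, seed=11))


@pytest.fixture(scope="session")
def tiny_configs():
    """Ten dorsal configurations with sliding semilandmarks (one group)."""
    study = generate_study(
        SimulationConfig(
            tree=None, n_per_group={g: 0 for g in _GROUPS} | {"viridis": 10}, seed=5
        )
    )
    return study.dorsal[0]


_GROUPS = [
    "abyssus",
    "caliginis",
    "cerberus",
    "concolor",
    "helleri",
    "lutosus",
    "nuntius",
    "oreganus",
    "viridis",
]


def random_similarity(rng, coords):
    """Apply a random proper rotation, scaling and translation."""
    theta = rng.uniform(0.0, 2.0 * np.pi)
    scale = rng.uniform(0.3, 3.0)
    shift = rng.uniform(-10.0, 10.0, 2)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    return scale * coords @ rot.T + shift


@pytest.fixture
def dorsal_shapes():
    """The p=33 dorsal template plus its curve specification."""
    return dorsal_template(33)
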