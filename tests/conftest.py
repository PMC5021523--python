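import numpy as np
import pytest

import attnorm as an
from attnorm.task import TaskDesign, enumerate_conditions


@pytest.fixture(scope="session")
def design() -> TaskDesign:
    return TaskDesign()


@pytest.fixture(scope="session")
def conditions(design):
    return enumerate_conditions(design)


@pytest.fixture(scope="session")
def population(design):
    """Small ground-truth population shared across tests (read-only)."""
    return an.sample_population(10, design, seed=42)


@pytest.fixture(scope="session")
def neuron(population):
    return population[0]


def random_params(rng) -> "an.ModelParams":
    """Random valid model parameters for property tests."""
    return an.ModelParams(
        L=rng.uniform(0.0, 15.0, size=(3, 2)),
        alpha2=rng.uniform(0.05, 3.0),
        alpha3=rng.uniform(0.05, 3.0),
        sigma=rng.uniform(0.0, 1.0),
        beta=rng.uniform(0.3, 3.0),
    )
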