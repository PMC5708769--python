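import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import cytobn as cb

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def demo_model():
    return cb.ground_truth_demo(seed=0)


@pytest.fixture(scope="session")
def demo_panel(demo_model):
    return cb.generate_panel(demo_model, 1000, seed=1234)


@pytest.fixture(scope="session")
def demo_discrete(demo_panel):
    return cb.discretize_panel(demo_panel)


def make_copy_model(strength: float = 1.0, seed: int = 0) -> cb.GroundTruthModel:
    """Two analytes, B a (noisy) copy of A."""
    from cytobn.synthetic import diagonal_cpt, uniform_cpt

    em = np.column_stack([np.log([5.0, 20.0, 80.0]), np.full(3, 0.2)])
    return cb.GroundTruthModel(
        nodes=("A", "B"),
        parents={"A": (), "B": ("A",)},
        cpts={"A": uniform_cpt(0), "B": diagonal_cpt(1, strength)},
        emission={"A": em, "B": em},
        zero_rate={"A": 0.0, "B": 0.0},
        seed=seed,
    )


@pytest.fixture
def copy_states():
    """Deterministic-copy states, n=200."""
    model = make_copy_model(1.0, seed=3)
    return cb.sample_states(model, 200)
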