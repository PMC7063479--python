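import numpy as np
import pytest

from cardiorisk.boundary import surrogate_boundary
from cardiorisk.drugs import bundled_drug_table
from cardiorisk.fixtures import SyntheticEADModel, make_oracle
from cardiorisk.gp import active_learning_loop, unit_grid


@pytest.fixture(scope="session")
def drugs():
    return bundled_drug_table()


@pytest.fixture(scope="session")
def surrogate(drugs):
    return surrogate_boundary(drugs)


@pytest.fixture(scope="session")
def ead_model():
    return SyntheticEADModel()


@pytest.fixture(scope="session")
def eval_grid():
    return unit_grid(101)


@pytest.fixture(scope="session")
def surrogate_oracle_truth(eval_grid):
    oracle = make_oracle("surrogate-paper")
    return oracle, np.array([oracle(p) for p in eval_grid])


@pytest.fixture(scope="session")
def surrogate_learning_runs(surrogate_oracle_truth):
    """Ten seeded active-learning runs against the surrogate oracle.

    Shared between the boundary-recovery and sampling-behaviour tests;
    each run queries 10 LHS + 30 adaptive points.
    """
    oracle, _ = surrogate_oracle_truth
    return [active_learning_loop(oracle, n_init=10, n_adapt=30, seed=s) for s in range(10)]


def boundary_polyline(boundary, n=2000):
    """Dense sampling of the surrogate threshold curve for distance checks."""
    xs = np.linspace(0.0, boundary.x_wall, n)
    return np.column_stack([xs, boundary.threshold(xs)])


def min_distances(points, polyline):
    d2 = ((points[:, None, :] - polyline[None, :, :]) ** 2).sum(axis=2)
    return np.sqrt(d2.min(axis=1))
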