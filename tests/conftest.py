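"""Shared fixtures: cohorts, model defaults, and the discretised toy
optimisation problem used for oracle-equivalence checks."""

from __future__ import annotations

import numpy as np
import pytest

from pesched import (CohortSpec, DecisionSpace, FitnessWeights, MetricNorms,
                     ResponseParams, generate_cohort)


@pytest.fixture(scope="session")
def default_params() -> ResponseParams:
    return ResponseParams()


@pytest.fixture(scope="session")
def default_weights() -> FitnessWeights:
    return FitnessWeights()


@pytest.fixture(scope="session")
def default_norms() -> MetricNorms:
    return MetricNorms()


@pytest.fixture(scope="session")
def default_space() -> DecisionSpace:
    return DecisionSpace()


@pytest.fixture(scope="session")
def small_cohort():
    """200 clean students, fixed seed."""
    return generate_cohort(CohortSpec(n_students=200, seed=11))


@pytest.fixture(scope="session")
def tiny_cohort():
    """30 clean students for fast objective evaluations."""
    return generate_cohort(CohortSpec(n_students=30, seed=5))


def make_toy_problem(seed: int):
    """A seeded separable concave objective on a 140-point grid.

    The objective snaps candidates to the grid, so continuous optimisers
    and the exhaustive oracle see exactly the same 140 attainable values.
    Mix coordinates are frozen to a single feasible level; the weekly cap
    is slack so repair is the identity on grid points.

    Returns ``(space, grid, objective)``.
    """
    space = DecisionSpace(t_bounds=(0.5, 1.5), n_range=(1, 7),
                          max_weekly_hours=11.0)
    mix = np.array([0.2] * 5 + [1.0 / 3] * 3)
    grid = space.discretize(t_levels=20, mix_values=mix)
    r = np.random.default_rng(seed)
    c_t = r.uniform(0.5, 1.5)
    c_n = r.uniform(1, 7)
    a = r.uniform(0.5, 2.0)
    b = r.uniform(0.05, 0.3)

    def objective(X: np.ndarray) -> np.ndarray:
        Xs = grid.snap(np.atleast_2d(X))
        return -a * (Xs[:, 0] - c_t) ** 2 - b * (Xs[:, 1] - c_n) ** 2

    return space, grid, objective


def make_1d_problem(target: float = 7.3):
    """Concave 1-D objective −(t − target)² over t ∈ [0, 10], all other
    variables frozen (single session, fixed mixes)."""
    space = DecisionSpace(t_bounds=(0.0, 10.0), n_range=(1, 1),
                          max_weekly_hours=10.0)

    def objective(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        return -(X[:, 0] - target) ** 2

    return space, objective
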