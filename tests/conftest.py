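import numpy as np
import pytest

import p13cmfa as p
from p13cmfa.optimize import OptimizerSettings

# desk-scale evolutionary budgets for the toy fixtures
SMALL = dict(
    n_islands=2,
    pop_size=20,
    migration_every=50,
    max_generations=300,
    stall_generations=100,
    seed=1,
)
TINY = dict(
    n_islands=2,
    pop_size=16,
    migration_every=50,
    max_generations=150,
    stall_generations=60,
    seed=1,
)


@pytest.fixture(scope="session")
def small_settings() -> OptimizerSettings:
    return OptimizerSettings(**SMALL)


@pytest.fixture(scope="session")
def tiny_settings() -> OptimizerSettings:
    return OptimizerSettings(**TINY)


@pytest.fixture(scope="session")
def fixtures() -> dict[str, p.Fixture]:
    return {name: p.generate_fixture(name, seed=1) for name in p.FIXTURE_NAMES}


def make_spec(fx: p.Fixture, weighted: bool = False) -> p.ProblemSpec:
    w = None
    if weighted and fx.expression is not None:
        w = p.expression_weights(fx.expression, fx.net)
    return p.ProblemSpec(
        fx.net, fx.transitions, fx.tracers, fx.measurements, weights=w
    )


@pytest.fixture(scope="session")
def specs(fixtures) -> dict[str, p.ProblemSpec]:
    return {name: make_spec(fx) for name, fx in fixtures.items()}


@pytest.fixture(scope="session")
def stage1_results(specs, small_settings) -> dict[str, p.OptimizationResult]:
    """Stage-1 13C MFA fits on every fixture, shared across tests."""
    return {name: p.fit_13c_mfa(spec, small_settings) for name, spec in specs.items()}


@pytest.fixture(scope="session")
def chain_network() -> p.MetabolicNetwork:
    """Fully determined linear chain Aext -> A -> B -> Bext."""
    return p.build_network(
        [
            p.Metabolite("Aext", compartment="e", n_carbons=1, is_boundary=True),
            p.Metabolite("A", n_carbons=1),
            p.Metabolite("B", n_carbons=1),
            p.Metabolite("Bext", compartment="e", n_carbons=1, is_boundary=True),
        ],
        [
            p.Reaction("r1", {"Aext": -1, "A": 1}, 1, 1),
            p.Reaction("r2", {"A": -1, "B": 1}, 0, 10),
            p.Reaction("r3", {"B": -1, "Bext": 1}, 0, 10),
        ],
    )


@pytest.fixture(scope="session")
def parallel_network() -> p.MetabolicNetwork:
    """Two parallel branches with forced unit uptake."""
    return p.build_network(
        [
            p.Metabolite("Aext", compartment="e", n_carbons=1, is_boundary=True),
            p.Metabolite("A", n_carbons=1),
            p.Metabolite("B", n_carbons=1),
            p.Metabolite("Bext", compartment="e", n_carbons=1, is_boundary=True),
        ],
        [
            p.Reaction("upt", {"Aext": -1, "A": 1}, 1, 1),
            p.Reaction("b1", {"A": -1, "B": 1}, 0, 1000),
            p.Reaction("b2", {"A": -1, "B": 1}, 0, 1000),
            p.Reaction("exp", {"B": -1, "Bext": 1}, 0, 1000),
        ],
    )


def random_feasible_decisions(
    spec: p.ProblemSpec, n: int, seed: int
) -> np.ndarray:
    return p.sample_initial_population(spec, n, seed)
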