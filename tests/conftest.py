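import numpy as np
import pytest

from mesomelt.optimize import OptimizationConfig
from mesomelt.synthetic import (
    EXPERIMENT_GRID,
    SyntheticSpec,
    example_parameters,
    generate_duplexes,
    simulate_melting_table,
)
from mesomelt.transfer import QuadratureGrid


@pytest.fixture(scope="session")
def dd_params():
    return example_parameters("DD")


@pytest.fixture(scope="session")
def dr_params():
    return example_parameters("DR")


@pytest.fixture(scope="session")
def small_grid():
    """Fast reduced-domain grid for optimizer-level tests."""
    return EXPERIMENT_GRID


@pytest.fixture(scope="session")
def default_grid():
    return QuadratureGrid()


@pytest.fixture(scope="session")
def small_dataset(dd_params):
    """12 noiseless DD records over two length groups (fast fixture)."""
    spec = SyntheticSpec(kind="DD", n_sequences=12, lengths=(8, 10), sigma=0.0, seed=42)
    rng = np.random.default_rng(spec.seed)
    duplexes = generate_duplexes(spec, rng)
    records, taus = simulate_melting_table(
        duplexes, dd_params, spec.b_true, 0.0, rng, grid=EXPERIMENT_GRID
    )
    return records, taus, spec


@pytest.fixture()
def fast_config():
    return OptimizationConfig(
        grid=EXPERIMENT_GRID,
        tau_tol=1e-3,
        n_starts=2,
        n_rounds=1,
        simplex_maxfev=60,
        simplex_maxiter=60,
        seed=0,
    )
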