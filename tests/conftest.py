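import pytest

from pwemix import AgeGrid, SimulationConfig, expand, simulate_cohort


@pytest.fixture(scope="session")
def grid():
    return AgeGrid()


@pytest.fixture(scope="session")
def dense_cohort():
    """Small cohort with a common outcome so every age interval sees events."""
    cfg = SimulationConfig(n_centers=6, subjects_per_center=400,
                           baseline_log_hazard=-4.2, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def dense_pp(dense_cohort, grid):
    return expand(dense_cohort, grid)


@pytest.fixture(scope="session")
def tiny_ri_fixture(grid):
    """J=2 centers, a handful of subjects: quadrature-checkable size."""
    cfg = SimulationConfig(n_centers=2, subjects_per_center=8,
                           baseline_log_hazard=-3.0, seed=7)
    cohort = simulate_cohort(cfg)
    return cohort, expand(cohort, grid)
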