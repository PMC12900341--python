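"""Shared fixtures: one synthetic input set reused across the suite."""

import numpy as np
import pytest

import tobaccosim as ts


@pytest.fixture(scope="session")
def truth():
    return ts.default_ground_truth()


@pytest.fixture(scope="session")
def panel(truth):
    """Mid-sized default panel (n=20,000, 4 waves)."""
    return ts.generate_panel(truth, 20_000, seed=1)


@pytest.fixture(scope="session")
def life_table():
    return ts.generate_life_table()


@pytest.fixture(scope="session")
def rr_table():
    return ts.generate_rr_tables()


@pytest.fixture(scope="session")
def prevalence_table():
    return ts.generate_prevalence_table()


@pytest.fixture(scope="session")
def adjustment(life_table, rr_table, prevalence_table):
    return ts.solve_adjusted_rates(life_table, rr_table, prevalence_table)


@pytest.fixture(scope="session")
def initial_population(panel):
    return ts.build_initial_population(
        panel, reference_wave=3, rng=np.random.default_rng(42)
    )


@pytest.fixture(scope="session")
def sim_inputs(panel, truth, life_table, rr_table, prevalence_table):
    return ts.SimulationInputs(
        panel=panel,
        coefficients=truth.coefficients,
        life_table=life_table,
        rr_table=rr_table,
        prevalence_table=prevalence_table,
        cohort_specs=ts.default_cohort_specs(2017, 2050, n_entrants=400),
    )
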