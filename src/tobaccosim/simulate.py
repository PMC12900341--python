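"""Annual simulation loop and the Monte-Carlo replication design.

One replication starts from a (possibly bootstrap-resampled and
weight-calibrated) initial population and advances it one calendar
year at a time. Within a year the event order is fixed: each living
person first faces a Bernoulli death draw; survivors draw a next-year
tobacco-use state from the second-order transition model (with the
rate calibration applied); histories shift; ages increment; the year's
cohort of 18-year-olds enters; and persons past 64 retire from the
reporting population.

Uncertainty follows a crossed design: ``n_rr_sets`` sampled
relative-risk sets x ``n_population_versions`` bootstrap initial
populations x ``n_seeds_per_iteration`` trajectory seeds (default
20 x 20 x 25 = 10,000 replications). Every random stream is derived
from the master seed and the replication indices through
``numpy.random.SeedSequence`` spawn keys, so any single replication is
reproducible in isolation and results do not depend on execution
order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coefficients import CoefficientSet
from .engine import (
    CalibrationPolicy,
    apply_calibration_matrix,
    sample_states,
    transition_probability_matrix,
)
from .mortality import (
    MortalityTable,
    SmokingMortalityAdjustment,
    death_probabilities,
    draw_rr_set,
    solve_adjusted_rates,
)
from .panel import PanelDataset
from .population import (
    CohortSpec,
    Population,
    build_initial_population,
    calibrate_weights,
    inject_cohort,
    resample_population,
    retire_aged_out,
)
from .states import TobaccoState

_STATE_CODES = [int(s) for s in TobaccoState]


@dataclass
class RunConfig:
    """Configuration of one simulation experiment."""

    start_year: int = 2016
    end_year: int = 2050
    n_rr_sets: int = 20
    n_population_versions: int = 20
    n_seeds_per_iteration: int = 25
    master_seed: int = 0
    calibration: CalibrationPolicy = field(default_factory=CalibrationPolicy)
    target_prevalence: float | None = 0.1513
    reference_wave: int = 3
    resample_populations: bool = True
    draw_rr: bool = True

    def __post_init__(self) -> None:
        if self.end_year <= self.start_year:
            raise ValueError("end_year must exceed start_year")

    @property
    def total_replications(self) -> int:
        return self.n_rr_sets * self.n_population_versions * self.n_seeds_per_iteration


@dataclass
class SimulationInputs:
    """All data a simulation experiment consumes."""

    panel: PanelDataset
    coefficients: CoefficientSet
    life_table: MortalityTable
    rr_table: pd.DataFrame
    prevalence_table: pd.DataFrame
    cohort_specs: dict[int, CohortSpec] | None = None


@dataclass
class ReplicationResult:
    """Per-year outcomes of one replication.

    ``state_weights`` has one row per (year, race_group, poverty,
    state) with the living weight in that cell; ``flows`` reconciles
    the year-over-year accounting (start - deaths - aged_out + entrants
    = end, exactly).
    """

    rr_index: int
    pop_index: int
    seed_index: int
    state_weights: pd.DataFrame
    flows: pd.DataFrame

    def to_csv_text(self) -> str:
        return self.state_weights.to_csv(index=False) + self.flows.to_csv(index=False)


def _seed_seq(master_seed: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(master_seed, spawn_key=tuple(key))


def _state_cells(pop: Population, year: int) -> pd.DataFrame:
    live = pop.living
    cells = (
        live.groupby(["race_group", "poverty", "state_current"], observed=True)["weight"]
        .sum()
        .reindex(
            pd.MultiIndex.from_product(
                [
                    ["non_hispanic_black", "other"],
                    ["below_fpl", "at_above_fpl"],
                    _STATE_CODES,
                ],
                names=["race_group", "poverty", "state_current"],
            ),
            fill_value=0.0,
        )
        .reset_index()
    )
    cells.insert(0, "year", year)
    cells = cells.rename(columns={"state_current": "state", "weight": "weight"})
    return cells


def step_year(
    pop: Population,
    year: int,
    coefficients: CoefficientSet,
    adjustment: SmokingMortalityAdjustment,
    policy: CalibrationPolicy,
    life_table: MortalityTable,
    rng: np.random.Generator,
    cohort_spec: CohortSpec | None = None,
) -> tuple[Population, dict]:
    """Advance the population from year-1 to ``year``.

    Returns the new population (its states now refer to ``year``) and
    a tally dict with the weight flows of the step.
    """
    df = pop.data.copy()
    live = df["alive"].to_numpy().copy()
    start_weight = float(df.loc[live, "weight"].sum())

    age = df["age"].to_numpy()
    male = (df["sex"] == "male").to_numpy()
    race_other = (df["race_group"] == "other").to_numpy()
    init_cat = df["init_age_cat"].to_numpy()
    below = (df["poverty"] == "below_fpl").to_numpy()
    prior = df["state_prior"].to_numpy().copy()
    cur = df["state_current"].to_numpy().copy()
    yq = df["years_quit"].to_numpy().copy()

    # 1. mortality draw for every living person
    p_death = np.zeros(len(df))
    p_death[live] = death_probabilities(
        age[live], male[live], cur[live], yq[live], year, life_table, adjustment
    )
    dies = live & (rng.random(len(df)) < p_death)
    deaths_weight = float(df.loc[dies, "weight"].sum())
    live = live & ~dies

    # 2. survivors draw a next-year state
    if live.any():
        P = transition_probability_matrix(
            age[live], male[live], race_other[live], init_cat[live], below[live],
            prior[live], cur[live], coefficients,
        )
        P = apply_calibration_matrix(P, cur[live], year, policy)
        new_state = sample_states(P, rng)
    else:
        new_state = np.empty(0, dtype=np.int8)

    # 3. shift histories and update the years-quit counter
    former = int(TobaccoState.FORMER)
    prior[live] = cur[live]
    old_cur = cur[live]
    cur_live = new_state
    yq_live = np.where(
        cur_live == former, np.where(old_cur == former, yq[live] + 1, 1), 0
    )
    cur[live] = cur_live
    yq[live] = yq_live

    # 4. age increment for the living
    age = age.copy()
    age[live] += 1

    df["age"] = age
    df["state_prior"] = prior
    df["state_current"] = cur
    df["years_quit"] = yq
    df.loc[dies, "alive"] = False
    new_pop = Population(df, year)

    # 5. entering cohort, 6. retirement
    entrant_weight = 0.0
    if cohort_spec is not None:
        new_pop = inject_cohort(new_pop, cohort_spec, rng)
        entrant_weight = cohort_spec.entry_weight
    new_pop, aged_out_weight = retire_aged_out(new_pop)

    tallies = {
        "year": year,
        "start_weight": start_weight,
        "deaths_weight": deaths_weight,
        "aged_out_weight": aged_out_weight,
        "entrant_weight": entrant_weight,
        "end_weight": new_pop.total_weight,
    }
    return new_pop, tallies


def prepare_base_population(
    config: RunConfig, inputs: SimulationInputs
) -> Population:
    """Initial population: built from the panel, then weight-calibrated.

    Deterministic given the config's master seed (the pre-panel
    years-quit durations of long-quit former smokers use a dedicated
    derived stream).
    """
    rng = np.random.default_rng(_seed_seq(config.master_seed, 3))
    pop = build_initial_population(
        inputs.panel,
        reference_wave=config.reference_wave,
        reference_year=config.start_year,
        rng=rng,
    )
    if config.target_prevalence is not None:
        pop, _ = calibrate_weights(pop, config.target_prevalence)
    return pop


def run_replication(
    config: RunConfig,
    inputs: SimulationInputs,
    rr_index: int,
    pop_index: int,
    seed_index: int,
    base_pop: Population | None = None,
) -> ReplicationResult:
    """Run one replication of the crossed uncertainty design.

    A deterministic function of (master_seed, rr_index, pop_index,
    seed_index): the same tuple always reproduces identical outcome
    rows, independent of any other replication.
    """
    if not (0 <= rr_index < config.n_rr_sets):
        raise ValueError("rr_index out of range")
    if not (0 <= pop_index < config.n_population_versions):
        raise ValueError("pop_index out of range")
    if not (0 <= seed_index < config.n_seeds_per_iteration):
        raise ValueError("seed_index out of range")

    if base_pop is None:
        base_pop = prepare_base_population(config, inputs)
    if config.resample_populations:
        pop_rng = np.random.default_rng(_seed_seq(config.master_seed, 0, pop_index))
        pop = resample_population(base_pop, pop_rng)
    else:
        pop = base_pop.copy()

    if config.draw_rr:
        rr_rng = np.random.default_rng(_seed_seq(config.master_seed, 1, rr_index))
        rr_set = draw_rr_set(inputs.rr_table, rr_rng)
    else:
        rr_set = inputs.rr_table
    adjustment = solve_adjusted_rates(inputs.life_table, rr_set, inputs.prevalence_table)

    traj_rng = np.random.default_rng(
        _seed_seq(config.master_seed, 2, rr_index, pop_index, seed_index)
    )

    cells = [_state_cells(pop, config.start_year)]
    flows = []
    for year in range(config.start_year + 1, config.end_year + 1):
        spec = None
        if inputs.cohort_specs is not None:
            spec = inputs.cohort_specs.get(year)
            if spec is None and inputs.cohort_specs:
                spec = inputs.cohort_specs[max(inputs.cohort_specs)]
        pop, tallies = step_year(
            pop,
            year,
            inputs.coefficients,
            adjustment,
            config.calibration,
            inputs.life_table,
            traj_rng,
            cohort_spec=spec,
        )
        cells.append(_state_cells(pop, year))
        flows.append(tallies)

    return ReplicationResult(
        rr_index=rr_index,
        pop_index=pop_index,
        seed_index=seed_index,
        state_weights=pd.concat(cells, ignore_index=True),
        flows=pd.DataFrame(flows),
    )


def run_experiment(
    config: RunConfig, inputs: SimulationInputs
) -> list[ReplicationResult]:
    """Execute the full crossed design serially.

    Replications are independent given their derived seeds; running
    them in any order (or subset) yields identical per-replication
    results.
    """
    base_pop = prepare_base_population(config, inputs)
    results = []
    for rr_i, pop_i, seed_i in itertools.product(
        range(config.n_rr_sets),
        range(config.n_population_versions),
        range(config.n_seeds_per_iteration),
    ):
        results.append(
            run_replication(config, inputs, rr_i, pop_i, seed_i, base_pop=base_pop)
        )
    return results
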