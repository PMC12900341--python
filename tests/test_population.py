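"""Initial-population construction, weight calibration and dynamics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tobaccosim as ts
from tobaccosim.panel import PanelDataset
from tobaccosim.population import (
    CohortSpec,
    POPULATION_COLUMNS,
    Population,
    build_initial_population,
    calibrate_weights,
    inject_cohort,
    resample_population,
    retire_aged_out,
)
from tobaccosim.states import TobaccoState


def _mini_panel(states_by_person, weights=None):
    rows = []
    for pid, states in enumerate(states_by_person):
        for w, s in enumerate(states, start=1):
            rows.append(
                {
                    "person_id": f"q{pid}",
                    "wave": w,
                    "age": 30 + (w - 1),
                    "sex": "female",
                    "race_group": "other",
                    "poverty": "at_above_fpl",
                    "init_age_cat": "not_smoking" if states[0] == 1 else "lt18",
                    "state": s,
                    "weight": (weights or {}).get(pid, 1.0),
                }
            )
    return PanelDataset(pd.DataFrame(rows))


class TestBuildInitialPopulation:
    def test_reference_wave_assignment(self):
        p = _mini_panel([[1, 3, 2, 2]])
        pop = build_initial_population(p, reference_wave=3)
        row = pop.data.iloc[0]
        assert row["state_current"] == int(TobaccoState.FORMER)
        assert row["state_prior"] == int(TobaccoState.MENTHOL)
        assert row["age"] == 32
        assert pop.reference_year == 2016

    def test_years_quit_counts_consecutive_former_waves(self):
        p = _mini_panel([[3, 2, 2]])
        pop = build_initial_population(p, reference_wave=3)
        assert pop.data.iloc[0]["years_quit"] == 2

    def test_long_quit_former_gets_pre_panel_duration(self):
        p = _mini_panel([[2, 2, 2]])
        pop = build_initial_population(p, reference_wave=3, rng=np.random.default_rng(0))
        assert pop.data.iloc[0]["years_quit"] >= 3

    def test_total_weight_carried_over(self, panel, initial_population):
        w1 = panel.data[panel.data["wave"] == 1]["weight"].sum()
        assert initial_population.total_weight == pytest.approx(w1)

    def test_missing_reference_wave_rejected(self):
        p = _mini_panel([[1, 1, 1]])
        with pytest.raises(ValueError, match="reference wave"):
            build_initial_population(p, reference_wave=4)


class TestCalibrateWeights:
    def test_hits_target_exactly_and_conserves_weight(self, initial_population):
        pre_w = initial_population.total_weight
        pop, cal = calibrate_weights(initial_population, 0.1513)
        assert pop.smoking_prevalence() == pytest.approx(0.1513, abs=1e-12)
        assert pop.total_weight == pytest.approx(pre_w, rel=1e-12)
        assert cal.smoker_factor != 1.0

    def test_factor_direction_when_target_below_observed(self, initial_population):
        observed = initial_population.smoking_prevalence()
        pop, cal = calibrate_weights(initial_population, observed / 2)
        assert cal.smoker_factor < 1.0 < cal.nonsmoker_factor

    def test_identity_when_target_equals_observed(self, initial_population):
        observed = initial_population.smoking_prevalence()
        _, cal = calibrate_weights(initial_population, observed)
        assert cal.smoker_factor == pytest.approx(1.0, abs=1e-12)
        assert cal.nonsmoker_factor == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self, initial_population):
        pop1, _ = calibrate_weights(initial_population, 0.1513)
        pop2, cal2 = calibrate_weights(pop1, 0.1513)
        assert np.allclose(pop1.data["weight"], pop2.data["weight"], rtol=1e-12)
        assert cal2.smoker_factor == pytest.approx(1.0, abs=1e-10)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(target=st.floats(0.01, 0.95))
    def test_weight_identity_any_target(self, initial_population, target):
        """a*W_s + b*W_n = W for every admissible target."""
        df = initial_population.living
        smoker = df["state_current"].isin([3, 4])
        W, Ws, Wn = df["weight"].sum(), df.loc[smoker, "weight"].sum(), df.loc[~smoker, "weight"].sum()
        _, cal = calibrate_weights(initial_population, target)
        assert cal.smoker_factor * Ws + cal.nonsmoker_factor * Wn == pytest.approx(W, rel=1e-9)

    def test_target_outside_unit_interval_rejected(self, initial_population):
        with pytest.raises(ValueError, match="target_prevalence"):
            calibrate_weights(initial_population, 1.2)


class TestInjectCohort:
    def _spec(self, **kw):
        return CohortSpec(
            year=2020,
            entry_weight=kw.get("entry_weight", 4.0e6),
            state_distribution=kw.get(
                "state_distribution",
                {
                    TobaccoState.NEVER: 0.9,
                    TobaccoState.MENTHOL: 0.05,
                    TobaccoState.NONMENTHOL: 0.05,
                },
            ),
            prior_state_distribution=kw.get(
                "prior_state_distribution",
                {
                    TobaccoState.NEVER: {TobaccoState.NEVER: 1.0},
                    TobaccoState.MENTHOL: {TobaccoState.NEVER: 0.5, TobaccoState.MENTHOL: 0.5},
                    TobaccoState.NONMENTHOL: {TobaccoState.NEVER: 1.0},
                },
            ),
            n_entrants=kw.get("n_entrants", 100),
        )

    def test_entry_weight_and_ages(self, initial_population):
        pop = inject_cohort(initial_population, self._spec(), np.random.default_rng(0))
        added = pop.data[pop.data["person_id"].str.startswith("cohort")]
        assert added["weight"].sum() == pytest.approx(4.0e6)
        assert (added["age"] == 18).all()

    def test_all_never_spec(self, initial_population):
        spec = self._spec(
            state_distribution={TobaccoState.NEVER: 1.0},
            prior_state_distribution={TobaccoState.NEVER: {TobaccoState.NEVER: 1.0}},
        )
        pop = inject_cohort(initial_population, spec, np.random.default_rng(0))
        added = pop.data[pop.data["person_id"].str.startswith("cohort")]
        assert (added["state_current"] == 1).all()
        assert (added["state_prior"] == 1).all()

    def test_invalid_shares_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            self._spec(state_distribution={TobaccoState.NEVER: 0.5})


class TestRetire:
    def test_aged_out_dropped_and_counted(self):
        p = _mini_panel([[1, 1, 1]])
        pop = build_initial_population(p, reference_wave=3)
        pop.data["age"] = 64
        kept, w = retire_aged_out(pop)
        assert len(kept.data) == 1 and w == 0.0
        pop.data["age"] = 65
        kept, w = retire_aged_out(pop)
        assert len(kept.data) == 0 and w == pytest.approx(1.0)

    def test_empty_population(self):
        pop = Population(pd.DataFrame(columns=POPULATION_COLUMNS), 2016)
        kept, w = retire_aged_out(pop)
        assert len(kept.data) == 0 and w == 0.0


class TestResample:
    def test_same_seed_identical(self, initial_population):
        a = resample_population(initial_population, np.random.default_rng(21))
        b = resample_population(initial_population, np.random.default_rng(21))
        assert a.data.equals(b.data)

    def test_total_weight_preserved(self, initial_population):
        v = resample_population(initial_population, np.random.default_rng(2))
        assert v.total_weight == pytest.approx(initial_population.total_weight)
        assert len(v.data) == len(initial_population.living)

    def test_prevalence_spread_matches_binomial_oracle(self, initial_population):
        """With equalized weights, the variant smoking prevalence is a
        binomial share: sd across variants ~ sqrt(p(1-p)/n)."""
        n = len(initial_population.living)
        p = initial_population.smoking_prevalence()
        prevs = [
            resample_population(initial_population, np.random.default_rng(100 + k)).smoking_prevalence()
            for k in range(30)
        ]
        sd = np.std(prevs, ddof=1)
        oracle = np.sqrt(p * (1 - p) / n)
        assert 0.55 * oracle < sd < 1.6 * oracle


def test_population_csv_roundtrip(tmp_path, initial_population):
    path = tmp_path / "pop.csv"
    initial_population.to_csv(path)
    header = path.read_text().splitlines()[0]
    assert header == ",".join(POPULATION_COLUMNS)
    back = Population.read_csv(path, 2016)
    assert back.total_weight == pytest.approx(initial_population.total_weight)
    assert len(back.data) == len(initial_population.living)


def test_person_record_invariants():
    with pytest.raises(ValueError, match="prior state NEVER"):
        ts.PersonRecord(
            person_id="a", age=30, sex="male", race_group="other",
            poverty="below_fpl", init_age_cat="lt18",
            state_prior=TobaccoState.MENTHOL, state_current=TobaccoState.NEVER,
        )
    with pytest.raises(ValueError, match="years_quit"):
        ts.PersonRecord(
            person_id="a", age=30, sex="male", race_group="other",
            poverty="below_fpl", init_age_cat="lt18",
            state_prior=TobaccoState.MENTHOL, state_current=TobaccoState.FORMER,
            years_quit=0,
        )
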