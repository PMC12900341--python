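"""Smoker-status mortality adjustment and relative-risk sampling."""

import numpy as np
import pandas as pd
import pytest

import tobaccosim as ts
from tobaccosim.mortality import (
    ADJUSTED_MIN_AGE,
    BIN_LABELS,
    death_probabilities,
    draw_rr_set,
    solve_adjusted_rates,
    years_quit_bin_label,
)
from tobaccosim.population import PersonRecord
from tobaccosim.states import TobaccoState


def _person(age, state, years_quit=0, sex="male"):
    return PersonRecord(
        person_id="x",
        age=age,
        sex=sex,
        race_group="other",
        poverty="at_above_fpl",
        init_age_cat="lt18" if state != TobaccoState.NEVER else "not_smoking",
        state_prior=TobaccoState.NEVER if state == TobaccoState.NEVER else state,
        state_current=state,
        years_quit=years_quit,
    )


@pytest.mark.parametrize(
    "years, label",
    [(1, "lt2"), (2, "2-4"), (4, "2-4"), (9, "5-9"), (25, "20-29"), (50, "ge50"), (70, "ge50")],
)
def test_years_quit_binning(years, label):
    assert years_quit_bin_label(years) == label


class TestSolveAdjustedRates:
    def test_unit_rrs_reproduce_life_table(self, life_table, rr_table, prevalence_table):
        flat = rr_table.copy()
        flat["rr"] = 1.0
        adj = solve_adjusted_rates(life_table, flat, prevalence_table)
        for age in (55, 60, 64):
            for sex in ("male", "female"):
                q = life_table.q(age, sex, 2018)
                for slot in range(10):
                    assert adj.rate(age, sex, slot, 2018) == pytest.approx(q, abs=1e-15)

    def test_two_group_algebra(self, life_table):
        """q=0.01 with shares (.5 never, .3 former RR 1.5, .2 current RR 2)
        implies a never-smoker rate of 0.01/1.35."""
        rr = pd.DataFrame(
            [
                {"age_group": "55-64", "sex": s, "status": "current", "years_quit_bin": "", "rr": 2.0}
                for s in ("male", "female")
            ]
            + [
                {"age_group": "55-64", "sex": s, "status": "former", "years_quit_bin": b, "rr": 1.5}
                for s in ("male", "female")
                for b in BIN_LABELS
            ]
            + [
                {"age_group": "55-64", "sex": s, "status": "never", "years_quit_bin": "", "rr": 1.0}
                for s in ("male", "female")
            ]
        )
        prev = pd.DataFrame(
            [
                {"age_group": "55-64", "sex": s, "status": "never", "years_quit_bin": "", "share": 0.5}
                for s in ("male", "female")
            ]
            + [
                {"age_group": "55-64", "sex": s, "status": "current", "years_quit_bin": "", "share": 0.2}
                for s in ("male", "female")
            ]
            + [
                {
                    "age_group": "55-64",
                    "sex": s,
                    "status": "former",
                    "years_quit_bin": b,
                    "share": 0.3 / len(BIN_LABELS),
                }
                for s in ("male", "female")
                for b in BIN_LABELS
            ]
        )
        flat_lt = ts.generate_life_table(
            anchors={18: 0.01, 64: 0.01}, sex_factors={"male": 1.0, "female": 1.0},
            regime_factors={2016: 1, 2017: 1, 2018: 1},
        )
        adj = solve_adjusted_rates(flat_lt, rr, prev)
        assert adj.rate(60, "male", 0, 2018) == pytest.approx(0.01 / 1.35, abs=1e-12)
        assert adj.rate(60, "male", 1, 2018) == pytest.approx(2 * 0.01 / 1.35, abs=1e-12)

    def test_conservation_identity(self, life_table, rr_table, prevalence_table, adjustment):
        """Prevalence-weighted solved rates reproduce q to 1e-12 everywhere."""
        for regime in (2016, 2017, 2018):
            for sex in ("male", "female"):
                for age in range(ADJUSTED_MIN_AGE, 65):
                    g = "55-59" if age <= 59 else "60-64"
                    prev = prevalence_table[
                        (prevalence_table["age_group"] == g) & (prevalence_table["sex"] == sex)
                    ]
                    mean = 0.0
                    mean += float(prev.loc[prev["status"] == "never", "share"].sum()) * adjustment.rate(age, sex, 0, regime)
                    mean += float(prev.loc[prev["status"] == "current", "share"].sum()) * adjustment.rate(age, sex, 1, regime)
                    f = prev[prev["status"] == "former"].set_index("years_quit_bin")["share"]
                    for k, b in enumerate(BIN_LABELS):
                        mean += float(f[b]) * adjustment.rate(age, sex, 2 + k, regime)
                    assert mean == pytest.approx(life_table.q(age, sex, regime), abs=1e-12)


class TestDeathProbability:
    def test_under_55_depends_only_on_age_and_sex(self, life_table, adjustment):
        smoker = _person(40, TobaccoState.MENTHOL)
        never = _person(40, TobaccoState.NEVER)
        a = ts.death_probability(smoker, 2020, adjustment, life_table)
        b = ts.death_probability(never, 2020, adjustment, life_table)
        assert a == b == life_table.q(40, "male", 2020)

    def test_older_smoker_riskier_than_never(self, life_table, adjustment):
        smoker = ts.death_probability(_person(60, TobaccoState.MENTHOL), 2020, adjustment, life_table)
        never = ts.death_probability(_person(60, TobaccoState.NEVER), 2020, adjustment, life_table)
        assert smoker > never

    def test_menthol_nonmenthol_and_ecig_share_current_rate(self, life_table, adjustment):
        rates = {
            s: ts.death_probability(_person(60, s), 2020, adjustment, life_table)
            for s in (TobaccoState.MENTHOL, TobaccoState.NONMENTHOL, TobaccoState.ECIG_DUAL)
        }
        assert len(set(rates.values())) == 1

    def test_former_uses_years_quit_bin(self, life_table, adjustment):
        p = ts.death_probability(
            _person(60, TobaccoState.FORMER, years_quit=25), 2020, adjustment, life_table
        )
        assert p == adjustment.rate(60, "male", 2 + BIN_LABELS.index("20-29"), 2020)

    def test_former_rate_non_increasing_in_years_quit(self, life_table, adjustment):
        rates = [
            ts.death_probability(
                _person(62, TobaccoState.FORMER, years_quit=y), 2020, adjustment, life_table
            )
            for y in (1, 3, 7, 15, 25, 35, 45, 55)
        ]
        assert all(a >= b - 1e-15 for a, b in zip(rates, rates[1:]))

    def test_missing_years_quit_rejected(self, life_table, adjustment):
        bad = _person(60, TobaccoState.FORMER, years_quit=1)
        bad.years_quit = 0  # corrupt after validation
        with pytest.raises(ValueError, match="years_quit"):
            ts.death_probability(bad, 2020, adjustment, life_table)

    def test_vectorized_matches_scalar(self, life_table, adjustment):
        people = [
            _person(40, TobaccoState.NEVER),
            _person(58, TobaccoState.MENTHOL),
            _person(61, TobaccoState.FORMER, years_quit=12, sex="female"),
        ]
        vec = death_probabilities(
            [p.age for p in people],
            [p.sex == "male" for p in people],
            [int(p.state_current) for p in people],
            [p.years_quit for p in people],
            2019,
            life_table,
            adjustment,
        )
        for p, v in zip(people, vec):
            assert ts.death_probability(p, 2019, adjustment, life_table) == pytest.approx(v)


class TestDrawRRSet:
    def test_degenerate_ci_returns_point(self, rr_table):
        fixed = rr_table.copy()
        fixed["ci_low"] = fixed["rr"]
        fixed["ci_high"] = fixed["rr"]
        out = draw_rr_set(fixed, np.random.default_rng(3))
        assert np.allclose(out["rr"], fixed["rr"])

    def test_equal_seeds_identical(self, rr_table):
        a = draw_rr_set(rr_table, np.random.default_rng(5))
        b = draw_rr_set(rr_table, np.random.default_rng(5))
        assert a.equals(b)

    def test_draw_quantiles_match_ci(self):
        """Empirical 2.5/97.5 quantiles of repeated draws track the CI."""
        row = pd.DataFrame(
            [{"age_group": "55-59", "sex": "male", "status": "current",
              "years_quit_bin": "", "rr": 2.0, "ci_low": 1.6, "ci_high": 2.5}]
        )
        rng = np.random.default_rng(11)
        draws = np.array([draw_rr_set(row, rng)["rr"].iloc[0] for _ in range(10_000)])
        lo, hi = np.percentile(draws, [2.5, 97.5])
        assert abs(lo - 1.6) / 1.6 < 0.02
        assert abs(hi - 2.5) / 2.5 < 0.02

    def test_monotone_repair_after_sampling(self, rr_table):
        out = draw_rr_set(rr_table, np.random.default_rng(17))
        former = out[out["status"] == "former"]
        for _, sub in former.groupby(["age_group", "sex"]):
            vals = sub.set_index("years_quit_bin").loc[BIN_LABELS, "rr"].to_numpy()
            assert (np.diff(vals) <= 1e-12).all()
            assert (vals >= 1.0).all()
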