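"""Transition-probability computation, rate calibration and sampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tobaccosim as ts
from tobaccosim.engine import (
    CalibrationPolicy,
    IDENTITY_POLICY,
    TransitionContext,
    apply_calibration,
    apply_calibration_matrix,
    compute_probabilities,
    sample_next_state,
    sample_states,
    transition_probability_matrix,
)
from tobaccosim.states import TobaccoState


def _ctx(cur, prior=None, **kw):
    prior = cur if prior is None else prior
    return TransitionContext(
        age=kw.get("age", 40),
        male=kw.get("male", False),
        race_other=kw.get("race_other", True),
        init_age_cat=kw.get("init_age_cat", "lt18"),
        below_fpl=kw.get("below_fpl", False),
        state_prior=TobaccoState(prior),
        state_current=TobaccoState(cur),
        year=kw.get("year", 2020),
    )


def bruteforce_probabilities(ctx: TransitionContext, coeffs) -> dict:
    """Independent scalar evaluation of the logit formulas.

    Builds each linear predictor term by term from the coefficient
    frames, then converts logits to probabilities with the reference
    relations p_ref = 1/(1 + sum e^L) and p_i = p_ref e^L_i.
    """
    if ctx.state_current is TobaccoState.NEVER:
        block = coeffs.never
        x = {
            "intercept": 1.0,
            "init_lt18": 1.0 if ctx.init_age_cat == "lt18" else 0.0,
            "init_ge18": 1.0 if ctx.init_age_cat == "ge18" else 0.0,
            "race_other": float(ctx.race_other),
            "age": float(ctx.age),
            "male": float(ctx.male),
            "below_fpl": float(ctx.below_fpl),
        }
    else:
        block = coeffs.ever
        x = {
            "intercept": 1.0,
            "prior_never": float(ctx.state_prior == TobaccoState.NEVER),
            "prior_former": float(ctx.state_prior == TobaccoState.FORMER),
            "prior_menthol": float(ctx.state_prior == TobaccoState.MENTHOL),
            "prior_nonmenthol": float(ctx.state_prior == TobaccoState.NONMENTHOL),
            "cur_former": float(ctx.state_current == TobaccoState.FORMER),
            "cur_menthol": float(ctx.state_current == TobaccoState.MENTHOL),
            "cur_nonmenthol": float(ctx.state_current == TobaccoState.NONMENTHOL),
            "init_lt18": 1.0 if ctx.init_age_cat == "lt18" else 0.0,
            "init_ge18": 1.0 if ctx.init_age_cat == "ge18" else 0.0,
            "race_other": float(ctx.race_other),
            "age": float(ctx.age),
            "male": float(ctx.male),
            "below_fpl": float(ctx.below_fpl),
        }
    logits = {
        int(d): sum(x[c] * float(block.loc[c, d]) for c in block.index)
        for d in block.columns
    }
    denom = 1.0 + sum(math.exp(v) for v in logits.values())
    probs = {TobaccoState(d): math.exp(v) / denom for d, v in logits.items()}
    probs[TobaccoState.NONMENTHOL] = 1.0 / denom
    return probs


def random_coefficients(rng) -> ts.CoefficientSet:
    cs = ts.CoefficientSet()
    cs.ever.iloc[:, :] = rng.normal(0, 0.5, cs.ever.shape)
    cs.ever.loc["age"] = rng.normal(0, 0.02, cs.ever.shape[1])
    cs.never.iloc[:, :] = rng.normal(0, 0.5, cs.never.shape)
    cs.never.loc["age"] = rng.normal(0, 0.02, cs.never.shape[1])
    return cs


def random_context(rng) -> TransitionContext:
    cur = int(rng.integers(1, 6))
    prior = 1 if cur == 1 else int(rng.integers(1, 6))
    return _ctx(
        cur,
        prior,
        age=int(rng.integers(18, 65)),
        male=bool(rng.integers(2)),
        race_other=bool(rng.integers(2)),
        init_age_cat=str(rng.choice(["not_smoking", "lt18", "ge18"])),
        below_fpl=bool(rng.integers(2)),
    )


class TestComputeProbabilities:
    def test_zero_logits_ever_history(self):
        probs = compute_probabilities(_ctx(3), ts.CoefficientSet())
        assert set(probs) == {TobaccoState(i) for i in (2, 3, 4, 5)}
        assert all(p == pytest.approx(0.25) for p in probs.values())

    def test_zero_logits_never_history(self):
        probs = compute_probabilities(_ctx(1), ts.CoefficientSet())
        assert set(probs) == set(TobaccoState)
        assert all(p == pytest.approx(0.2) for p in probs.values())

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            coeffs = random_coefficients(rng)
            ctx = random_context(rng)
            got = compute_probabilities(ctx, coeffs)
            want = bruteforce_probabilities(ctx, coeffs)
            for s, p in got.items():
                assert p == pytest.approx(want[s], abs=1e-10)
            assert sum(got.values()) == pytest.approx(1.0, abs=1e-12)

    def test_forbidden_destination_has_zero_mass(self, truth):
        P = transition_probability_matrix(
            [40, 50], [True, False], [True, True], ["lt18", "lt18"],
            [False, True], [3, 2], [3, 2], truth.coefficients,
        )
        assert (P[:, 0] == 0).all()
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_inconsistent_never_context_rejected(self):
        with pytest.raises(ValueError, match="prior state NEVER"):
            compute_probabilities(_ctx(1, prior=3), ts.CoefficientSet())


class TestCalibration:
    def test_never_context_worked_example(self):
        """Initiation destinations shrink by 0.945; NEVER absorbs the mass."""
        probs = {
            TobaccoState.NEVER: 0.90,
            TobaccoState.FORMER: 0.02,
            TobaccoState.MENTHOL: 0.03,
            TobaccoState.NONMENTHOL: 0.03,
            TobaccoState.ECIG_DUAL: 0.02,
        }
        out = apply_calibration(probs, _ctx(1), CalibrationPolicy())
        assert out[TobaccoState.MENTHOL] == pytest.approx(0.02835)
        assert out[TobaccoState.NONMENTHOL] == pytest.approx(0.02835)
        assert out[TobaccoState.ECIG_DUAL] == pytest.approx(0.0189)
        assert out[TobaccoState.FORMER] == pytest.approx(0.02)  # not initiation
        assert out[TobaccoState.NEVER] == pytest.approx(0.90 + 0.055 * 0.08)
        assert sum(out.values()) == pytest.approx(1.0, abs=1e-12)

    def test_smoker_context_worked_example(self):
        """Quit probability scales by 1.055; the rest shrink proportionally."""
        probs = {
            TobaccoState.FORMER: 0.10,
            TobaccoState.MENTHOL: 0.80,
            TobaccoState.NONMENTHOL: 0.05,
            TobaccoState.ECIG_DUAL: 0.05,
        }
        out = apply_calibration(probs, _ctx(3), CalibrationPolicy())
        assert out[TobaccoState.FORMER] == pytest.approx(0.1055)
        shrink = (1 - 0.1055) / 0.9
        assert out[TobaccoState.MENTHOL] == pytest.approx(0.80 * shrink)
        assert sum(out.values()) == pytest.approx(1.0, abs=1e-12)

    def test_identity_multipliers(self):
        probs = {TobaccoState(i): p for i, p in zip((2, 3, 4, 5), (0.1, 0.6, 0.2, 0.1))}
        out = apply_calibration(probs, _ctx(3), CalibrationPolicy(1.0, 1.0))
        assert out == pytest.approx(probs)

    def test_former_context_unchanged(self):
        probs = {TobaccoState(i): p for i, p in zip((2, 3, 4, 5), (0.9, 0.03, 0.05, 0.02))}
        out = apply_calibration(probs, _ctx(2), CalibrationPolicy())
        assert out == pytest.approx(probs)

    def test_inactive_before_start_year(self):
        probs = {TobaccoState(i): p for i, p in zip((2, 3, 4, 5), (0.1, 0.6, 0.2, 0.1))}
        out = apply_calibration(probs, _ctx(3, year=2016), CalibrationPolicy(applies_from_year=2017))
        assert out == pytest.approx(probs)

    def test_quit_probability_clipped_at_one(self):
        P = np.array([[0.0, 0.97, 0.01, 0.01, 0.01]])
        out = apply_calibration_matrix(P, [3], 2020, CalibrationPolicy(cessation_multiplier=1.2))
        assert out[0, 1] == 1.0
        assert out[0].sum() == pytest.approx(1.0, abs=1e-12)

    def test_compounding_mode(self):
        pol = CalibrationPolicy(mode="compounding", applies_from_year=2017)
        assert pol.effective(2018) == (0.945**2, 1.055**2)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        raw=st.lists(st.floats(0.01, 1.0), min_size=5, max_size=5),
        cur=st.integers(1, 5),
        m=st.floats(0.5, 1.0),
        c=st.floats(1.0, 1.5),
    )
    def test_calibration_properties(self, raw, cur, m, c):
        """Sum 1, forbidden mass zero, quitting up, initiation down."""
        p = np.array(raw)
        if cur != 1:
            p[0] = 0.0
        p = p / p.sum()
        out = apply_calibration_matrix(p[None, :], [cur], 2020, CalibrationPolicy(m, c))[0]
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        assert (out >= -1e-15).all() and (out <= 1 + 1e-15).all()
        if cur == 1:
            assert out[2] + out[3] + out[4] <= p[2] + p[3] + p[4] + 1e-12
        elif cur in (3, 4, 5):
            assert out[1] >= p[1] - 1e-12
        else:
            assert out == pytest.approx(p)


class TestSampling:
    def test_degenerate_vector(self):
        rng = np.random.default_rng(0)
        probs = {TobaccoState(i): p for i, p in zip((2, 3, 4, 5), (0.0, 1.0, 0.0, 0.0))}
        assert all(sample_next_state(probs, rng) is TobaccoState.MENTHOL for _ in range(20))

    def test_frequencies_converge(self):
        rng = np.random.default_rng(1)
        P = np.tile([0.5, 0.5, 0.0, 0.0, 0.0], (100_000, 1))
        draws = sample_states(P, rng)
        share = (draws == 1).mean()
        assert abs(share - 0.5) < 0.005

    def test_fixed_stream_reproducible(self):
        P = np.tile([0.2, 0.2, 0.2, 0.2, 0.2], (1000, 1))
        a = sample_states(P, np.random.default_rng(99))
        b = sample_states(P, np.random.default_rng(99))
        assert (a == b).all()

    def test_identity_policy_exported(self):
        assert IDENTITY_POLICY.effective(2050) == (1.0, 1.0)
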