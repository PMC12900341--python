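"""Annual transition probabilities and state sampling.

Given a fitted :class:`~tobaccosim.coefficients.CoefficientSet`, the
engine turns each person's covariates and two-year state history into a
probability vector over next-year states. Logits are taken relative to
the NONMENTHOL reference destination, so with logits ``L_i`` the
reference probability is ``p_ref = 1 / (1 + sum_i exp(L_i))`` and every
other destination has ``p_i = p_ref * exp(L_i)``.

The engine also applies the rate calibration: a constant per-year
multiplier that lowers initiation probabilities of never smokers and
raises the quit probability of current menthol, non-menthol and
e-cigarette/dual users, re-normalizing so each vector still sums to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coefficients import (
    CoefficientSet,
    EVER_DESTINATIONS,
    NEVER_DESTINATIONS,
    ever_design_matrix,
    never_design_matrix,
)
from .states import CURRENT_USER_STATES, TobaccoState, allowed_transitions

_N_STATES = 5
_EVER_COLS = np.array([int(d) - 1 for d in EVER_DESTINATIONS])  # 0-based columns
_NEVER_COLS = np.array([int(d) - 1 for d in NEVER_DESTINATIONS])
_REF_COL = int(TobaccoState.NONMENTHOL) - 1


@dataclass(frozen=True)
class TransitionContext:
    """Covariate view of one person at one simulated year.

    ``age`` is the person's age in the year before the transition lands
    (year j-1), ``state_current`` the state in year j-1 and
    ``state_prior`` the state in year j-2.
    """

    age: int
    male: bool
    race_other: bool
    init_age_cat: str
    below_fpl: bool
    state_prior: TobaccoState
    state_current: TobaccoState
    year: int = 0


@dataclass(frozen=True)
class CalibrationPolicy:
    """Annual initiation/cessation rate adjustment.

    ``initiation_multiplier`` scales the never-smoker probabilities of
    transitioning into any current-use state (MENTHOL, NONMENTHOL,
    ECIG_DUAL); the freed mass stays on NEVER. ``cessation_multiplier``
    scales the probability that a current user quits (moves to FORMER);
    the added mass is removed proportionally from the other
    destinations. In ``constant`` mode the same multipliers apply in
    every year from ``applies_from_year`` on; ``compounding`` raises
    them to the power of the number of elapsed adjustment years.
    """

    initiation_multiplier: float = 0.945
    cessation_multiplier: float = 1.055
    active: bool = True
    applies_from_year: int = 2017
    mode: str = "constant"

    def __post_init__(self) -> None:
        if self.initiation_multiplier <= 0 or self.cessation_multiplier <= 0:
            raise ValueError("calibration multipliers must be positive")
        if self.mode not in ("constant", "compounding"):
            raise ValueError("mode must be 'constant' or 'compounding'")

    def effective(self, year: int) -> tuple[float, float]:
        """(initiation, cessation) multipliers in force for ``year``."""
        if not self.active or year < self.applies_from_year:
            return 1.0, 1.0
        if self.mode == "constant":
            return self.initiation_multiplier, self.cessation_multiplier
        k = year - self.applies_from_year + 1
        return self.initiation_multiplier**k, self.cessation_multiplier**k


IDENTITY_POLICY = CalibrationPolicy(1.0, 1.0, active=False)


def _softmax_with_reference(logits: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Full (n, 5) probability matrix from logits relative to NONMENTHOL.

    ``logits`` has one column per non-reference destination (in ``cols``
    order); the reference logit is 0. Stabilized by subtracting the
    row-wise max before exponentiating.
    """
    n = logits.shape[0]
    full = np.full((n, _N_STATES), -np.inf)
    full[:, cols] = logits
    full[:, _REF_COL] = 0.0
    m = full.max(axis=1, keepdims=True)
    ex = np.exp(full - m)
    ex[np.isneginf(full)] = 0.0
    return ex / ex.sum(axis=1, keepdims=True)


def transition_probability_matrix(
    age,
    male,
    race_other,
    init_age_cat,
    below_fpl,
    state_prior,
    state_current,
    coefficients: CoefficientSet,
) -> np.ndarray:
    """Per-person next-state probabilities, shape (n, 5).

    Column ``k`` holds the probability of landing in state code
    ``k + 1``. Forbidden destinations (NEVER for any ever-smoker
    history) carry exactly zero mass; each row sums to 1.
    """
    cur = np.asarray(state_current, dtype=int)
    n = len(cur)
    P = np.zeros((n, _N_STATES), dtype=np.float64)
    never_mask = cur == int(TobaccoState.NEVER)
    ever_mask = ~never_mask

    age = np.asarray(age)
    male = np.asarray(male)
    race_other = np.asarray(race_other)
    init_age_cat = np.asarray(init_age_cat, dtype=object)
    below_fpl = np.asarray(below_fpl)
    prior = np.asarray(state_prior, dtype=int)

    if ever_mask.any():
        X = ever_design_matrix(
            age[ever_mask],
            male[ever_mask],
            race_other[ever_mask],
            init_age_cat[ever_mask],
            below_fpl[ever_mask],
            prior[ever_mask],
            cur[ever_mask],
        )
        L = X @ coefficients.ever_matrix()
        P[ever_mask] = _softmax_with_reference(L, _EVER_COLS)
    if never_mask.any():
        X = never_design_matrix(
            age[never_mask],
            male[never_mask],
            race_other[never_mask],
            init_age_cat[never_mask],
            below_fpl[never_mask],
        )
        L = X @ coefficients.never_matrix()
        P[never_mask] = _softmax_with_reference(L, _NEVER_COLS)
    return P


def compute_probabilities(
    context: TransitionContext, coefficients: CoefficientSet
) -> dict[TobaccoState, float]:
    """Next-state probabilities for a single person.

    Returns a dict over the destinations allowed from the person's
    current state; values sum to 1.
    """
    if context.state_current is TobaccoState.NEVER and context.state_prior is not TobaccoState.NEVER:
        raise ValueError("a never-smoker context requires prior state NEVER")
    P = transition_probability_matrix(
        [context.age],
        [context.male],
        [context.race_other],
        [context.init_age_cat],
        [context.below_fpl],
        [int(context.state_prior)],
        [int(context.state_current)],
        coefficients,
    )[0]
    allowed = allowed_transitions(context.state_current)
    return {s: float(P[int(s) - 1]) for s in sorted(allowed)}


# ---------------------------------------------------------------------
# Rate calibration
# ---------------------------------------------------------------------

_INIT_DEST_COLS = [
    int(TobaccoState.MENTHOL) - 1,
    int(TobaccoState.NONMENTHOL) - 1,
    int(TobaccoState.ECIG_DUAL) - 1,
]
_NEVER_COL = int(TobaccoState.NEVER) - 1
_FORMER_COL = int(TobaccoState.FORMER) - 1
_USER_CODES = np.array([int(s) for s in sorted(CURRENT_USER_STATES)])


def apply_calibration_matrix(
    P: np.ndarray,
    state_current,
    year: int,
    policy: CalibrationPolicy,
) -> np.ndarray:
    """Calibrated copy of an (n, 5) probability matrix.

    Never-smoker rows: the three initiation destinations are scaled by
    the initiation multiplier and the freed mass is returned to NEVER
    (the NEVER->FORMER probability is left untouched — it is not an
    initiation into current use). Current-user rows: the quit
    probability is scaled by the cessation multiplier (clipped at 1)
    and the remaining destinations shrink proportionally. FORMER rows
    pass through unchanged.
    """
    m_init, m_cess = policy.effective(year)
    out = P.copy()
    if m_init == 1.0 and m_cess == 1.0:
        return out
    cur = np.asarray(state_current, dtype=int)

    never = cur == int(TobaccoState.NEVER)
    if never.any() and m_init != 1.0:
        block = out[never]
        freed = (1.0 - m_init) * block[:, _INIT_DEST_COLS].sum(axis=1)
        block[:, _INIT_DEST_COLS] *= m_init
        block[:, _NEVER_COL] += freed
        out[never] = block

    users = np.isin(cur, _USER_CODES)
    if users.any() and m_cess != 1.0:
        block = out[users]
        p_quit = block[:, _FORMER_COL]
        new_quit = np.minimum(p_quit * m_cess, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            shrink = np.where(p_quit < 1.0, (1.0 - new_quit) / (1.0 - p_quit), 0.0)
        block *= shrink[:, None]
        block[:, _FORMER_COL] = new_quit
        out[users] = block
    return out


def apply_calibration(
    probabilities: dict[TobaccoState, float],
    context: TransitionContext,
    policy: CalibrationPolicy,
) -> dict[TobaccoState, float]:
    """Calibrated copy of a single person's probability dict."""
    P = np.zeros((1, _N_STATES))
    for s, p in probabilities.items():
        P[0, int(s) - 1] = p
    out = apply_calibration_matrix(P, [int(context.state_current)], context.year, policy)[0]
    return {s: float(out[int(s) - 1]) for s in probabilities}


# ---------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------


def sample_states(P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per row of an (n, 5) probability matrix.

    Returns state codes (1-5). Uses inverse-CDF sampling on a single
    uniform per row, so the draw is a deterministic function of the
    generator state.
    """
    cdf = np.cumsum(P, axis=1)
    u = rng.random(P.shape[0])
    idx = (u[:, None] > cdf).sum(axis=1)
    return (np.minimum(idx, _N_STATES - 1) + 1).astype(np.int8)


def sample_next_state(
    probabilities: dict[TobaccoState, float], rng: np.random.Generator
) -> TobaccoState:
    """Draw one next-year state from a probability dict."""
    states = sorted(probabilities)
    P = np.array([[probabilities[s] for s in states]])
    total = P.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError("probabilities must sum to 1")
    cdf = np.cumsum(P[0] / total)
    u = rng.random()
    return states[int(np.searchsorted(cdf, u, side="right").clip(max=len(states) - 1))]
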