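"""Tobacco-use state space and transition topology.

Five mutually exclusive adult tobacco-use states, coded 1-5. The codes are
part of the public contract: fitted coefficient tables, serialized
populations and panel files all refer to states by these integers (or the
short names below).

The key structural rule of the model is irreversibility of ever-smoking:
once a person has left the never-smoker state they can never return to it,
so the reachable destination set depends only on whether the current state
is NEVER or not.
"""

from __future__ import annotations

import enum


class TobaccoState(enum.IntEnum):
    """One of the five mutually exclusive tobacco-use states.

    NEVER       never smoked 100 lifetime cigarettes and no regular
                current e-cigarette use
    FORMER      100+ lifetime cigarettes but not a current smoker
    MENTHOL     current smoker whose regular/last brand is menthol- or
                mint-flavored
    NONMENTHOL  current smoker of a non-menthol brand
    ECIG_DUAL   regular current e-cigarette user, with or without
                concurrent cigarette smoking (exclusive e-cigarette users
                and dual users are pooled)
    """

    NEVER = 1
    FORMER = 2
    MENTHOL = 3
    NONMENTHOL = 4
    ECIG_DUAL = 5


#: Short names used in CSV files and configuration.
STATE_NAMES = {
    TobaccoState.NEVER: "never",
    TobaccoState.FORMER: "former",
    TobaccoState.MENTHOL: "menthol",
    TobaccoState.NONMENTHOL: "nonmenthol",
    TobaccoState.ECIG_DUAL: "ecig_dual",
}
STATE_FROM_NAME = {v: k for k, v in STATE_NAMES.items()}

#: States that imply current cigarette smoking (the "cigarette smoker"
#: aggregate reported against cross-sectional survey benchmarks).
CIGARETTE_STATES = frozenset({TobaccoState.MENTHOL, TobaccoState.NONMENTHOL})

#: States implying a lifetime history of smoking / regular e-cig use.
EVER_STATES = frozenset(
    {
        TobaccoState.FORMER,
        TobaccoState.MENTHOL,
        TobaccoState.NONMENTHOL,
        TobaccoState.ECIG_DUAL,
    }
)

#: Current-smoker states subject to the cessation-rate calibration
#: (a transition from any of these to FORMER is a quit event).
CURRENT_USER_STATES = frozenset(
    {TobaccoState.MENTHOL, TobaccoState.NONMENTHOL, TobaccoState.ECIG_DUAL}
)


def allowed_transitions(from_state: TobaccoState) -> frozenset[TobaccoState]:
    """Destination states reachable in one annual step from ``from_state``.

    Never smokers may stay, initiate into any current-use state, or (as a
    rare within-year initiate-and-quit) become former smokers, so all five
    states are reachable. Every ever-smoker state can reach every state
    except NEVER: never-smoking is exited irreversibly.

    Raises
    ------
    ValueError
        If ``from_state`` is not a valid state code.
    """
    try:
        from_state = TobaccoState(from_state)
    except ValueError as err:
        raise ValueError(f"unknown tobacco-use state code: {from_state!r}") from err
    if from_state is TobaccoState.NEVER:
        return frozenset(TobaccoState)
    return EVER_STATES


def classify_record(
    cig_lifetime_100: bool,
    current_smoker: bool,
    menthol_brand: bool | None,
    ecig_regular_current: bool,
) -> TobaccoState:
    """Classify a survey record into one of the five states.

    Parameters mirror the underlying survey items: the lifetime
    100-cigarette threshold, current some-day/every-day smoking, the
    menthol/mint flavor of the regular (or last) brand, and regular
    current e-cigarette use. Regular current e-cigarette use dominates:
    such a person is ECIG_DUAL whether or not they also smoke cigarettes.

    Raises
    ------
    ValueError
        If ``current_smoker`` is claimed without the lifetime threshold,
        or if a current smoker's brand flavor is missing.
    """
    if current_smoker and not cig_lifetime_100:
        raise ValueError(
            "contradictory flags: current smoker without 100 lifetime cigarettes"
        )
    if ecig_regular_current:
        return TobaccoState.ECIG_DUAL
    if current_smoker:
        if menthol_brand is None:
            raise ValueError("menthol_brand required for a current smoker")
        return TobaccoState.MENTHOL if menthol_brand else TobaccoState.NONMENTHOL
    if cig_lifetime_100:
        return TobaccoState.FORMER
    return TobaccoState.NEVER
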