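"""Fitted parameters of the two multinomial transition models.

The next-year state of a person whose current state is an ever-smoker
state follows a multinomial logit over destinations {FORMER, MENTHOL,
NONMENTHOL, ECIG_DUAL} with NONMENTHOL as the reference; the linear
predictor contains dummies for the state two years back (ECIG_DUAL
reference), dummies for the current state (ECIG_DUAL reference), and
six demographic terms. A current never smoker follows a separate
multinomial logit over all five destinations (same NONMENTHOL
reference) with demographic terms only, since every never smoker has
the identical tobacco-use history.

This module defines the covariate vocabulary, the per-person design
rows, and the :class:`CoefficientSet` container with its CSV
round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import TobaccoState

#: Covariates of the ever-smoker model, in design-matrix order.
EVER_COVARIATES = [
    "intercept",
    "prior_never",
    "prior_former",
    "prior_menthol",
    "prior_nonmenthol",
    "cur_former",
    "cur_menthol",
    "cur_nonmenthol",
    "init_lt18",
    "init_ge18",
    "race_other",
    "age",
    "male",
    "below_fpl",
]

#: Covariates of the never-smoker model, in design-matrix order.
NEVER_COVARIATES = [
    "intercept",
    "init_lt18",
    "init_ge18",
    "race_other",
    "age",
    "male",
    "below_fpl",
]

#: Destination states of each model (reference NONMENTHOL omitted).
EVER_DESTINATIONS = [TobaccoState.FORMER, TobaccoState.MENTHOL, TobaccoState.ECIG_DUAL]
NEVER_DESTINATIONS = [
    TobaccoState.NEVER,
    TobaccoState.FORMER,
    TobaccoState.MENTHOL,
    TobaccoState.ECIG_DUAL,
]
REFERENCE_DESTINATION = TobaccoState.NONMENTHOL


def _empty_block(covariates, destinations) -> pd.DataFrame:
    return pd.DataFrame(
        0.0, index=covariates, columns=[int(d) for d in destinations]
    )


@dataclass
class CoefficientSet:
    """Coefficients of both transition models.

    ``ever`` is a (14 covariates x 3 destinations) frame and ``never``
    a (7 x 4) frame; columns are the integer destination codes, rows
    the covariate names above. The reference destination (NONMENTHOL)
    carries implicit zero coefficients and has no column.
    """

    ever: pd.DataFrame = field(default_factory=lambda: _empty_block(EVER_COVARIATES, EVER_DESTINATIONS))
    never: pd.DataFrame = field(default_factory=lambda: _empty_block(NEVER_COVARIATES, NEVER_DESTINATIONS))

    def __post_init__(self) -> None:
        self.ever = self.ever.reindex(
            index=EVER_COVARIATES, columns=[int(d) for d in EVER_DESTINATIONS]
        ).astype(float)
        self.never = self.never.reindex(
            index=NEVER_COVARIATES, columns=[int(d) for d in NEVER_DESTINATIONS]
        ).astype(float)
        if self.ever.isna().any().any() or self.never.isna().any().any():
            raise ValueError("coefficient blocks contain missing cells")

    # matrices in design order, shape (n_covariates, n_destinations)
    def ever_matrix(self) -> np.ndarray:
        return self.ever.to_numpy()

    def never_matrix(self) -> np.ndarray:
        return self.never.to_numpy()

    # -- serialization -------------------------------------------------

    def to_frame(self, standard_errors: "CoefficientSet | None" = None) -> pd.DataFrame:
        rows = []
        for model, block in (("ever", self.ever), ("never", self.never)):
            se_block = None
            if standard_errors is not None:
                se_block = standard_errors.ever if model == "ever" else standard_errors.never
            for cov in block.index:
                for dest in block.columns:
                    rows.append(
                        {
                            "model": model,
                            "destination": int(dest),
                            "covariate": cov,
                            "estimate": float(block.loc[cov, dest]),
                            "std_error": (
                                float(se_block.loc[cov, dest]) if se_block is not None else np.nan
                            ),
                        }
                    )
        return pd.DataFrame(rows)

    def to_csv(self, path, standard_errors: "CoefficientSet | None" = None) -> None:
        self.to_frame(standard_errors).to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CoefficientSet":
        ever = df[df["model"] == "ever"].pivot(
            index="covariate", columns="destination", values="estimate"
        )
        never = df[df["model"] == "never"].pivot(
            index="covariate", columns="destination", values="estimate"
        )
        return cls(ever=ever, never=never)

    @classmethod
    def read_csv(cls, path) -> "CoefficientSet":
        return cls.from_frame(pd.read_csv(path))


# ---------------------------------------------------------------------
# Design rows
# ---------------------------------------------------------------------

_INIT_LT18 = "lt18"
_INIT_GE18 = "ge18"


def ever_design_matrix(
    age,
    male,
    race_other,
    init_age_cat,
    below_fpl,
    state_prior,
    state_current,
) -> np.ndarray:
    """Design matrix rows of the ever-smoker model.

    All arguments are equal-length arrays: ``age`` in integer years at
    the current year, ``male``/``race_other``/``below_fpl`` booleans,
    ``init_age_cat`` strings, and the state codes of the prior
    (two-years-back) and current (one-year-back) states. ECIG_DUAL is
    the omitted reference of both history-dummy blocks.
    """
    age = np.asarray(age, dtype=float)
    prior = np.asarray(state_prior, dtype=int)
    cur = np.asarray(state_current, dtype=int)
    init = np.asarray(init_age_cat, dtype=object)
    n = len(age)
    X = np.empty((n, len(EVER_COVARIATES)), dtype=np.float64)
    X[:, 0] = 1.0
    X[:, 1] = prior == int(TobaccoState.NEVER)
    X[:, 2] = prior == int(TobaccoState.FORMER)
    X[:, 3] = prior == int(TobaccoState.MENTHOL)
    X[:, 4] = prior == int(TobaccoState.NONMENTHOL)
    X[:, 5] = cur == int(TobaccoState.FORMER)
    X[:, 6] = cur == int(TobaccoState.MENTHOL)
    X[:, 7] = cur == int(TobaccoState.NONMENTHOL)
    X[:, 8] = init == _INIT_LT18
    X[:, 9] = init == _INIT_GE18
    X[:, 10] = np.asarray(race_other, dtype=float)
    X[:, 11] = age
    X[:, 12] = np.asarray(male, dtype=float)
    X[:, 13] = np.asarray(below_fpl, dtype=float)
    return X


def never_design_matrix(age, male, race_other, init_age_cat, below_fpl) -> np.ndarray:
    """Design matrix rows of the never-smoker model (demographics only)."""
    age = np.asarray(age, dtype=float)
    init = np.asarray(init_age_cat, dtype=object)
    n = len(age)
    X = np.empty((n, len(NEVER_COVARIATES)), dtype=np.float64)
    X[:, 0] = 1.0
    X[:, 1] = init == _INIT_LT18
    X[:, 2] = init == _INIT_GE18
    X[:, 3] = np.asarray(race_other, dtype=float)
    X[:, 4] = age
    X[:, 5] = np.asarray(male, dtype=float)
    X[:, 6] = np.asarray(below_fpl, dtype=float)
    return X
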