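"""Estimation of the two multinomial transition models from a panel.

Every person observed in three or more consecutive annual waves
contributes one estimation row per sliding window of three waves
(j-2, j-1, j): the states at j-2 and j-1 are predictors, the state at
j is the outcome, and the person's longitudinal survey weight enters
the likelihood as a frequency-style multiplier. Rows whose year-(j-1)
state is NEVER go to the never-smoker model (demographics only); all
other rows go to the ever-smoker model.

The fit maximizes the weighted multinomial log-likelihood by
Newton-Raphson with step halving. Weights are normalized to mean 1
inside the optimizer, which leaves the point estimates unchanged (the
weighted MLE is invariant to a constant rescaling of the weights) and
makes the reported naive standard errors correspond to the actual
number of observation rows rather than the represented population.
Sliding windows from the same person are treated as independent
contributions, so the standard errors ignore within-person
correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coefficients import (
    CoefficientSet,
    EVER_COVARIATES,
    EVER_DESTINATIONS,
    NEVER_COVARIATES,
    NEVER_DESTINATIONS,
    ever_design_matrix,
    never_design_matrix,
)
from .panel import PanelDataset
from .states import TobaccoState


class EstimationError(RuntimeError):
    """Raised when a multinomial fit fails to converge."""


@dataclass
class ModelRows:
    """Design rows of one model: X (n, k), outcome state codes, weights."""

    X: np.ndarray
    outcome: np.ndarray
    weight: np.ndarray
    covariates: list[str]
    destinations: list[TobaccoState]

    def __len__(self) -> int:
        return len(self.outcome)


@dataclass
class BlockFit:
    coefficients: pd.DataFrame  # covariate x destination code
    standard_errors: pd.DataFrame
    log_likelihood: float
    n_obs: int
    dropped_covariates: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class EstimationResult:
    """Fitted coefficients of both models plus diagnostics."""

    coefficients: CoefficientSet
    standard_errors: CoefficientSet
    log_likelihood: float
    n_obs_ever: int
    n_obs_never: int
    dropped_covariates: list[tuple[str, str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------
# Design rows
# ---------------------------------------------------------------------


def build_design_rows(panel: PanelDataset) -> tuple[ModelRows, ModelRows]:
    """Sliding-window estimation rows for the ever and never models.

    Raises a validation error if any person has non-consecutive waves,
    and a data-integrity error if an ever->never transition is observed
    (the state space forbids it).
    """
    panel.validate_consecutive()
    if panel.n_waves < 3:
        raise ValueError("second-order estimation needs at least three waves")
    df = panel.data.sort_values(["person_id", "wave"])
    wide = df.pivot(index="person_id", columns="wave", values="state")
    base = df[df["wave"] == 1].set_index("person_id").loc[wide.index]

    ever_parts: list[dict] = []
    never_parts: list[dict] = []
    waves = sorted(int(w) for w in wide.columns)
    never_code = int(TobaccoState.NEVER)
    for j in waves[2:]:
        s2 = wide[j - 2].to_numpy()
        s1 = wide[j - 1].to_numpy()
        y = wide[j].to_numpy()
        ok = ~(pd.isna(s2) | pd.isna(s1) | pd.isna(y))
        s2, s1, y = s2[ok].astype(int), s1[ok].astype(int), y[ok].astype(int)
        sub = base[ok]
        age_j1 = sub["age"].to_numpy() + (j - 2)  # age in year j-1

        bad = (y == never_code) & (s1 != never_code)
        bad |= (s1 == never_code) & (s2 != never_code)
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} rows show an ever->never transition; "
                "never-smoking cannot be re-entered"
            )
        never_mask = s1 == never_code
        common = dict(
            age=age_j1,
            male=(sub["sex"].to_numpy() == "male"),
            race_other=(sub["race_group"].to_numpy() == "other"),
            init_age_cat=sub["init_age_cat"].to_numpy(),
            below_fpl=(sub["poverty"].to_numpy() == "below_fpl"),
            weight=sub["weight"].to_numpy().astype(float),
        )
        ever_parts.append(
            {k: v[~never_mask] for k, v in common.items()}
            | {"s2": s2[~never_mask], "s1": s1[~never_mask], "y": y[~never_mask]}
        )
        never_parts.append(
            {k: v[never_mask] for k, v in common.items()} | {"y": y[never_mask]}
        )

    def _stack(parts, key):
        return np.concatenate([p[key] for p in parts])

    ever_X = ever_design_matrix(
        _stack(ever_parts, "age"),
        _stack(ever_parts, "male"),
        _stack(ever_parts, "race_other"),
        _stack(ever_parts, "init_age_cat"),
        _stack(ever_parts, "below_fpl"),
        _stack(ever_parts, "s2"),
        _stack(ever_parts, "s1"),
    )
    ever_rows = ModelRows(
        ever_X,
        _stack(ever_parts, "y"),
        _stack(ever_parts, "weight"),
        list(EVER_COVARIATES),
        list(EVER_DESTINATIONS),
    )
    never_X = never_design_matrix(
        _stack(never_parts, "age"),
        _stack(never_parts, "male"),
        _stack(never_parts, "race_other"),
        _stack(never_parts, "init_age_cat"),
        _stack(never_parts, "below_fpl"),
    )
    never_rows = ModelRows(
        never_X,
        _stack(never_parts, "y"),
        _stack(never_parts, "weight"),
        list(NEVER_COVARIATES),
        list(NEVER_DESTINATIONS),
    )
    return ever_rows, never_rows


# ---------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------


def _full_logits(X: np.ndarray, B: np.ndarray) -> np.ndarray:
    """(n, d+1) logit matrix with the reference category appended as 0."""
    L = X @ B
    return np.hstack([L, np.zeros((len(L), 1))])


def _log_softmax(full: np.ndarray) -> np.ndarray:
    m = full.max(axis=1, keepdims=True)
    lse = m + np.log(np.exp(full - m).sum(axis=1, keepdims=True))
    return full - lse


def _outcome_index(outcome: np.ndarray, destinations, reference: int) -> np.ndarray:
    codes = [int(d) for d in destinations] + [reference]
    lut = {c: i for i, c in enumerate(codes)}
    try:
        return np.array([lut[int(c)] for c in outcome])
    except KeyError as err:
        raise ValueError(f"outcome state {err} not among model destinations") from err


def loglik(rows: ModelRows, block: pd.DataFrame, reference: int = int(TobaccoState.NONMENTHOL)) -> float:
    """Weighted multinomial log-likelihood of one model block.

    ``block`` is a covariate-by-destination coefficient frame as stored
    in :class:`CoefficientSet`. Computed via log-sum-exp so the result
    is finite for any finite logits.
    """
    B = block.reindex(index=rows.covariates).to_numpy()
    yidx = _outcome_index(rows.outcome, block.columns, reference)
    logp = _log_softmax(_full_logits(rows.X, B))
    return float(np.sum(rows.weight * logp[np.arange(len(yidx)), yidx]))


def fit_multinomial(
    rows: ModelRows,
    reference_destination: TobaccoState = TobaccoState.NONMENTHOL,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> BlockFit:
    """Weighted multinomial logit fit of one model block.

    Covariates with no within-sample variation are dropped (their
    coefficients fixed at zero) and reported; an outcome category that
    never occurs is likewise dropped from the fit, with its
    coefficients set so the predicted probability is effectively zero.
    Convergence requires the gradient max-norm (at mean-1 weight
    scale) to fall below ``tol``.
    """
    if len(rows) == 0:
        raise ValueError("no estimation rows")
    ref = int(reference_destination)
    dest_codes = [int(d) for d in rows.destinations if int(d) != ref]
    dropped: list[tuple[str, str]] = []

    present = set(np.unique(rows.outcome).astype(int))
    if ref not in present:
        raise EstimationError("reference destination absent from outcomes")
    absent = [c for c in dest_codes if c not in present]
    for c in absent:
        warnings.warn(
            f"outcome state {c} absent; fitting reduced destination set", stacklevel=2
        )
        dropped.append((TobaccoState(c).name.lower(), "outcome category absent"))
    kept_dest = [c for c in dest_codes if c in present]

    keep_cov = [0] + [
        k
        for k in range(1, rows.X.shape[1])
        if np.ptp(rows.X[:, k]) > 0
    ]
    for k in range(1, rows.X.shape[1]):
        if k not in keep_cov:
            dropped.append((rows.covariates[k], "no within-sample variation"))
    X = rows.X[:, keep_cov]
    n, k = X.shape
    d = len(kept_dest)
    w = rows.weight * (n / rows.weight.sum())  # mean-1 normalization
    yidx = _outcome_index(rows.outcome, kept_dest, ref)
    Y = np.zeros((n, d))
    on = yidx < d
    Y[np.arange(n)[on], yidx[on]] = 1.0

    B = np.zeros((k, d))
    prev_ll = -np.inf
    H = None
    for _ in range(max_iter):
        logp = _log_softmax(_full_logits(X, B))
        P = np.exp(logp[:, :d])
        ll = float(np.sum(w * logp[np.arange(n), yidx]))
        G = X.T @ (w[:, None] * (P - Y))  # (k, d) gradient of -ll is G
        gnorm = np.abs(G).max()
        H = np.empty((k * d, k * d))
        for a in range(d):
            for b in range(a, d):
                s = w * (P[:, a] * ((a == b) - P[:, b]))
                blockH = X.T @ (X * s[:, None])
                H[a * k : (a + 1) * k, b * k : (b + 1) * k] = blockH
                H[b * k : (b + 1) * k, a * k : (a + 1) * k] = blockH
        if gnorm < tol:
            prev_ll = ll
            break
        try:
            delta = np.linalg.solve(
                H + 1e-10 * np.eye(k * d), -G.reshape(-1, order="F")
            ).reshape((k, d), order="F")
        except np.linalg.LinAlgError as err:
            raise EstimationError(f"singular Hessian (separation?): {err}") from err
        # step halving on the penalized objective
        step = 1.0
        for _half in range(40):
            cand = B + step * delta
            logp_c = _log_softmax(_full_logits(X, cand))
            ll_c = float(np.sum(w * logp_c[np.arange(n), yidx]))
            if ll_c >= ll - 1e-12:
                break
            step *= 0.5
        B = B + step * delta
        prev_ll = ll
    else:
        raise EstimationError(
            f"no convergence after {max_iter} iterations (grad norm {gnorm:.3g})"
        )

    cov = np.linalg.inv(H + 1e-10 * np.eye(k * d))
    se = np.sqrt(np.maximum(np.diag(cov), 0.0)).reshape((k, d), order="F")

    coef_full = pd.DataFrame(0.0, index=rows.covariates, columns=dest_codes)
    se_full = pd.DataFrame(np.nan, index=rows.covariates, columns=dest_codes)
    for j, c in enumerate(kept_dest):
        coef_full.loc[[rows.covariates[i] for i in keep_cov], c] = B[:, j]
        se_full.loc[[rows.covariates[i] for i in keep_cov], c] = se[:, j]
    for c in absent:
        coef_full.loc["intercept", c] = -30.0  # probability effectively zero

    # report log-likelihood on the original weight scale
    ll_actual = prev_ll * (rows.weight.sum() / n)
    return BlockFit(coef_full, se_full, ll_actual, n, dropped)


def fit_transition_models(panel: PanelDataset, tol: float = 1e-8, max_iter: int = 500) -> EstimationResult:
    """Fit both transition models to a weighted panel."""
    ever_rows, never_rows = build_design_rows(panel)
    ever_fit = fit_multinomial(ever_rows, tol=tol, max_iter=max_iter)
    never_fit = fit_multinomial(never_rows, tol=tol, max_iter=max_iter)
    coeffs = CoefficientSet(ever=ever_fit.coefficients, never=never_fit.coefficients)
    ses = CoefficientSet(
        ever=ever_fit.standard_errors.fillna(0.0),
        never=never_fit.standard_errors.fillna(0.0),
    )
    dropped = [("ever", c, r) for c, r in ever_fit.dropped_covariates] + [
        ("never", c, r) for c, r in never_fit.dropped_covariates
    ]
    return EstimationResult(
        coefficients=coeffs,
        standard_errors=ses,
        log_likelihood=ever_fit.log_likelihood + never_fit.log_likelihood,
        n_obs_ever=ever_fit.n_obs,
        n_obs_never=never_fit.n_obs,
        dropped_covariates=dropped,
    )
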