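"""Logistic model of participation given pre-consent observations.

The fitted model serves two roles: its Nagelkerke pseudo-R-squared summarizes
how much of the variation in consent the observational measurements explain,
and its fitted probabilities are the propensity scores used for matching.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .data_model import (
    OBS_MEASUREMENTS,
    DyadRecord,
    ParticipationStatus,
    not_participating,
    participating,
    records_to_frame,
)

log = logging.getLogger(__name__)

#: predictor presets; "observational" is the default model of the pipeline,
#: "extended" adds the demographic covariates (incl. child gender).
PREDICTOR_PRESETS: dict[str, list[str]] = {
    "observational": list(OBS_MEASUREMENTS),
    "extended": list(OBS_MEASUREMENTS)
    + ["child_age", "child_gender_male", "parent_gender_female", "other_adults_present", "other_children_present", "site_code"],
}

RIDGE_LAMBDA = 1e-4  # slope-only penalty, auto-enabled on detected separation
MAX_ITER = 100
LL_TOL = 1e-10


class NoVariationError(ValueError):
    """The participation outcome takes a single value."""


class ConvergenceError(RuntimeError):
    """Maximum-likelihood iterations failed to converge."""

    def __init__(self, msg: str, last_params: np.ndarray | None = None):
        super().__init__(msg)
        self.last_params = last_params


class SeparationError(RuntimeError):
    """Perfect separation without a penalty: the MLE does not exist."""


@dataclass
class LogisticFit:
    """Raw logistic fit shared by the consent and binary imputation models."""

    params: np.ndarray  # intercept first
    cov_params: np.ndarray
    loglik: float
    converged: bool
    penalized: bool


@dataclass
class PropensityModel:
    predictor_names: list[str]
    params: np.ndarray  # [intercept, slopes...], log-odds units
    cov_params: np.ndarray
    loglik_full: float
    loglik_null: float
    n: int
    nagelkerke_r2: float
    converged: bool
    penalized: bool = False
    n_positive: int = 0

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    def summary_frame(self) -> pd.DataFrame:
        """Tidy per-term table: estimate, Wald SE, z and two-tailed p."""
        se = self.se
        z = self.params / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "term": ["intercept"] + list(self.predictor_names),
                "estimate": self.params,
                "se": se,
                "z": z,
                "p": p,
            }
        )


def _derived_columns(frame: pd.DataFrame) -> pd.DataFrame:
    """Add encoded demographic predictors used by the 'extended' preset."""
    out = frame.copy()
    if "child_gender" in out.columns:
        out["child_gender_male"] = (out["child_gender"] == "male").astype(float)
    if "parent_gender" in out.columns:
        out["parent_gender_female"] = (out["parent_gender"] == "female").astype(float)
    if "site" in out.columns:
        levels = sorted(out["site"].astype(str).unique())
        codes = {lvl: i for i, lvl in enumerate(levels)}
        out["site_code"] = out["site"].astype(str).map(codes).astype(float)
    for col in ("other_adults_present", "other_children_present"):
        if col in out.columns:
            out[col] = out[col].astype(float)
    return out


def _loglik(params: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ params
    # log(1+exp(eta)) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 0.0,
    allow_auto_ridge: bool = True,
) -> LogisticFit:
    """Maximum-likelihood logistic regression (intercept in column 0 of X).

    Fits by IRLS/Newton through statsmodels; on detected separation or
    non-convergence an L2 penalty of ``RIDGE_LAMBDA`` on the slopes (never
    the intercept) is auto-enabled with a logged warning.
    """
    y = np.asarray(y, dtype=float)
    if np.all(y == y[0]):
        raise NoVariationError("outcome is constant; logistic model has no variation to fit")
    if ridge > 0:
        return _fit_ridge(X, y, ridge)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            # non-convergence is detected below via mle_retvals; the stock
            # warning would only duplicate our own handling
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.filterwarnings("ignore", message="Maximum Likelihood optimization failed")
            res = sm.Logit(y, X).fit(disp=0, maxiter=MAX_ITER, tol=LL_TOL)
        converged = bool(res.mle_retvals.get("converged", True))
        suspicious = not converged or not np.all(np.isfinite(res.bse)) or np.abs(res.params).max() > 30
        if suspicious:
            raise PerfectSeparationError("suspect separation / non-convergence")
        return LogisticFit(
            params=np.asarray(res.params, dtype=float),
            cov_params=np.asarray(res.cov_params(), dtype=float),
            loglik=float(res.llf),
            converged=True,
            penalized=False,
        )
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError) as exc:
        if not allow_auto_ridge:
            raise SeparationError(f"separation detected and penalty disabled: {exc}") from exc
        log.warning("separation/non-convergence detected; refitting with ridge lambda=%g on slopes", RIDGE_LAMBDA)
        return _fit_ridge(X, y, RIDGE_LAMBDA)


def _fit_ridge(X: np.ndarray, y: np.ndarray, lam: float) -> LogisticFit:
    p = X.shape[1]
    pen_mask = np.ones(p)
    pen_mask[0] = 0.0  # never penalize the intercept

    def nll(beta: np.ndarray) -> float:
        return -_loglik(beta, X, y) + 0.5 * lam * np.sum(pen_mask * beta**2)

    def grad(beta: np.ndarray) -> np.ndarray:
        mu = special.expit(X @ beta)
        return -(X.T @ (y - mu)) + lam * pen_mask * beta

    res = optimize.minimize(nll, np.zeros(p), jac=grad, method="L-BFGS-B", options={"maxiter": 1000})
    beta = res.x
    if not res.success:
        raise ConvergenceError(f"penalized logistic fit failed: {res.message}", last_params=beta)
    mu = special.expit(X @ beta)
    W = mu * (1 - mu)
    hess = (X.T * W) @ X + lam * np.diag(pen_mask)
    cov = np.linalg.inv(hess)
    return LogisticFit(params=beta, cov_params=cov, loglik=_loglik(beta, X, y), converged=True, penalized=True)


def null_loglik(y: np.ndarray) -> float:
    """Log-likelihood of the intercept-only logistic model (closed form)."""
    y = np.asarray(y, dtype=float)
    n, n1 = y.size, y.sum()
    n0 = n - n1
    if n1 == 0 or n0 == 0:
        return 0.0
    p = n1 / n
    return float(n1 * np.log(p) + n0 * np.log(1 - p))


def nagelkerke_r2(loglik_null: float, loglik_full: float, n: int) -> float:
    """Nagelkerke's pseudo-R-squared (Cox-Snell normalized to [0, 1])."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if loglik_full < loglik_null - 1e-9:
        raise ValueError("full-model log-likelihood below null log-likelihood")
    cox_snell = 1.0 - np.exp(2.0 * (loglik_null - loglik_full) / n)
    denom = 1.0 - np.exp(2.0 * loglik_null / n)
    if denom == 0:
        raise ZeroDivisionError("Nagelkerke denominator is zero (null log-likelihood is 0)")
    return float(cox_snell / denom)


def fit_consent_model(
    records: Sequence[DyadRecord] | pd.DataFrame,
    predictors: Sequence[str] | str = "observational",
    pool_consented_untested: bool = False,
    ridge: float = 0.0,
) -> PropensityModel:
    """Fit the participation logistic model.

    Participation is 1 for tested dyads and 0 for the not-participating group
    (refusers by default).  Rows with a missing predictor are dropped
    (complete-case) with a logged count.
    """
    if isinstance(records, pd.DataFrame):
        frame = records.copy()
        part = frame[frame["status"] == ParticipationStatus.TESTED.value]
        pools = [ParticipationStatus.REFUSED.value]
        if pool_consented_untested:
            pools.append(ParticipationStatus.CONSENTED_UNTESTED.value)
        nonpart = frame[frame["status"].isin(pools)]
    else:
        part = records_to_frame(participating(records))
        nonpart = records_to_frame(not_participating(records, pool_consented_untested))
    if len(part) == 0 or len(nonpart) == 0:
        raise NoVariationError(
            f"need both outcome classes: {len(part)} participating, {len(nonpart)} not-participating"
        )
    names = list(PREDICTOR_PRESETS[predictors]) if isinstance(predictors, str) else list(predictors)
    data = _derived_columns(pd.concat([part, nonpart], ignore_index=True))
    y = np.concatenate([np.ones(len(part)), np.zeros(len(nonpart))])
    complete = data[names].notna().all(axis=1).to_numpy()
    if not complete.all():
        log.warning("dropping %d rows with missing predictors from the consent model", (~complete).sum())
    data, y = data[complete], y[complete]
    X = np.column_stack([np.ones(len(data)), data[names].to_numpy(dtype=float)])
    fit = fit_logistic(X, y, ridge=ridge)
    ll0 = null_loglik(y)
    return PropensityModel(
        predictor_names=names,
        params=fit.params,
        cov_params=fit.cov_params,
        loglik_full=fit.loglik,
        loglik_null=ll0,
        n=int(len(y)),
        nagelkerke_r2=nagelkerke_r2(ll0, fit.loglik, len(y)),
        converged=fit.converged,
        penalized=fit.penalized,
        n_positive=int(y.sum()),
    )


def propensity_scores(
    model: PropensityModel, records: Sequence[DyadRecord] | pd.DataFrame
) -> pd.Series:
    """Propensity score (fitted participation probability) per dyad.

    Returns a Series indexed by dyad_id.  Dyads missing a predictor get NaN
    and a logged warning; others are unaffected.
    """
    if not model.converged:
        raise ConvergenceError("propensity scores requested from a non-converged model")
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(list(records))
    data = _derived_columns(frame)
    values = data[model.predictor_names].to_numpy(dtype=float)
    eta = model.params[0] + values @ model.params[1:]
    scores = special.expit(eta)
    missing = ~np.isfinite(values).all(axis=1)
    if missing.any():
        log.warning("%d dyads missing predictors: propensity set to NaN", missing.sum())
        scores = np.where(missing, np.nan, scores)
    return pd.Series(scores, index=frame["dyad_id"].astype(str).to_numpy(), name="propensity")
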