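"""Per-outcome predictive models and stochastic multiple imputation.

Models are fitted on the participating group only: gaussian linear models
(ordinary least squares) for the continuous/count test measurements and
logistic models for the binary ones.  Imputation is "proper" by default —
each run first draws the residual variance from its scaled inverse
chi-square sampling distribution, then the coefficients from their normal
sampling distribution, and only then the outcomes — so the spread across
runs reflects estimation uncertainty as well as residual noise.  A plug-in
variant (point estimates, residual noise only) is exposed for tests and
degenerate fixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special

from . import consent_model
from .data_model import (
    BINARY_TEST_MEASUREMENTS,
    CUMULATIVE_PAIRS,
    OBS_MEASUREMENTS,
    TEST_MEASUREMENTS,
    DyadRecord,
    ParticipationStatus,
    ValidationError,
    records_to_frame,
)
from .scores import CollinearityError
from .util import ReproducibilityError, as_rng, child_rng, child_seed_int

log = logging.getLogger(__name__)

GAUSSIAN = "gaussian-linear"
BINARY = "binary-logistic"

#: valid ranges imputed values are clipped to (counts >= 0, nontarget <= 4)
CLIP_RANGES: dict[str, tuple[float, float | None]] = {
    "total_play_time": (0.0, None),
    "whole_unique_actions": (0.0, None),
    "first_unique_actions": (0.0, None),
    "whole_nontarget_functions": (0.0, 4.0),
    "first_nontarget_functions": (0.0, 4.0),
}


@dataclass
class ImputationModel:
    measurement: str
    family: str
    predictor_names: list[str]
    params: np.ndarray | None  # intercept first; None when degenerate-constant
    cov_params: np.ndarray | None = None
    resid_var: float = 0.0
    df_resid: int = 0
    n: int = 0
    degenerate_constant: float | None = None
    penalized: bool = False


@dataclass
class ImputationModelSet:
    predictor_names: list[str]
    models: dict[str, ImputationModel]
    measurements: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.measurements:
            self.measurements = list(self.models)


@dataclass
class ImputedRun:
    """One stochastic imputation of the target group's outcomes.

    ``values`` holds the raw model-scale draws used for all group statistics:
    clipping or rounding before averaging would bias the group means, so the
    draws are left untouched there.  ``n_clipped`` records how many draws per
    measurement fall outside the valid outcome ranges; ``postprocessed()``
    materializes a table of valid outcome values (clipped, integer-rounded,
    first-minute counts capped at their whole-period counterparts) for export
    as records or human-facing reports.
    """

    run_index: int
    seed: int
    values: pd.DataFrame  # index dyad_id, columns = measurements
    n_clipped: dict[str, int] = field(default_factory=dict)

    def postprocessed(self) -> pd.DataFrame:
        out = self.values.copy()
        for m, (lo, hi) in CLIP_RANGES.items():
            if m in out:
                out[m] = out[m].clip(lower=lo, upper=hi)
        for m in out.columns:
            if m != "total_play_time":
                out[m] = out[m].round()
        for first, whole in CUMULATIVE_PAIRS:
            if first in out and whole in out:
                out[first] = np.minimum(out[first], out[whole])
        return out


def _design(frame: pd.DataFrame, predictors: Sequence[str]) -> np.ndarray:
    vals = frame[list(predictors)].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(frame)), vals])


def _check_rank(X: np.ndarray, predictors: Sequence[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the aliased predictors via the QR diagonal
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        aliased = [(["intercept"] + list(predictors))[j] for j in np.where(diag < tol)[0]]
        raise CollinearityError(f"design matrix rank-deficient; aliased predictors: {aliased}")


def fit_imputation_models(
    participating: Sequence[DyadRecord] | pd.DataFrame,
    predictors: Sequence[str] | None = None,
    measurements: Sequence[str] | None = None,
) -> ImputationModelSet:
    """Fit one predictive model per test measurement on the participating group.

    Gaussian measurements use OLS with the unbiased residual-variance
    estimate (df = n - p - 1) and the coefficient covariance retained for
    proper draws.  Binary measurements use the logistic fitting machinery of
    the consent model; a constant binary outcome is marked degenerate and
    later imputed as that constant with a warning.
    """
    predictors = list(predictors) if predictors is not None else list(OBS_MEASUREMENTS)
    measurements = list(measurements) if measurements is not None else list(TEST_MEASUREMENTS)
    frame = participating if isinstance(participating, pd.DataFrame) else records_to_frame(list(participating))
    if "status" in frame.columns:
        frame = frame[frame["status"] == ParticipationStatus.TESTED.value]
    n, p = len(frame), len(predictors)
    X = _design(frame, predictors)
    _check_rank(X, predictors)

    models: dict[str, ImputationModel] = {}
    for m in measurements:
        y = frame[m].to_numpy(dtype=float)
        if m in BINARY_TEST_MEASUREMENTS:
            if np.all(y == y[0]):
                log.warning("binary measurement %r constant in training data; imputing the constant", m)
                models[m] = ImputationModel(
                    measurement=m, family=BINARY, predictor_names=predictors,
                    params=None, n=n, degenerate_constant=float(y[0]),
                )
                continue
            fit = consent_model.fit_logistic(X, y)
            models[m] = ImputationModel(
                measurement=m, family=BINARY, predictor_names=predictors,
                params=fit.params, cov_params=fit.cov_params, n=n, penalized=fit.penalized,
            )
        else:
            if n <= p + 1:
                raise ValueError(
                    f"gaussian model for {m!r} underdetermined: n={n} with {p} predictors"
                )
            res = sm.OLS(y, X).fit()
            resid_var = float(res.ssr / res.df_resid)
            # covariance at the point estimate: resid_var * (X'X)^-1
            cov = np.asarray(res.normalized_cov_params, dtype=float) * resid_var
            models[m] = ImputationModel(
                measurement=m, family=GAUSSIAN, predictor_names=predictors,
                params=np.asarray(res.params, dtype=float), cov_params=cov,
                resid_var=resid_var, df_resid=int(res.df_resid), n=n,
            )
    return ImputationModelSet(predictor_names=predictors, models=models, measurements=measurements)


def _coef_factor(cov: np.ndarray) -> np.ndarray | None:
    """Square-root factor of a coefficient covariance; None when it is zero."""
    if not np.any(cov):
        return None
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        # near-singular covariance: eigenvalue square root with clipping
        w, v = np.linalg.eigh(cov)
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def _draw_gaussian(
    model: ImputationModel, Xt: np.ndarray, rng: np.random.Generator, proper: bool
) -> np.ndarray:
    nt = Xt.shape[0]
    if model.resid_var == 0.0:
        # deterministic relation: no residual noise in either mode, and no
        # coefficient uncertainty worth drawing (covariance is zero too)
        return Xt @ model.params
    if not proper:
        return Xt @ model.params + rng.normal(0.0, np.sqrt(model.resid_var), nt)
    sigma2_star = model.resid_var * model.df_resid / rng.chisquare(model.df_resid)
    scale = sigma2_star / model.resid_var
    factor = _coef_factor(model.cov_params * scale)
    beta_star = model.params
    if factor is not None:
        beta_star = beta_star + factor @ rng.standard_normal(model.params.size)
    return Xt @ beta_star + rng.normal(0.0, np.sqrt(sigma2_star), nt)


def _draw_binary(
    model: ImputationModel, Xt: np.ndarray, rng: np.random.Generator, proper: bool
) -> np.ndarray:
    nt = Xt.shape[0]
    if model.degenerate_constant is not None:
        return np.full(nt, model.degenerate_constant)
    beta = model.params
    if proper:
        factor = _coef_factor(model.cov_params)
        if factor is not None:
            beta = beta + factor @ rng.standard_normal(beta.size)
    p = special.expit(Xt @ beta)
    return rng.binomial(1, p).astype(float)


def impute_run(
    models: ImputationModelSet,
    targets: Sequence[DyadRecord] | pd.DataFrame,
    rng: int | np.random.Generator,
    proper: bool = True,
    run_index: int = 1,
    seed: int = -1,
) -> ImputedRun:
    """Impute one stochastic outcome set for the target dyads."""
    rng = as_rng(rng)
    frame = targets if isinstance(targets, pd.DataFrame) else records_to_frame(list(targets))
    vals = frame[models.predictor_names].to_numpy(dtype=float)
    bad = ~np.isfinite(vals).all(axis=1)
    if bad.any():
        ids = frame.loc[bad, "dyad_id"].tolist()
        raise ValidationError(f"targets missing predictor values: {ids}")
    Xt = np.column_stack([np.ones(len(frame)), vals])

    out: dict[str, np.ndarray] = {}
    n_clipped: dict[str, int] = {}
    for m in models.measurements:
        model = models.models[m]
        if model.family == BINARY:
            y = _draw_binary(model, Xt, rng, proper)
        else:
            y = _draw_gaussian(model, Xt, rng, proper)
        lo, hi = CLIP_RANGES.get(m, (None, None))
        clipped = np.zeros(len(y), dtype=bool)
        if lo is not None:
            clipped |= y < lo
        if hi is not None:
            clipped |= y > hi
        n_clipped[m] = int(clipped.sum())
        out[m] = y
    values = pd.DataFrame(out, index=pd.Index(frame["dyad_id"].astype(str), name="dyad_id"))
    return ImputedRun(run_index=run_index, seed=seed, values=values, n_clipped=n_clipped)


def multiple_impute(
    models: ImputationModelSet,
    targets: Sequence[DyadRecord] | pd.DataFrame,
    m: int,
    master_seed: int,
    proper: bool = True,
) -> list[ImputedRun]:
    """Run ``m`` independent imputations with counter-derived child seeds.

    Run k draws from the stream seeded by ``SeedSequence((master_seed, k))``,
    so identical master seeds reproduce all runs bit-for-bit while the runs
    stay mutually independent.
    """
    if m < 1:
        raise ValueError(f"number of imputation runs must be >= 1, got {m}")
    frame = targets if isinstance(targets, pd.DataFrame) else records_to_frame(list(targets))
    runs = []
    for k in range(1, m + 1):
        runs.append(
            impute_run(
                models, frame, child_rng(master_seed, k), proper=proper,
                run_index=k, seed=child_seed_int(master_seed, k),
            )
        )
    return runs


def stack_runs(runs: Sequence[ImputedRun], measurements: Sequence[str] | None = None) -> np.ndarray:
    """Imputed values as an (m, n_targets, n_measurements) array."""
    if measurements is None:
        measurements = list(runs[0].values.columns)
    return np.stack([r.values[list(measurements)].to_numpy(dtype=float) for r in runs])


def runs_to_long(runs: Sequence[ImputedRun]) -> pd.DataFrame:
    """Long-format (run_index, dyad_id, measurement, value) table."""
    frames = []
    for r in runs:
        df = r.values.reset_index().melt(id_vars="dyad_id", var_name="measurement", value_name="value")
        df.insert(0, "run_index", r.run_index)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def long_to_runs(long: pd.DataFrame) -> list[ImputedRun]:
    """Rebuild ImputedRun values from the persisted long-format table."""
    runs = []
    for k, chunk in long.groupby("run_index", sort=True):
        values = chunk.pivot_table(index="dyad_id", columns="measurement", values="value", sort=False)
        # preserve the original dyad order within each run
        order = chunk["dyad_id"].drop_duplicates().tolist()
        runs.append(ImputedRun(run_index=int(k), seed=-1, values=values.loc[order]))
    return runs
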