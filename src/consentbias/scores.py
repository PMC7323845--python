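"""Standardization, composite exploration scores, and shared statistics.

Exploration variability is the sum of z-scores of the whole-period test
measurements; exploration efficiency is the sum of z-scores of the
first-minute measurements.  Imputed children are standardized against the
same participating-group reference parameters as observed children, so the
composites of the two groups live on a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    FIRST_MINUTE_MEASUREMENTS,
    TEST_MEASUREMENTS,
    WHOLE_PERIOD_MEASUREMENTS,
    ValidationError,
)


class DegenerateScaleError(ValueError):
    """A standard deviation needed as a denominator is zero or undefined."""


class CollinearityError(ValueError):
    """Rank-deficient control/design matrix."""


class UndefinedCorrelationError(ValueError):
    """Residuals are constant, so the correlation is undefined."""


def zscore(
    values: Sequence[float] | np.ndarray,
    reference: tuple[float, float] | None = None,
) -> np.ndarray:
    """Standardize ``values`` to z-scores.

    With ``reference=(mean, sd)`` the linear transform ``(v - mean)/sd`` is
    applied; otherwise the sample mean and sample SD (n-1 denominator) of
    ``values`` themselves are used, giving output with mean 0 and SD 1.
    """
    arr = np.asarray(values, dtype=float)
    if reference is None:
        if arr.size < 2:
            raise DegenerateScaleError("self-referenced z-scores need at least 2 values")
        mean, sd = arr.mean(), arr.std(ddof=1)
    else:
        mean, sd = float(reference[0]), float(reference[1])
    if not np.isfinite(sd) or sd <= 0:
        raise DegenerateScaleError(f"standard deviation must be positive, got {sd}")
    return (arr - mean) / sd


@dataclass
class CompositeScores:
    """Per-child composite scores plus the reference parameters used."""

    scores: pd.DataFrame  # columns: exploration_variability, exploration_efficiency
    reference_params: dict[str, tuple[float, float]] = field(default_factory=dict)


def reference_parameters(
    reference_group: pd.DataFrame, measurements: Sequence[str]
) -> dict[str, tuple[float, float]]:
    """(mean, sample SD) per measurement from the reference group."""
    params: dict[str, tuple[float, float]] = {}
    for m in measurements:
        col = reference_group[m].astype(float)
        mean, sd = col.mean(), col.std(ddof=1)
        if not np.isfinite(sd) or sd <= 0:
            raise DegenerateScaleError(f"reference SD for measurement {m!r} is degenerate ({sd})")
        params[m] = (float(mean), float(sd))
    return params


def composite_scores(
    outcomes: pd.DataFrame,
    reference_group: pd.DataFrame | None = None,
    variability_set: Sequence[str] | None = None,
    efficiency_set: Sequence[str] | None = None,
) -> CompositeScores:
    """Compute exploration variability and efficiency per child.

    ``outcomes`` holds one row per child with the test-measurement columns;
    ``reference_group`` (default: ``outcomes`` itself, i.e. the participating
    group) supplies the standardization parameters.  The measurement sets
    default to the three whole-period and three first-minute measurements;
    total play time belongs to neither window and is reported separately.
    """
    variability_set = list(variability_set if variability_set is not None else WHOLE_PERIOD_MEASUREMENTS)
    efficiency_set = list(efficiency_set if efficiency_set is not None else FIRST_MINUTE_MEASUREMENTS)
    if reference_group is None:
        reference_group = outcomes
    params = reference_parameters(reference_group, sorted(set(variability_set) | set(efficiency_set)))

    def summed_z(cols: Sequence[str]) -> pd.Series:
        total = pd.Series(0.0, index=outcomes.index)
        for m in cols:
            total = total + zscore(outcomes[m].to_numpy(dtype=float), reference=params[m])
        return total

    frame = pd.DataFrame(
        {
            "exploration_variability": summed_z(variability_set),
            "exploration_efficiency": summed_z(efficiency_set),
        },
        index=outcomes.index,
    )
    return CompositeScores(scores=frame, reference_params=params)


@dataclass(frozen=True)
class PartialCorrelation:
    r: float
    df: int
    p: float
    n: int


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    controls: Sequence[Sequence[float]] | np.ndarray | None = None,
) -> PartialCorrelation:
    """Partial Pearson correlation of x and y controlling for covariates.

    Both variables are regressed (with intercept) on the control vectors; the
    Pearson correlation of the residuals is returned with df = n - 2 - k and
    a two-tailed p from the t transform.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if controls is None or len(controls) == 0:
        C = np.empty((x.size, 0))
    else:
        C = np.column_stack([np.asarray(c, dtype=float) for c in controls])
    n, k = x.size, C.shape[1]
    if y.size != n or C.shape[0] != n:
        raise ValueError("x, y and controls must have equal length")
    if n <= 2 + k:
        raise ValueError(f"need n > 2 + k, got n={n}, k={k}")
    design = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError("control matrix (with intercept) is rank-deficient")
    coef_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ coef_x
    ry = y - design @ coef_y
    if np.allclose(rx, 0) or np.allclose(ry, 0) or rx.std() == 0 or ry.std() == 0:
        raise UndefinedCorrelationError("residuals are constant; partial correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialCorrelation(r=r, df=df, p=p, n=n)


def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Cohen's d with the pooled (n-1-weighted) within-group SD."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 members")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    diff = a.mean() - b.mean()
    if pooled_var <= 0:
        if diff == 0:
            return 0.0
        raise DegenerateScaleError("pooled SD is zero")
    return float(diff / np.sqrt(pooled_var))


def fishers_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-tailed Fisher's exact p for a 2x2 table.

    Uses the probability-mass rule: the p-value sums hypergeometric
    probabilities of all tables with the observed margins whose probability
    does not exceed that of the observed table.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValidationError("table cells must be non-negative")
    if not np.all(arr == np.floor(arr)):
        raise ValidationError("table cells must be integers")
    _, p = stats.fisher_exact(arr.astype(int), alternative="two-sided")
    return float(min(p, 1.0))
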