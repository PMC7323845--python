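"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's own code paths (and scipy's Fisher
routine): enumeration, grid search and explicit formulas only.
"""

from __future__ import annotations

from math import comb

import numpy as np


def fisher_enum_two_tailed(table) -> float:
    """Two-tailed Fisher p by full enumeration of margin-consistent tables."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> float:
        # hypergeometric probability of the table with top-left cell x
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return min(total, 1.0)


def logistic_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ beta
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def logistic_grid_mle(X: np.ndarray, y: np.ndarray, half_width: float = 8.0, rounds: int = 9) -> np.ndarray:
    """Coarse-to-fine grid search for the logistic MLE (<= 3 parameters)."""
    p = X.shape[1]
    assert p <= 3, "grid oracle only for <= 3 parameters"
    center = np.zeros(p)
    w = half_width
    pts = 13
    for _ in range(rounds):
        axes = [np.linspace(center[j] - w, center[j] + w, pts) for j in range(p)]
        grids = np.meshgrid(*axes, indexing="ij")
        flat = np.stack([g.ravel() for g in grids], axis=1)
        lls = np.array([logistic_loglik(b, X, y) for b in flat])
        center = flat[np.argmax(lls)]
        w = 2 * w / (pts - 1)  # new half-width = one old grid step
    return center


def combined_variance_two_group(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-sample variance via the within + between decomposition."""
    na, nb = a.size, b.size
    n = na + nb
    ma, mb = a.mean(), b.mean()
    within = (na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)
    between = na * nb / n * (ma - mb) ** 2
    return (within + between) / (n - 1)
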