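"""Group summaries, comparisons, population estimates and bias quantification.

Four group kinds are summarized per test measurement: the empirical
participating group (one realization), and the bootstrap, PSM and imputed
ensembles (m runs each).  Two inferential routes are reported side by side:

* ``ensemble`` tests — t tests on the run-mean ensembles with the SE across
  runs, mirroring how ensemble error bars are usually presented.  These
  treat run-to-run spread as the only uncertainty and therefore understate
  total uncertainty.
* ``rubin`` tests — Rubin's-rules pooling of the per-run (imputed mean −
  empirical mean) difference with within- plus between-imputation variance
  and Barnard–Rubin small-sample degrees of freedom; the statistically
  principled route.

The population estimate pools, per run, the empirical members with the
imputed not-participating members; bias is the participant-only statistic
minus the population statistic (positive mean bias = overestimation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scores import cohens_d

EMPIRICAL = "empirical"
IMPUTED = "imputed"


class InsufficientRunsError(ValueError):
    """Fewer than 2 runs: between-run variability is undefined."""


def _check_ensembles(ensembles: Mapping[str, np.ndarray], n_meas: int) -> None:
    for kind, arr in ensembles.items():
        if arr.ndim != 3 or arr.shape[2] != n_meas:
            raise ValueError(f"ensemble {kind!r} must be (m, n, n_measurements); got {arr.shape}")
        if arr.shape[0] < 2:
            raise InsufficientRunsError(f"ensemble {kind!r} has {arr.shape[0]} run(s); need >= 2")


def summarize_groups(
    empirical: pd.DataFrame,
    ensembles: Mapping[str, np.ndarray],
    measurements: Sequence[str],
) -> pd.DataFrame:
    """Tidy per-(group, measurement) summary.

    ``empirical`` holds member-level values (columns = measurements);
    ensembles are (m, n, n_meas) member-level arrays.  For ensembles the
    grand mean of run means is reported with the SE across runs
    (sd of run means / sqrt(m)) and the run-to-run SD itself.
    """
    measurements = list(measurements)
    _check_ensembles(ensembles, len(measurements))
    rows = []
    emp = empirical[measurements].to_numpy(dtype=float)
    for j, m_name in enumerate(measurements):
        rows.append(
            {
                "group_kind": EMPIRICAL, "measurement": m_name,
                "grand_mean": emp[:, j].mean(), "grand_sd": emp[:, j].std(ddof=1),
                "se_across_runs": np.nan, "sd_across_runs": np.nan,
                "n": emp.shape[0], "m_runs": 1,
            }
        )
    for kind, arr in ensembles.items():
        run_means = arr.mean(axis=1)  # (m, n_meas)
        run_sds = arr.std(axis=1, ddof=1)
        m = arr.shape[0]
        for j, m_name in enumerate(measurements):
            rows.append(
                {
                    "group_kind": kind, "measurement": m_name,
                    "grand_mean": run_means[:, j].mean(), "grand_sd": run_sds[:, j].mean(),
                    "se_across_runs": run_means[:, j].std(ddof=1) / np.sqrt(m),
                    "sd_across_runs": run_means[:, j].std(ddof=1),
                    "n": arr.shape[1], "m_runs": m,
                }
            )
    return pd.DataFrame(rows)


def rubin_pool(
    theta_runs: np.ndarray, within_vars: np.ndarray, df_complete: float
) -> tuple[float, float, float, float]:
    """Pool per-run estimates by Rubin's rules.

    Returns (estimate, se, df, two-tailed p against 0).  ``within_vars`` are
    the per-run within-imputation variances of the estimate; df uses the
    Barnard–Rubin small-sample adjustment with complete-data df
    ``df_complete``.
    """
    m = theta_runs.size
    if m < 2:
        raise InsufficientRunsError("Rubin pooling needs m >= 2 runs")
    qbar = theta_runs.mean()
    wbar = within_vars.mean()
    b = theta_runs.var(ddof=1)
    t = wbar + (1 + 1 / m) * b
    if t <= 0:
        return float(qbar), 0.0, np.inf, 0.0 if qbar != 0 else 1.0
    gamma = (1 + 1 / m) * b / t
    if gamma <= 0:
        df = np.inf
    else:
        nu_m = (m - 1) / gamma**2
        nu_obs = (df_complete + 1) / (df_complete + 3) * df_complete * (1 - gamma)
        df = 1.0 / (1.0 / nu_m + 1.0 / nu_obs) if nu_obs > 0 else nu_m
    se = float(np.sqrt(t))
    p = float(2 * stats.t.sf(abs(qbar) / se, df)) if se > 0 else (1.0 if qbar == 0 else 0.0)
    return float(qbar), se, float(df), p


def compare_groups(
    empirical: pd.DataFrame,
    imputed: np.ndarray,
    measurements: Sequence[str],
    psm: np.ndarray | None = None,
    bootstrap: np.ndarray | None = None,
    alpha: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """Per-measurement comparison table across group kinds.

    Columns include both the ensemble-level tests (explicitly so labelled)
    and the Rubin's-rules pooled test of imputed vs empirical means, the
    member-level Cohen's d (empirical vs imputed pooled across runs), an
    ensemble test on SDs, and — when the reference ensembles are supplied —
    two-sample ensemble t tests psm-vs-bootstrap and psm-vs-imputed.
    All tests are two-tailed; flags use ``alpha``.
    """
    measurements = list(measurements)
    _check_ensembles({"imputed": imputed}, len(measurements))
    emp = empirical[measurements].to_numpy(dtype=float)
    n_p = emp.shape[0]
    m, n_np, _ = imputed.shape
    run_means = imputed.mean(axis=1)
    run_sds = imputed.std(axis=1, ddof=1)
    run_vars = imputed.var(axis=1, ddof=1)

    rows = []
    for j, name in enumerate(measurements):
        emp_mean, emp_sd = emp[:, j].mean(), emp[:, j].std(ddof=1)
        grand = run_means[:, j].mean()
        # ensemble route: one-sample t of run means against the empirical mean
        rm = run_means[:, j]
        if np.ptp(rm) <= 1e-10 * (1.0 + abs(rm[0])):
            ens_t, ens_p = (0.0, 1.0) if np.isclose(rm[0], emp_mean) else (np.inf, 0.0)
        else:
            ens_t, ens_p = stats.ttest_1samp(rm, emp_mean)
        # Rubin route: difference of means with within+between variance
        theta = run_means[:, j] - emp_mean
        within = run_vars[:, j] / n_np + emp[:, j].var(ddof=1) / n_p
        r_est, r_se, r_df, r_p = rubin_pool(theta, within, df_complete=n_p + n_np - 2)
        # member-level effect size, imputed members pooled across runs
        d = cohens_d(emp[:, j], imputed[:, :, j].ravel())
        # ensemble test on SDs (is individual variation under-estimated?)
        rs = run_sds[:, j]
        if np.ptp(rs) <= 1e-10 * (1.0 + abs(rs[0])):
            sd_p = 1.0 if np.isclose(rs[0], emp_sd) else 0.0
        else:
            sd_p = stats.ttest_1samp(rs, emp_sd).pvalue
        row = {
            "measurement": name,
            "empirical_mean": emp_mean, "empirical_sd": emp_sd,
            "imputed_mean": grand, "imputed_sd": run_sds[:, j].mean(),
            "ensemble_t": float(ens_t), "ensemble_p": float(ens_p),
            "rubin_diff": r_est, "rubin_se": r_se, "rubin_df": r_df, "rubin_p": r_p,
            "cohens_d": d,
            "sd_ensemble_p": float(sd_p),
        }
        if psm is not None:
            psm_means = psm.mean(axis=1)
            row["psm_mean"] = psm_means[:, j].mean()
            row["psm_vs_imputed_p"] = float(stats.ttest_ind(psm_means[:, j], run_means[:, j]).pvalue)
            if bootstrap is not None:
                boot_means = bootstrap.mean(axis=1)
                row["bootstrap_mean"] = boot_means[:, j].mean()
                row["psm_vs_bootstrap_p"] = float(stats.ttest_ind(psm_means[:, j], boot_means[:, j]).pvalue)
        rows.append(row)
    table = pd.DataFrame(rows)

    p_cols = [c for c in table.columns if c.endswith("_p")]
    if holm:
        for c in p_cols:
            table[c] = _holm(table[c].to_numpy())
    table["ensemble_sig_lower"] = (table["ensemble_p"] < alpha) & (table["imputed_mean"] < table["empirical_mean"])
    table["rubin_sig_lower"] = (table["rubin_p"] < alpha) & (table["rubin_diff"] < 0)
    table["sd_sig_higher"] = (table["sd_ensemble_p"] < alpha) & (table["imputed_sd"] > table["empirical_sd"])
    return table


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    n = p.size
    adj = np.empty(n)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (n - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def population_estimate(
    empirical: pd.DataFrame,
    imputed: np.ndarray,
    measurements: Sequence[str],
) -> pd.DataFrame:
    """Combined-population mean/SD per measurement, per run and pooled.

    Per run, the n_p empirical member values are pooled with that run's
    n_np imputed values; the mean and SD of the combined n_p + n_np values
    form the run-level population estimate.  The pooled estimate is the
    grand mean across runs, reported with both the run-to-run SD and the
    SE (sd/sqrt(m)), plus a Rubin's-rules SE for the population mean.
    Bias columns are empirical statistic minus population statistic.
    """
    measurements = list(measurements)
    _check_ensembles({"imputed": imputed}, len(measurements))
    emp = empirical[measurements].to_numpy(dtype=float)
    n_p, (m, n_np, _) = emp.shape[0], imputed.shape
    if n_p < 1 or n_np < 1:
        raise ValueError("both the empirical and imputed groups must be non-empty")
    n_tot = n_p + n_np

    rows = []
    for j, name in enumerate(measurements):
        pooled = np.concatenate(
            [np.broadcast_to(emp[:, j], (m, n_p)), imputed[:, :, j]], axis=1
        )  # (m, n_tot)
        pop_means = pooled.mean(axis=1)
        pop_sds = pooled.std(axis=1, ddof=1)
        emp_mean, emp_sd = emp[:, j].mean(), emp[:, j].std(ddof=1)
        _, rubin_se, _, _ = rubin_pool(
            pop_means, pooled.var(axis=1, ddof=1) / n_tot, df_complete=n_tot - 1
        )
        rows.append(
            {
                "measurement": name,
                "n_participating": n_p, "n_not_participating": n_np, "m_runs": m,
                "empirical_mean": emp_mean, "empirical_sd": emp_sd,
                "population_mean": pop_means.mean(),
                "population_mean_sd_runs": pop_means.std(ddof=1),
                "population_mean_se": pop_means.std(ddof=1) / np.sqrt(m),
                "population_mean_rubin_se": rubin_se,
                "population_sd": pop_sds.mean(),
                "population_sd_sd_runs": pop_sds.std(ddof=1),
                "mean_bias": emp_mean - pop_means.mean(),
                "sd_bias": emp_sd - pop_sds.mean(),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class BiasReport:
    """Bundle of the summary, comparison and population tables."""

    summary: pd.DataFrame
    comparisons: pd.DataFrame
    population: pd.DataFrame
    alpha: float = 0.05

    def text_summary(self) -> str:
        lines = [f"Bias report (alpha = {self.alpha}, two-tailed)"]
        if self.comparisons.empty:
            lines.append("No not-participating dyads: nothing to impute; bias is 0 by definition.")
            for _, row in self.population.iterrows():
                lines.append(
                    f"  {row['measurement']}: mean {row['empirical_mean']:.3f}, sd {row['empirical_sd']:.3f}"
                )
            return "\n".join(lines)
        n_lower = int(self.comparisons["ensemble_sig_lower"].sum())
        n_meas = len(self.comparisons)
        lines.append(
            f"Imputed not-participating group mean significantly below the empirical mean "
            f"(ensemble test) for {n_lower} of {n_meas} measurements."
        )
        for _, row in self.comparisons.iterrows():
            lines.append(
                f"  {row['measurement']}: empirical {row['empirical_mean']:.3f} vs imputed "
                f"{row['imputed_mean']:.3f}; d = {row['cohens_d']:.3f}; "
                f"ensemble p = {row['ensemble_p']:.4g}; Rubin p = {row['rubin_p']:.4g}"
            )
        lines.append("Participant-only bias relative to the combined population:")
        for _, row in self.population.iterrows():
            lines.append(
                f"  {row['measurement']}: mean bias {row['mean_bias']:+.3f}, "
                f"sd bias {row['sd_bias']:+.3f}"
            )
        return "\n".join(lines)


def build_bias_report(
    empirical: pd.DataFrame,
    imputed: np.ndarray,
    measurements: Sequence[str],
    psm: np.ndarray | None = None,
    bootstrap: np.ndarray | None = None,
    alpha: float = 0.05,
    holm: bool = False,
) -> BiasReport:
    ensembles = {IMPUTED: imputed}
    if psm is not None:
        ensembles["psm"] = psm
    if bootstrap is not None:
        ensembles["bootstrap"] = bootstrap
    return BiasReport(
        summary=summarize_groups(empirical, ensembles, measurements),
        comparisons=compare_groups(
            empirical, imputed, measurements, psm=psm, bootstrap=bootstrap, alpha=alpha, holm=holm
        ),
        population=population_estimate(empirical, imputed, measurements),
        alpha=alpha,
    )
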