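"""End-to-end orchestration: scores -> consent model -> imputation ->
reference ensembles -> bias report, with persistence and a run manifest.

All stage seeds derive from a single master seed through fixed stage tags,
so the full pipeline and manually composed stage commands produce identical
outputs, and a rerun with the same master seed is byte-identical across all
output tables (the manifest carries the only timestamp).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, bias_report, consent_model, imputer, resampler, scores
from .data_model import (
    FIRST_MINUTE_MEASUREMENTS,
    TEST_MEASUREMENTS,
    WHOLE_PERIOD_MEASUREMENTS,
    DyadRecord,
    not_participating,
    participating,
    records_to_frame,
    write_output_table,
)
from .util import STAGE_BOOTSTRAP, STAGE_IMPUTE, STAGE_PSM, child_seed_int

log = logging.getLogger(__name__)

COMPOSITES = ["exploration_variability", "exploration_efficiency"]


@dataclass
class PipelineConfig:
    """Analysis options; defaults mirror the study conditions."""

    m: int = 100
    alpha: float = 0.05
    proper: bool = True
    predictors: str | list[str] = "observational"
    pool_consented_untested: bool = False
    psm_caliper: float | None = None
    include_psm: bool = True
    include_bootstrap: bool = True
    include_composites: bool = True
    holm: bool = False
    window_s: float = 300.0
    age_bounds: tuple[float, float] = (2.0, 8.0)
    column_map: dict[str, str] | None = None
    variability_set: list[str] = field(default_factory=lambda: list(WHOLE_PERIOD_MEASUREMENTS))
    efficiency_set: list[str] = field(default_factory=lambda: list(FIRST_MINUTE_MEASUREMENTS))
    crossval_factor: str = "child_gender"
    crossval_level: str = "male"
    crossval_fraction: float = 0.5

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        data = dict(data)
        if "age_bounds" in data and isinstance(data["age_bounds"], list):
            data["age_bounds"] = tuple(data["age_bounds"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass
class PipelineResult:
    config: PipelineConfig
    master_seed: int
    empirical: pd.DataFrame  # member-level values of the participating group
    nonpart: pd.DataFrame
    consent: consent_model.PropensityModel | None = None
    propensity: pd.Series | None = None
    models: imputer.ImputationModelSet | None = None
    imputed_runs: list[imputer.ImputedRun] = field(default_factory=list)
    bootstrap_runs: list[resampler.SubsampleRun] = field(default_factory=list)
    psm_runs: list[resampler.SubsampleRun] = field(default_factory=list)
    report: bias_report.BiasReport | None = None
    measurements: list[str] = field(default_factory=list)
    message: str = ""


def extend_with_composites(
    empirical: pd.DataFrame,
    arrays: dict[str, np.ndarray],
    measurements: Sequence[str],
    variability_set: Sequence[str],
    efficiency_set: Sequence[str],
) -> tuple[pd.DataFrame, dict[str, np.ndarray], list[str]]:
    """Append the two composite scores to member-level values everywhere.

    The participating group supplies the standardization reference for every
    group, observed or imputed, so all composites share one scale.
    """
    measurements = list(measurements)
    params = scores.reference_parameters(empirical, sorted(set(variability_set) | set(efficiency_set)))
    mean = np.array([params.get(m, (0.0, 1.0))[0] for m in measurements])
    sd = np.array([params.get(m, (0.0, 1.0))[1] for m in measurements])
    var_idx = [measurements.index(m) for m in variability_set]
    eff_idx = [measurements.index(m) for m in efficiency_set]

    comp = scores.composite_scores(
        empirical, reference_group=empirical,
        variability_set=variability_set, efficiency_set=efficiency_set,
    )
    emp_ext = empirical[measurements].copy()
    emp_ext[COMPOSITES[0]] = comp.scores["exploration_variability"].to_numpy()
    emp_ext[COMPOSITES[1]] = comp.scores["exploration_efficiency"].to_numpy()

    arrays_ext = {}
    for kind, arr in arrays.items():
        z = (arr - mean) / sd
        variability = z[:, :, var_idx].sum(axis=2, keepdims=True)
        efficiency = z[:, :, eff_idx].sum(axis=2, keepdims=True)
        arrays_ext[kind] = np.concatenate([arr, variability, efficiency], axis=2)
    return emp_ext, arrays_ext, measurements + COMPOSITES


def run_analysis(
    records: Sequence[DyadRecord],
    config: PipelineConfig | None = None,
    master_seed: int = 0,
) -> PipelineResult:
    """Execute the full analysis on an observed study table."""
    config = config or PipelineConfig()
    part = participating(list(records))
    nonpart = not_participating(list(records), config.pool_consented_untested)
    emp_frame = records_to_frame(part)
    nonpart_frame = records_to_frame(nonpart)
    result = PipelineResult(
        config=config, master_seed=master_seed, empirical=emp_frame, nonpart=nonpart_frame
    )
    if len(nonpart) == 0:
        result.message = "nothing to impute: no not-participating dyads; bias defined as 0"
        log.warning(result.message)
        pop = pd.DataFrame(
            {
                "measurement": TEST_MEASUREMENTS,
                "n_participating": len(part),
                "n_not_participating": 0,
                "m_runs": 0,
                "empirical_mean": [emp_frame[m].mean() for m in TEST_MEASUREMENTS],
                "empirical_sd": [emp_frame[m].std(ddof=1) for m in TEST_MEASUREMENTS],
            }
        )
        pop["population_mean"] = pop["empirical_mean"]
        pop["population_sd"] = pop["empirical_sd"]
        pop["mean_bias"] = 0.0
        pop["sd_bias"] = 0.0
        result.report = bias_report.BiasReport(
            summary=pd.DataFrame(), comparisons=pd.DataFrame(), population=pop, alpha=config.alpha
        )
        result.measurements = list(TEST_MEASUREMENTS)
        return result

    result.consent = consent_model.fit_consent_model(
        list(records), predictors=config.predictors,
        pool_consented_untested=config.pool_consented_untested,
    )
    both = pd.concat([emp_frame, nonpart_frame], ignore_index=True)
    result.propensity = consent_model.propensity_scores(result.consent, both)

    result.models = imputer.fit_imputation_models(emp_frame)
    result.imputed_runs = imputer.multiple_impute(
        result.models, nonpart_frame, config.m,
        child_seed_int(master_seed, STAGE_IMPUTE), proper=config.proper,
    )
    arrays = {"imputed": imputer.stack_runs(result.imputed_runs, TEST_MEASUREMENTS)}

    n_np = len(nonpart)
    if config.include_bootstrap:
        result.bootstrap_runs = resampler.bootstrap_groups(
            emp_frame, n_np, config.m, child_seed_int(master_seed, STAGE_BOOTSTRAP)
        )
        arrays["bootstrap"] = resampler.subsample_values(result.bootstrap_runs, emp_frame, TEST_MEASUREMENTS)
    if config.include_psm:
        result.psm_runs = resampler.psm_ensemble(
            emp_frame, nonpart_frame, result.propensity, config.m,
            child_seed_int(master_seed, STAGE_PSM), caliper=config.psm_caliper,
        )
        arrays["psm"] = resampler.subsample_values(result.psm_runs, emp_frame, TEST_MEASUREMENTS)

    measurements = list(TEST_MEASUREMENTS)
    emp_values = emp_frame[measurements]
    if config.include_composites:
        emp_values, arrays, measurements = extend_with_composites(
            emp_frame, arrays, measurements, config.variability_set, config.efficiency_set
        )
    result.measurements = measurements
    result.report = bias_report.build_bias_report(
        emp_values, arrays["imputed"], measurements,
        psm=arrays.get("psm"), bootstrap=arrays.get("bootstrap"),
        alpha=config.alpha, holm=config.holm,
    )
    return result


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: Path,
    master_seed: int,
    config: PipelineConfig,
    input_paths: Sequence[str | Path] = (),
    status: str = "SUCCESS",
    failed_stage: str | None = None,
) -> Path:
    manifest = {
        "tool": "consentbias",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "master_seed": master_seed,
        "child_seeds": {
            "impute": child_seed_int(master_seed, STAGE_IMPUTE),
            "bootstrap": child_seed_int(master_seed, STAGE_BOOTSTRAP),
            "psm": child_seed_int(master_seed, STAGE_PSM),
        },
        "config": config.to_dict(),
        "inputs": {str(p): _digest(p) for p in input_paths},
        "status": status,
    }
    if failed_stage:
        manifest["failed_stage"] = failed_stage
    path = Path(out_dir) / "manifest.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return path


def write_outputs(
    result: PipelineResult,
    out_dir: str | Path,
    input_paths: Sequence[str | Path] = (),
) -> None:
    """Persist all intermediate and final tables plus the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = result.master_seed
    if result.consent is not None:
        write_output_table(result.consent.summary_frame(), out / "consent_model.csv", seed=seed)
        fitline = pd.DataFrame(
            [
                {
                    "n": result.consent.n,
                    "n_positive": result.consent.n_positive,
                    "loglik_full": result.consent.loglik_full,
                    "loglik_null": result.consent.loglik_null,
                    "nagelkerke_r2": result.consent.nagelkerke_r2,
                    "converged": result.consent.converged,
                    "penalized": result.consent.penalized,
                }
            ]
        )
        write_output_table(fitline, out / "consent_fit.csv", seed=seed)
    if result.propensity is not None:
        write_output_table(
            result.propensity.rename_axis("dyad_id").reset_index(), out / "propensity.csv", seed=seed
        )
    if result.imputed_runs:
        write_output_table(imputer.runs_to_long(result.imputed_runs), out / "imputed_runs.csv", seed=seed)
        run_manifest = pd.DataFrame(
            [{"run_index": r.run_index, "seed": r.seed} for r in result.imputed_runs]
        )
        write_output_table(run_manifest, out / "imputed_run_seeds.csv", seed=seed)
    subsamples = result.bootstrap_runs + result.psm_runs
    if subsamples:
        write_output_table(resampler.runs_to_long(subsamples), out / "subsamples.csv", seed=seed)
    if result.report is not None:
        if len(result.report.summary):
            write_output_table(result.report.summary, out / "group_summary.csv", seed=seed)
        if len(result.report.comparisons):
            write_output_table(result.report.comparisons, out / "comparisons.csv", seed=seed)
        write_output_table(result.report.population, out / "population.csv", seed=seed)
        (out / "summary.txt").write_text(
            (result.message + "\n" if result.message else "") + result.report.text_summary() + "\n",
            encoding="utf-8",
        )
    write_manifest(out, seed, result.config, input_paths)
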