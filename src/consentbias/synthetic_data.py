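"""Synthetic populations with known ground truth.

The generator emulates the statistical structure of the study table: seven
pre-consent observational measurements (a 3-part composition of the
observation window plus four over-dispersed communication counts), a consent
decision driven by a logistic model on those covariates, and latent test
outcomes for *every* dyad — including refusers — driven by linear/logistic
models on the same covariates.  Consent and outcomes share covariates (by
default the pedagogical-question count) but are conditionally independent
given them, so missingness in the observed view is missing at random by
construction, and every pipeline stage can be checked against ground truth.

The defaults are a "paper-scale" preset: 78 dyads over two sites, ages
3.0-6.3 y, a ~75.6% consent rate, and consent coefficients of 1.49 per
pedagogical question and 1.47 for boys.  ``null_config`` zeroes every
coupling for calibration studies.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .data_model import (
    COUNT_MEASUREMENTS,
    DURATION_MEASUREMENTS,
    OBS_MEASUREMENTS,
    TEST_MEASUREMENTS,
    DyadRecord,
    ObservationMeasures,
    ParticipationStatus,
    TestOutcome,
    ValidationError,
)
from .scores import cohens_d

GAUSSIAN_OUTCOMES = ["total_play_time", "whole_unique_actions", "whole_nontarget_functions"]
INTEGER_OUTCOMES = {"whole_unique_actions", "whole_nontarget_functions"}


def _default_count_means() -> dict[str, float]:
    return {
        "pedagogical_questions": 0.9,
        "information_seeking_questions": 3.5,
        "statements": 16.0,
        "commands": 6.0,
    }


def _default_count_dispersion() -> dict[str, float]:
    return {
        "pedagogical_questions": 1.0,
        "information_seeking_questions": 2.0,
        "statements": 4.0,
        "commands": 2.0,
    }


def _default_consent_slopes() -> dict[str, float]:
    # the reported participation coefficients: per pedagogical question, and for boys
    return {"pedagogical_questions": 1.49, "child_gender_male": 1.47}


def _default_gaussian_outcomes() -> dict[str, dict]:
    return {
        "total_play_time": {
            "intercept": 150.0,
            "slopes": {"pedagogical_questions": 8.0, "dyadic_time": 0.08},
            "resid_sd": 60.0,
        },
        "whole_unique_actions": {
            "intercept": 6.0,
            "slopes": {"pedagogical_questions": 0.6, "dyadic_time": 0.004},
            "resid_sd": 3.0,
        },
        "whole_nontarget_functions": {
            "intercept": 1.6,
            "slopes": {"pedagogical_questions": 0.15},
            "resid_sd": 1.0,
        },
    }


def _default_binary_outcomes() -> dict[str, dict]:
    return {"whole_target_activated": {"intercept": 0.2, "slopes": {"pedagogical_questions": 0.35}}}


def _default_first_minute() -> dict[str, object]:
    # first-minute counts are binomial thinnings of the whole-period counts,
    # which enforces first <= whole by construction
    return {
        "first_unique_actions_p": 0.55,
        "first_nontarget_functions_p": 0.6,
        "first_target_given_whole": {"intercept": 0.5, "slopes": {"pedagogical_questions": 0.2}},
    }


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic population model (units in field names)."""

    n_dyads: int = 78
    seed: int = 0
    window_s: float = 300.0
    site_labels: tuple[str, str] = ("zoo", "playground")
    site_probs: tuple[float, float] = (41 / 78, 37 / 78)
    age_range: tuple[float, float] = (3.0, 6.3)
    p_child_male: float = 0.5
    p_parent_female: float = 0.7
    p_other_adults: float = 0.25
    p_other_children: float = 0.35
    # composition of the observation window: (dyadic, supervised, unsupervised,
    # uncoded).  The uncoded share keeps the three coded durations from summing
    # to exactly the window, as gaps in live coding do in real tables.
    duration_alpha: tuple[float, ...] = (2.0, 2.5, 1.5, 0.7)
    count_means: dict[str, float] = field(default_factory=_default_count_means)
    count_dispersion: dict[str, float | None] = field(default_factory=_default_count_dispersion)
    consent_target_rate: float = 59 / 78
    consent_slopes: dict[str, float] = field(default_factory=_default_consent_slopes)
    p_tested_given_consent: float = 47 / 59
    gaussian_outcomes: dict[str, dict] = field(default_factory=_default_gaussian_outcomes)
    binary_outcomes: dict[str, dict] = field(default_factory=_default_binary_outcomes)
    first_minute: dict[str, object] = field(default_factory=_default_first_minute)

    def validate(self) -> None:
        if self.n_dyads < 1:
            raise ValidationError(f"n_dyads must be >= 1, got {self.n_dyads}")
        for name in (
            "p_child_male",
            "p_parent_female",
            "p_other_adults",
            "p_other_children",
            "consent_target_rate",
            "p_tested_given_consent",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be a probability in [0, 1], got {v}")
        if not 0.0 < self.consent_target_rate < 1.0:
            raise ValidationError(f"consent_target_rate must be in (0, 1), got {self.consent_target_rate}")
        if abs(sum(self.site_probs) - 1.0) > 1e-9:
            raise ValidationError(f"site_probs must sum to 1, got {self.site_probs}")
        if len(self.duration_alpha) != 4 or any(a <= 0 for a in self.duration_alpha):
            raise ValidationError(
                f"duration_alpha must be 4 positive shares (dyadic, supervised, unsupervised, uncoded), got {self.duration_alpha}"
            )
        if self.window_s <= 0:
            raise ValidationError(f"window_s must be > 0, got {self.window_s}")
        if self.age_range[0] >= self.age_range[1]:
            raise ValidationError(f"age_range must be increasing, got {self.age_range}")
        for m in COUNT_MEASUREMENTS:
            if m not in self.count_means:
                raise ValidationError(f"count_means missing entry for {m}")
            if self.count_means[m] < 0:
                raise ValidationError(f"count_means[{m}] must be >= 0")
            k = self.count_dispersion.get(m)
            if k is not None and k <= 0:
                raise ValidationError(f"count_dispersion[{m}] must be > 0 or None (Poisson)")
        for m, spec in self.gaussian_outcomes.items():
            if spec["resid_sd"] < 0:
                raise ValidationError(f"gaussian_outcomes[{m}].resid_sd must be >= 0")

    # -- analytic covariate means, used to solve for the consent intercept --

    def covariate_mean(self, name: str) -> float:
        if name in COUNT_MEASUREMENTS:
            return float(self.count_means[name])
        if name in DURATION_MEASUREMENTS:
            alpha = np.asarray(self.duration_alpha, dtype=float)
            idx = DURATION_MEASUREMENTS.index(name)
            return float(alpha[idx] / alpha.sum() * self.window_s)
        if name == "child_gender_male":
            return float(self.p_child_male)
        if name == "parent_gender_female":
            return float(self.p_parent_female)
        if name == "child_age":
            return float(np.mean(self.age_range))
        if name == "other_adults_present":
            return float(self.p_other_adults)
        if name == "other_children_present":
            return float(self.p_other_children)
        if name == "site_code":
            return float(self.site_probs[1])
        raise ValidationError(f"unknown consent-model covariate {name!r}")

    @property
    def consent_intercept(self) -> float:
        """Intercept giving logit(consent_target_rate) at the covariate means."""
        lp_slopes = sum(b * self.covariate_mean(x) for x, b in self.consent_slopes.items())
        return float(special.logit(self.consent_target_rate) - lp_slopes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SyntheticConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown SyntheticConfig field(s): {sorted(unknown)}")
        data = dict(data)
        for tup in ("site_labels", "site_probs", "age_range", "duration_alpha"):
            if tup in data and isinstance(data[tup], list):
                data[tup] = tuple(data[tup])
        return cls(**data)


def null_config(n_dyads: int = 500, seed: int = 0) -> SyntheticConfig:
    """Zero-coupling configuration: consent and outcomes share no covariates."""
    cfg = SyntheticConfig(n_dyads=n_dyads, seed=seed)
    cfg.consent_slopes = {}
    for spec in cfg.gaussian_outcomes.values():
        spec["slopes"] = {}
    for spec in cfg.binary_outcomes.values():
        spec["slopes"] = {}
    cfg.first_minute = dict(cfg.first_minute)
    cfg.first_minute["first_target_given_whole"] = {"intercept": 0.5, "slopes": {}}
    return cfg


def paper_scale_config(seed: int = 0) -> SyntheticConfig:
    """The 78-dyad preset used in docs and smoke tests."""
    return SyntheticConfig(n_dyads=78, seed=seed)


@dataclass
class SyntheticPopulation:
    """Full population with latent outcomes and ground-truth bookkeeping.

    ``frame`` has one row per dyad with covariates, the realized consent and
    tested indicators, latent test outcomes (prefixed ``latent_``), the true
    consent probability and true conditional outcome means (``true_mean_*``;
    for rounded/thinned measurements these are the pre-discretization means).
    """

    config: SyntheticConfig
    frame: pd.DataFrame

    @property
    def latent_outcomes(self) -> pd.DataFrame:
        out = self.frame[[f"latent_{m}" for m in TEST_MEASUREMENTS]].copy()
        out.columns = TEST_MEASUREMENTS
        return out


def _linear_predictor(frame: pd.DataFrame, intercept: float, slopes: Mapping[str, float]) -> np.ndarray:
    lp = np.full(len(frame), float(intercept))
    for name, b in slopes.items():
        lp = lp + b * frame[name].to_numpy(dtype=float)
    return lp


def generate_population(config: SyntheticConfig) -> SyntheticPopulation:
    """Draw a full synthetic population, reproducibly from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_dyads

    site_idx = rng.choice(2, size=n, p=np.asarray(config.site_probs))
    frame = pd.DataFrame(
        {
            "dyad_id": [f"d{i + 1:04d}" for i in range(n)],
            "site": np.asarray(config.site_labels, dtype=object)[site_idx],
            "site_code": site_idx.astype(float),
            "child_age": rng.uniform(*config.age_range, size=n).round(1),
            "child_gender_male": rng.binomial(1, config.p_child_male, n).astype(float),
            "parent_gender_female": rng.binomial(1, config.p_parent_female, n).astype(float),
            "other_adults_present": rng.binomial(1, config.p_other_adults, n).astype(float),
            "other_children_present": rng.binomial(1, config.p_other_children, n).astype(float),
        }
    )
    frame["child_gender"] = np.where(frame["child_gender_male"] == 1, "male", "female")
    frame["parent_gender"] = np.where(frame["parent_gender_female"] == 1, "female", "male")

    shares = rng.dirichlet(np.asarray(config.duration_alpha, dtype=float), size=n)
    for i, m in enumerate(DURATION_MEASUREMENTS):
        frame[m] = np.round(shares[:, i] * config.window_s, 1)
    for m in COUNT_MEASUREMENTS:
        mu, k = config.count_means[m], config.count_dispersion.get(m)
        if k is None:
            frame[m] = rng.poisson(mu, n).astype(float)
        else:
            frame[m] = rng.negative_binomial(k, k / (k + mu), n).astype(float)

    # consent: Bernoulli(inverse-logit), covariate-driven; independent of the
    # outcome noise below, hence MAR by construction
    lp_consent = _linear_predictor(frame, config.consent_intercept, config.consent_slopes)
    p_consent = special.expit(lp_consent)
    frame["true_consent_p"] = p_consent
    frame["consented"] = rng.binomial(1, p_consent, n)
    frame["tested"] = frame["consented"] * rng.binomial(1, config.p_tested_given_consent, n)

    # latent outcomes for everyone
    for m, spec in config.gaussian_outcomes.items():
        mu = _linear_predictor(frame, spec["intercept"], spec["slopes"])
        y = mu + rng.normal(0.0, spec["resid_sd"], n)
        if m in INTEGER_OUTCOMES:
            y = np.round(y)
        hi = 4.0 if m.endswith("nontarget_functions") else np.inf
        y = np.clip(y, 0.0, hi)
        frame[f"latent_{m}"] = y
        frame[f"true_mean_{m}"] = mu
    for m, spec in config.binary_outcomes.items():
        p = special.expit(_linear_predictor(frame, spec["intercept"], spec["slopes"]))
        frame[f"latent_{m}"] = rng.binomial(1, p, n).astype(float)
        frame[f"true_mean_{m}"] = p

    fm = config.first_minute
    whole_unique = frame["latent_whole_unique_actions"].to_numpy()
    whole_nontarget = frame["latent_whole_nontarget_functions"].to_numpy()
    frame["latent_first_unique_actions"] = rng.binomial(
        whole_unique.astype(int), fm["first_unique_actions_p"]
    ).astype(float)
    frame["true_mean_first_unique_actions"] = fm["first_unique_actions_p"] * frame["true_mean_whole_unique_actions"]
    frame["latent_first_nontarget_functions"] = rng.binomial(
        whole_nontarget.astype(int), fm["first_nontarget_functions_p"]
    ).astype(float)
    frame["true_mean_first_nontarget_functions"] = (
        fm["first_nontarget_functions_p"] * frame["true_mean_whole_nontarget_functions"]
    )
    ft = fm["first_target_given_whole"]
    p_first = special.expit(_linear_predictor(frame, ft["intercept"], ft["slopes"]))
    frame["latent_first_target_activated"] = (
        frame["latent_whole_target_activated"].to_numpy() * rng.binomial(1, p_first, n)
    ).astype(float)
    frame["true_mean_first_target_activated"] = frame["true_mean_whole_target_activated"] * p_first

    return SyntheticPopulation(config=config, frame=frame)


def observed_view(population: SyntheticPopulation) -> list[DyadRecord]:
    """Project the population to a valid study table: refusers lose outcomes.

    Consenters whose test phase did not complete get status
    ``consented_untested`` and likewise carry no outcome.
    """
    records: list[DyadRecord] = []
    for _, row in population.frame.iterrows():
        if row["tested"]:
            status = ParticipationStatus.TESTED
        elif row["consented"]:
            status = ParticipationStatus.CONSENTED_UNTESTED
        else:
            status = ParticipationStatus.REFUSED
        outcome = None
        if status is ParticipationStatus.TESTED:
            outcome = TestOutcome(**{m: float(row[f"latent_{m}"]) for m in TEST_MEASUREMENTS})
        records.append(
            DyadRecord(
                dyad_id=str(row["dyad_id"]),
                site=str(row["site"]),
                child_age=float(row["child_age"]),
                child_gender=str(row["child_gender"]),
                parent_gender=str(row["parent_gender"]),
                other_adults_present=bool(row["other_adults_present"]),
                other_children_present=bool(row["other_children_present"]),
                observation=ObservationMeasures(**{m: float(row[m]) for m in OBS_MEASUREMENTS}),
                status=status,
                outcome=outcome,
            )
        )
    return records


def true_bias(population: SyntheticPopulation) -> pd.DataFrame:
    """Ground-truth consenter/refuser gaps and population statistics.

    Uses the latent outcomes of both groups, which the observed view never
    exposes for refusers.  Positive d means consenters score above refusers.
    """
    frame = population.frame
    consent = frame["consented"].to_numpy() == 1
    if consent.sum() == 0 or (~consent).sum() == 0:
        raise ValueError("true_bias needs both consenters and refusers in the population")
    rows = []
    for m in TEST_MEASUREMENTS:
        y = frame[f"latent_{m}"].to_numpy(dtype=float)
        rows.append(
            {
                "measurement": m,
                "true_d": cohens_d(y[consent], y[~consent]),
                "true_mean_gap": y[consent].mean() - y[~consent].mean(),
                "true_sd_gap": y[consent].std(ddof=1) - y[~consent].std(ddof=1),
                "population_mean": y.mean(),
                "population_sd": y.std(ddof=1),
            }
        )
    return pd.DataFrame(rows)
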