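"""Domain types, validation, and delimited-text I/O for dyad study tables.

One row of a study table describes one parent-child dyad: identifiers, site,
demographics, the seven pre-consent observational measurements (three
interaction-duration measures over a fixed observation window plus four
communication counts), a participation status, and — only for dyads whose
child completed the test — the seven test measurements.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# canonical column vocabulary

OBS_MEASUREMENTS: list[str] = [
    "dyadic_time",
    "supervised_time",
    "unsupervised_time",
    "pedagogical_questions",
    "information_seeking_questions",
    "statements",
    "commands",
]
DURATION_MEASUREMENTS: list[str] = OBS_MEASUREMENTS[:3]
COUNT_MEASUREMENTS: list[str] = OBS_MEASUREMENTS[3:]

TEST_MEASUREMENTS: list[str] = [
    "total_play_time",
    "whole_target_activated",
    "whole_unique_actions",
    "whole_nontarget_functions",
    "first_target_activated",
    "first_unique_actions",
    "first_nontarget_functions",
]
BINARY_TEST_MEASUREMENTS = frozenset({"whole_target_activated", "first_target_activated"})
WHOLE_PERIOD_MEASUREMENTS: list[str] = TEST_MEASUREMENTS[1:4]
FIRST_MINUTE_MEASUREMENTS: list[str] = TEST_MEASUREMENTS[4:7]
# first-minute counts can never exceed their whole-period counterparts
CUMULATIVE_PAIRS: list[tuple[str, str]] = [
    ("first_unique_actions", "whole_unique_actions"),
    ("first_nontarget_functions", "whole_nontarget_functions"),
]

DEMOGRAPHICS: list[str] = [
    "site",
    "child_age",
    "child_gender",
    "parent_gender",
    "other_adults_present",
    "other_children_present",
]
STUDY_COLUMNS: list[str] = ["dyad_id"] + DEMOGRAPHICS + ["status"] + OBS_MEASUREMENTS + TEST_MEASUREMENTS

CHILD_GENDERS = frozenset({"male", "female"})
PARENT_GENDERS = frozenset({"male", "female", "other"})

DEFAULT_WINDOW_S = 300.0
DEFAULT_AGE_BOUNDS = (2.0, 8.0)


class StudyDataError(ValueError):
    """Base class for study-table problems."""


class SchemaError(StudyDataError):
    """A mandatory column is missing or mis-typed."""


class ConsistencyError(StudyDataError):
    """Cross-field contradiction (e.g. outcomes for a non-tested dyad)."""


class ValidationError(StudyDataError):
    """A field value violates a type invariant."""


class UndefinedRateError(StudyDataError):
    """Consent rate requested with zero invited dyads."""


class ParticipationStatus(str, enum.Enum):
    NOT_INVITED = "not_invited"
    REFUSED = "refused"
    CONSENTED_UNTESTED = "consented_untested"
    TESTED = "tested"


@dataclass(frozen=True, slots=True)
class ObservationMeasures:
    """The seven pre-consent observational measurements for one dyad.

    Durations are seconds within the observation window; counts are
    non-negative reals (averaging two coders can yield half-integers).
    """

    dyadic_time: float
    supervised_time: float
    unsupervised_time: float
    pedagogical_questions: float
    information_seeking_questions: float
    statements: float
    commands: float

    def validate(self, window_s: float = DEFAULT_WINDOW_S) -> None:
        for name in OBS_MEASUREMENTS:
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise ValidationError(f"observational measurement {name!r} is missing")
            if v < 0:
                raise ValidationError(f"observational measurement {name!r} must be >= 0, got {v}")
        total = self.dyadic_time + self.supervised_time + self.unsupervised_time
        if total > window_s * (1 + 1e-9):
            raise ValidationError(
                f"durations sum to {total:.1f} s, exceeding the {window_s:.0f} s observation window"
            )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in OBS_MEASUREMENTS}


@dataclass(frozen=True, slots=True)
class TestOutcome:
    """The seven test measurements for one tested child.

    ``*_target_activated`` are 0/1 indicators; ``*_nontarget_functions``
    count activated non-target functions out of 4; the first-minute counts
    are cumulative and so cannot exceed their whole-period counterparts.
    """

    total_play_time: float
    whole_target_activated: float
    whole_unique_actions: float
    whole_nontarget_functions: float
    first_target_activated: float
    first_unique_actions: float
    first_nontarget_functions: float

    def validate(self) -> None:
        for name in TEST_MEASUREMENTS:
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise ValidationError(f"test measurement {name!r} is missing")
            if v < 0:
                raise ValidationError(f"test measurement {name!r} must be >= 0, got {v}")
        for name in BINARY_TEST_MEASUREMENTS:
            v = getattr(self, name)
            if v not in (0, 1, 0.0, 1.0):
                raise ValidationError(f"{name!r} must be 0 or 1, got {v}")
        for name in ("whole_nontarget_functions", "first_nontarget_functions"):
            if getattr(self, name) > 4:
                raise ValidationError(f"{name!r} must be at most 4, got {getattr(self, name)}")
        for first, whole in CUMULATIVE_PAIRS:
            if getattr(self, first) > getattr(self, whole) + 1e-9:
                raise ValidationError(
                    f"{first!r} ({getattr(self, first)}) exceeds {whole!r} ({getattr(self, whole)})"
                )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in TEST_MEASUREMENTS}


@dataclass(slots=True)
class DyadRecord:
    """One observed parent-child dyad.

    Covariates and observational measurements exist for every dyad; the test
    outcome exists iff the dyad's status is ``tested``.  Missing demographic
    covariates are tolerated (``None``) and flagged, because analyses handle
    them by per-analysis complete-case exclusion.
    """

    dyad_id: str
    site: str
    child_age: float | None
    child_gender: str | None
    parent_gender: str | None
    other_adults_present: bool | None
    other_children_present: bool | None
    observation: ObservationMeasures
    status: ParticipationStatus
    outcome: TestOutcome | None = None

    def validate(
        self,
        window_s: float = DEFAULT_WINDOW_S,
        age_bounds: tuple[float, float] = DEFAULT_AGE_BOUNDS,
    ) -> None:
        try:
            self._validate(window_s, age_bounds)
        except StudyDataError as exc:
            raise type(exc)(f"dyad {self.dyad_id!r}: {exc}") from None

    def _validate(self, window_s: float, age_bounds: tuple[float, float]) -> None:
        if self.child_age is not None and not math.isnan(self.child_age):
            lo, hi = age_bounds
            if not (lo <= self.child_age <= hi):
                raise ValidationError(
                    f"child_age {self.child_age} outside plausible bounds [{lo}, {hi}]"
                )
        if self.child_gender is not None and self.child_gender not in CHILD_GENDERS:
            raise ValidationError(f"child_gender {self.child_gender!r} not in {sorted(CHILD_GENDERS)}")
        if self.parent_gender is not None and self.parent_gender not in PARENT_GENDERS:
            raise ValidationError(f"parent_gender {self.parent_gender!r} not in {sorted(PARENT_GENDERS)}")
        self.observation.validate(window_s=window_s)
        if self.status is ParticipationStatus.TESTED:
            if self.outcome is None:
                raise ConsistencyError("status is 'tested' but no test outcome is present")
            self.outcome.validate()
        elif self.outcome is not None:
            raise ConsistencyError(f"status is {self.status.value!r} but test outcome columns are filled")

    @property
    def has_missing_covariates(self) -> bool:
        return any(
            getattr(self, f) is None or (isinstance(getattr(self, f), float) and math.isnan(getattr(self, f)))
            for f in DEMOGRAPHICS
        )


# ---------------------------------------------------------------------------
# group selection

def participating(records: Sequence[DyadRecord]) -> list[DyadRecord]:
    """Dyads with observed test outcomes (the 'participating' analysis group)."""
    return [r for r in records if r.status is ParticipationStatus.TESTED]


def not_participating(
    records: Sequence[DyadRecord], pool_consented_untested: bool = False
) -> list[DyadRecord]:
    """Dyads forming the 'not-participating' analysis group.

    By default only refusers; consented-but-untested dyads can optionally be
    pooled in (they have no outcomes either way).
    """
    keep = {ParticipationStatus.REFUSED}
    if pool_consented_untested:
        keep.add(ParticipationStatus.CONSENTED_UNTESTED)
    return [r for r in records if r.status in keep]


@dataclass(frozen=True)
class ConsentRate:
    n_invited: int
    n_agreed: int
    n_refused: int

    @property
    def proportion(self) -> float:
        return self.n_agreed / self.n_invited

    @property
    def percent(self) -> float:
        return 100.0 * self.n_agreed / self.n_invited


def consent_rate(records: Sequence[DyadRecord]) -> ConsentRate:
    """Consent rate among invited dyads: agreed / invited.

    'Agreed' counts dyads that consented, whether or not the test phase was
    completed; 'invited' excludes dyads that were never invited.
    """
    invited = [r for r in records if r.status is not ParticipationStatus.NOT_INVITED]
    if not invited:
        raise UndefinedRateError("consent rate undefined: no invited dyads")
    agreed = sum(
        r.status in (ParticipationStatus.CONSENTED_UNTESTED, ParticipationStatus.TESTED)
        for r in invited
    )
    refused = sum(r.status is ParticipationStatus.REFUSED for r in invited)
    return ConsentRate(n_invited=len(invited), n_agreed=agreed, n_refused=refused)


# ---------------------------------------------------------------------------
# frame conversion

def records_to_frame(records: Sequence[DyadRecord]) -> pd.DataFrame:
    """Tidy DataFrame with the canonical study columns, one row per dyad."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "dyad_id": r.dyad_id,
            "site": r.site,
            "child_age": r.child_age,
            "child_gender": r.child_gender,
            "parent_gender": r.parent_gender,
            "other_adults_present": r.other_adults_present,
            "other_children_present": r.other_children_present,
            "status": r.status.value,
        }
        row.update(r.observation.as_dict())
        if r.outcome is not None:
            row.update(r.outcome.as_dict())
        else:
            row.update({m: np.nan for m in TEST_MEASUREMENTS})
        rows.append(row)
    return pd.DataFrame(rows, columns=STUDY_COLUMNS)


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or pd.isna(v):
        return None
    return float(v)


def _opt_bool(v) -> bool | None:
    if v is None or pd.isna(v):
        return None
    return bool(int(v))


def frame_to_records(frame: pd.DataFrame) -> list[DyadRecord]:
    records: list[DyadRecord] = []
    for _, row in frame.iterrows():
        status = ParticipationStatus(str(row["status"]))
        obs = ObservationMeasures(**{m: float(row[m]) for m in OBS_MEASUREMENTS})
        outcome = None
        out_vals = {m: row.get(m, np.nan) for m in TEST_MEASUREMENTS}
        if status is ParticipationStatus.TESTED:
            outcome = TestOutcome(**{m: float(v) for m, v in out_vals.items()})
        records.append(
            DyadRecord(
                dyad_id=str(row["dyad_id"]),
                site=str(row["site"]),
                child_age=_opt_float(row["child_age"]),
                child_gender=None if pd.isna(row["child_gender"]) else str(row["child_gender"]),
                parent_gender=None if pd.isna(row["parent_gender"]) else str(row["parent_gender"]),
                other_adults_present=_opt_bool(row["other_adults_present"]),
                other_children_present=_opt_bool(row["other_children_present"]),
                observation=obs,
                status=status,
                outcome=outcome,
            )
        )
    return records


# ---------------------------------------------------------------------------
# delimited-text I/O

def read_study_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    window_s: float = DEFAULT_WINDOW_S,
    age_bounds: tuple[float, float] = DEFAULT_AGE_BOUNDS,
    validate: bool = True,
) -> list[DyadRecord]:
    """Read a comma-delimited study table into validated DyadRecords.

    ``column_map`` maps external column names to the canonical ones.  Raw
    two-coder columns ``<measurement>_coder1``/``_coder2`` are averaged when
    the already-averaged column is absent.  Lines starting with ``#`` are
    header comments and skipped.  Row order is preserved.
    """
    frame = pd.read_csv(path, comment="#")
    if column_map:
        frame = frame.rename(columns=dict(column_map))

    # average raw coder columns where the combined column is missing
    for m in OBS_MEASUREMENTS:
        c1, c2 = f"{m}_coder1", f"{m}_coder2"
        if m not in frame.columns and c1 in frame.columns and c2 in frame.columns:
            frame[m] = (frame[c1] + frame[c2]) / 2.0

    mandatory = ["dyad_id", "site", "status"] + OBS_MEASUREMENTS
    for col in mandatory:
        if col not in frame.columns:
            raise SchemaError(f"mandatory column {col!r} missing from {path}")
    for col in STUDY_COLUMNS:
        if col not in frame.columns:
            frame[col] = np.nan

    if frame.empty:
        log.warning("study table %s contains a header but no rows", path)
        return []

    # a non-tested dyad must not carry outcome values
    non_tested = frame["status"] != ParticipationStatus.TESTED.value
    filled = frame.loc[non_tested, TEST_MEASUREMENTS].notna().any(axis=1)
    if filled.any():
        bad = frame.loc[non_tested].loc[filled, "dyad_id"].tolist()
        raise ConsistencyError(f"outcome columns filled for non-tested dyad(s): {bad}")

    records = frame_to_records(frame[STUDY_COLUMNS])
    if validate:
        for r in records:
            r.validate(window_s=window_s, age_bounds=age_bounds)
    n_flagged = sum(r.has_missing_covariates for r in records)
    if n_flagged:
        log.warning("%d of %d rows have missing covariates (complete-case per analysis)", n_flagged, len(records))
    return records


def write_study_table(
    records: Sequence[DyadRecord], path: str | Path, seed: int | None = None
) -> None:
    """Write records as UTF-8 CSV with a version/seed header comment."""
    frame = records_to_frame(records)
    # booleans encoded 0/1, empty cells for missing
    for col in ("other_adults_present", "other_children_present"):
        frame[col] = frame[col].map(lambda v: "" if v is None or pd.isna(v) else str(int(v)))
    write_output_table(frame, path, seed=seed)


def write_output_table(frame: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    """Write any result table in the package dialect (header comment + CSV)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# consentbias v{__version__} seed={'-' if seed is None else seed}\n")
        frame.to_csv(fh, index=False)


def status_counts(records: Iterable[DyadRecord]) -> dict[str, int]:
    counts = {s.value: 0 for s in ParticipationStatus}
    for r in records:
        counts[r.status.value] += 1
    return counts
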