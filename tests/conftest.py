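import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from consentbias.data_model import (
    OBS_MEASUREMENTS,
    TEST_MEASUREMENTS,
    DyadRecord,
    ObservationMeasures,
    ParticipationStatus,
    TestOutcome,
)
from consentbias.synthetic_data import generate_population, observed_view, paper_scale_config

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_dyad(
    i,
    status=ParticipationStatus.TESTED,
    pq=1.0,
    obs=None,
    outcome="auto",
    child_gender="female",
    child_age=4.5,
    site="zoo",
):
    """Hand-fixture dyad with simple defaults."""
    observation = ObservationMeasures(
        dyadic_time=100.0 + (obs or 0.0) + 7 * (i % 5),
        supervised_time=80.0 - 5 * (i % 4),
        unsupervised_time=40.0 + 11 * (i % 3),
        pedagogical_questions=pq,
        information_seeking_questions=2.0 + ((2 * i) % 5),
        statements=10.0 + ((3 * i) % 11),
        commands=4.0 + ((5 * i) % 9),
    )
    if outcome == "auto":
        outcome = (
            TestOutcome(
                total_play_time=120.0 + 10 * i,
                whole_target_activated=float(i % 2),
                whole_unique_actions=5.0 + i,
                whole_nontarget_functions=float(i % 5 if i % 5 <= 4 else 4),
                first_target_activated=float(i % 2),
                first_unique_actions=3.0 + i / 2,
                first_nontarget_functions=min(float(i % 3), float(i % 5)),
            )
            if status is ParticipationStatus.TESTED
            else None
        )
    return DyadRecord(
        dyad_id=f"x{i:03d}",
        site=site,
        child_age=child_age,
        child_gender=child_gender,
        parent_gender="female",
        other_adults_present=False,
        other_children_present=False,
        observation=observation,
        status=status,
        outcome=outcome,
    )


@pytest.fixture(scope="session")
def paper_records():
    """Observed view of a paper-scale synthetic population (78 dyads)."""
    pop = generate_population(paper_scale_config(seed=11))
    return observed_view(pop)


@pytest.fixture(scope="session")
def paper_population():
    return generate_population(paper_scale_config(seed=11))
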