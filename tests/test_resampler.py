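import numpy as np
import pandas as pd
import pytest
from scipy import special

from consentbias.data_model import ParticipationStatus, records_to_frame
from consentbias.resampler import (
    MatchingExhaustedError,
    bootstrap_groups,
    long_to_runs,
    psm_ensemble,
    psm_match,
    runs_to_long,
    subsample_values,
)

from conftest import make_dyad


@pytest.fixture(scope="module")
def participating():
    return [make_dyad(i) for i in range(47)]


@pytest.fixture(scope="module")
def refusers():
    return [make_dyad(500 + i, status=ParticipationStatus.REFUSED, outcome=None) for i in range(19)]


class TestBootstrap:
    def test_sizes_and_distinct_members(self, participating):
        runs = bootstrap_groups(participating, 19, 100, master_seed=1)
        assert len(runs) == 100
        assert len({r.seed for r in runs}) == 100
        for r in runs:
            assert len(r.member_ids) == 19 == len(set(r.member_ids))

    def test_full_size_forces_whole_group(self, participating):
        runs = bootstrap_groups(participating, 47, 5, master_seed=2)
        all_ids = {r.dyad_id for r in participating}
        for r in runs:
            assert set(r.member_ids) == all_ids

    def test_oversized_request_rejected(self, participating):
        with pytest.raises(ValueError):
            bootstrap_groups(participating, 48, 1, master_seed=0)

    def test_inclusion_frequency_matches_binomial_oracle(self, participating):
        m = 400
        runs = bootstrap_groups(participating, 19, m, master_seed=3)
        freq = pd.Series([d for r in runs for d in r.member_ids]).value_counts() / m
        p = 19 / 47
        se = np.sqrt(p * (1 - p) / m)
        assert (np.abs(freq - p) < 3 * se).mean() > 0.97

    def test_run_means_centred_on_participating_mean(self, participating):
        emp = records_to_frame(participating)
        runs = bootstrap_groups(participating, 19, 100, master_seed=4)
        vals = subsample_values(runs, emp, ["whole_unique_actions"])
        run_means = vals[:, :, 0].mean(axis=1)
        assert abs(run_means.mean() - emp["whole_unique_actions"].mean()) < 3 * run_means.std(ddof=1) / 10


def uniform_scores(records, values):
    return pd.Series(values, index=[r.dyad_id for r in records], dtype=float)


class TestPsm:
    def test_exact_propensity_twin_is_matched_at_distance_zero(self, participating, refusers):
        part_scores = np.linspace(0.6, 0.9, len(participating))
        np_scores = np.linspace(0.2, 0.35, len(refusers))
        np_scores[0] = part_scores[10]  # a participant twin of refuser 0
        scores = pd.concat(
            [uniform_scores(participating, part_scores), uniform_scores(refusers, np_scores)]
        )
        run = psm_match(participating, [refusers[0]], scores, rng=0)
        assert run.member_ids == [participating[10].dyad_id]
        assert run.mean_abs_distance == pytest.approx(0.0, abs=1e-12)

    def test_more_refusers_than_participants_rejected(self, refusers, participating):
        scores = pd.concat(
            [uniform_scores(participating[:5], np.full(5, 0.5)), uniform_scores(refusers, np.full(19, 0.4))]
        )
        with pytest.raises(MatchingExhaustedError):
            psm_match(participating[:5], refusers, scores, rng=0)

    def test_matched_group_mean_propensity_closer_than_full_group(self, participating, refusers):
        # clustered propensities: a low cluster overlapping the refusers
        part_scores = np.r_[np.linspace(0.3, 0.45, 19), np.linspace(0.8, 0.95, 28)]
        np_scores = np.linspace(0.3, 0.45, 19)
        scores = pd.concat(
            [uniform_scores(participating, part_scores), uniform_scores(refusers, np_scores)]
        )
        run = psm_match(participating, refusers, scores, rng=1)
        matched_mean = scores[run.member_ids].mean()
        np_mean = np_scores.mean()
        assert abs(matched_mean - np_mean) < abs(part_scores.mean() - np_mean)

    def test_invariant_to_relabeling_and_logit_shift(self, participating, refusers):
        rng_scores = np.random.default_rng(5)
        part_scores = rng_scores.uniform(0.3, 0.9, len(participating))
        np_scores = rng_scores.uniform(0.2, 0.7, len(refusers))
        scores = pd.concat(
            [uniform_scores(participating, part_scores), uniform_scores(refusers, np_scores)]
        )
        run_a = psm_match(participating, refusers, scores, rng=7)
        shifted = pd.Series(special.expit(special.logit(scores.to_numpy()) + 1.7), index=scores.index)
        run_b = psm_match(participating, refusers, shifted, rng=7)
        assert run_a.member_ids == run_b.member_ids
        # relabel every dyad_id
        relabel = {d: f"r_{d}" for d in scores.index}
        part2 = records_to_frame(participating).assign(dyad_id=lambda f: f["dyad_id"].map(relabel))
        np2 = records_to_frame(refusers).assign(dyad_id=lambda f: f["dyad_id"].map(relabel))
        scores2 = pd.Series(scores.to_numpy(), index=[relabel[d] for d in scores.index])
        run_c = psm_match(part2, np2, scores2, rng=7)
        assert run_c.member_ids == [relabel[d] for d in run_a.member_ids]

    def test_caliper_exhaustion_is_an_error_not_a_partial_match(self, participating, refusers):
        part_scores = np.full(len(participating), 0.95)
        np_scores = np.full(len(refusers), 0.05)
        scores = pd.concat(
            [uniform_scores(participating, part_scores), uniform_scores(refusers, np_scores)]
        )
        with pytest.raises(MatchingExhaustedError):
            psm_match(participating, refusers, scores, rng=0, caliper=0.1)

    def test_ensemble_runs_vary_only_in_order_and_ties(self, participating, refusers):
        rng_scores = np.random.default_rng(6)
        scores = pd.concat(
            [
                uniform_scores(participating, rng_scores.uniform(0.3, 0.9, len(participating))),
                uniform_scores(refusers, rng_scores.uniform(0.2, 0.7, len(refusers))),
            ]
        )
        runs = psm_ensemble(participating, refusers, scores, 10, master_seed=9)
        assert len(runs) == 10
        for r in runs:
            assert len(r.member_ids) == 19 == len(set(r.member_ids))

    def test_membership_long_round_trip(self, participating, refusers):
        runs = bootstrap_groups(participating, 5, 3, master_seed=1)
        back = long_to_runs(runs_to_long(runs), "bootstrap")
        assert [r.member_ids for r in back] == [r.member_ids for r in runs]
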