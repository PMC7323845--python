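import numpy as np
import pandas as pd
import pytest

from consentbias.data_model import (
    OBS_MEASUREMENTS,
    TEST_MEASUREMENTS,
    ParticipationStatus,
    records_to_frame,
)
from consentbias.imputer import (
    BINARY,
    GAUSSIAN,
    ImputationModel,
    ImputationModelSet,
    fit_imputation_models,
    impute_run,
    long_to_runs,
    multiple_impute,
    runs_to_long,
    stack_runs,
)
from consentbias.util import ReproducibilityError

from conftest import make_dyad
from consentbias.synthetic_data import generate_population, observed_view, paper_scale_config


def linear_records(n=12, slope=2.0, noise=0.0, seed=0):
    """Tested dyads whose total_play_time is slope*pq (+ noise)."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        pq = float(i % 6)
        r = make_dyad(i, pq=pq)
        out = r.outcome
        object.__setattr__(out, "total_play_time", slope * pq + noise * rng.normal())
        records.append(r)
    return records


class TestFitImputationModels:
    def test_deterministic_relation_recovered_exactly(self):
        models = fit_imputation_models(linear_records(), measurements=["total_play_time"])
        m = models.models["total_play_time"]
        assert m.family == GAUSSIAN
        pq_idx = 1 + OBS_MEASUREMENTS.index("pedagogical_questions")
        assert m.params[pq_idx] == pytest.approx(2.0, abs=1e-8)
        assert m.resid_var == pytest.approx(0.0, abs=1e-12)

    def test_six_row_fixture_matches_normal_equations(self):
        rng = np.random.default_rng(5)
        records = [make_dyad(i, pq=float(rng.integers(0, 5))) for i in range(6)]
        frame = records_to_frame(records)
        predictors = ["pedagogical_questions", "statements"]
        models = fit_imputation_models(frame, predictors=predictors, measurements=["whole_unique_actions"])
        X = np.column_stack([np.ones(6), frame[predictors].to_numpy(float)])
        y = frame["whole_unique_actions"].to_numpy(float)
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(models.models["whole_unique_actions"].params, beta_oracle, atol=1e-10)

    def test_underdetermined_design_is_rejected(self):
        # n = 8 with 7 predictors + intercept
        records = [make_dyad(i, pq=0.3 * ((3 * i) % 7)) for i in range(8)]
        with pytest.raises(ValueError, match="underdetermined"):
            fit_imputation_models(records)

    def test_constant_binary_outcome_marked_degenerate(self):
        records = []
        for i in range(12):
            r = make_dyad(i, pq=0.5 * ((3 * i) % 7))
            object.__setattr__(r.outcome, "whole_target_activated", 1.0)
            object.__setattr__(r.outcome, "first_target_activated", 1.0)
            records.append(r)
        models = fit_imputation_models(records)
        m = models.models["whole_target_activated"]
        assert m.family == BINARY
        assert m.degenerate_constant == 1.0


class TestImputeRun:
    def test_plugin_zero_residual_is_exact(self):
        models = fit_imputation_models(linear_records(), measurements=["total_play_time"])
        target = records_to_frame([make_dyad(99, pq=3.0, outcome=None, status=ParticipationStatus.REFUSED)])
        run = impute_run(models, target, rng=1, proper=False)
        assert run.values["total_play_time"].iloc[0] == pytest.approx(6.0, abs=1e-8)

    def test_proper_mean_matches_monte_carlo_oracle(self):
        models = fit_imputation_models(linear_records(n=20, noise=1.0, seed=2), measurements=["total_play_time"])
        target = records_to_frame([make_dyad(99, pq=3.0, outcome=None, status=ParticipationStatus.REFUSED)])
        X = np.array([1.0, *target[OBS_MEASUREMENTS].to_numpy(float)[0]])
        expected = X @ models.models["total_play_time"].params
        draws = np.array(
            [impute_run(models, target, rng=np.random.default_rng(k), proper=True).values.iloc[0, 0] for k in range(1000)]
        )
        mc_se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - expected) < 3 * mc_se

    def test_binary_half_probability_matches_binomial_oracle(self):
        model = ImputationModel(
            measurement="whole_target_activated", family=BINARY,
            predictor_names=list(OBS_MEASUREMENTS),
            params=np.zeros(len(OBS_MEASUREMENTS) + 1),
            cov_params=np.zeros((len(OBS_MEASUREMENTS) + 1,) * 2),
        )
        models = ImputationModelSet(predictor_names=list(OBS_MEASUREMENTS), models={"whole_target_activated": model})
        target = records_to_frame([make_dyad(99, outcome=None, status=ParticipationStatus.REFUSED)])
        draws = np.array(
            [impute_run(models, target, rng=np.random.default_rng(k), proper=True).values.iloc[0, 0] for k in range(1000)]
        )
        se = np.sqrt(0.25 / draws.size)
        assert abs(draws.mean() - 0.5) < 3 * se

    def test_unseeded_source_is_refused(self):
        models = fit_imputation_models(linear_records(), measurements=["total_play_time"])
        target = records_to_frame([make_dyad(99, outcome=None, status=ParticipationStatus.REFUSED)])
        with pytest.raises(ReproducibilityError):
            impute_run(models, target, rng=None)

    def test_out_of_range_draws_are_counted_not_altered(self):
        # a model centred near zero with large residual noise must flag draws
        # below the count floor while leaving the model-scale values intact
        models = fit_imputation_models(
            linear_records(n=30, slope=0.0, noise=5.0, seed=4), measurements=["whole_unique_actions"]
        )
        model = models.models["whole_unique_actions"]
        model.params[:] = 0.0
        model.resid_var = 25.0
        target = records_to_frame([make_dyad(99, outcome=None, status=ParticipationStatus.REFUSED)])
        runs = multiple_impute(models, target, 200, master_seed=0, proper=False)
        values = np.array([r.values.iloc[0, 0] for r in runs])
        n_flagged = sum(r.n_clipped["whole_unique_actions"] for r in runs)
        assert (values < 0).sum() == n_flagged > 0


@pytest.fixture(scope="module")
def setup(paper_records):
    part = [r for r in paper_records if r.status is ParticipationStatus.TESTED]
    nonpart = [r for r in paper_records if r.status is ParticipationStatus.REFUSED]
    models = fit_imputation_models(part)
    return models, records_to_frame(nonpart)


class TestMultipleImpute:

    def test_run_count_and_determinism(self, setup):
        models, targets = setup
        runs_a = multiple_impute(models, targets, 5, master_seed=123)
        runs_b = multiple_impute(models, targets, 5, master_seed=123)
        assert len(runs_a) == 5
        for a, b in zip(runs_a, runs_b):
            pd.testing.assert_frame_equal(a.values, b.values)
            assert a.seed == b.seed

    def test_runs_differ_between_indices(self, setup):
        models, targets = setup
        runs = multiple_impute(models, targets, 2, master_seed=123)
        assert not runs[0].values.equals(runs[1].values)

    def test_proper_between_run_variance_exceeds_plugin(self, setup):
        models, targets = setup
        proper = stack_runs(multiple_impute(models, targets, 100, master_seed=7, proper=True))
        plugin = stack_runs(multiple_impute(models, targets, 100, master_seed=7, proper=False))
        gaussian_idx = [i for i, m in enumerate(TEST_MEASUREMENTS) if models.models[m].family == GAUSSIAN]
        var_proper = proper.var(axis=0, ddof=1)[:, gaussian_idx].mean()
        var_plugin = plugin.var(axis=0, ddof=1)[:, gaussian_idx].mean()
        assert var_proper > var_plugin

    def test_clipping_rare_when_generator_respects_the_ranges(self):
        # outcomes placed comfortably inside their valid ranges
        cfg = paper_scale_config(seed=21)
        cfg.n_dyads = 150
        cfg.gaussian_outcomes["whole_nontarget_functions"] = {
            "intercept": 2.0, "slopes": {"pedagogical_questions": 0.15}, "resid_sd": 0.7,
        }
        cfg.first_minute = dict(cfg.first_minute)
        cfg.first_minute["first_nontarget_functions_p"] = 0.75
        recs = observed_view(generate_population(cfg))
        part = [r for r in recs if r.status is ParticipationStatus.TESTED]
        nonpart = [r for r in recs if r.status is ParticipationStatus.REFUSED]
        models = fit_imputation_models(part)
        runs = multiple_impute(models, records_to_frame(nonpart), 50, master_seed=11)
        total_flagged = sum(sum(r.n_clipped.values()) for r in runs)
        total_values = 50 * len(nonpart) * len(TEST_MEASUREMENTS)
        assert total_flagged / total_values < 0.05

    def test_postprocessed_values_satisfy_outcome_ranges(self, setup):
        models, targets = setup
        run = multiple_impute(models, targets, 1, master_seed=3)[0]
        post = run.postprocessed()
        assert (post["whole_nontarget_functions"] <= 4).all()
        assert (post.drop(columns="total_play_time") >= 0).to_numpy().all()
        assert (post["first_unique_actions"] <= post["whole_unique_actions"]).all()

    def test_long_format_round_trip(self, setup):
        models, targets = setup
        runs = multiple_impute(models, targets, 3, master_seed=9)
        back = long_to_runs(runs_to_long(runs))
        for a, b in zip(runs, back):
            assert np.allclose(a.values.to_numpy(), b.values[a.values.columns].to_numpy())

    def test_zero_runs_rejected(self, setup):
        models, targets = setup
        with pytest.raises(ValueError):
            multiple_impute(models, targets, 0, master_seed=1)
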