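import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from consentbias.data_model import FIRST_MINUTE_MEASUREMENTS, WHOLE_PERIOD_MEASUREMENTS
from consentbias.scores import (
    CollinearityError,
    DegenerateScaleError,
    cohens_d,
    composite_scores,
    fishers_exact,
    partial_correlation,
    zscore,
)

from _oracles import fisher_enum_two_tailed

finite_floats = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)


class TestZscore:
    def test_simple_triple(self):
        assert np.allclose(zscore([1, 2, 3]), [-1, 0, 1])

    def test_constant_input_is_degenerate(self):
        with pytest.raises(DegenerateScaleError):
            zscore([5, 5, 5])

    def test_external_reference_is_linear_transform(self):
        assert np.allclose(zscore([2], reference=(0, 2)), [1.0])

    @given(st.lists(finite_floats, min_size=3, max_size=40, unique=True))
    def test_self_referenced_output_is_standardized(self, values):
        z = zscore(values)
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1) < 1e-9


class TestCompositeScores:
    def _outcomes(self, rows):
        cols = WHOLE_PERIOD_MEASUREMENTS + FIRST_MINUTE_MEASUREMENTS
        return pd.DataFrame(rows, columns=cols)

    def test_child_at_reference_mean_scores_zero(self):
        ref = self._outcomes([[0, 2, 1, 0, 1, 0], [2, 6, 3, 1, 3, 2]])
        child = self._outcomes([[1, 4, 2, 0.5, 2, 1]])  # the column means of ref
        comp = composite_scores(child, reference_group=ref)
        assert np.allclose(comp.scores.to_numpy(), 0.0)

    def test_one_sd_above_on_all_whole_measurements_gives_three(self):
        ref = self._outcomes([[0, 2, 1, 0, 1, 0], [2, 6, 3, 1, 3, 2]])
        means = ref.mean()
        sds = ref.std(ddof=1)
        child = self._outcomes([(means + sds).to_numpy()])
        comp = composite_scores(child, reference_group=ref)
        assert comp.scores["exploration_variability"].iloc[0] == pytest.approx(3.0)
        assert comp.scores["exploration_efficiency"].iloc[0] == pytest.approx(3.0)

    def test_five_child_fixture_matches_hand_summed_zscores(self):
        rng = np.random.default_rng(42)
        group = self._outcomes(rng.uniform(0, 10, size=(5, 6)))
        comp = composite_scores(group)
        # oracle: per-measurement z via the statistics module, summed manually
        expected_var = np.zeros(5)
        for m in WHOLE_PERIOD_MEASUREMENTS:
            col = group[m].tolist()
            mu, sd = statistics.fmean(col), statistics.stdev(col)
            expected_var += (np.array(col) - mu) / sd
        assert np.allclose(comp.scores["exploration_variability"].to_numpy(), expected_var)

    def test_additive_in_measurement_set(self):
        rng = np.random.default_rng(7)
        group = self._outcomes(rng.uniform(0, 10, size=(6, 6)))
        s_set = [WHOLE_PERIOD_MEASUREMENTS[0]]
        t_set = WHOLE_PERIOD_MEASUREMENTS[1:]
        full = composite_scores(group, variability_set=s_set + t_set).scores["exploration_variability"]
        part_s = composite_scores(group, variability_set=s_set).scores["exploration_variability"]
        part_t = composite_scores(group, variability_set=t_set).scores["exploration_variability"]
        assert np.allclose(full, part_s + part_t)

    def test_degenerate_reference_names_the_measurement(self):
        ref = self._outcomes([[1, 2, 1, 0, 1, 0], [1, 6, 3, 1, 3, 2]])
        with pytest.raises(DegenerateScaleError, match="whole_target_activated"):
            composite_scores(ref)


class TestPartialCorrelation:
    def test_empty_controls_equals_pearson(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        res = partial_correlation(x, y)
        r_ref, p_ref = stats.pearsonr(x, y)
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, rel=1e-9)
        assert res.df == 28

    def test_self_correlation(self):
        x = np.arange(10.0)
        res = partial_correlation(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_df_formula_with_two_controls(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(2, 47))
        controls = rng.normal(size=(2, 47))
        assert partial_correlation(x, y, controls).df == 43

    def test_matches_residual_correlation_oracle(self):
        # 8-point fixture, one control; oracle solves the normal equations directly
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        y = np.array([2.0, 1, 4, 3, 7, 5, 8, 9])
        c = np.array([0.5, 1, 0, 2, 1, 3, 2, 4])
        D = np.column_stack([np.ones(8), c])
        coef_x = np.linalg.solve(D.T @ D, D.T @ x)
        coef_y = np.linalg.solve(D.T @ D, D.T @ y)
        r_oracle = np.corrcoef(x - D @ coef_x, y - D @ coef_y)[0, 1]
        res = partial_correlation(x, y, [c])
        assert res.r == pytest.approx(r_oracle, abs=1e-12)
        assert res.df == 5

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(40, 4)), columns=["x", "y", "c1", "c2"])
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        res = partial_correlation(df["x"], df["y"], [df["c1"], df["c2"]])
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_collinear_controls_rejected(self):
        x, y = np.arange(10.0), np.arange(10.0)[::-1].copy()
        with pytest.raises(CollinearityError):
            partial_correlation(x, y, [np.ones(10)])


class TestCohensD:
    def test_hand_example(self):
        assert cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(-2.0)

    def test_identical_groups_give_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=15),
        st.lists(st.floats(-100, 100), min_size=3, max_size=15),
        st.floats(-50, 50),
        st.floats(0.1, 10),
    )
    def test_shift_invariance_scale_equivariance_antisymmetry(self, a, b, shift, scale):
        a, b = np.asarray(a), np.asarray(b)
        if a.var(ddof=1) + b.var(ddof=1) == 0:
            return
        d = cohens_d(a, b)
        assert cohens_d(b, a) == pytest.approx(-d, rel=1e-9, abs=1e-12)
        assert cohens_d(a + shift, b + shift) == pytest.approx(d, rel=1e-6, abs=1e-9)
        assert cohens_d(a * scale, b * scale) == pytest.approx(d, rel=1e-6, abs=1e-9)


class TestFishersExact:
    def test_diagonal_table(self):
        assert fishers_exact([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_modal_table_gives_one(self):
        assert fishers_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_zero_margin_gives_one(self):
        assert fishers_exact([[0, 0], [3, 4]]) == pytest.approx(1.0)

    def test_negative_cell_rejected(self):
        with pytest.raises(Exception):
            fishers_exact([[1, -1], [2, 3]])

    @given(st.lists(st.integers(0, 8), min_size=4, max_size=4))
    def test_matches_enumeration_oracle(self, cells):
        table = [cells[:2], cells[2:]]
        if sum(cells) == 0:
            return
        assert fishers_exact(table) == pytest.approx(fisher_enum_two_tailed(table), rel=1e-9)
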