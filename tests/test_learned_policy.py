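import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from adaptive_coach.cohort_model import DailyMessage
from adaptive_coach.learned_policy import (
    ACTION_NAMES,
    FEATURE_NAMES,
    ActivityResponseModel,
    ActivityResponseResults,
    FeatureVector,
    InsufficientDataError,
    boltzmann_probabilities,
    boltzmann_sample,
    build_features,
    compute_reward,
    expand_interactions,
    interaction_manifest,
    kesler_augment,
)
from conftest import MONDAY, make_day


def naive_expand(row):
    """Independent double-loop oracle for the interaction expansion."""
    row = list(row)
    out = list(row)
    n_features = len(FEATURE_NAMES)
    for i in range(len(row)):
        for j in range(i + 1, len(row)):
            if i >= n_features and j >= n_features:
                continue  # both are action indicators
            out.append(row[i] * row[j])
    return np.array(out)


def make_fv(**overrides):
    kwargs = dict(
        minutes_last_day=20.0,
        cumulative_week_minutes=60.0,
        fraction_of_goal=0.4,
        fraction_vs_expected=0.8,
        age=58.0,
        gender_female=0,
        days_since_message=(1, 3, 7, 30),
    )
    kwargs.update(overrides)
    return FeatureVector(**kwargs)


class TestReward:
    def test_unchanged_activity_is_one(self):
        assert compute_reward(30, 30) == pytest.approx(1.0)

    def test_raw_ratio_without_epsilon(self):
        assert compute_reward(30, 60, epsilon=0.0) == pytest.approx(2.0)

    def test_zero_day_convention(self):
        assert compute_reward(0, 30, epsilon=1.0) == pytest.approx(31.0)

    def test_negative_minutes_rejected(self):
        with pytest.raises(ValueError):
            compute_reward(-1, 10)


class TestBuildFeatures:
    def test_goal_fractions_on_last_day_of_week(self, make_patient):
        patient = make_patient()  # weekly target 140
        sunday = MONDAY + dt.timedelta(days=6)
        history = [make_day("p001", MONDAY + dt.timedelta(days=k), 10) for k in range(7)]
        fv = build_features(patient, history, [], sunday)
        assert fv.cumulative_week_minutes == pytest.approx(70)
        assert fv.fraction_of_goal == pytest.approx(0.5)
        assert fv.fraction_vs_expected == pytest.approx(0.5)  # expected fraction is 1 on day 7
        assert fv.minutes_last_day == pytest.approx(10)

    def test_days_since_capped_at_horizon_when_never_sent(self, make_patient):
        patient = make_patient()
        fv = build_features(patient, [make_day("p001", MONDAY, 5)], [], MONDAY, horizon=30)
        assert fv.days_since_message == (30, 30, 30, 30)

    def test_message_sent_yesterday_morning_counts_one(self, make_patient):
        patient = make_patient()
        date = MONDAY + dt.timedelta(days=5)
        log = [(date, DailyMessage.POSITIVE_SELF)]  # decision happens the morning after `date`
        fv = build_features(patient, [make_day("p001", date, 5)], log, date)
        assert fv.days_since_message[DailyMessage.POSITIVE_SELF] == 1

    def test_minimum_days_since_is_enforced(self):
        with pytest.raises(ValueError):
            make_fv(days_since_message=(0, 1, 1, 1))


class TestKeslerAndInteractions:
    def test_one_hot_position_and_length(self):
        row = kesler_augment(make_fv(), DailyMessage.NEGATIVE)
        assert row.shape == (14,)
        assert list(row[10:]) == [1, 0, 0, 0]

    def test_actions_differ_only_in_action_block(self):
        fv = make_fv()
        a = kesler_augment(fv, DailyMessage.NEGATIVE)
        b = kesler_augment(fv, DailyMessage.NONE)
        assert np.array_equal(a[:10], b[:10])
        assert not np.array_equal(a[10:], b[10:])

    def test_design_width_matches_brute_force_count(self):
        # 14 main effects + all pairs of distinct columns minus action x action
        n_pairs = sum(
            1
            for i in range(14)
            for j in range(i + 1, 14)
            if not (i >= 10 and j >= 10)
        )
        assert len(interaction_manifest()) == 14 + n_pairs == 99

    def test_zero_row_expands_to_zeros(self):
        assert np.all(expand_interactions(np.zeros(14)) == 0)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_double_loop_oracle(self, seed):
        row = np.random.default_rng(seed).normal(size=14)
        assert np.allclose(expand_interactions(row), naive_expand(row), atol=1e-12)


class TestModelFit:
    @staticmethod
    def _random_design(rng, n):
        # continuous base columns keep the expanded design full rank
        base = rng.normal(size=(n, 14))
        return expand_interactions(base)

    def test_noiseless_coefficient_recovery(self):
        rng = np.random.default_rng(1)
        X = self._random_design(rng, 400)
        beta = rng.normal(size=X.shape[1])
        y = 0.7 + X @ beta
        res = ActivityResponseModel(
            design=X, rewards=y, winsorize_cap=np.inf, min_examples=10
        ).fit()
        assert res.intercept == pytest.approx(0.7, abs=1e-6)
        assert np.allclose(res.params, beta, atol=1e-6)

    def test_matches_normal_equations_oracle_on_small_instance(self):
        # n=120 x 10 columns, oracle built with explicit loops
        rng = np.random.default_rng(2)
        X = self._random_design(rng, 120)[:, :10]
        y = rng.normal(loc=1.0, scale=0.3, size=120)
        res = ActivityResponseModel(
            design=X, rewards=y, winsorize_cap=np.inf, min_examples=10
        ).fit()

        Xi = np.column_stack([np.ones(120), X])
        k = Xi.shape[1]
        xtx = np.zeros((k, k))
        xty = np.zeros(k)
        for a in range(k):
            xty[a] = sum(Xi[r, a] * y[r] for r in range(120))
            for b in range(k):
                xtx[a, b] = sum(Xi[r, a] * Xi[r, b] for r in range(120))
            if a > 0:
                xtx[a, a] += 1e-6  # same ridge, intercept unpenalized
        beta = np.linalg.solve(xtx, xty)
        assert res.intercept == pytest.approx(beta[0], abs=1e-8)
        assert np.allclose(res.params, beta[1:], atol=1e-8)

    def test_cross_check_against_statsmodels_ols(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        X = self._random_design(rng, 500)[:, :20]
        y = rng.normal(loc=1.0, scale=0.3, size=500)
        res = ActivityResponseModel(
            design=X, rewards=y, winsorize_cap=np.inf, min_examples=10, ridge=0.0
        ).fit()
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        assert res.intercept == pytest.approx(ols.params[0], abs=1e-8)
        assert np.allclose(res.params, ols.params[1:], atol=1e-8)
        assert res.rsquared_adj == pytest.approx(ols.rsquared_adj, abs=1e-10)
        assert np.allclose(res.bse, ols.bse[1:], atol=1e-8)

    def test_refit_is_deterministic(self):
        rng = np.random.default_rng(4)
        X = self._random_design(rng, 300)
        y = rng.normal(loc=1.0, scale=0.3, size=300)
        r1 = ActivityResponseModel(design=X, rewards=y, min_examples=10).fit()
        r2 = ActivityResponseModel(design=X, rewards=y, min_examples=10).fit()
        assert np.array_equal(r1.params, r2.params)
        assert r1.intercept == r2.intercept

    def test_insufficient_data_signals_initial_policy(self):
        X = np.zeros((10, 99))
        with pytest.raises(InsufficientDataError):
            ActivityResponseModel(design=X, rewards=np.ones(10), min_examples=200).fit()

    def test_adjusted_r2_approaches_theoretical_value(self):
        # y generated exactly from the model with noise SD 0.2 at n=5000
        rng = np.random.default_rng(5)
        X = self._random_design(rng, 5000)[:, :30]
        beta = rng.normal(scale=0.05, size=30)
        signal = X @ beta
        y = 1.0 + signal + rng.normal(scale=0.2, size=5000)
        res = ActivityResponseModel(
            design=X, rewards=y, winsorize_cap=np.inf, min_examples=10
        ).fit()
        theoretical = signal.var() / (signal.var() + 0.04)
        assert res.rsquared_adj == pytest.approx(theoretical, abs=0.05)

    def test_snapshot_round_trip(self):
        rng = np.random.default_rng(6)
        X = self._random_design(rng, 300)
        y = rng.normal(loc=1.0, scale=0.3, size=300)
        res = ActivityResponseModel(design=X, rewards=y, min_examples=10).fit(
            fit_date=dt.date(2016, 4, 1)
        )
        back = ActivityResponseResults.from_json(res.to_json())
        assert np.allclose(back.params, res.params)
        assert back.fit_date == res.fit_date
        assert back.manifest == res.manifest


class TestPrediction:
    def test_intercept_only_model(self):
        res = ActivityResponseResults(
            intercept=1.0,
            params=np.zeros(99),
            bse=np.zeros(99),
            intercept_se=0.0,
            manifest=interaction_manifest(),
            nobs=10,
            rsquared_adj=0.0,
            rsquared=0.0,
        )
        for action in DailyMessage:
            assert res.predict_gain(make_fv(), action) == pytest.approx(1.0)

    def test_single_action_main_effect(self):
        params = np.zeros(99)
        params[interaction_manifest().index("action_positive_social")] = 0.3
        res = ActivityResponseResults(
            intercept=1.0,
            params=params,
            bse=np.zeros(99),
            intercept_se=0.0,
            manifest=interaction_manifest(),
            nobs=10,
            rsquared_adj=0.0,
            rsquared=0.0,
        )
        gains = res.action_gains(make_fv())
        assert gains[DailyMessage.POSITIVE_SOCIAL] == pytest.approx(1.3)
        assert gains[DailyMessage.NEGATIVE] == pytest.approx(1.0)

    def test_matches_term_by_term_oracle(self):
        rng = np.random.default_rng(9)
        params = rng.normal(scale=0.1, size=99)
        res = ActivityResponseResults(
            intercept=0.5,
            params=params,
            bse=np.zeros(99),
            intercept_se=0.0,
            manifest=interaction_manifest(),
            nobs=10,
            rsquared_adj=0.0,
            rsquared=0.0,
        )
        fv = make_fv()
        for action in DailyMessage:
            cols = naive_expand(kesler_augment(fv, action))
            expected = 0.5 + sum(params[k] * cols[k] for k in range(99))
            assert res.predict_gain(fv, action) == pytest.approx(expected, abs=1e-10)


class TestBoltzmann:
    def test_equal_gains_are_uniform(self):
        assert np.allclose(boltzmann_probabilities(np.zeros(4), 5.0), 0.25)

    def test_softmax_formula_example(self):
        probs = boltzmann_probabilities(np.array([2.0, 0.0, 0.0, 0.0]), 5.0)
        expected = math.exp(0.4) / (math.exp(0.4) + 3)
        assert probs[0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.332, abs=5e-4)

    def test_high_temperature_limit_is_uniform(self):
        probs = boltzmann_probabilities(np.array([2.0, 0.0, 1.0, 0.5]), 1e6)
        assert np.allclose(probs, 0.25, atol=1e-6)

    @given(st.floats(min_value=-100, max_value=100))
    def test_shift_invariance(self, shift):
        gains = np.array([1.8, 0.4, 1.1, 0.9])
        assert np.allclose(
            boltzmann_probabilities(gains, 5.0),
            boltzmann_probabilities(gains + shift, 5.0),
            atol=1e-12,
        )

    def test_monotone_in_own_gain(self):
        gains = np.array([1.0, 1.0, 1.0, 1.0])
        bumped = gains.copy()
        bumped[2] += 0.5
        assert boltzmann_probabilities(bumped, 5.0)[2] > boltzmann_probabilities(gains, 5.0)[2]

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            probs = boltzmann_probabilities(rng.normal(size=4) * 5, 5.0)
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_non_finite_gain_rejected(self):
        with pytest.raises(ValueError):
            boltzmann_probabilities(np.array([1.0, np.nan, 0.0, 0.0]), 5.0)

    def test_sampler_matches_analytic_distribution(self):
        rng = np.random.default_rng(11)
        gains = np.array([2.0, 0.0, 0.0, 0.0])
        n = 100_000
        counts = np.zeros(4)
        for _ in range(n):
            counts[boltzmann_sample(gains, 5.0, rng)] += 1
        expected = boltzmann_probabilities(gains, 5.0)
        se = np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(counts / n - expected) <= 3 * se)
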