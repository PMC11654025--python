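"""Survival estimators and tests against hand computations and oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

from morphmr.survstats import (
    SurvivalSample,
    compare_auc,
    horizon_mortality_auc,
    km_estimate,
    km_median,
    log_rank,
    proportion_test,
)


def sample(times, events=None):
    if events is None:
        events = [True] * len(times)
    return SurvivalSample(times=np.array(times, float), events=np.array(events, bool))


class TestKaplanMeier:
    def test_uncensored_product_limit_hand_values(self):
        curve = km_estimate(sample([2, 4, 6]))
        assert np.allclose(curve.survival_probs, [2 / 3, 1 / 3, 0.0])
        assert np.array_equal(curve.at_risk, [3, 2, 1])

    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate(sample([5, 10, 15], [False, False, False]))
        assert np.all(curve.survival_probs == 1.0)
        assert km_median(curve) is None

    def test_single_death_drops_to_zero(self):
        curve = km_estimate(sample([5]))
        assert curve.survival_at(5) == 0.0

    def test_km_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(11)
        times = rng.exponential(10, size=50).round(2) + 0.01
        curve = km_estimate(sample(times))
        for t in [1.0, 5.0, 12.0, 30.0]:
            assert curve.survival_at(t) == pytest.approx(np.mean(times > t))

    def test_median_conventions(self):
        assert km_median(km_estimate(sample([2, 4, 6]))) == 4
        assert km_median(km_estimate(sample([1, 1, 1, 1]))) == 1

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(5)
        times = rng.exponential(20, 40) + 0.1
        events = rng.random(40) < 0.7
        kmf = lifelines.KaplanMeierFitter().fit(times, events)
        curve = km_estimate(sample(times, events))
        for t in [2.0, 10.0, 25.0]:
            assert curve.survival_at(t) == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0])
            )

    def test_curve_monotone_and_starts_below_one(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(10, 30) + 0.1
        events = rng.random(30) < 0.5
        curve = km_estimate(sample(times, events))
        assert np.all(np.diff(curve.survival_probs) <= 1e-12)
        assert curve.survival_probs[0] <= 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            sample([])


class TestLogRank:
    def test_identical_samples_give_null(self):
        s = sample([3, 6, 9], [True, True, False])
        res = log_rank(s, s)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_symmetric_in_arms(self):
        a = sample([1, 4, 7], [True, False, True])
        b = sample([2, 3, 8, 12], [True, True, True, False])
        assert log_rank(a, b).chi_square == pytest.approx(log_rank(b, a).chi_square)

    def test_separated_samples_significant_and_extreme_under_permutation(self):
        """Well-separated arms: small p, and the observed statistic is the most
        extreme over all 20 relabellings of the pooled sample."""
        a_times, b_times = [1, 2, 3], [10, 20, 30]
        obs = log_rank(sample(a_times), sample(b_times))
        assert obs.p_value < 0.05

        pooled = a_times + b_times
        stats_all = []
        for idx in itertools.combinations(range(6), 3):
            ta = [pooled[i] for i in idx]
            tb = [pooled[i] for i in range(6) if i not in idx]
            stats_all.append(log_rank(sample(ta), sample(tb)).chi_square)
        assert obs.chi_square == pytest.approx(max(stats_all))
        # permutation p-value: both extreme assignments (A low / A high)
        perm_p = np.mean(np.array(stats_all) >= obs.chi_square - 1e-9)
        assert perm_p == pytest.approx(2 / 20)

    def test_matches_lifelines_statistic(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(8)
        ta, tb = rng.exponential(10, 25) + 0.1, rng.exponential(20, 30) + 0.1
        ea, eb = rng.random(25) < 0.8, rng.random(30) < 0.8
        mine = log_rank(sample(ta, ea), sample(tb, eb))
        ref = lifelines_stats.logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert mine.chi_square == pytest.approx(ref.test_statistic, rel=1e-6)
        assert mine.p_value == pytest.approx(ref.p_value, rel=1e-6)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            log_rank(sample([1, 2], [False, False]), sample([3], [False]))


class TestHorizonAUC:
    def test_perfect_marker_gives_auc_one(self):
        s = sample([6, 7, 30, 40])
        marker = [True, True, False, False]  # exactly the early deaths
        res = horizon_mortality_auc(marker, s, 12.0)
        assert res.auc == pytest.approx(1.0)

    def test_independent_marker_near_half(self):
        rng = np.random.default_rng(4)
        n = 4000
        times = rng.exponential(24, n) + 0.1
        marker = rng.random(n) < 0.5
        res = horizon_mortality_auc(marker, sample(list(times)), 12.0)
        assert res.auc == pytest.approx(0.5, abs=0.03)

    def test_binary_auc_equals_sens_spec_average_and_rank_auc(self):
        """(sens+spec)/2 identity, cross-checked against sklearn's rank AUC."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        times = rng.exponential(20, 200) + 0.1
        events = rng.random(200) < 0.8
        marker = rng.random(200) < 0.4
        s = sample(times, events)
        res = horizon_mortality_auc(marker, s, 18.0)
        assert res.auc == pytest.approx((res.sensitivity + res.specificity) / 2)
        cases = s.events & (s.times <= 18.0)
        controls = (s.times >= 18.0) & ~cases
        keep = cases | controls
        rank_auc = roc_auc_score(cases[keep], np.asarray(marker, float)[keep])
        assert res.auc == pytest.approx(rank_auc)

    def test_designed_sensitivity_specificity(self):
        """Cases with 80% marker rate, controls with 40%: AUC = (0.8+0.6)/2."""
        n_cases, n_controls = 50, 50
        marker = [True] * 40 + [False] * 10 + [True] * 20 + [False] * 30
        times = [6.0] * n_cases + [30.0] * n_controls
        events = [True] * n_cases + [False] * n_controls
        res = horizon_mortality_auc(marker, sample(times, events), 12.0)
        assert res.auc == pytest.approx(0.7)
        assert res.ci_low <= res.auc <= res.ci_high

    def test_censored_before_horizon_excluded_and_counted(self):
        times = [6, 10, 30, 8]
        events = [True, False, False, True]  # second patient censored at 10 < 24
        res = horizon_mortality_auc([1, 0, 0, 1], sample(times, events), 24.0)
        assert res.n_excluded == 1
        assert res.n_cases == 2 and res.n_controls == 1

    def test_undefined_without_controls(self):
        res = horizon_mortality_auc([1, 0], sample([5, 6]), 12.0)
        assert not res.defined


class TestCompareAUC:
    def test_identical_markers_give_p_one(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(20, 100) + 0.1
        marker = rng.random(100) < 0.5
        s = sample(list(times))
        assert compare_auc(marker, marker, s, 12.0) == pytest.approx(1.0)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(6)
        times = rng.exponential(20, 120) + 0.1
        a, b = rng.random(120) < 0.5, rng.random(120) < 0.5
        s = sample(list(times))
        assert compare_auc(a, b, s, 12.0) == pytest.approx(compare_auc(b, a, s, 12.0))

    def test_detects_informative_vs_noise_marker(self):
        """Marker tracking early death vs pure noise at n=200: p < 0.05."""
        rng = np.random.default_rng(12)
        n = 200
        times = rng.exponential(24, n) + 0.1
        dead_by_12 = times <= 12.0
        informative = np.where(rng.random(n) < 0.9, dead_by_12, rng.random(n) < 0.5)
        noise = rng.random(n) < 0.5
        s = sample(list(times))
        assert compare_auc(informative, noise, s, 12.0) < 0.05

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_auc([1, 0], [1, 0, 1], sample([5, 6, 30]), 12.0)


def _fisher_oracle(a_yes, a_n, b_yes, b_n):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    total_yes = a_yes + b_yes
    n = a_n + b_n
    probs = {
        k: stats.hypergeom.pmf(k, n, total_yes, a_n)
        for k in range(max(0, total_yes - b_n), min(a_n, total_yes) + 1)
    }
    p_obs = probs[a_yes]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


class TestProportionTest:
    def test_identical_proportions_p_one(self):
        assert proportion_test(5, 10, 5, 10) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table", [(6, 16, 7, 40), (2, 10, 8, 12), (3, 12, 9, 10), (1, 8, 7, 9)]
    )
    def test_small_tables_match_hypergeometric_enumeration(self, table):
        assert proportion_test(*table) == pytest.approx(_fisher_oracle(*table), rel=1e-9)

    def test_extreme_table_highly_significant(self):
        assert proportion_test(10, 10, 0, 10) < 0.01

    def test_large_table_uses_chi_square(self):
        p = proportion_test(40, 100, 60, 100)
        chi2, p_ref, _, _ = stats.chi2_contingency(
            [[40, 60], [60, 40]], correction=False
        )
        assert p == pytest.approx(p_ref)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            proportion_test(5, 0, 1, 10)
        with pytest.raises(ValueError):
            proportion_test(11, 10, 1, 10)
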