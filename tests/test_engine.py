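import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from qalypy import (
    EstimationError,
    HybridQalyEstimator,
    InputError,
    SurvivalRecord,
    WeibullFit,
    default_spec,
    fit_km,
    fit_weibull,
    followup_qaly,
    generate_cohort,
    mean_qaly_at_death,
    mean_qaly_at_horizon,
    mean_utility_at_horizon,
    records_from_frame,
    restricted_life_years,
    tail_qaly,
    total_qaly,
    true_group_qaly,
    weibull_mean,
)


def frame(times, events, weights=None, utilities=None):
    n = len(times)
    return pd.DataFrame({
        "time": times,
        "event": events,
        "weight": weights if weights is not None else np.ones(n),
        "utility": utilities if utilities is not None else np.ones(n),
    })


# ---------------------------------------------------------------------------
# Kaplan-Meier


class TestFitKM:
    def test_single_death_drops_to_zero(self):
        km = fit_km([SurvivalRecord(2.0, True)])
        assert km.times.tolist() == [2.0]
        assert km.survival.tolist() == [0.0]

    def test_all_censored_is_flat_one(self):
        km = fit_km(frame([1.0, 2.0, 3.0], [0, 0, 0]))
        assert len(km.times) == 0
        assert km.survival_at(5.0) == 1.0

    def test_hand_product_limit(self):
        km = fit_km(frame([1.0, 2.0, 3.0], [1, 1, 0]))
        assert km.survival_at(1.0) == pytest.approx(2 / 3)
        assert km.survival_at(2.0) == pytest.approx(1 / 3)

    def test_empty_input_rejected(self):
        with pytest.raises(EstimationError):
            fit_km(frame([], []))

    def test_nonpositive_time_or_weight_rejected(self):
        with pytest.raises(InputError):
            SurvivalRecord(0.0, True)
        with pytest.raises(InputError):
            SurvivalRecord(1.0, True, weight=0.0)

    def test_exhaustive_small_datasets_match_oracle(self):
        """All event patterns on <= 8 records (tied and untied times,
        unequal weights) agree with the brute-force product-limit oracle."""
        time_sets = [
            [1.0, 2.0, 3.0, 4.0],
            [1.0, 1.0, 2.0, 3.0],       # tied pair
            [2.0, 2.0, 2.0, 5.0],       # triple tie
            [0.5, 1.5, 1.5, 2.5, 4.0, 4.0, 5.5, 6.0],
        ]
        for times in time_sets:
            n = len(times)
            weights = [1.0 + 0.5 * (i % 3) for i in range(n)]
            for events in itertools.product([0, 1], repeat=n):
                km = fit_km(frame(times, list(events), weights))
                o_times, o_surv = oracles.km_oracle(times, events, weights)
                assert km.times.tolist() == o_times
                np.testing.assert_allclose(km.survival, o_surv, atol=1e-12)

    def test_curve_nonincreasing_in_unit_interval(self, rng):
        for _ in range(20):
            n = rng.integers(2, 40)
            df = frame(rng.uniform(0.1, 10, n), rng.integers(0, 2, n),
                       rng.uniform(0.2, 5, n))
            km = fit_km(df)
            assert np.all(np.diff(km.survival) <= 1e-15)
            assert np.all((km.survival >= -1e-15) & (km.survival <= 1))


class TestRestrictedLifeYears:
    def test_flat_curve_gives_horizon(self):
        km = fit_km(frame([1.0, 2.0], [0, 0]))
        assert restricted_life_years(km, 5.0) == 5.0

    def test_hand_integration(self):
        km = fit_km(frame([1.0, 2.0, 3.0], [1, 1, 0]))
        # 1*1 + (2/3)*1 + (1/3)*1
        assert restricted_life_years(km, 3.0) == pytest.approx(2.0)

    def test_zero_horizon(self):
        km = fit_km(frame([1.0], [1]))
        assert restricted_life_years(km, 0.0) == 0.0

    def test_negative_horizon_rejected(self):
        km = fit_km(frame([1.0], [1]))
        with pytest.raises(InputError):
            restricted_life_years(km, -1.0)

    def test_never_exceeds_horizon(self, rng):
        for _ in range(20):
            n = rng.integers(2, 30)
            df = frame(rng.uniform(0.1, 8, n), rng.integers(0, 2, n))
            km = fit_km(df)
            L = float(df["time"].max()) + 0.5
            area = restricted_life_years(km, L)
            assert area <= L + 1e-12
            if df["event"].sum() > 0:
                assert area < L

    def test_matches_step_oracle(self, rng):
        for _ in range(10):
            n = rng.integers(3, 25)
            df = frame(rng.uniform(0.1, 8, n), rng.integers(0, 2, n),
                       rng.uniform(0.5, 3, n))
            km = fit_km(df)
            L = float(df["time"].max())
            o = oracles.rmst_oracle(km.times.tolist(), km.survival.tolist(), L)
            assert restricted_life_years(km, L) == pytest.approx(o, abs=1e-12)


# ---------------------------------------------------------------------------
# QALY means at death / horizon


class TestQalyMeans:
    def test_single_death_scales_utility_by_time(self):
        df = frame([4.0], [1], utilities=[0.5])
        assert mean_qaly_at_death(df, 4.0) == pytest.approx(2.0)

    def test_full_health_anchor(self):
        df = frame([5.0, 5.0], [0, 0])
        assert mean_qaly_at_horizon(df, 5.0) == pytest.approx(5.0)
        assert mean_utility_at_horizon(df, 5.0) == pytest.approx(1.0)

    def test_weighted_mean_at_tied_deaths(self):
        df = frame([2.0, 2.0], [1, 1], weights=[1.0, 3.0],
                   utilities=[0.6, 0.8])
        assert mean_qaly_at_death(df, 2.0) == pytest.approx(1.5)

    def test_empty_subsets_error_names_timepoint(self):
        df = frame([1.0], [1], utilities=[0.5])
        with pytest.raises(EstimationError, match="3.0"):
            mean_qaly_at_death(df, 3.0)
        with pytest.raises(EstimationError, match="L=2.0"):
            mean_qaly_at_horizon(df, 2.0)


# ---------------------------------------------------------------------------
# Follow-up QALY sum


class TestFollowupQaly:
    def test_reduces_to_mean_death_time_when_all_die(self):
        times = [1.0, 2.0, 4.0, 5.0]
        df = frame(times, [1, 1, 1, 1])
        km = fit_km(df)
        assert followup_qaly(df, km, 6.0) == pytest.approx(np.mean(times))

    def test_no_deaths_full_health_gives_horizon(self):
        df = frame([2.0, 3.0], [0, 0])
        km = fit_km(df)
        assert followup_qaly(df, km, 3.0) == pytest.approx(3.0)

    def test_mixed_fixture_matches_bruteforce(self, mixed_records):
        km = fit_km(mixed_records)
        L = 4.0
        oracle = oracles.followup_qaly_oracle(
            mixed_records["time"].tolist(),
            mixed_records["event"].tolist(),
            mixed_records["weight"].tolist(),
            mixed_records["utility"].tolist(),
            L,
        )
        assert followup_qaly(mixed_records, km, L) == pytest.approx(
            oracle, abs=1e-12)

    def test_exhaustive_small_datasets_match_bruteforce(self):
        times = [1.0, 2.0, 2.0, 3.0, 4.5]
        weights = [1.0, 2.0, 0.5, 1.5, 1.0]
        utils = [0.9, 0.4, 0.7, 1.0, 0.55]
        L = 5.0
        for events in itertools.product([0, 1], repeat=5):
            df = frame(times, list(events), weights, utils)
            km = fit_km(df)
            oracle = oracles.followup_qaly_oracle(
                times, list(events), weights, utils, L)
            assert followup_qaly(df, km, L) == pytest.approx(oracle, abs=1e-12)

    def test_constant_utility_factors_out(self, rng):
        """With utility == u everywhere the sum is u times the utility-1 sum."""
        n = 30
        df = frame(rng.uniform(0.1, 5, n), rng.integers(0, 2, n),
                   rng.uniform(0.5, 3, n))
        km = fit_km(df)
        L = 6.0
        base = followup_qaly(df, km, L)
        for u in (0.3, 0.85):
            df_u = df.assign(utility=u)
            assert followup_qaly(df_u, km, L) == pytest.approx(u * base)

    def test_horizon_below_last_event_rejected(self):
        df = frame([1.0, 3.0], [1, 1])
        km = fit_km(df)
        with pytest.warns(UserWarning, match="clamped"), \
                pytest.raises(InputError):
            followup_qaly(df, km, 2.0)


# ---------------------------------------------------------------------------
# Weibull tail


class TestWeibullMean:
    def test_exponential_mean_is_scale(self):
        assert weibull_mean(WeibullFit(5.0, 1.0, 0.0, True)) == pytest.approx(5.0)

    def test_rayleigh_mean_root_pi_over_two(self):
        assert weibull_mean(WeibullFit(1.0, 2.0, 0.0, True)) == pytest.approx(
            np.sqrt(np.pi) / 2)

    def test_matches_quadrature_over_grid(self):
        for lam in (1.0, 5.0, 13.0, 20.0):
            for beta in (0.7, 1.0, 1.4, 3.0):
                o = oracles.weibull_mean_quadrature(lam, beta)
                assert weibull_mean(
                    WeibullFit(lam, beta, 0.0, True)) == pytest.approx(o, abs=1e-6)


class TestFitWeibull:
    def test_recovery_under_administrative_censoring(self, rng):
        lam, beta, n = 13.0, 1.3, 5000
        T = lam * rng.weibull(beta, n)
        C = rng.uniform(4.0, 40.0, n)  # ~20% censored
        df = frame(np.minimum(T, C), (T <= C).astype(int))
        assert 0.15 < 1 - df["event"].mean() < 0.30
        fit = fit_weibull(df)
        assert fit.converged
        assert fit.scale == pytest.approx(lam, rel=0.05)
        assert fit.shape == pytest.approx(beta, rel=0.05)

    def test_exponential_data_recovers_shape_one(self, rng):
        T = rng.exponential(8.0, 8000)
        df = frame(T, np.ones(len(T), dtype=int))
        fit = fit_weibull(df)
        assert fit.shape == pytest.approx(1.0, abs=0.05)

    def test_matches_dense_grid_search_oracle(self, rng):
        T = 6.0 * rng.weibull(1.5, 80)
        df = frame(T, np.ones(len(T), dtype=int))
        fit = fit_weibull(df)
        lam_grid = np.linspace(4.0, 8.0, 81).tolist()
        beta_grid = np.linspace(1.0, 2.2, 61).tolist()
        lam_g, beta_g, _ = oracles.weibull_grid_mle(
            T.tolist(), [1] * len(T), [1.0] * len(T), lam_grid, beta_grid)
        assert abs(fit.scale - lam_g) <= (lam_grid[1] - lam_grid[0])
        assert abs(fit.shape - beta_g) <= (beta_grid[1] - beta_grid[0])

    def test_matches_lifelines_weibull(self, rng):
        lifelines = pytest.importorskip("lifelines")
        T = 10.0 * rng.weibull(1.2, 2000)
        C = rng.uniform(2.0, 25.0, 2000)
        t, e = np.minimum(T, C), (T <= C).astype(int)
        fit = fit_weibull(frame(t, e))
        wf = lifelines.WeibullFitter().fit(t, e)
        assert fit.scale == pytest.approx(wf.lambda_, rel=1e-4)
        assert fit.shape == pytest.approx(wf.rho_, rel=1e-4)

    def test_too_few_events_rejected(self):
        with pytest.raises(EstimationError, match="2 distinct"):
            fit_weibull(frame([1.0, 2.0, 3.0], [1, 0, 0]))


class TestTailQaly:
    def test_zero_utility_gives_zero(self):
        km = fit_km(frame([1.0, 2.0], [1, 0]))
        fit = WeibullFit(10.0, 1.2, 0.0, True)
        assert tail_qaly(0.0, fit, km, 2.0) == 0.0

    def test_zero_extra_years_gives_zero(self):
        km = fit_km(frame([1.0, 2.0], [0, 0]))  # flat curve: RMST(L) = L
        L = 4.0
        fit = WeibullFit(L, 1.0, 0.0, True)  # exponential mean = L exactly
        assert tail_qaly(0.8, fit, km, L) == pytest.approx(0.0, abs=1e-12)

    def test_compositional_oracle(self, mixed_records):
        km = fit_km(mixed_records)
        L = 4.0
        fit = fit_weibull(mixed_records)
        q_L = mean_utility_at_horizon(mixed_records, L)
        expected = q_L * (
            oracles.weibull_mean_quadrature(fit.scale, fit.shape)
            - oracles.rmst_oracle(km.times.tolist(), km.survival.tolist(), L)
        )
        assert tail_qaly(q_L, fit, km, L) == pytest.approx(expected, abs=1e-5)

    def test_negative_tail_warned_not_floored(self):
        km = fit_km(frame([1.0, 2.0], [0, 0]))  # RMST(4) = 4
        fit = WeibullFit(1.0, 1.0, 0.0, True)   # mean 1 < 4
        with pytest.warns(UserWarning, match="negative tail"):
            v = tail_qaly(0.9, fit, km, 4.0)
        assert v == pytest.approx(0.9 * (1.0 - 4.0))


# ---------------------------------------------------------------------------
# Composite estimator


class TestTotalQaly:
    @staticmethod
    def _group(n=4000, seed=20110, category="mild"):
        spec = default_spec()
        prev = {k: (1.0 if k == category else 0.0)
                for k in spec.category_prevalence}
        spec = replace(spec, n=n, seed=seed, category_prevalence=prev)
        return spec, records_from_frame(generate_cohort(spec))

    def test_decomposition_adds_up(self, mixed_records):
        est = total_qaly(mixed_records, 4.0)
        assert est.total == pytest.approx(est.followup_part + est.tail_part)

    def test_full_health_reduces_to_life_expectancy(self):
        _, rec = self._group()
        rec_full = rec.assign(utility=1.0)
        est = total_qaly(rec_full)
        # with utility 1 the estimate is the hybrid life-expectancy:
        # KM RMST within follow-up plus the Weibull-extrapolated years
        hybrid_le = weibull_mean(est.weibull)
        assert est.total == pytest.approx(hybrid_le, rel=1e-9)

    def test_weight_rescaling_invariance(self, mixed_records):
        base = total_qaly(mixed_records, 4.0)
        for factor in (2.0, 0.125, 7.3):
            scaled = mixed_records.assign(
                weight=mixed_records["weight"] * factor)
            est = total_qaly(scaled, 4.0)
            # identical up to the Weibull optimiser's tolerance
            assert est.total == pytest.approx(base.total, rel=1e-6)
            assert est.followup_part == pytest.approx(
                base.followup_part, rel=1e-12)

    def test_recovers_generator_truth_single_category(self):
        spec, rec = self._group(n=20_000, category="mild")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = total_qaly(rec)
        truth = true_group_qaly(spec, "mild")
        assert est.total == pytest.approx(truth, rel=0.05)

    def test_replicate_mean_within_mc_error_of_truth(self):
        """Consistency: over replicate cohorts the mean per-category
        estimate sits within 2 Monte-Carlo SEs of the analytic truth."""
        n_rep = 40
        for category in ("mild", "modsev_severe"):
            totals = []
            for seed in range(500, 500 + n_rep):
                spec, rec = self._group(n=2000, seed=seed, category=category)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    totals.append(total_qaly(rec).total)
            truth = true_group_qaly(spec, category)
            mean = np.mean(totals)
            se = np.std(totals, ddof=1) / np.sqrt(n_rep)
            assert abs(mean - truth) < 2 * se + 1e-12, (
                f"{category}: mean {mean:.3f} vs truth {truth:.3f} (se {se:.3f})")

    def test_bootstrap_se_deterministic_given_seed(self, mixed_records):
        df = pd.concat([mixed_records] * 6, ignore_index=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = total_qaly(df, 4.0, bootstrap=40, seed=9)
            b = total_qaly(df, 4.0, bootstrap=40, seed=9)
        assert a.se == b.se
        assert a.se is not None and a.se > 0

    def test_times_beyond_horizon_clamped_with_warning(self):
        df = frame([1.0, 2.0, 5.0], [1, 1, 0])
        with pytest.warns(UserWarning, match="clamped"):
            est = total_qaly(df, 4.0)
        assert est.total > 0


class TestHybridQalyEstimatorAPI:
    def test_fit_exposes_components(self, mixed_records):
        est = HybridQalyEstimator(L=4.0).fit(mixed_records)
        assert est.total_qaly_ == pytest.approx(
            est.followup_qaly_ + est.tail_qaly_)
        assert est.km_ is not None and est.weibull_ is not None
        assert est.n_ == len(mixed_records)

    def test_get_params_roundtrip(self):
        est = HybridQalyEstimator(L=5.0, bootstrap=10, seed=3)
        params = est.get_params()
        clone = HybridQalyEstimator(**params)
        assert clone.get_params() == params


@given(st.floats(0.5, 30), st.floats(0.5, 4))
@settings(deadline=None, max_examples=40)
def test_weibull_mean_positive_and_scales_linearly(lam, beta):
    m = weibull_mean(WeibullFit(lam, beta, 0.0, True))
    assert m > 0
    assert weibull_mean(WeibullFit(2 * lam, beta, 0.0, True)) == pytest.approx(
        2 * m, rel=1e-12)
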