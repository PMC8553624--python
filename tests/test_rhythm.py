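import numpy as np
import pytest
from scipy import stats

from perilymph import (
    RhythmSeries,
    ValidationError,
    cosinor_fit,
    detrend_lumi,
    fold_change_matrix,
    integrate_profiles,
    screen_normalize,
    timepoint_anova,
)
from perilymph.rhythm import LumiSeries, significance_tier
from perilymph.simulate import gen_lumi, gen_rhythm_series


def cosine(t, mesor, amp, phi, period=24.0):
    return mesor + amp * np.cos(2 * np.pi * (np.asarray(t, float) - phi) / period)


class TestCosinorFit:
    def test_noiseless_exact_recovery(self):
        series = gen_rhythm_series(5.0, 2.0, 7.0, sigma=0.0, n_per_time=3)
        fit = cosinor_fit(series)
        assert fit.mesor == pytest.approx(5.0, abs=1e-10)
        assert fit.amplitude == pytest.approx(2.0, abs=1e-10)
        assert fit.acrophase_h == pytest.approx(7.0, abs=1e-10)
        assert fit.p_zero_amplitude == 0.0

    def test_constant_series_not_rhythmic(self):
        series = RhythmSeries(times=[1, 7, 13, 19, 1, 7, 13, 19], values=[3.0] * 8)
        fit = cosinor_fit(series)
        assert fit.amplitude == pytest.approx(0.0, abs=1e-9)
        assert fit.p_zero_amplitude == 1.0

    def test_phase_equivariance(self, rng):
        t = np.tile([1.0, 7.0, 13.0, 19.0], 4)
        y = cosine(t, 10, 3, 5) + rng.normal(0, 0.5, t.size)
        base = cosinor_fit(RhythmSeries(times=t, values=y))
        for delta in (3.0, 11.5, 20.0):
            shifted = cosinor_fit(RhythmSeries(times=t + delta, values=y))
            assert shifted.mesor == pytest.approx(base.mesor)
            assert shifted.amplitude == pytest.approx(base.amplitude)
            assert shifted.acrophase_h % 24 == pytest.approx(
                (base.acrophase_h + delta) % 24, abs=1e-8
            )

    def test_scale_equivariance(self, rng):
        t = np.tile([1.0, 7.0, 13.0, 19.0], 4)
        y = cosine(t, 10, 3, 5) + rng.normal(0, 0.5, t.size)
        base = cosinor_fit(RhythmSeries(times=t, values=y))
        scaled = cosinor_fit(RhythmSeries(times=t, values=3.0 * y))
        assert scaled.mesor == pytest.approx(3 * base.mesor)
        assert scaled.amplitude == pytest.approx(3 * base.amplitude)
        assert scaled.acrophase_h == pytest.approx(base.acrophase_h)

    def test_monte_carlo_recovery(self):
        # light version of the calibration sweep (full one in acceptance)
        phi_errs, amp_errs = [], []
        for seed in range(50):
            series = gen_rhythm_series(10.0, 2.0, 7.0, sigma=1.0, n_per_time=5, seed=seed)
            fit = cosinor_fit(series)
            d = abs(fit.acrophase_h - 7.0)
            phi_errs.append(min(d, 24 - d))
            amp_errs.append(abs(fit.amplitude - 2.0) / 2.0)
        assert np.median(phi_errs) <= 1.5
        assert np.median(amp_errs) <= 0.2

    def test_too_few_distinct_times_rejected(self):
        with pytest.raises(ValidationError, match="distinct"):
            cosinor_fit(RhythmSeries(times=[1, 1, 13, 13], values=[1, 2, 3, 4]))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValidationError, match="4 observations"):
            cosinor_fit(RhythmSeries(times=[1, 7, 13], values=[1, 2, 3]))


class TestScreenNormalize:
    def test_worked_example(self):
        row = screen_normalize([10, 8, 6, 4], isotype_mfi=2.0)
        np.testing.assert_allclose(row.subtracted_mfi, [8, 6, 4, 2])
        assert row.second_highest == 6.0
        np.testing.assert_allclose(row.normalized, [4 / 3, 1.0, 2 / 3, 1 / 3])

    def test_low_expression_flag(self):
        # entry peaking at 1.2% of the screen-wide max: flagged no/low
        row = screen_normalize([1.2, 1.0, 0.8, 0.5], isotype_mfi=0.0, screen_max=100.0)
        assert row.expressed is False
        high = screen_normalize([10, 8, 6, 4], isotype_mfi=0.0, screen_max=100.0)
        assert high.expressed is True

    def test_ties_normalize_to_one(self):
        row = screen_normalize([5, 5, 5, 5], isotype_mfi=0.0)
        np.testing.assert_allclose(row.normalized, 1.0)

    def test_second_highest_zero_flagged(self):
        row = screen_normalize([3, 0, 0, 0], isotype_mfi=0.0)
        assert not row.normalizable and row.normalized is None

    def test_idempotent_on_normalized_rows(self):
        row = screen_normalize([10, 8, 6, 4], isotype_mfi=0.0)
        again = screen_normalize(row.normalized, isotype_mfi=0.0)
        np.testing.assert_allclose(again.normalized, row.normalized)

    def test_needs_two_times(self):
        with pytest.raises(ValidationError):
            screen_normalize([5.0], isotype_mfi=0.0)


class TestFoldChangeMatrix:
    def test_identical_values_all_ones(self):
        np.testing.assert_allclose(fold_change_matrix([3, 3, 3]), 1.0)

    def test_two_values(self):
        np.testing.assert_allclose(fold_change_matrix([2, 1]), [[1, 2], [0.5, 1]])

    def test_oracle_and_reciprocity(self, rng):
        v = rng.random(6) + 0.1
        m = fold_change_matrix(v)
        for i in range(6):
            for j in range(6):
                assert m[i, j] == pytest.approx(v[i] / v[j])
        np.testing.assert_allclose(m * m.T, 1.0)

    def test_zero_denominator_flagged(self):
        with pytest.warns(UserWarning, match="zero"):
            m = fold_change_matrix([1.0, 0.0])
        assert np.isnan(m[0, 1])


class TestIntegrateProfiles:
    def test_identical_profiles(self):
        p = [1.0, 3.0, 2.0, 0.0]
        out = integrate_profiles([p, p])
        np.testing.assert_allclose(out["mean"], [1 / 3, 1.0, 2 / 3, 0.0])
        np.testing.assert_allclose(out["sem"], 0.0)

    def test_antiphase_flat_at_half(self):
        a = [0.0, 1.0, 0.0, 1.0]
        b = [1.0, 0.0, 1.0, 0.0]
        out = integrate_profiles([a, b])
        np.testing.assert_allclose(out["mean"], 0.5)

    def test_output_in_unit_interval(self, rng):
        arr = rng.random((20, 4)) * 100
        out = integrate_profiles(arr)
        assert np.all(out["mean"] >= 0.0) and np.all(out["mean"] <= 1.0)

    def test_flat_profile_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="flat"):
            out = integrate_profiles([[1, 2, 3], [5, 5, 5]])
        assert out["n_profiles"] == 1 and out["n_excluded"] == 1

    def test_common_acrophase_recovered(self, rng):
        times = np.array([1.0, 7.0, 13.0, 19.0])
        profiles = []
        for _ in range(50):
            amp = rng.uniform(0.5, 5.0)
            mesor = rng.uniform(5, 50)
            profiles.append(cosine(times, mesor, amp, 7.0) + rng.normal(0, 0.1 * amp, 4))
        out = integrate_profiles(profiles)
        fit = cosinor_fit(RhythmSeries(times=times, values=out["mean"]))
        d = abs(fit.acrophase_h - 7.0)
        assert min(d, 24 - d) <= 1.0


class TestDetrendLumi:
    def test_linear_ramp_detrends_to_zero(self):
        slope_per_h = 2.0
        series = gen_lumi(
            baseline=100.0, amplitude=0.0, trend_slope_per_h=slope_per_h,
            duration_h=72.0, sigma=0.0,
        )
        out = detrend_lumi(series)
        assert np.max(np.abs(out.detrended)) < 1e-6 * slope_per_h * 24.0

    def test_cosine_preserved(self):
        series = gen_lumi(baseline=50.0, amplitude=10.0, duration_h=72.0, sigma=0.0)
        out = detrend_lumi(series)
        ref = 10.0 * np.cos(2 * np.pi * out.detrended_t_min / 60.0 / 24.0)
        r = np.corrcoef(out.detrended, ref)[0, 1]
        assert r > 0.99

    def test_output_length_contract(self):
        series = gen_lumi(duration_h=72.0)
        out = detrend_lumi(series)
        window = int(round(24 * 60 / series.dt_min))
        if window % 2 == 0:
            window += 1
        assert out.detrended.size == series.counts.size - (window - 1)
        assert out.detrended_t_min.size == out.detrended.size

    def test_divide_mode(self):
        series = gen_lumi(baseline=100.0, amplitude=0.0, duration_h=72.0)
        out = detrend_lumi(series, mode="divide")
        np.testing.assert_allclose(out.detrended, 1.0)

    def test_short_series_rejected(self):
        t = np.arange(0, 20 * 60, 1.0)
        with pytest.raises(ValidationError, match="window"):
            detrend_lumi(LumiSeries(t_min=t, counts=np.ones_like(t)))

    def test_irregular_sampling_rejected(self):
        t = np.sort(np.random.default_rng(0).uniform(0, 48 * 60, 3000))
        with pytest.raises(ValidationError, match="regular"):
            detrend_lumi(LumiSeries(t_min=t, counts=np.ones_like(t)))


class TestTimepointAnova:
    def test_identical_group_means_not_significant(self):
        series = RhythmSeries(
            times=[1, 1, 1, 7, 7, 7, 13, 13, 13],
            values=[1.0, 2.0, 3.0, 2.0, 3.0, 1.0, 3.0, 1.0, 2.0],
        )
        res = timepoint_anova(series)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.9

    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 6)
        series = RhythmSeries(times=[1] * 6 + [13] * 6, values=np.r_[a, b])
        res = timepoint_anova(series)
        t_stat, _ = stats.ttest_ind(a, b)
        assert res.f_statistic == pytest.approx(t_stat**2)

    def test_three_group_sum_of_squares_oracle(self):
        groups = {1: [6.0, 8.0, 4.0], 7: [5.0, 9.0, 7.0], 13: [11.0, 12.0, 10.0]}
        times = sum(([t] * len(v) for t, v in groups.items()), [])
        values = sum((v for v in groups.values()), [])
        res = timepoint_anova(RhythmSeries(times=times, values=values))
        # brute-force sums of squares
        grand = np.mean(values)
        ss_between = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
        ss_within = sum(sum((x - np.mean(v)) ** 2 for x in v) for v in groups.values())
        f_expected = (ss_between / 2) / (ss_within / 6)
        assert res.f_statistic == pytest.approx(f_expected)
        assert len(res.tukey) == 3

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValidationError):
            timepoint_anova(RhythmSeries(times=[1, 7], values=[1.0, 2.0]))


def test_significance_tiers():
    assert significance_tier(0.03) == "*"
    assert significance_tier(0.004) == "**"
    assert significance_tier(5e-4) == "***"
    assert significance_tier(5e-5) == "****"
    assert significance_tier(0.2) == "ns"
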