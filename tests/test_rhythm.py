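import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from circaplast.records import ActivityRecord, make_light_schedule
from circaplast.rhythm import (
    AnalysisConfig,
    OnsetSeries,
    Periodogram,
    activity_rest_split,
    analyze_record,
    bin_activity,
    build_actogram,
    chi_square_periodogram,
    classify_rhythmicity,
    derive_phase_params,
    detect_breaks,
    detect_onsets,
    estimate_tau,
    fourier_periodogram,
    overall_activity,
    percent_qp,
    split_day_night,
)
from circaplast.synthetic import SimActivityParams, simulate_activity

from conftest import make_record, naive_qp


class TestBinActivity:
    def test_six_one_minute_bins_merge(self):
        rec = make_record([1, 1, 1, 1, 1, 1], bin_minutes=1.0)
        out = bin_activity(rec, 6.0)
        assert out.counts.tolist() == [6.0]
        assert out.bin_minutes == 6.0

    def test_identity_rebin(self):
        rec = make_record([3, 1, 4, 1, 5], bin_minutes=6.0)
        out = bin_activity(rec, 6.0)
        np.testing.assert_array_equal(out.counts, rec.counts)

    def test_non_divisible_rejected(self):
        rec = make_record([1, 2, 3], bin_minutes=6.0)
        with pytest.raises(ValueError, match="multiple"):
            bin_activity(rec, 9.0)

    @given(st.lists(st.floats(0, 100), min_size=12, max_size=60))
    @settings(max_examples=30, deadline=None)
    def test_totals_conserved(self, counts):
        rec = make_record(counts, bin_minutes=1.0)
        out = bin_activity(rec, 6.0)
        kept = (len(counts) // 6) * 6
        assert out.counts.sum() == pytest.approx(sum(counts[:kept]))


class TestActogram:
    def test_double_plot_shape(self):
        rec = make_record(np.arange(10 * 240), bin_minutes=6.0)
        act = build_actogram(rec, 24.0, double_plot=True)
        assert act.matrix.shape == (9, 480)

    def test_single_plot_shape(self):
        rec = make_record(np.arange(10 * 240), bin_minutes=6.0)
        act = build_actogram(rec, 24.0, double_plot=False)
        assert act.matrix.shape == (10, 240)

    def test_double_plot_row_overlap(self):
        rec = make_record(np.arange(5 * 240), bin_minutes=6.0)
        act = build_actogram(rec, 24.0, double_plot=True)
        for i in range(act.matrix.shape[0] - 1):
            np.testing.assert_array_equal(
                act.matrix[i, 240:], act.matrix[i + 1, :240]
            )

    def test_too_short_rejected(self):
        rec = make_record(np.arange(200), bin_minutes=6.0)
        with pytest.raises(ValueError, match="two row periods"):
            build_actogram(rec, 24.0)


class TestChiSquarePeriodogram:
    def test_toy_series_qp_values(self, toy_record):
        pg = chi_square_periodogram(toy_record, period_min_h=3, period_max_h=6)
        stat = dict(zip(pg.periods_h, pg.statistic))
        assert stat[4.0] == pytest.approx(12.0, abs=1e-9)
        assert stat[3.0] == pytest.approx(0.0, abs=1e-9)
        assert stat[4.0] == pytest.approx(naive_qp(toy_record.counts, 4), abs=1e-9)
        assert stat[3.0] == pytest.approx(naive_qp(toy_record.counts, 3), abs=1e-9)

    def test_constant_series_all_zero(self):
        rec = make_record(np.full(2400, 5.0), bin_minutes=6.0)
        pg = chi_square_periodogram(rec)
        assert np.all(pg.statistic == 0.0)

    def test_oracle_equivalence_random_series(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            counts = rng.poisson(rng.uniform(1, 50), 360)
            rec = make_record(counts, bin_minutes=60.0)
            pg = chi_square_periodogram(rec, period_min_h=20, period_max_h=28)
            for p_h, qp, n in zip(pg.periods_h, pg.statistic, pg.n_bins_used):
                expected = naive_qp(counts, int(p_h))
                assert qp == pytest.approx(expected, abs=1e-9)
                assert 0.0 <= qp <= n

    def test_qp_bounded_on_fuzzed_series(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(600, 2400)
            kind = rng.integers(3)
            if kind == 0:
                counts = rng.poisson(rng.uniform(0.1, 80), n)
            elif kind == 1:
                counts = rng.exponential(rng.uniform(1, 30), n)
            else:
                counts = np.zeros(n)
                counts[rng.integers(0, n, 5)] = rng.uniform(1, 100, 5)
            rec = make_record(counts, bin_minutes=6.0)
            pg = chi_square_periodogram(rec, period_min_h=20, period_max_h=28)
            assert np.all(pg.statistic >= 0.0)
            assert np.all(pg.statistic <= pg.n_bins_used + 1e-9)

    def test_short_record_rejected(self):
        rec = make_record(np.ones(100), bin_minutes=6.0)
        with pytest.raises(ValueError, match="two cycles"):
            chi_square_periodogram(rec)


class TestFourierPeriodogram:
    def test_sinusoid_peak_at_24h(self):
        t = np.arange(2400) * 0.1
        rec = make_record(50 + 40 * np.sin(2 * np.pi * t / 24.0), bin_minutes=6.0)
        pg = fourier_periodogram(rec)
        assert pg.peak_period == pytest.approx(24.0, abs=2.0)
        assert pg.statistic.sum() == pytest.approx(1.0)

    def test_constant_series_zero_power(self):
        rec = make_record(np.full(2400, 7.0), bin_minutes=6.0)
        pg = fourier_periodogram(rec)
        assert np.all(pg.statistic == 0.0)

    def test_mixture_peaks_at_dominant_period(self):
        t = np.arange(2400) * 0.1
        x = 50 + 40 * np.sin(2 * np.pi * t / 24.0) + 8 * np.sin(2 * np.pi * t / 12.0)
        pg = fourier_periodogram(make_record(x, bin_minutes=6.0), 20.0, 28.0)
        assert abs(pg.peak_period - 24.0) < 2.0


class TestTauAndRobustness:
    def test_toy_grid_peak(self, toy_record):
        pg = chi_square_periodogram(toy_record, period_min_h=3, period_max_h=6)
        assert estimate_tau(pg) == 4.0

    def test_entrained_record_tau_24(self, ld_schedule):
        p = SimActivityParams(masking=True, alpha_true=11.8, seed=0)
        rec, _ = simulate_activity(p, ld_schedule, n_days=10)
        pg = chi_square_periodogram(bin_activity(rec, 6.0))
        assert estimate_tau(pg) == pytest.approx(24.0, abs=0.1)

    def test_tie_broken_toward_24(self):
        pg = Periodogram(
            method="chi_square",
            periods_h=np.array([23.9, 24.3]),
            statistic=np.array([5.0, 5.0]),
            significance_line=np.array([3.0, 3.0]),
            n_bins_used=np.array([100, 100]),
            periods_bins=np.array([239, 243]),
            peak_period=0.0,
            peak_statistic=5.0,
        )
        from circaplast.rhythm import _peak_index

        assert pg.periods_h[_peak_index(pg.periods_h, pg.statistic)] == 23.9

    def test_percent_qp_toy_is_100(self, toy_record):
        pg = chi_square_periodogram(toy_record, period_min_h=3, period_max_h=6)
        # Qp = N = 12 at P=4; line = chi2(0.95, 3) = 7.815
        assert pg.significance_line[1] == pytest.approx(7.8147, abs=1e-3)
        assert percent_qp(pg) == pytest.approx(100.0)

    def test_percent_qp_constant_is_0(self):
        rec = make_record(np.full(2400, 5.0), bin_minutes=6.0)
        assert percent_qp(chi_square_periodogram(rec)) == 0.0

    def test_percent_qp_in_range_and_fourier_rejected(self):
        rng = np.random.default_rng(3)
        rec = make_record(rng.poisson(20, 2400), bin_minutes=6.0)
        assert 0.0 <= percent_qp(chi_square_periodogram(rec)) <= 100.0
        with pytest.raises(ValueError, match="chi-square"):
            percent_qp(fourier_periodogram(rec))

    def test_percent_qp_monotone_in_amplitude(self):
        means = []
        for amp in [0.0, 2.0, 5.0, 10.0, 20.0]:
            vals = []
            for seed in range(10):
                rng = np.random.default_rng(seed)
                t = np.arange(2400) * 0.1
                lam = 10 + amp * (1 + np.sin(2 * np.pi * t / 24.0))
                rec = make_record(rng.poisson(lam), bin_minutes=6.0)
                vals.append(percent_qp(chi_square_periodogram(rec)))
            means.append(np.mean(vals))
        assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))

    def test_classify_toy_rhythmic(self, toy_record):
        pg = chi_square_periodogram(toy_record, period_min_h=3, period_max_h=6)
        assert classify_rhythmicity(pg)

    def test_classify_constant_arrhythmic(self):
        rec = make_record(np.full(2400, 5.0), bin_minutes=6.0)
        assert not classify_rhythmicity(chi_square_periodogram(rec))


class TestOnsets:
    def test_square_wave_exact_onsets(self, ld_schedule):
        p = SimActivityParams(
            tau_true=24.0, alpha_true=12.0, onset_phase0=12.0,
            mean_rate_rest=0.0, noise="none", seed=0,
        )
        rec, _ = simulate_activity(p, ld_schedule, n_days=10, bin_minutes=6.0)
        ons = detect_onsets(rec, 24.0)
        np.testing.assert_allclose(
            ons.onsets_h[:4], [12.0, 36.0, 60.0, 84.0], atol=1e-9
        )
        np.testing.assert_allclose(ons.offsets_h[0], 24.0, atol=1e-9)

    def test_planted_drift_recovered(self, dd_schedule):
        p = SimActivityParams(drift_per_cycle=-19.0, seed=4)
        rec, _ = simulate_activity(p, dd_schedule, n_days=10)
        rec6 = bin_activity(rec, 6.0)
        tau = estimate_tau(chi_square_periodogram(rec6))
        ons = detect_onsets(rec6, tau)
        diffs = np.diff(ons.onsets_h) * 60.0  # minutes
        assert np.all(np.abs(diffs - (24 * 60 - 19)) <= 6.0 + 1e-9)

    def test_constant_series_rejected(self):
        rec = make_record(np.full(2400, 5.0), bin_minutes=6.0)
        with pytest.raises(ValueError):
            detect_onsets(rec, 24.0)


class TestPhaseParams:
    def test_square_wave_params(self, ld_schedule):
        p = SimActivityParams(
            tau_true=24.0, alpha_true=12.0, onset_phase0=12.0,
            mean_rate_rest=0.0, noise="none", seed=0,
        )
        rec, _ = simulate_activity(p, ld_schedule, n_days=10, bin_minutes=6.0)
        ph = derive_phase_params(detect_onsets(rec, 24.0), 24.0)
        assert ph.alpha_h == pytest.approx(12.0)
        assert ph.delta_h == pytest.approx(0.0, abs=1e-9)
        assert ph.rho_h == pytest.approx(12.0)

    def test_advancing_onsets_arithmetic(self):
        onsets = np.array([12.0 - 0.3 * k for k in range(9)])
        offsets = onsets + 10.0
        series = OnsetSeries(onsets + np.arange(9) * 24, offsets + np.arange(9) * 24,
                             23.7, 9)
        ph = derive_phase_params(series, 23.7)
        assert ph.delta_h == pytest.approx(-2.4)
        assert ph.mean_shift_min == pytest.approx(-18.0)

    def test_rho_is_tau_minus_alpha(self):
        onsets = np.arange(9) * 24.0 + 5.0
        series = OnsetSeries(onsets, onsets + 9.1, 24.56, 9)
        ph = derive_phase_params(series, 24.56)
        assert ph.rho_h == pytest.approx(24.56 - 9.1)
        assert ph.rho_h + ph.alpha_h == 24.56  # exact identity

    def test_too_few_cycles_rejected(self):
        onsets = np.arange(5) * 24.0
        series = OnsetSeries(onsets, onsets + 8, 24.0, 5)
        with pytest.raises(ValueError, match="onsets"):
            derive_phase_params(series, 24.0)


class TestActivityTotals:
    def test_overall_activity_example(self):
        rec = make_record(np.full(10 * 240, 5.0), bin_minutes=6.0)
        assert overall_activity(rec, 24.0) == pytest.approx(1200.0)

    def test_overall_zero_record(self):
        rec = make_record(np.zeros(10 * 240), bin_minutes=6.0)
        assert overall_activity(rec, 24.0) == 0.0

    def test_overall_scales_with_tau(self):
        rec = make_record(np.full(10 * 240, 2.0), bin_minutes=6.0)
        assert overall_activity(rec, 12.0) == pytest.approx(
            overall_activity(rec, 24.0) / 2
        )

    def test_day_night_all_dark_activity(self, ld_schedule):
        counts = np.zeros(10 * 240)
        for d in range(10):
            counts[d * 240 + 120 : (d + 1) * 240] = 4.0
        rec = make_record(counts, bin_minutes=6.0, schedule=ld_schedule)
        day, night, pct = split_day_night(rec)
        assert pct == 0.0
        assert night == pytest.approx(480.0)

    def test_day_night_uniform_is_50(self, ld_schedule):
        rec = make_record(np.full(10 * 240, 3.0), schedule=ld_schedule)
        _, _, pct = split_day_night(rec)
        assert pct == pytest.approx(50.0)

    def test_day_plus_night_equals_overall(self, dd_schedule):
        rng = np.random.default_rng(9)
        for _ in range(30):
            counts = rng.poisson(rng.uniform(0.5, 40), 10 * 240)
            rec = make_record(counts, bin_minutes=6.0, schedule=dd_schedule)
            day, night, _ = split_day_night(rec)
            assert day + night == pytest.approx(overall_activity(rec, 24.0))


class TestActivityRestSplit:
    def test_square_wave_captures_all(self, ld_schedule):
        p = SimActivityParams(
            tau_true=24.0, alpha_true=12.0, onset_phase0=12.0,
            mean_rate_rest=0.0, noise="none", seed=0,
        )
        rec, _ = simulate_activity(p, ld_schedule, n_days=10, bin_minutes=6.0)
        sp = activity_rest_split(rec, 24.0)
        assert sp.rest_phase_total == pytest.approx(0.0)
        assert sp.window_start_h == pytest.approx(12.0)

    def test_uniform_ties_at_phase_zero(self):
        rec = make_record(np.full(10 * 240, 2.0), bin_minutes=6.0)
        sp = activity_rest_split(rec, 24.0)
        assert sp.window_start_h == 0.0
        assert sp.activity_phase_total == pytest.approx(sp.rest_phase_total)

    def test_matches_bruteforce_window_scan(self):
        rng = np.random.default_rng(17)
        lam = 2 + 30 * np.exp(-((np.arange(240) - 170) % 240) ** 2 / (2 * 30.0**2))
        counts = rng.poisson(np.tile(lam, 10)).astype(float)
        rec = make_record(counts, bin_minutes=6.0)
        sp = activity_rest_split(rec, 24.0)
        wave = counts.reshape(10, 240).mean(axis=0)
        best_start, best_sum = 0, -1.0
        for s in range(240):  # exhaustive circular scan
            w = sum(wave[(s + i) % 240] for i in range(120))
            if w > best_sum:
                best_sum, best_start = w, s
        assert sp.window_start_h == pytest.approx(best_start * 0.1)
        assert sp.activity_phase_total == pytest.approx(best_sum)


class TestBreaks:
    def _record_with_gaps(self, gaps):
        """Square wave active 12-24 h daily with given (offset_h, dur_h) gaps."""
        counts = np.zeros(10 * 240)
        for d in range(10):
            counts[d * 240 + 120 : (d + 1) * 240] = 10.0
            for off, dur in gaps:
                a = d * 240 + 120 + int(off * 10)
                counts[a : a + int(dur * 10)] = 0.0
        return make_record(counts, bin_minutes=6.0)

    def _onsets(self, rec):
        return detect_onsets(rec, 24.0)

    def test_planted_gap_reported(self):
        rec = self._record_with_gaps([(5.0, 1.5)])
        br = detect_breaks(rec, self._onsets(rec))
        assert br.mean_duration_h == pytest.approx(1.5)

    def test_no_gap_empty(self):
        rec = self._record_with_gaps([])
        br = detect_breaks(rec, self._onsets(rec))
        assert all(len(d) == 0 for d in br.durations_h)
        assert np.isnan(br.mean_duration_h)

    def test_min_gap_threshold(self):
        rec = self._record_with_gaps([(3.0, 0.5), (8.0, 1.0 / 3.0)])
        br = detect_breaks(rec, self._onsets(rec), min_gap_minutes=25.0)
        flat = [d for cyc in br.durations_h for d in cyc]
        assert all(abs(d - 0.5) < 1e-9 for d in flat)
        assert len(flat) > 0


class TestAnalyzeRecord:
    def test_rho_alpha_identity_and_schema(self, dd_schedule):
        p = SimActivityParams(drift_per_cycle=-19.0, alpha_true=12.7,
                              break_spec=(5.5, 2.34), seed=5)
        rec, _ = simulate_activity(p, dd_schedule, n_days=10)
        rp = analyze_record(rec.slice_hours(24.0))
        assert rp.rhythmic
        assert rp.rho_h + rp.alpha_h == rp.tau_h  # exact identity
        # conservation holds against the 24-h cycle the day/night split uses
        rec6 = bin_activity(rec.slice_hours(24.0), 6.0)
        assert rp.day_activity + rp.night_activity == pytest.approx(
            overall_activity(rec6, 24.0)
        )
        # per-tau-cycle overall stays within a cycle-length ratio of it
        assert rp.overall_activity == pytest.approx(
            (rp.day_activity + rp.night_activity) * rp.tau_h / 24.0, rel=0.05
        )
        assert abs(rp.delta_h * 60 - (-152.0)) <= 12.0
        assert abs(rp.break_mean_h - 2.34) < 0.3

    def test_arrhythmic_record_withholds_phase_params(self, dd_schedule):
        p = SimActivityParams(arrhythmic=True, seed=6)
        rec, _ = simulate_activity(p, dd_schedule, n_days=10)
        rp = analyze_record(rec.slice_hours(24.0))
        assert not rp.rhythmic
        assert np.isnan(rp.alpha_h) and np.isnan(rp.delta_h)
        assert rp.overall_activity > 0
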