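"""Trace feature estimators against analytic and simulation oracles."""
import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from curlipulse import (
    ExpressionParams,
    GrowthParams,
    SimulationConfig,
    align_traces,
    decay_half_time,
    detect_divisions,
    expression_kde,
    extract_features,
    first_peak_amplitude,
    fraction_positive_over_time,
    growth_rate_series,
    instantaneous_growth_rate,
    max_induction_rate,
    simulate_mother_machine,
    simulate_pulse_traces,
    threshold_crossing_time,
)
from curlipulse.errors import (
    EmptyProfileError,
    InsufficientDataError,
    InvalidArgumentsError,
    InvalidTraceError,
)

from conftest import make_trace, noiseless_config


class TestGrowthRate:
    def test_exact_on_log_linear_trace(self):
        t = 10.0 * np.arange(20)
        tr = make_trace(np.zeros(20) + 100, times=t, lengths=2.0 * np.exp(0.01 * t))
        rates = instantaneous_growth_rate(tr, window=3)
        assert np.allclose(rates, 0.01, rtol=1e-9)

    def test_zero_on_constant_length(self):
        tr = make_trace(np.full(10, 100.0), lengths=np.full(10, 3.0))
        assert np.allclose(instantaneous_growth_rate(tr), 0.0, atol=1e-12)

    def test_division_breaks_segments(self):
        # two exponential segments at different rates separated by a division
        t = 10.0 * np.arange(10)
        L = np.concatenate([2.0 * np.exp(0.02 * t[:5]),
                            1.2 * np.exp(0.005 * (t[5:] - t[5]))])
        div = np.zeros(10, bool)
        div[5] = True
        tr = make_trace(np.full(10, 100.0), times=t, lengths=L, divisions=div)
        rates = instantaneous_growth_rate(tr, window=3)
        assert np.allclose(rates[:5], 0.02, rtol=1e-9)
        assert np.allclose(rates[5:], 0.005, rtol=1e-9)

    def test_single_frame_segment_is_missing(self):
        div = np.array([False, True, True, False])
        tr = make_trace(np.full(4, 100.0), lengths=[2.0, 1.0, 0.6, 0.7],
                        divisions=div)
        rates = instantaneous_growth_rate(tr)
        assert np.isnan(rates[0]) and np.isnan(rates[1])
        assert np.isfinite(rates[2]) and np.isfinite(rates[3])

    @settings(deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 100.0))
    def test_invariant_to_length_rescaling(self, scale):
        rng = np.random.default_rng(0)
        L = np.exp(np.cumsum(rng.normal(0.01, 0.002, 30)))
        tr1 = make_trace(np.full(30, 100.0), lengths=L)
        tr2 = make_trace(np.full(30, 100.0), lengths=scale * L)
        r1 = instantaneous_growth_rate(tr1)
        r2 = instantaneous_growth_rate(tr2)
        assert np.allclose(r1, r2, rtol=1e-9, atol=1e-12)

    def test_recovers_configured_rates_before_and_after_switch(self):
        cfg = noiseless_config(seed=11, n_traps=40,
                               growth=GrowthParams(g_fresh=0.02, g_cond=0.004,
                                                   tau_relax=1e-6))
        traces = simulate_mother_machine(cfg)
        series = growth_rate_series(traces)
        pre = series.times < cfg.t_switch - 20
        post = series.times > cfg.t_switch + 200
        assert np.nanmedian(series.median_rate[pre]) == pytest.approx(0.02, rel=0.01)
        assert np.nanmedian(series.median_rate[post]) == pytest.approx(0.004, rel=0.01)

    def test_quartiles_bracket_median(self, default_traces):
        s = growth_rate_series(default_traces[:60])
        ok = np.isfinite(s.median_rate)
        assert np.all(s.q25[ok] <= s.median_rate[ok] + 1e-12)
        assert np.all(s.median_rate[ok] <= s.q75[ok] + 1e-12)

    def test_nonpositive_length_rejected(self):
        tr = make_trace(np.full(4, 100.0))
        tr.lengths = np.array([1.0, -1.0, 1.0, 1.0])
        with pytest.raises(InvalidTraceError):
            instantaneous_growth_rate(tr)


class TestDetectDivisions:
    def test_flags_large_drop(self):
        flags = detect_divisions(np.array([2.0, 2.2, 1.1, 1.2]))
        assert list(flags) == [False, False, True, False]

    def test_monotone_series_has_no_flags(self):
        assert not detect_divisions(np.linspace(1, 5, 20)).any()

    def test_recovers_simulator_ground_truth_on_noiseless_trace(self):
        cfg = noiseless_config(seed=12, n_traps=10)
        for tr in simulate_mother_machine(cfg):
            recovered = detect_divisions(tr.lengths)
            assert np.array_equal(recovered, tr.division_flags)


class TestThresholdCrossing:
    def test_first_frame_at_or_above(self):
        tr = make_trace([500.0, 800.0, 1200.0])
        assert threshold_crossing_time(tr, 1000.0) == 20.0

    def test_censored_when_never_crossed(self):
        tr = make_trace([500.0, 800.0, 900.0])
        assert threshold_crossing_time(tr, 1000.0) is None

    def test_positive_at_start_crosses_at_zero(self):
        tr = make_trace([1500.0, 1200.0, 900.0])
        assert threshold_crossing_time(tr, 1000.0) == 0.0

    def test_optional_interpolation(self):
        tr = make_trace([500.0, 1500.0])
        assert threshold_crossing_time(tr, 1000.0, interpolate=True) == \
            pytest.approx(5.0)


class TestAlignTraces:
    def test_single_trace_profile_equals_shifted_trace(self):
        f = np.array([100.0, 100.0, 1200.0, 5000.0, 3000.0])
        tr = make_trace(f)
        p = align_traces([tr], threshold=1000.0, window_before=20,
                         window_after=20)
        assert np.array_equal(p.median, p.q25)
        assert np.array_equal(p.median, p.q75)
        i0 = int(np.nonzero(p.rel_times == 0.0)[0][0])
        assert p.median[i0] == 1200.0

    def test_identical_pulses_reproduce_generating_shape(self):
        cfg = noiseless_config(seed=13, division=None)
        traces = simulate_pulse_traces(cfg, t_on=600.0, on_duration=300.0,
                                       n_traces=200)
        p = align_traces(traces, threshold=1000.0, window_before=100,
                         window_after=300)
        # all pulses share one deterministic shape -> quartiles collapse
        assert np.allclose(p.q25, p.q75, rtol=1e-9)
        assert np.allclose(p.median, traces[0].fluorescence[
            np.isin(traces[0].times,
                    p.rel_times + threshold_crossing_time(traces[0], 1000.0))],
            rtol=1e-9)

    def test_value_at_zero_meets_threshold(self, default_traces):
        p = align_traces(default_traces, threshold=1000.0)
        i0 = int(np.nonzero(p.rel_times == 0.0)[0][0])
        assert p.q25[i0] >= 1000.0

    def test_no_crossers_raises(self):
        tr = make_trace([100.0, 200.0, 300.0])
        with pytest.raises(EmptyProfileError):
            align_traces([tr], threshold=1000.0)

    def test_quartiles_bracket_median(self, default_traces):
        p = align_traces(default_traces)
        assert np.all(p.q25 <= p.median + 1e-12)
        assert np.all(p.median <= p.q75 + 1e-12)


class TestMaxInductionRate:
    def test_piecewise_linear_trace(self):
        tr = make_trace([0.0, 100.0, 300.0, 350.0])
        assert max_induction_rate(tr, threshold=50.0) == pytest.approx(20.0)

    def test_censored_without_crossing(self):
        tr = make_trace([100.0, 200.0, 300.0])
        assert max_induction_rate(tr, threshold=1000.0) is None

    def test_censored_when_never_increasing(self):
        tr = make_trace([2000.0, 1500.0, 1000.0])
        assert max_induction_rate(tr, threshold=1000.0) is None

    def test_matches_frame_averaged_slope_on_simulated_pulse(self,
                                                             noiseless_pulses):
        g, beta, dt = 0.004, 40.0, 10.0
        expected = beta * (1 - math.exp(-g * dt)) / (g * dt)
        rates = [max_induction_rate(tr) for tr in noiseless_pulses]
        rates = [r for r in rates if r is not None]
        assert np.median(rates) == pytest.approx(expected, rel=0.10)


class TestFirstPeak:
    def test_rise_then_fall(self):
        f = np.array([100.0, 2000.0, 5000.0, 3000.0, 2000.0])
        t, a = first_peak_amplitude(make_trace(f), threshold=1000.0)
        assert a == 5000.0 and t == 20.0

    def test_monotone_rising_is_censored(self):
        f = np.array([100.0, 2000.0, 3000.0, 4000.0])
        assert first_peak_amplitude(make_trace(f), threshold=1000.0) is None

    def test_small_blips_do_not_terminate_the_pulse(self):
        # a 2% dip on the rise is below the 10% prominence floor
        f = np.array([100.0, 2000.0, 3000.0, 2950.0, 4000.0, 6000.0, 3000.0,
                      1000.0])
        t, a = first_peak_amplitude(make_trace(f), threshold=1000.0)
        assert a == 6000.0

    def test_matches_analytic_pulse_maximum(self, noiseless_pulses):
        g, beta, F0, dur = 0.004, 40.0, 100.0, 300.0
        expected = F0 + beta / g * (1 - math.exp(-g * dur))
        amps = [first_peak_amplitude(tr) for tr in noiseless_pulses]
        amps = [a for _, a in filter(None, amps)]
        assert np.median(amps) == pytest.approx(expected, rel=0.05)


class TestDecayHalfTime:
    def test_exponential_half_life(self):
        k = math.log(2) / 60.0
        t = 10.0 * np.arange(30)
        f = 5000.0 * np.exp(-k * np.maximum(t - 50.0, 0.0))
        tr = make_trace(f, times=t)
        ht = decay_half_time(tr, peak_time=50.0, peak_amplitude=5000.0,
                             baseline=0.0)
        assert ht == pytest.approx(60.0, abs=10.0)  # one interpolation step

    def test_truncated_decay_is_censored(self):
        tr = make_trace([100.0, 5000.0, 4500.0])
        assert decay_half_time(tr, 10.0, 5000.0, 100.0) is None

    def test_baseline_above_peak_rejected(self):
        tr = make_trace([100.0, 5000.0, 4000.0])
        with pytest.raises(InvalidArgumentsError):
            decay_half_time(tr, 10.0, 5000.0, 6000.0)

    def test_dilution_half_life_on_simulated_pulse(self, noiseless_pulses):
        expected = math.log(2) / 0.004
        hts = [extract_features(tr).decay_half_time for tr in noiseless_pulses]
        hts = [h for h in hts if h is not None]
        assert np.median(hts) == pytest.approx(expected, rel=0.10)


class TestFractionPositive:
    def test_zero_when_all_below(self):
        traces = [make_trace(np.full(5, 200.0), trap_id=f"t{i}")
                  for i in range(3)]
        _, frac, n = fraction_positive_over_time(traces, threshold=1000.0)
        assert np.all(frac == 0.0) and np.all(n == 3)

    def test_zero_after_burn_in_without_activation(self):
        cfg = dataclasses.replace(
            SimulationConfig(seed=14, n_traps=30),
            expression=ExpressionParams(k_on=0.0))
        _, frac, _ = fraction_positive_over_time(
            simulate_mother_machine(cfg))
        assert np.all(frac == 0.0)

    def test_terminal_fraction_matches_telegraph_stationary_value(self):
        k_on, k_off = 0.01, 0.01 * 7 / 3  # stationary 0.3
        cfg = dataclasses.replace(
            SimulationConfig(seed=15, n_traps=300, t_switch=0.001),
            expression=ExpressionParams(k_on=k_on, k_off=k_off, lag=0.0))
        traces = simulate_mother_machine(cfg)
        p = k_on / (k_on + k_off)
        se = math.sqrt(p * (1 - p) / 300)
        observed = np.mean([tr.on_state[-1] for tr in traces])
        assert abs(observed - p) <= 3 * se


class TestExpressionKde:
    def test_unimodal_mode_near_component_mean(self):
        rng = np.random.default_rng(16)
        values = 10 ** rng.normal(3.0, 0.25, 100_000)
        grid, dens = expression_kde(values)
        assert grid[np.argmax(dens)] == pytest.approx(3.0, abs=0.05)

    def test_balanced_mixture_has_exactly_two_maxima(self):
        rng = np.random.default_rng(17)
        z = np.where(rng.random(50_000) < 0.5,
                     rng.normal(2.0, 0.25, 50_000),
                     rng.normal(4.0, 0.25, 50_000))
        grid, dens = expression_kde(10 ** z, grid=np.linspace(0.5, 5.5, 512))
        interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
        assert interior.sum() == 2

    def test_density_nonnegative_and_unit_mass(self):
        rng = np.random.default_rng(18)
        values = 10 ** rng.normal(2.5, 0.3, 5_000)
        grid, dens = expression_kde(values)
        assert np.all(dens >= 0)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=0.01)

    def test_insufficient_data_rejected(self):
        with pytest.raises(InsufficientDataError):
            expression_kde(np.array([100.0]))


class TestCensoringConsistency:
    def test_every_trace_counted_once_per_feature(self, default_traces):
        feats = [extract_features(tr) for tr in default_traces]
        n = len(default_traces)
        for attr, reasons in [
            ("crossing_time", {"never_crossed", "trace_too_short"}),
            ("max_rate", {"never_crossed", "no_peak", "trace_too_short"}),
            ("peak_amplitude", {"never_crossed", "no_peak", "trace_too_short"}),
            ("decay_half_time", {"never_crossed", "no_peak",
                                 "decay_unfinished", "trace_too_short"}),
        ]:
            present = sum(getattr(f, attr) is not None for f in feats)
            censored = sum(getattr(f, attr) is None
                           and bool(f.censor_reasons & reasons) for f in feats)
            assert present + censored == n

    def test_crossing_precedes_peak_and_halftime_requires_peak(self,
                                                               default_traces):
        for f in (extract_features(tr) for tr in default_traces):
            if f.crossing_time is not None and f.peak_time is not None:
                assert f.crossing_time <= f.peak_time
            if f.decay_half_time is not None:
                assert f.peak_amplitude is not None
                assert f.decay_half_time > 0
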