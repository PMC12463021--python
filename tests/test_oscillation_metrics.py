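"""Detrending, filtering, extrema detection and cycle statistics."""

import numpy as np
import pytest

from algalogic import (ChannelParams, PeakTable, TimeSeries, add_gaussian_noise,
                       analyze_channel, cycle_amplitudes, cycle_periods,
                       detect_extrema, generate_channel, linear_detrend,
                       lowpass_filter, nyquist_frequency, summarize)


def brute_force_extrema(values, rate, min_height, prominence, min_separation):
    """Exhaustive reference scan: local maxima filtered by height, prominence
    (computed by walking left/right to the first higher sample) and minimum
    spacing (greedy by decreasing height, earlier wins ties)."""
    n = len(values)
    candidates = [i for i in range(1, n - 1)
                  if values[i - 1] < values[i] >= values[i + 1]]
    kept = []
    for i in candidates:
        if values[i] < min_height:
            continue
        # prominence: lowest valley on each side before a higher sample
        left_min = values[i]
        for j in range(i - 1, -1, -1):
            if values[j] > values[i]:
                break
            left_min = min(left_min, values[j])
        else:
            left_min = min(left_min, values[0])
        right_min = values[i]
        for j in range(i + 1, n):
            if values[j] > values[i]:
                break
            right_min = min(right_min, values[j])
        else:
            right_min = min(right_min, values[-1])
        if values[i] - max(left_min, right_min) < prominence:
            continue
        kept.append(i)
    # enforce spacing: highest first, earlier index on ties
    dist = int(round(min_separation * rate))
    kept_sorted = sorted(kept, key=lambda i: (-values[i], i))
    selected = []
    for i in kept_sorted:
        if all(abs(i - j) >= dist for j in selected):
            selected.append(i)
    return sorted(selected)


class TestNyquist:
    def test_values(self):
        assert nyquist_frequency(2.5) == 1.25
        assert nyquist_frequency(1.0) == 0.5

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            nyquist_frequency(0.0)


class TestLinearDetrend:
    def test_perfect_ramp(self):
        ts = TimeSeries(0.0, 1.0, np.arange(10.0), "ramp")
        detrended, fit = linear_detrend(ts)
        assert fit.slope == pytest.approx(1.0)
        assert np.max(np.abs(detrended.values)) < 1e-12

    def test_cosine_has_no_trend(self):
        # cosine phase is orthogonal to a linear ramp over whole periods;
        # the discrete grid leaves an O(1/N^2) residue, far below any
        # physically meaningful drift slope
        p = ChannelParams("c", 80.0, 500.0, 0.0)
        ts = generate_channel(p, 5000.0, 1.0, phase=np.pi / 2)
        _, fit = linear_detrend(ts)
        assert abs(fit.slope) < 1e-3 * 80.0 / 500.0

    def test_residual_mean_zero(self, sine_500s):
        detrended, _ = linear_detrend(sine_500s)
        assert abs(np.mean(detrended.values)) < 1e-9 * 80.0

    def test_too_short(self):
        with pytest.raises(ValueError):
            linear_detrend(TimeSeries(0.0, 1.0, np.array([1.0]), "x"))


class TestLowpassFilter:
    def test_supra_nyquist_cutoff_is_identity(self, sine_500s):
        out = lowpass_filter(sine_500s, cutoff=2.0)  # Nyquist is 0.5 Hz
        assert out is sine_500s

    def test_dc_preserved(self):
        ts = TimeSeries(0.0, 1.0, np.full(4000, 7.5), "dc")
        out = lowpass_filter(ts, cutoff=0.01)
        assert np.allclose(out.values, 7.5, rtol=1e-6)

    def test_stopband_attenuation(self):
        t = np.arange(20_000.0)
        values = np.sin(2 * np.pi * 0.001 * t) + np.sin(2 * np.pi * 0.4 * t)
        ts = TimeSeries(0.0, 1.0, values, "mix")
        out = lowpass_filter(ts, cutoff=0.01)

        def band_power(v, f):
            return np.abs(np.fft.rfft(v)[int(round(f * len(v)))]) ** 2

        before = band_power(values, 0.4)
        after = band_power(out.values, 0.4)
        assert 10 * np.log10(before / after) >= 20.0

    def test_rejects_nonpositive_cutoff(self, sine_500s):
        with pytest.raises(ValueError):
            lowpass_filter(sine_500s, 0.0)


class TestDetectExtrema:
    def test_sinusoid_extrema_locations(self, sine_500s):
        table = detect_extrema(sine_500s)
        assert table.n_peaks == 10
        assert len(table.trough_times) == 10
        for k, (tp, tt) in enumerate(zip(table.peak_times, table.trough_times)):
            assert abs(tp - (125 + 500 * k)) <= 1.0
            assert abs(tt - (375 + 500 * k)) <= 1.0

    def test_empty_and_flat(self, zero_series):
        table = detect_extrema(zero_series)
        assert table.n_peaks == 0 and len(table.trough_times) == 0
        empty = detect_extrema(TimeSeries(0.0, 1.0, np.empty(0), "e"))
        assert empty.n_peaks == 0

    def test_height_gate_blocks_small_oscillations(self):
        p = ChannelParams("small", 8.0, 500.0, 0.0)
        ts = generate_channel(p, 5000.0, 1.0)
        assert detect_extrema(ts).n_peaks == 0

    def test_min_separation_below_sample_interval(self, sine_500s):
        with pytest.raises(ValueError):
            detect_extrema(sine_500s, min_separation=0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle(self, seed):
        """Peak picker agrees with an exhaustive reference scan on short
        noisy damped sinusoids (<= 2000 samples)."""
        rng = np.random.default_rng(seed)
        t = np.arange(2000.0)
        values = (60.0 * np.sin(2 * np.pi * t / (200 + 150 * seed))
                  + rng.normal(0, 6.0, size=t.size))
        ts = TimeSeries(0.0, 1.0, values, "noisy")
        table = detect_extrema(ts, min_height=10.0, prominence=5.0,
                               min_separation=100.0)
        expect = brute_force_extrema(values, 1.0, 10.0, 5.0, 100.0)
        assert list(table.peak_times) == [float(i) for i in expect]


class TestCycleStatistics:
    def test_periods_simple(self):
        table = PeakTable(np.array([100.0, 400.0, 700.0]), np.array([1.0, 1.0, 1.0]),
                          np.empty(0), np.empty(0))
        assert list(cycle_periods(table)) == [300.0, 300.0]

    def test_single_peak_empty(self):
        table = PeakTable(np.array([100.0]), np.array([1.0]), np.empty(0), np.empty(0))
        assert len(cycle_periods(table)) == 0

    def test_periods_telescope(self, sine_500s):
        table = detect_extrema(sine_500s)
        periods = cycle_periods(table)
        assert np.all(np.abs(periods - 500.0) <= 2.0)
        assert np.sum(periods) == pytest.approx(table.peak_times[-1] - table.peak_times[0])

    def test_amplitudes_sinusoid_peak_to_trough(self, sine_500s):
        table = detect_extrema(sine_500s)
        amps = cycle_amplitudes(table)
        assert len(amps) > 0
        assert np.all(np.abs(amps - 160.0) <= 0.02 * 160.0)

    def test_amplitude_arithmetic(self):
        table = PeakTable(np.array([100.0, 600.0]), np.array([10.0, 10.0]),
                          np.array([300.0]), np.array([-20.0]))
        assert list(cycle_amplitudes(table)) == [30.0]

    def test_no_troughs_empty(self):
        table = PeakTable(np.array([100.0, 600.0]), np.array([10.0, 10.0]),
                          np.empty(0), np.empty(0))
        assert len(cycle_amplitudes(table)) == 0


class TestSummarize:
    def test_printed_frequency_and_power(self):
        """f = 1/T and P = f*A^2 reproduce the published per-channel values."""
        s = summarize(np.array([299.88]), np.array([50.41]), 480)
        assert round(s.frequency_f, 6) == 0.003335
        s = summarize(np.array([724.00]), np.array([80.94]), 239)
        assert round(s.power_P, 3) == 9.049

    def test_identities_exact(self):
        s = summarize(np.array([300.0, 320.0]), np.array([50.0, 55.0]), 3)
        assert s.frequency_f == 1.0 / s.mean_period_Tbar
        assert s.power_P == s.frequency_f * s.mean_amplitude_Abar ** 2

    def test_population_sd(self):
        s = summarize(np.array([100.0]), np.array([3.0, 5.0]), 2)
        # population divisor: sqrt(mean((A - 4)^2)) = 1
        assert s.sd_amplitude_sigmaA == pytest.approx(1.0)
        two_pass = np.sqrt(np.mean((np.array([3.0, 5.0]) - 4.0) ** 2))
        assert s.sd_amplitude_sigmaA == pytest.approx(two_pass, rel=1e-9)

    def test_equal_amplitudes_zero_sd(self):
        s = summarize(np.array([100.0, 100.0]), np.array([5.0, 5.0, 5.0]), 3)
        assert s.sd_amplitude_sigmaA == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize(np.empty(0), np.empty(0), 0)


class TestAnalyzeChannel:
    def test_noiseless_parameter_recovery(self):
        p = ChannelParams("x", 80.0, 500.0, 0.0)
        ts = generate_channel(p, 5000.0, 1.0)
        _, s = analyze_channel(ts, detrend=False)
        assert s.mean_period_Tbar == pytest.approx(500.0, rel=0.005)
        assert s.mean_amplitude_Abar == pytest.approx(160.0, rel=0.03)

    def test_noisy_period_recovery(self):
        # the low-pass stage exists to remove broadband noise before peak
        # detection; without it 8 mV noise defeats the 5 mV prominence gate
        p = ChannelParams("x", 80.0, 500.0, 0.0)
        ts = generate_channel(p, 5000.0, 1.0)
        noisy = add_gaussian_noise(ts, 0.1, 80.0, seed=11)
        _, s = analyze_channel(noisy, detrend=False, filter_cutoff=0.01)
        assert s.mean_period_Tbar == pytest.approx(500.0, rel=0.02)

    def test_flat_series_rejected(self, zero_series):
        with pytest.raises(ValueError):
            analyze_channel(zero_series, detrend=False)
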