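"""Inter-tap times, fatigue-line fitting, and windowed excursions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fingertap import (
    DegenerateSignalError,
    DetectionParams,
    DomainError,
    FingerLabel,
    InsufficientEventsError,
    SynthParams,
    TapSeries,
    detect_taps,
    excursion_percent_difference,
    fit_fatigue_line,
    generate_tap_times,
    inter_tap_times,
    render_trace,
    windowed_excursion,
)

from conftest import ols_closed_form


def _taps(times, amps=None):
    times = np.asarray(times, float)
    amps = np.ones_like(times) if amps is None else np.asarray(amps, float)
    return TapSeries(FingerLabel.INDEX_DOM, times, amps)


class TestInterTapTimes:
    def test_uniform_train(self):
        ev, it = inter_tap_times(_taps([0.0, 1.0, 2.0, 3.0]))
        np.testing.assert_allclose(it, [1.0, 1.0, 1.0])
        np.testing.assert_allclose(ev, [1.0, 2.0, 3.0])

    def test_irregular_train(self):
        ev, it = inter_tap_times(_taps([0.0, 0.4, 1.0]))
        np.testing.assert_allclose(it, [0.4, 0.6])

    def test_single_tap_rejected(self):
        with pytest.raises(InsufficientEventsError):
            inter_tap_times(_taps([1.0]))

    def test_generator_constant_period(self):
        params = SynthParams(base_interval=0.25, timing_jitter=0.0, noise=0.0,
                             seed=0)
        times = generate_tap_times(params, 1)
        _, it = inter_tap_times(_taps(times))
        np.testing.assert_allclose(it, 0.25, atol=1 / 120)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(2, 50))
    def test_conservation_exact(self, seed, n):
        """sum(inter_times) == last - first peak time, exactly in floats."""
        r = np.random.default_rng(seed)
        times = np.cumsum(r.uniform(0.1, 0.5, n))
        ev, it = inter_tap_times(_taps(times))
        assert np.sum(it) == pytest.approx(times[-1] - times[0], abs=1e-12)


class TestFatigueLine:
    def test_exact_line_recovered(self):
        t = np.linspace(1, 29, 40)
        fit = fit_fatigue_line(t, 0.2 + 0.01 * t)
        assert fit.slope == pytest.approx(0.01, abs=1e-12)
        assert fit.intercept == pytest.approx(0.2, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert not fit.degenerate

    def test_constant_inter_times_degenerate_convention(self):
        fit = fit_fatigue_line([1.0, 2.0, 3.0], [0.2, 0.2, 0.2])
        assert fit.slope == 0.0
        assert fit.r_squared == 1.0
        assert fit.degenerate

    def test_too_few_points(self):
        with pytest.raises(InsufficientEventsError):
            fit_fatigue_line([1.0, 2.0], [0.2, 0.3])

    def test_zero_time_variance_rejected(self):
        with pytest.raises(DegenerateSignalError):
            fit_fatigue_line([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(3, 40))
    def test_matches_closed_form_ols(self, seed, n):
        r = np.random.default_rng(seed)
        x = np.sort(r.uniform(0, 30, n))
        if np.ptp(x) == 0:
            return
        y = 0.2 + 0.01 * x + r.normal(0, 0.02, n)
        fit = fit_fatigue_line(x, y)
        slope, intercept, r2 = ols_closed_form(x, y)
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10)
        assert fit.r_squared == pytest.approx(r2, rel=1e-10, abs=1e-12)

    def test_slope_recovery_across_drift_grid(self):
        """95% spread of fitted slopes over seeds covers the true drift.

        A drift of -0.02 s/s shortens intervals by 0.6 s over the trial,
        so the base interval is 0.8 s to keep the tap train clear of the
        physical minimum-interval floor throughout."""
        for m in (-0.02, 0.0, 0.02):
            fitted = []
            for s in range(60):
                params = SynthParams(base_interval=0.8, pulse_width=0.05,
                                     drift=m, timing_jitter=0.01, noise=0.0,
                                     seed=40000 + s)
                times = generate_tap_times(params, 1)
                ev, it = inter_tap_times(_taps(times))
                fitted.append(fit_fatigue_line(ev, it).slope)
            lo, hi = np.percentile(fitted, [2.5, 97.5])
            assert lo <= m <= hi or abs(np.mean(fitted) - m) < 5e-4


class TestWindowedExcursion:
    def _biphasic_trace(self, params):
        times = generate_tap_times(params, 1)
        trace = render_trace(times, params)
        return times, trace

    def test_biphasic_construction(self):
        """Crest +2 g, trough -1 g on a zero baseline: excursion 3 g in
        every window, std 0.  pulse_width 0.05 puts crest and trough
        exactly on grid samples so the values are exact."""
        params = SynthParams(base_interval=0.25, pulse_width=0.05,
                             timing_jitter=0.0, noise=0.0, seed=0)
        times, trace = self._biphasic_trace(params)
        taps = detect_taps(trace.timestamps, trace.az, DetectionParams())
        values, mean, std, n_windows = windowed_excursion(
            trace.timestamps, trace.az, taps, window=5.0
        )
        assert n_windows == 6
        assert mean == pytest.approx(3.0, abs=0.01)
        assert std == pytest.approx(0.0, abs=0.01)

    def test_window_count_30s(self):
        params = SynthParams(timing_jitter=0.0, noise=0.0, seed=0)
        times, trace = self._biphasic_trace(params)
        taps = detect_taps(trace.timestamps, trace.az, DetectionParams())
        *_, n_windows = windowed_excursion(trace.timestamps, trace.az, taps, 5.0)
        assert n_windows == int(np.ceil(trace.duration / 5.0)) == 6

    def test_amplitude_linearity(self):
        params = SynthParams(timing_jitter=0.0, noise=0.0, seed=0)
        times, trace = self._biphasic_trace(params)
        taps = detect_taps(trace.timestamps, trace.az, DetectionParams())
        _, mean1, _, _ = windowed_excursion(trace.timestamps, trace.az, taps)
        taps2 = TapSeries(
            taps.source_finger, taps.peak_times, 2 * taps.peak_amplitudes
        )
        _, mean2, _, _ = windowed_excursion(
            trace.timestamps, 2 * trace.az, taps2
        )
        assert mean2 == pytest.approx(2 * mean1, rel=1e-12)

    def test_offset_invariance(self):
        params = SynthParams(timing_jitter=0.0, noise=0.0, seed=0)
        times, trace = self._biphasic_trace(params)
        taps = detect_taps(trace.timestamps, trace.az, DetectionParams())
        _, mean1, _, _ = windowed_excursion(trace.timestamps, trace.az, taps)
        offset_taps = TapSeries(
            taps.source_finger, taps.peak_times, taps.peak_amplitudes + 0.5
        )
        _, mean2, _, _ = windowed_excursion(
            trace.timestamps, trace.az + 0.5, offset_taps
        )
        assert mean2 == pytest.approx(mean1, rel=1e-12)

    def test_no_taps_rejected(self):
        t = np.arange(100) / 120
        with pytest.raises(InsufficientEventsError):
            windowed_excursion(t, np.zeros(100), TapSeries(None, [], []))


class TestPercentDifference:
    @pytest.mark.parametrize(
        "ref,other,expected",
        [(2.0, 2.0, 0.0), (2.0, 1.0, 50.0), (1.0, 0.7767, 22.33)],
    )
    def test_values(self, ref, other, expected):
        assert excursion_percent_difference(ref, other) == pytest.approx(
            expected, abs=1e-9
        )

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(DomainError):
            excursion_percent_difference(0.0, 1.0)
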