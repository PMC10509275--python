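"""Tablet stream labeling: force, interpolation, smoothing, velocity, filters."""

import numpy as np
import pytest
from scipy.signal import sawtooth

import scratchring as sr
from scratchring.tablet_labeling import (
    CriticalPointSet,
    InsufficientContactError,
    LabelingError,
    NoContactError,
    TABLET_RATE_HZ,
    WindowTooShortError,
)

FS = TABLET_RATE_HZ


def make_stream(y, x=None, f=None, t=None):
    n = len(y)
    t = np.arange(n) / FS if t is None else np.asarray(t)
    x = np.full(n, 100.0) if x is None else np.asarray(x, float)
    f = np.full(n, 0.5) if f is None else np.asarray(f, float)
    return sr.TabletStream(t=t, x=x, y=np.asarray(y, float), f=f)


def triangle(t, amplitude, freq, phase=0.0):
    return amplitude * sawtooth(2 * np.pi * freq * t + phase, 0.5)


class TestMeanForce:
    def test_constant_force(self):
        assert sr.mean_force(np.full(150, 0.5)) == pytest.approx(0.5)

    def test_missing_values_discarded(self):
        assert sr.mean_force(np.array([1.0, np.nan, 3.0])) == pytest.approx(2.0)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(42)
        f = rng.uniform(0, 2, 150)
        f[rng.choice(150, 30, replace=False)] = np.nan
        # brute-force oracle: explicit sum over non-missing entries
        total, count = 0.0, 0
        for v in f:
            if not np.isnan(v):
                total += v
                count += 1
        assert sr.mean_force(f) == pytest.approx(total / count)

    def test_all_missing_rejected(self):
        with pytest.raises(NoContactError):
            sr.mean_force(np.full(10, np.nan))


class TestInterpolatePositions:
    def test_linear_midpoint(self):
        s = make_stream([10.0, np.nan, 30.0], x=[5.0, np.nan, 15.0])
        out = sr.interpolate_positions(s)
        assert out.y[1] == pytest.approx(20.0)
        assert out.x[1] == pytest.approx(10.0)

    def test_identity_without_gaps(self):
        s = make_stream(np.linspace(0, 50, 40))
        out = sr.interpolate_positions(s)
        np.testing.assert_array_equal(out.y, s.y)

    def test_non_missing_values_unchanged(self):
        y = np.linspace(0, 50, 40)
        y[10:13] = np.nan
        s = make_stream(y)
        out = sr.interpolate_positions(s)
        keep = ~np.isnan(y)
        np.testing.assert_array_equal(out.y[keep], y[keep])

    def test_sinusoid_with_random_gaps_recovered(self):
        t = np.arange(0, 4, 1 / FS)
        true = 60 + 30 * np.sin(2 * np.pi * 2.0 * t)
        y = true.copy()
        rng = np.random.default_rng(0)
        gaps = rng.choice(np.arange(1, t.size - 1), int(0.2 * t.size), replace=False)
        y[gaps] = np.nan
        out = sr.interpolate_positions(make_stream(y, t=t))
        # linear bridging of short gaps in a 2 Hz sinusoid: curvature error
        # bounded by (2 pi f dt_gap)^2 A / 8 per gap; generous envelope here
        assert np.nanmax(np.abs(out.y - true)) < 2.0

    def test_leading_trailing_missing_stay_missing(self):
        y = np.array([np.nan, 10.0, 20.0, 30.0, np.nan])
        out = sr.interpolate_positions(make_stream(y))
        assert np.isnan(out.y[0]) and np.isnan(out.y[-1])

    def test_insufficient_contact(self):
        y = np.full(10, np.nan)
        y[3] = 5.0
        with pytest.raises(InsufficientContactError):
            sr.interpolate_positions(make_stream(y))


class TestSmoothY:
    def test_constant_unchanged(self):
        y = np.full(100, 42.0)
        np.testing.assert_allclose(sr.smooth_y(y), y)

    def test_degree5_polynomial_reproduced(self):
        # a Savitzky-Golay filter of order 5 reproduces polynomials of
        # degree <= 5 exactly at interior points
        t = np.linspace(-1, 1, 200)
        y = 3 + t - 2 * t**2 + 0.5 * t**3 - t**4 + 0.2 * t**5
        out = sr.smooth_y(y)
        np.testing.assert_allclose(out[15:-15], y[15:-15], atol=1e-10)

    def test_3hz_sinusoid_attenuation_below_5_percent(self):
        t = np.arange(0, 4, 1 / FS)
        y = 20 * np.sin(2 * np.pi * 3 * t)
        out = sr.smooth_y(y)
        interior = slice(30, -30)
        assert np.max(np.abs(out[interior])) > 0.95 * 20

    def test_matches_published_convolution_coefficients(self):
        # independent oracle: direct convolution with the closed-form
        # least-squares projection coefficients
        m, order = 31, 5
        j = np.arange(m) - m // 2
        V = np.vander(j, order + 1, increasing=True)
        # projection row evaluating the fit at the window center
        coeffs = (np.linalg.pinv(V.T @ V) @ V.T)[0]
        rng = np.random.default_rng(1)
        y = rng.normal(size=120)
        out = sr.smooth_y(y)
        k = 60
        expected = float(coeffs @ y[k - m // 2 : k + m // 2 + 1])
        assert out[k] == pytest.approx(expected, abs=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(WindowTooShortError):
            sr.smooth_y(np.ones(30))


class TestFindCriticalPoints:
    def test_monotone_ramp_has_none(self):
        t = np.arange(0, 2, 1 / FS)
        y = np.linspace(0, 100, t.size)
        cps = sr.find_critical_points(y, np.full(t.size, 50.0), t)
        assert len(cps) == 0

    def test_triangle_turnarounds_found(self):
        t = np.arange(0, 10, 1 / FS)
        y = 60 + triangle(t, 20, 2.0, phase=np.pi / 2)  # period 0.5 s
        y_s = sr.smooth_y(y)
        cps = sr.find_critical_points(y_s, np.full(t.size, 50.0), t, y_interp=y)
        peaks = cps.t_c[cps.is_peak]
        valleys = cps.t_c[~cps.is_peak]
        assert len(peaks) == 20 and len(valleys) == 20
        # analytic turnaround times for sawtooth(2 pi f t + pi/2, 0.5),
        # f = 2 Hz: peaks at 0.125 + 0.5 k, valleys at 0.375 + 0.5 k
        expected_peaks = 0.125 + np.arange(20) * 0.5
        expected_valleys = 0.375 + np.arange(20) * 0.5
        assert np.max(np.abs(np.sort(peaks) - expected_peaks)) <= 1.01 / FS
        assert np.max(np.abs(np.sort(valleys) - expected_valleys)) <= 1.01 / FS

    def test_3hz_sinusoid_six_alternating_points_per_second(self):
        t = np.arange(0, 1.2, 1 / FS)
        y = 60 + 20 * np.sin(2 * np.pi * 3 * t)
        y_s = sr.smooth_y(y)
        cps = sr.find_critical_points(y_s, np.full(t.size, 50.0), t, y_interp=y)
        inside = cps.in_window(0.0, 1.0)
        assert len(inside) == 6
        assert np.all(inside.is_peak[1:] != inside.is_peak[:-1])


class TestMeanVelocity:
    def make_points(self, ts, ys, xs, kinds):
        return CriticalPointSet(
            idx=np.arange(len(ts)), t_c=np.array(ts), x_c=np.array(xs, float),
            y_c=np.array(ys, float), is_peak=np.array(kinds),
        )

    def test_triangle_peak_to_valley(self):
        pts = self.make_points([0.0, 0.25, 0.5], [40.0, 0.0, 40.0], [5, 5, 5],
                               [True, False, True])
        assert sr.mean_velocity(pts) == pytest.approx(160.0)

    def test_diagonal_345_euclidean(self):
        pts = self.make_points([0.0, 0.5], [0.0, 30.0], [0.0, 40.0], [False, True])
        assert sr.mean_velocity(pts) == pytest.approx(100.0)

    def test_sinusoid_mean_speed_within_5_percent(self):
        t = np.arange(0, 3, 1 / FS)
        A, f = 20.0, 3.0
        y = 60 + A * np.sin(2 * np.pi * f * t)
        y_s = sr.smooth_y(y)
        cps = sr.find_critical_points(y_s, np.full(t.size, 50.0), t, y_interp=y)
        v = sr.mean_velocity(cps.in_window(1.0, 2.0))
        assert v == pytest.approx(4 * A * f, rel=0.05)

    def test_needs_two_points(self):
        pts = self.make_points([0.1], [5.0], [5.0], [True])
        with pytest.raises(LabelingError):
            sr.mean_velocity(pts)


class TestLabelStream:
    def scratch_stream(self, duration=3.0, A=15.0, f=3.0, force=0.5):
        t = np.arange(0, duration, 1 / FS)
        y = 60 + triangle(t, A, f)
        return make_stream(y, f=np.full(t.size, force), t=t)

    def test_power_is_force_times_velocity(self):
        labels = sr.label_stream(self.scratch_stream())
        valid = [s for s in labels if s.valid]
        assert valid
        for s in valid:
            assert s.power == pytest.approx(s.mean_force * s.mean_velocity)
            assert 0 <= s.power <= 600

    def test_empty_stream(self):
        empty = sr.TabletStream(np.empty(0), np.empty(0), np.empty(0), np.empty(0))
        assert sr.label_stream(empty) == []

    def test_determinism(self):
        a = sr.label_stream(self.scratch_stream())
        b = sr.label_stream(self.scratch_stream())
        assert [(s.window_start, s.power, s.valid) for s in a] == [
            (s.window_start, s.power, s.valid) for s in b
        ]

    def test_alternation_holds_in_valid_windows(self):
        stream = self.scratch_stream(duration=5.0)
        interp = sr.interpolate_positions(stream)
        y_s = sr.smooth_y(interp.y)
        cps = sr.find_critical_points(y_s, interp.x, interp.t, y_interp=interp.y)
        for s in sr.label_stream(stream):
            if s.valid:
                inside = cps.in_window(s.window_start, s.window_start + 1.0)
                assert np.all(inside.is_peak[1:] != inside.is_peak[:-1])

    def test_jump_injection_flips_accepted_window(self):
        stream = self.scratch_stream(duration=3.0)
        base = sr.label_stream(stream, stride_s=1.0)
        target = next(s for s in base if s.valid)
        x = stream.x.copy()
        k = int((target.window_start + 0.5) * FS)
        x[k:] += 6.0  # single-timestep 6 mm jump inside the window
        bumped = sr.label_stream(
            sr.TabletStream(stream.t, x, stream.y, stream.f), stride_s=1.0
        )
        flipped = next(s for s in bumped if s.window_start == target.window_start)
        assert not flipped.valid and flipped.reject_reason == "position_jump"

    def test_trailing_no_contact_windows_rejected(self):
        stream = self.scratch_stream(duration=4.0)
        f = stream.f.copy()
        x, y = stream.x.copy(), stream.y.copy()
        cut = int(2.5 * FS)
        f[cut:] = np.nan
        x[cut:] = np.nan
        y[cut:] = np.nan
        labels = sr.label_stream(sr.TabletStream(stream.t, x, y, f), stride_s=1.0)
        assert labels[-1].reject_reason == "no_contact"
        assert labels[0].valid
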