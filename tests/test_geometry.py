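"""Midline geometry and kinematic-field extraction."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from coleokin.fields import KinematicField
from coleokin.geometry import (MalformedInputError, MarkerProfileSeries,
                               MidlineFrame, MidlineSeries, advection_velocity,
                               curvature_profile, material_curvature_derivative,
                               orientation_profile, regr_from_markers,
                               resample_midline, temporal_field_average)

from conftest import arc_midlines, line_midlines


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

class TestResample:
    def test_straight_segment_identity(self):
        ms = resample_midline(line_midlines(length=10.0), target_step=0.5)
        f = ms.frames[0]
        assert f.points.shape[0] == 21
        assert np.allclose(np.diff(f.arc_length()), 0.5)

    def test_quarter_circle_length_preserved(self):
        ms = arc_midlines(radius=10.0, span=np.pi / 2, n_pts=2001)
        rs = resample_midline(ms, target_step=0.1)
        L = rs.frames[0].length
        assert abs(L - 10 * np.pi / 2) < 0.1

    def test_single_point_frame_errors(self):
        with pytest.raises(MalformedInputError):
            MidlineFrame(0.0, np.array([[0.0, 0.0]]))

    def test_bad_step_rejected(self):
        with pytest.raises(ValueError):
            resample_midline(line_midlines(), target_step=0.0)


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

class TestOrientation:
    def test_vertical_line_is_zero(self):
        field = orientation_profile(line_midlines(angle=0.0))
        assert np.nanmax(np.abs(field.masked_values())) < 1e-9

    def test_horizontal_line_is_half_pi(self):
        # apex pointing along +x, clockwise-positive convention
        field = orientation_profile(line_midlines(angle=np.pi / 2))
        vals = field.masked_values()
        assert np.allclose(vals[np.isfinite(vals)], np.pi / 2, atol=1e-9)

    def test_arc_linear_in_s(self):
        # quarter circle: horizontal at the apex (A = pi/2), vertical at
        # the base (A = 0); A decreases linearly with distance from apex
        field = orientation_profile(arc_midlines(radius=20.0), s_step=0.1)
        row = field.masked_values()[0]
        good = np.isfinite(row)
        s = field.s_grid[good]
        A = row[good]
        expected = np.pi / 2 - s / 20.0  # tangent angle of the circle
        assert np.max(np.abs(A - expected)) < 5e-3
        assert abs(A[0] - np.pi / 2) < 3e-3

    def test_duplicate_points_error(self):
        pts = np.array([[0.0, 5.0], [0.0, 5.0], [0.0, 0.0]])
        ms = MidlineSeries([MidlineFrame(0.0, pts)], 0.25)
        with pytest.raises(MalformedInputError):
            orientation_profile(ms, s_step=1.0)


# ---------------------------------------------------------------------------
# curvature
# ---------------------------------------------------------------------------

class TestCurvature:
    def test_straight_organ_zero_curvature(self):
        orient = orientation_profile(line_midlines(angle=0.3))
        curv = curvature_profile(orient)
        assert np.nanmax(np.abs(curv.masked_values())) < 1e-9

    @pytest.mark.parametrize("radius", [5.0, 20.0, 100.0])
    def test_circle_oracle(self, radius):
        # |C| = 1/R everywhere on a circular arc, within 2%
        ms = arc_midlines(radius=radius, span=min(np.pi / 2, 10 / radius + 0.5),
                          n_pts=4001)
        orient = orientation_profile(ms, s_step=radius / 200)
        curv = curvature_profile(orient)
        vals = np.abs(curv.masked_values()[0])
        good = np.isfinite(vals)
        assert np.nanmax(np.abs(vals[good] - 1 / radius)) < 0.02 / radius

    def test_integral_recovers_orientation(self):
        # discrete consistency: cumulative s-integration of C recovers A
        # up to its apex value; exact for a quadratic profile
        s = 0.1 * np.arange(101)
        A = 0.03 * s**2 - 0.2 * s + 0.5
        field = KinematicField(s, np.array([0.0, 0.25]),
                               np.vstack([A, A]), np.ones((2, 101), bool),
                               "orientation")
        curv = curvature_profile(field)
        rec = A[0] + cumulative_trapezoid(curv.values[0], s, initial=0.0)
        assert np.max(np.abs(rec - A)) < 1e-6
        # and the total integral telescopes to the endpoint difference
        assert abs(np.trapezoid(curv.values[0], s) - (A[-1] - A[0])) < 1e-9

    def test_too_few_samples_error(self):
        s = np.array([0.0, 0.1, 0.2])
        vals = np.array([[0.1, 0.2, 0.3]])
        mask = np.array([[True, True, False]])
        field = KinematicField(s, np.array([0.0]), vals, mask, "orientation")
        with pytest.raises(MalformedInputError):
            curvature_profile(field)


# ---------------------------------------------------------------------------
# REGR from marker profiles (1-D DIC)
# ---------------------------------------------------------------------------

def speckle_profile(rng, length=30.0, step=0.02, density=8.0, sigma=0.15):
    """Synthetic marker positions/amplitudes and a renderer."""
    n = int(density * length)
    pos = np.sort(rng.uniform(0, length, n))
    amp = rng.uniform(0.5, 1.0, n)

    def render(marker_s, L):
        grid = step * np.arange(int(np.floor(L / step)) + 1)
        prof = np.zeros(grid.size)
        for p, a in zip(marker_s, amp):
            lo = np.searchsorted(grid, p - 4 * sigma)
            hi = np.searchsorted(grid, p + 4 * sigma)
            prof[lo:hi] += a * np.exp(-0.5 * ((grid[lo:hi] - p) / sigma) ** 2)
        return grid, prof

    return pos, render


class TestRegrFromMarkers:
    def test_identical_frames_zero(self):
        rng = np.random.default_rng(0)
        pos, render = speckle_profile(rng)
        prof = render(pos, 30.0)
        series = MarkerProfileSeries(np.array([0.0, 0.25, 0.5]),
                                     [prof, prof, prof], 0.02)
        field = regr_from_markers(series, baseline=1)
        # the 3-point parabolic subpixel fit carries a pattern-dependent
        # bias of ~0.1 sample even at zero true displacement
        assert np.nanmax(np.abs(field.masked_values())) < 2e-3

    @pytest.mark.parametrize("strain_rate", [0.005, 0.02, 0.05])
    def test_uniform_strain_recovered(self, strain_rate):
        # stretch about the apex by (1 + e*dt) per frame: REGR = e
        rng = np.random.default_rng(1)
        pos, render = speckle_profile(rng)
        dt = 0.25
        factors = [1.0, 1 + strain_rate * dt, (1 + strain_rate * dt) ** 2]
        series = MarkerProfileSeries(
            dt * np.arange(3), [render(pos * f, 30.0 * f) for f in factors], 0.02)
        field = regr_from_markers(series, baseline=1)
        vals = field.masked_values()[0]
        good = np.isfinite(vals)
        est = np.median(vals[good])
        assert abs(est - strain_rate) < 0.05 * strain_rate

    def test_step_profile_localized(self):
        # stretch only material with s < 10 mm: step REGR profile with the
        # transition confined to about one window width
        rng = np.random.default_rng(2)
        pos, render = speckle_profile(rng)
        dt, e = 0.25, 0.04
        def displace(p):
            return np.where(p < 10.0, p * (1 + e * dt), p + 10.0 * e * dt)
        series = MarkerProfileSeries(
            dt * np.arange(2), [render(pos, 30.0), render(displace(pos), 30.4)],
            0.02)
        field = regr_from_markers(series, baseline=1)
        vals = field.masked_values()[0]
        s = field.s_grid
        inner = np.isfinite(vals) & (s > 3) & (s < 8)
        outer = np.isfinite(vals) & (s > 13) & (s < 25)
        assert abs(np.median(vals[inner]) - e) < 0.2 * e
        assert np.abs(np.median(vals[outer])) < 0.1 * e

    def test_flat_profile_masked(self):
        grid = 0.02 * np.arange(1000)
        flat = np.ones(grid.size)
        series = MarkerProfileSeries(np.array([0.0, 0.25]),
                                     [(grid, flat), (grid, flat)], 0.02)
        field = regr_from_markers(series, baseline=1)
        assert field.mask.sum() == 0

    def test_needs_two_frames(self):
        grid = 0.02 * np.arange(1000)
        series = MarkerProfileSeries(np.array([0.0]), [(grid, grid % 1)], 0.02)
        with pytest.raises(MalformedInputError):
            regr_from_markers(series)


# ---------------------------------------------------------------------------
# material derivative of curvature
# ---------------------------------------------------------------------------

def _mk(s, t, vals, quantity):
    vals = np.asarray(vals, float)
    return KinematicField(s, t, vals, np.ones_like(vals, bool), quantity)


class TestMaterialDerivative:
    s = 0.1 * np.arange(151)
    t = 0.25 * np.arange(40)

    def test_zero_regr_reduces_to_time_derivative(self):
        S, T = np.meshgrid(self.s, self.t)
        C = 0.1 * np.sin(S) * np.exp(-T / 5)
        curv = _mk(self.s, self.t, C, "curvature")
        regr = _mk(self.s, self.t, np.zeros_like(C), "regr")
        out = material_curvature_derivative(curv, regr)
        dCdt = np.gradient(C, self.t, axis=0)
        assert np.allclose(out.values[out.mask], dCdt[out.mask], atol=1e-12)

    def test_static_curvature_uniform_regr(self):
        # time-independent C with uniform REGR e0: DC/Dt = e0 * s * dC/ds
        e0 = 0.03
        C1 = 0.2 * np.sin(0.5 * self.s)
        C = np.tile(C1, (self.t.size, 1))
        curv = _mk(self.s, self.t, C, "curvature")
        regr = _mk(self.s, self.t, np.full_like(C, e0), "regr")
        out = material_curvature_derivative(curv, regr)
        expected = e0 * self.s * np.gradient(C1, self.s)
        mid = out.values[5, 2:-2]
        assert np.max(np.abs(mid - expected[2:-2])) < 1e-4

    def test_comoving_wave_is_stationary(self):
        # C(s,t) = sin(k(s - vt)) riding on advection velocity v: the
        # material derivative vanishes.  REGR is concentrated near the
        # apex so that its cumulative integral equals v beyond s = w.
        k, v, w = 0.8, 1.3, 0.5
        s = 0.05 * np.arange(301)
        t = 0.05 * np.arange(100)
        S, T = np.meshgrid(s, t)
        C = np.sin(k * (S - v * T))
        # triangular REGR pulse at the apex: piecewise linear, so the
        # discrete trapezoid integral equals v exactly beyond s = w
        E = np.where(S <= w, 2 * v / w * (1 - S / w), 0.0)
        out = material_curvature_derivative(
            _mk(s, t, C, "curvature"), _mk(s, t, E, "regr"))
        beyond = (S > w + 0.2) & out.mask
        inner = np.abs(out.values[beyond & (S > s[2]) & (S < s[-3])
                                  & (T > t[1]) & (T < t[-2])])
        assert inner.max() < 1e-3

    def test_comoving_point_tracking_oracle(self):
        # advect a material point with the velocity field and finite-
        # difference C along its trajectory; compare with the field op
        s, t = self.s, self.t
        S, T = np.meshgrid(s, t)
        C = 0.15 * np.sin(0.6 * S + 0.4 * T) + 0.05 * S / 15
        e0 = 0.02
        E = np.full_like(C, e0)  # uniform REGR: v(s) = e0 * s
        curv = _mk(s, t, C, "curvature")
        regr = _mk(s, t, E, "regr")
        out = material_curvature_derivative(curv, regr)

        def C_at(si, ti):
            return 0.15 * np.sin(0.6 * si + 0.4 * ti) + 0.05 * si / 15

        for s0 in (3.0, 7.0, 11.0):
            for ti in (2.0, 5.0):
                dt = 1e-3
                # trajectory: ds/dt = e0 * s -> s(t) = s0 * exp(e0 (t-t0))
                s_plus = s0 * np.exp(e0 * dt)
                s_minus = s0 * np.exp(-e0 * dt)
                oracle = (C_at(s_plus, ti + dt) - C_at(s_minus, ti - dt)) / (2 * dt)
                i = np.argmin(np.abs(t - ti))
                j = np.argmin(np.abs(s - s0))
                assert abs(out.values[i, j] - oracle) < 1e-3

    def test_grid_mismatch_error(self):
        curv = _mk(self.s, self.t, np.zeros((self.t.size, self.s.size)),
                   "curvature")
        regr = _mk(self.s[:-1], self.t,
                   np.zeros((self.t.size, self.s.size - 1)), "regr")
        with pytest.raises(ValueError):
            material_curvature_derivative(curv, regr)

    def test_advection_velocity_cumulative(self):
        E = np.full((self.t.size, self.s.size), 0.04)
        regr = _mk(self.s, self.t, E, "regr")
        v = advection_velocity(regr)
        assert np.allclose(v[0], 0.04 * self.s, atol=1e-12)


# ---------------------------------------------------------------------------
# temporal averages
# ---------------------------------------------------------------------------

class TestTemporalAverage:
    def test_constant_field(self):
        f = _mk(np.arange(5.0), np.arange(4.0), np.full((4, 5), -2.5), "wave")
        out = temporal_field_average(f, t_split=1.5)
        assert out["overall"] == out["pre"] == out["post"] == 2.5

    def test_sign_flip_at_split(self):
        vals = np.ones((8, 5))
        vals[4:] = -1.0
        f = _mk(np.arange(5.0), np.arange(8.0), vals, "wave")
        out = temporal_field_average(f, t_split=3.0)
        assert out["pre"] == 1.0 and out["post"] == 1.0

    def test_checkerboard(self):
        vals = np.indices((6, 6)).sum(axis=0) % 2 * 2.0 - 1.0
        vals *= 0.7
        f = _mk(np.arange(6.0), np.arange(6.0), vals, "wave")
        assert temporal_field_average(f)["overall"] == pytest.approx(0.7)

    def test_empty_support_error(self):
        f = KinematicField(np.arange(3.0), np.arange(3.0), np.zeros((3, 3)),
                           np.zeros((3, 3), bool), "wave")
        with pytest.raises(ValueError):
            temporal_field_average(f)
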