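"""Circular statistics: day/angle mapping, von Mises density, fitting,
central intervals and circular distances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import vonmises as scipy_vonmises

from phenoscreen import (
    CircularSample,
    angle_to_day,
    circ_dist_days,
    day_to_angle,
    vm_central_halfwidth,
    vm_cdf,
    vm_fit,
    vm_logpdf,
)
from phenoscreen.circular import KAPPA_MAX, bessel_ratio, inv_bessel_ratio

TWO_PI = 2 * np.pi


class TestDayAngleMapping:
    def test_anchor_points(self):
        assert day_to_angle(0.0, 365.25) == 0.0
        assert day_to_angle(365.25 / 2, 365.25) == pytest.approx(np.pi)

    @given(st.floats(-1000, 1000))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_identity(self, d):
        period = 365.25
        back = angle_to_day(day_to_angle(d, period), period)
        # compare on the circle: values straddling 0/period are identical
        assert circ_dist_days(back, d % period, period) == pytest.approx(
            0.0, abs=1e-9)

    def test_bad_period_fatal(self):
        with pytest.raises(ValueError):
            day_to_angle(10.0, 0.0)
        with pytest.raises(ValueError):
            angle_to_day(1.0, -1.0)


class TestCircularDistance:
    @pytest.mark.parametrize("d1, d2, expected", [
        (100.0, 145.0, 45.0),
        (360.0, 10.0, 15.25),   # wraps across the year boundary
        (50.0, 50.0, 0.0),
    ])
    def test_known_distances(self, d1, d2, expected):
        assert circ_dist_days(d1, d2, 365.25) == pytest.approx(expected)

    @given(st.floats(0, 400), st.floats(0, 400))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_bounds(self, a, b):
        d = circ_dist_days(a, b)
        assert d == pytest.approx(circ_dist_days(b, a))
        assert 0 <= d <= 365.25 / 2 + 1e-9


class TestLogDensity:
    def test_uniform_limit(self):
        theta = np.linspace(0, TWO_PI, 7)
        np.testing.assert_allclose(vm_logpdf(theta, 1.0, 0.0),
                                   np.log(1 / TWO_PI))

    @pytest.mark.parametrize("kappa", [0.5, 2.0, 10.0])
    def test_density_maximal_at_mean(self, kappa):
        mu = 1.3
        others = mu + np.array([-2.0, -0.5, 0.3, 2.9])
        assert np.all(vm_logpdf(mu, mu, kappa) > vm_logpdf(others, mu, kappa))

    @pytest.mark.parametrize("kappa", [0.5, 2.0, 10.0])
    def test_integrates_to_one(self, kappa):
        # independent quadrature oracle for the normalising constant
        total, err = quad(lambda t: np.exp(vm_logpdf(t, 2.0, kappa)),
                          0.0, TWO_PI, limit=200)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_negative_kappa_fatal(self):
        with pytest.raises(ValueError):
            vm_logpdf(0.0, 0.0, -1.0)


class TestFit:
    def test_constant_series_degenerate_concentration(self):
        s = CircularSample(np.full(5, 100.0))
        f = vm_fit(s)
        assert f.mean_day() == pytest.approx(100.0, abs=1e-9)
        assert f.kappa == KAPPA_MAX

    def test_antipodal_pair_is_uniform(self):
        s = CircularSample(np.array([0.0, 365.25 / 2]))
        f = vm_fit(s)
        assert f.rbar == pytest.approx(0.0, abs=1e-12)
        assert f.kappa == pytest.approx(0.0, abs=1e-10)

    def test_matches_grid_search_mle(self, rng):
        # brute-force maximization of the log-likelihood over (mu, kappa)
        # via sufficient statistics, at grid resolution
        theta = rng.vonmises(np.pi / 2, 4.0, 2000) % TWO_PI
        f = vm_fit(CircularSample(angle_to_day(theta)))
        C, S, n = np.cos(theta).sum(), np.sin(theta).sum(), theta.size
        mu_grid = np.linspace(0, TWO_PI, 4000, endpoint=False)
        kappa_grid = np.linspace(0.01, 20, 2000)
        from scipy.special import i0e
        ll = (kappa_grid[:, None] * (np.cos(mu_grid)[None, :] * C
                                     + np.sin(mu_grid)[None, :] * S - n)
              - n * np.log(TWO_PI * i0e(kappa_grid))[:, None])
        ki, mi = np.unravel_index(np.argmax(ll), ll.shape)
        assert f.mu == pytest.approx(mu_grid[mi], abs=TWO_PI / 4000 * 1.5)
        assert f.kappa == pytest.approx(kappa_grid[ki], abs=20 / 2000 * 1.5)

    def test_agrees_with_scipy_mle(self, rng):
        # independent implementation cross-check
        theta = rng.vonmises(1.0, 3.0, 500)
        f = vm_fit(CircularSample(angle_to_day(theta % TWO_PI)))
        kappa_sp, loc_sp, _ = scipy_vonmises.fit(theta, fscale=1)
        assert f.mu == pytest.approx(loc_sp % TWO_PI, abs=1e-3)
        assert f.kappa == pytest.approx(kappa_sp, rel=1e-2)

    @given(st.floats(0, TWO_PI))
    @settings(max_examples=25, deadline=None)
    def test_rotation_equivariance(self, shift):
        days = np.array([100.0, 110.0, 130.0, 95.0, 160.0, 120.0])
        period = 365.25
        base = vm_fit(CircularSample(days, period))
        shifted = vm_fit(CircularSample(
            (days + shift * period / TWO_PI) % period, period))
        assert shifted.kappa == pytest.approx(base.kappa, abs=1e-10)
        dmu = (shifted.mu - base.mu - shift) % TWO_PI
        assert min(dmu, TWO_PI - dmu) == pytest.approx(0.0, abs=1e-9)

    def test_empty_sample_fatal(self):
        with pytest.raises(ValueError):
            CircularSample(np.array([]))


class TestKappaInversion:
    @given(st.floats(0, 1 - 1e-6))
    @settings(max_examples=100, deadline=None)
    def test_bessel_ratio_round_trip(self, rbar):
        kappa = inv_bessel_ratio(rbar)
        if kappa < KAPPA_MAX:
            assert float(bessel_ratio(kappa)) == pytest.approx(rbar, abs=1e-10)

    def test_clips_at_cap(self):
        assert inv_bessel_ratio(1.0) == KAPPA_MAX


class TestCentralInterval:
    def test_uniform_closed_form(self):
        for p in (0.1, 0.5, 0.9999367):
            assert vm_central_halfwidth(0.0, p) == pytest.approx(p * np.pi)

    def test_monotone_in_mass(self):
        widths = [vm_central_halfwidth(2.0, p)
                  for p in (0.1, 0.3, 0.5, 0.9, 0.99, 0.9999)]
        assert np.all(np.diff(widths) > 0)

    def test_quadrature_mass_matches(self):
        # mass of [mu-delta, mu+delta] recomputed by direct quadrature
        delta = vm_central_halfwidth(2.0, 0.95)
        mass, _ = quad(lambda t: np.exp(vm_logpdf(t, 0.0, 2.0)),
                       -delta, delta, limit=200)
        assert mass == pytest.approx(0.95, abs=1e-8)

    def test_gaussian_limit(self):
        # large kappa: VM ~ N(mu, 1/kappa); 95% half-width -> 1.96/sqrt(kappa)
        hw = vm_central_halfwidth(50.0, 0.95)
        assert hw == pytest.approx(1.959964 / np.sqrt(50.0), rel=0.02)

    def test_concentrated_limit_shrinks_to_zero(self):
        assert vm_central_halfwidth(KAPPA_MAX, 0.95) < 0.1

    def test_bad_mass_fatal(self):
        for p in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                vm_central_halfwidth(1.0, p)


class TestCdf:
    def test_uniform_cdf_linear(self):
        assert vm_cdf(np.pi / 2, 0.0, 0.0) == pytest.approx(0.75)

    def test_mass_below_mean_is_half(self):
        for kappa in (0.5, 2.0, 10.0):
            assert vm_cdf(1.0, 1.0, kappa) == pytest.approx(0.5, abs=1e-9)
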