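"""Electrical shape-factor model, per-event fits, cumulative pooling."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from nanopulse import (
    CumulativeEstimate,
    PoreSpec,
    blockade,
    cumulative_update,
    depolarization,
    effective_pore_volume,
    filtered_orientation_quantiles,
    fit_event,
    intraevent_pdf,
    shape_factor,
    shape_factor_extremes,
)
from nanopulse.shape import SPHERE_GAMMA, EventShapeEstimate, _weighted_median


def depolarization_integral(m: float) -> float:
    """Numeric oracle: L_par = (a^2 b / 2) * Int ds / ((b^2+s)^{3/2} (a^2+s))
    for an ellipsoid of revolution with semiaxes (a, a, b), b = m a."""
    a, b = 1.0, m

    def integrand(s):
        return 1.0 / ((b * b + s) ** 1.5 * (a * a + s))

    val, _ = quad(integrand, 0.0, np.inf)
    return 0.5 * a * a * b * val


class TestDepolarization:
    @pytest.mark.parametrize("m", [0.2, 0.3, 0.5, 0.8, 1.2, 2.0, 5.0])
    def test_matches_integral_oracle(self, m):
        assert depolarization(m) == pytest.approx(depolarization_integral(m), rel=1e-8)

    def test_sphere_is_one_third(self):
        assert depolarization(1.0) == pytest.approx(1.0 / 3.0)
        # continuity across the branch point
        assert depolarization(1.0 - 1e-7) == pytest.approx(1.0 / 3.0, abs=1e-6)
        assert depolarization(1.0 + 1e-7) == pytest.approx(1.0 / 3.0, abs=1e-6)

    def test_limits_and_validation(self):
        assert 0.0 < depolarization(10.0) < 1.0 / 3.0  # prolate: L_par -> 0
        assert 1.0 / 3.0 < depolarization(0.1) < 1.0  # oblate: L_par -> 1
        with pytest.raises(ValueError):
            depolarization(0.0)


class TestShapeFactor:
    def test_sphere_gamma(self):
        assert shape_factor(1.0, 0.0) == pytest.approx(SPHERE_GAMMA)
        assert shape_factor(1.0, math.pi / 2) == pytest.approx(SPHERE_GAMMA)

    def test_extreme_ordering(self):
        g_par, g_perp = shape_factor_extremes(0.5)  # oblate
        assert g_par > g_perp
        g_par, g_perp = shape_factor_extremes(2.0)  # prolate
        assert g_par < g_perp

    def test_interpolation_in_cos2(self):
        m = 0.4
        g_par, g_perp = shape_factor_extremes(m)
        theta = 0.7
        ref = g_perp + (g_par - g_perp) * math.cos(theta) ** 2
        assert shape_factor(m, theta) == pytest.approx(ref)

    def test_theta_domain(self):
        with pytest.raises(ValueError):
            shape_factor(1.0, 3.0)


class TestBlockade:
    def test_effective_volume_oracle(self):
        # (pi/4) * 20^2 * (30 + 0.8*20) = (pi/4) * 400 * 46
        assert effective_pore_volume(20.0, 30.0) == pytest.approx(
            math.pi / 4.0 * 400.0 * 46.0
        )

    def test_blockade_formula(self):
        pore = PoreSpec(diameter=20.0, length=30.0, open_current=-10_000.0)
        d_i = blockade(1.5, 150.0, pore, -10_000.0)
        assert d_i == pytest.approx(-10_000.0 * 1.5 * 150.0 / 14451.3262, rel=1e-4)

    def test_blockade_bound(self):
        pore = PoreSpec()
        with pytest.raises(ValueError):
            blockade(1.5, 50_000.0, pore, -10_000.0)


class TestIntraeventPdf:
    @pytest.mark.parametrize("m", [0.5, 2.0])
    def test_normalized_and_supported(self, m):
        pore = PoreSpec()
        grid, pdf = intraevent_pdf(m, 300.0, pore, -10_000.0, noise_sd=20.0)
        area = np.trapezoid(pdf, grid)
        assert area == pytest.approx(1.0, abs=0.02)
        g_par, g_perp = shape_factor_extremes(m)
        k = 10_000.0 * 300.0 / effective_pore_volume(20.0, 30.0)
        lo, hi = k * min(g_par, g_perp), k * max(g_par, g_perp)
        mass_inside = np.trapezoid(pdf[(grid > lo - 80) & (grid < hi + 80)],
                               grid[(grid > lo - 80) & (grid < hi + 80)])
        assert mass_inside > 0.97

    def test_noise_free_singularity_side(self):
        pore = PoreSpec()
        grid, pdf_o = intraevent_pdf(0.5, 300.0, pore, -10_000.0, noise_sd=0.0)
        # oblate: common orientations near theta = pi/2 -> density peaks at
        # the small-|dI| end
        lo_half = np.trapezoid(pdf_o[: grid.size // 2], grid[: grid.size // 2])
        assert lo_half > 0.6
        grid, pdf_p = intraevent_pdf(2.0, 300.0, pore, -10_000.0, noise_sd=0.0)
        hi_half = np.trapezoid(pdf_p[grid.size // 2 :], grid[grid.size // 2 :])
        assert hi_half > 0.6


class TestFilteredOrientationQuantiles:
    def test_monotone_unit_interval(self):
        q = filtered_orientation_quantiles(16_667.0, 500_000.0, 50_000.0)
        assert q.shape == (2048,)
        assert np.all(np.diff(q) >= 0)
        assert q[0] >= 0.0 and q[-1] <= 1.0

    def test_cached(self):
        q1 = filtered_orientation_quantiles(16_667.0, 500_000.0, 50_000.0)
        q2 = filtered_orientation_quantiles(16_667.0, 500_000.0, 50_000.0)
        assert q1 is q2

    def test_mean_preserved_by_filtering(self):
        # linear filtering preserves E[cos^2 theta] = 1/3
        q = filtered_orientation_quantiles(16_667.0, 500_000.0, 50_000.0)
        assert np.mean(q) == pytest.approx(1.0 / 3.0, abs=0.02)


def _synthetic_magnitudes(m, volume, pore, i0, noise_sd, n, rng):
    """Draw |dI| samples from the instantaneous tumbling-ellipsoid model."""
    g_par, g_perp = shape_factor_extremes(m)
    c2 = rng.uniform(0.0, 1.0, n) ** 2  # cos(theta) ~ U(0,1) on the sphere
    gamma = g_perp + (g_par - g_perp) * c2
    k = abs(i0) * volume / effective_pore_volume(pore.diameter, pore.length)
    return k * gamma + rng.normal(0.0, noise_sd, n)


class TestFitEvent:
    @pytest.mark.parametrize("m,branch", [(0.5, "oblate"), (2.0, "prolate")])
    def test_recovers_m_and_v(self, m, branch):
        pore = PoreSpec()
        rng = np.random.default_rng(0)
        x = _synthetic_magnitudes(m, 300.0, pore, -10_000.0, 10.0, 4000, rng)
        est = fit_event(x, 10.0, pore, -10_000.0)
        assert est.branch == branch
        assert est.m_hat == pytest.approx(m, rel=0.10)
        assert est.v_hat == pytest.approx(300.0, rel=0.05)
        assert est.converged

    def test_min_samples(self):
        pore = PoreSpec()
        with pytest.raises(ValueError):
            fit_event(np.ones(5), 10.0, pore, -10_000.0)

    def test_near_sphere_reports_small_anisotropy(self):
        pore = PoreSpec()
        rng = np.random.default_rng(1)
        x = _synthetic_magnitudes(1.0, 300.0, pore, -10_000.0, 5.0, 4000, rng)
        est = fit_event(x, 5.0, pore, -10_000.0)
        g_par, g_perp = shape_factor_extremes(est.m_hat)
        assert max(g_par, g_perp) / min(g_par, g_perp) < 1.2
        assert est.v_hat == pytest.approx(300.0, rel=0.10)


class TestCumulative:
    def test_weighted_median_oracle(self):
        assert _weighted_median([1.0, 2.0, 10.0], [1.0, 1.0, 1.0]) == 2.0
        assert _weighted_median([1.0, 2.0, 10.0], [5.0, 1.0, 1.0]) == 1.0
        assert _weighted_median([3.0], [0.5]) == 3.0

    def test_min_dwell_filter(self):
        acc = CumulativeEstimate()
        est = EventShapeEstimate(10.0, 20.0, 0.5, 300.0, "oblate", 0.01)
        cumulative_update(acc, est, 50e-6)  # below the 150 us gate
        assert acc.n_events == 0
        cumulative_update(acc, est, 400e-6)
        assert acc.n_events == 1
        assert acc.m_hat == 0.5
        assert acc.v_hat == 300.0
        assert acc.cumulative_residence_s == pytest.approx(400e-6)

    def test_unconverged_skipped(self):
        acc = CumulativeEstimate()
        bad = EventShapeEstimate(10.0, 20.0, 0.5, 300.0, "oblate", 0.5, converged=False)
        cumulative_update(acc, bad, 1e-3)
        assert acc.n_events == 0
        with pytest.raises(ValueError):
            _ = acc.m_hat

    def test_residence_weighting_dominates(self):
        acc = CumulativeEstimate()
        long_est = EventShapeEstimate(10.0, 20.0, 0.5, 300.0, "oblate", 0.01)
        short_est = EventShapeEstimate(10.0, 30.0, 2.0, 500.0, "prolate", 0.01)
        cumulative_update(acc, long_est, 10e-3)
        for _ in range(3):
            cumulative_update(acc, short_est, 200e-6)
        # the long event outweighs three short outliers
        assert acc.m_hat == 0.5
        assert len(acc.m_series) == 4
        assert acc.residence_series[-1] == pytest.approx(10.6e-3)
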