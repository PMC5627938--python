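"""Refractory-density transport: weight bins, hazard, density bookkeeping."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

from cbrd_iid import _kernels as K
from cbrd_iid.cbrd_core import (HazardParams, PopulationState, TStarGrid,
                                WeightDistribution, advance_density,
                                build_lognormal_bins, firing_rate, hazard_rate,
                                map_bin_voltages, mean_voltage)


def make_state(n=20, k=1, bound=20.0):
    grid = TStarGrid(bound, n)
    w = WeightDistribution.delta() if k == 1 else build_lognormal_bins(0.5, k)
    return PopulationState(grid=grid, weights=w)


class TestLognormalBins:
    def test_masses_sum_to_one(self):
        w = build_lognormal_bins(0.5, 10)
        assert w.n_bins == 10
        assert abs(w.bin_masses.sum() - 1.0) < 1e-12
        assert np.all(np.diff(w.bin_scales) > 0)

    def test_single_bin(self):
        w = build_lognormal_bins(0.5, 1)
        assert w.n_bins == 1
        assert w.bin_masses[0] == 1.0

    def test_printed_density_normalised(self):
        # integral over (0, inf) of the weight density is 1
        sig = 0.5
        val, _ = quad(lambda x: math.exp(-math.log(x) ** 2 / (2 * sig ** 2))
                      / (math.sqrt(2 * math.pi) * sig * x), 1e-12, np.inf)
        assert abs(val - 1.0) < 1e-8

    def test_moments(self):
        # median 1, mean exp(sigma^2/2) for the as-printed parameterisation
        w = build_lognormal_bins(0.5, 200)
        mean = float(w.bin_masses @ w.bin_scales)
        assert abs(mean - math.exp(0.125)) < 2e-3
        below = w.bin_masses[w.bin_scales < 1.0].sum()
        assert abs(below - 0.5) < 0.01

    def test_mean_normalised_variant(self):
        w = build_lognormal_bins(0.5, 50, mean_normalize=True)
        assert abs(float(w.bin_masses @ w.bin_scales) - 1.0) < 1e-3

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            build_lognormal_bins(0.5, 0)
        with pytest.raises(ValueError):
            build_lognormal_bins(-1.0, 5)


class TestHazard:
    params = HazardParams()

    def test_ftilde_at_zero(self):
        # closed form sqrt(2/pi); cross-checked against numerical quadrature
        # of the underlying Gaussian flux expression
        assert abs(K.ftilde(0.0) - math.sqrt(2.0 / math.pi)) < 1e-12
        num = math.sqrt(2 / math.pi) * math.exp(0.0) / (1 + math.erf(0.0))
        assert abs(K.ftilde(0.0) - num) < 1e-12

    def test_far_subthreshold(self):
        p = self.params
        h = hazard_rate(p.v_th_base - 10 * p.sigma_v0, 0.5, 50.0, 0.05, p)
        assert h < 1e-6

    def test_drift_term_requires_depolarisation(self):
        p = self.params
        # at large t* the threshold is static; without depolarisation B = 0
        h_still = hazard_rate(-50.0, 0.0, 500.0, 0.05, p)
        h_repol = hazard_rate(-50.0, -2.0, 500.0, 0.05, p)
        h_depol = hazard_rate(-50.0, +2.0, 500.0, 0.05, p)
        assert h_repol == pytest.approx(h_still, rel=1e-12)
        assert h_depol > h_still

    def test_monotone_in_voltage(self):
        p = self.params
        u = np.linspace(-80.0, -20.0, 60)
        h = hazard_rate(u, 0.0, 500.0, 0.05, p)
        assert np.all(np.diff(h) >= 0)

    def test_zero_in_spike_window(self):
        p = self.params
        assert hazard_rate(0.0, 5.0, 0.5 * p.dt_ap, 0.05, p) == 0.0

    def test_clamped(self):
        p = self.params
        h = hazard_rate(0.0, 100.0, 50.0, 0.05, p, h_max=10.0)
        assert h <= 10.0

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            hazard_rate(np.nan, 0.0, 50.0, 0.05, self.params)


class TestAdvanceDensity:
    def test_pure_translation(self):
        st_ = make_state()
        h = np.zeros_like(st_.rho)
        t0 = st_.t_star.copy()
        advance_density(st_, h, 0.1)
        assert st_.nu == 0.0
        np.testing.assert_allclose(st_.total_mass(), 1.0, atol=1e-14)
        assert np.all((st_.t_star - t0 == pytest.approx(0.1)) | (st_.t_star == 0.0))

    def test_constant_hazard_mass_halving(self):
        st_ = make_state()
        dt = 0.1
        h_val = math.log(2.0) / dt
        i = int(np.argmax(st_.rho.sum(axis=1)))
        h = np.zeros_like(st_.rho)
        h[i, :] = h_val
        advance_density(st_, h, dt)
        total = st_.rho.sum() + st_.flux.sum()
        assert abs(total - 1.0) < 1e-12
        assert st_.flux.sum() + st_.rho[np.argmax(st_.t_star)].sum() \
            == pytest.approx(1.0, abs=1e-12)

    def test_renewal_limit(self):
        # constant hazard h, no spike window: long-run nu converges to h
        st_ = make_state(n=50, bound=50.0)
        dt = 0.1
        h_val = 0.02  # 1/ms
        h = np.full_like(st_.rho, h_val)
        for _ in range(40000):
            advance_density(st_, h, dt)
        assert st_.nu == pytest.approx(h_val, rel=5e-3)

    def test_mass_conserved_many_steps(self):
        st_ = make_state(n=20, k=3)
        rng = np.random.default_rng(0)
        h = rng.uniform(0.0, 0.5, st_.rho.shape)
        for _ in range(5000):
            advance_density(st_, h, 0.1)
        np.testing.assert_allclose(st_.total_mass(), 1.0, atol=1e-9)

    def test_shape_mismatch(self):
        st_ = make_state()
        with pytest.raises(ValueError):
            advance_density(st_, np.zeros((3, 3)), 0.1)


class TestFiringRateAndVoltages:
    def test_zero_hazard(self):
        st_ = make_state(k=4)
        assert firing_rate(st_, np.zeros_like(st_.rho)) == 0.0

    def test_two_bin_weighted_mean(self):
        grid = TStarGrid(10.0, 5)
        w = WeightDistribution(0.5, np.array([0.5, 2.0]), np.array([0.5, 0.5]))
        st_ = PopulationState(grid=grid, weights=w)
        st_.rho[:] = 0.0
        st_.rho[0, 0] = 1.0
        st_.rho[0, 1] = 1.0
        h = np.zeros_like(st_.rho)
        h[0, 0], h[0, 1] = 0.4, 0.6
        assert firing_rate(st_, h) == pytest.approx(0.5 * 0.4 + 0.5 * 0.6)

    def test_identical_bins_match_single_bin(self):
        st1 = make_state(k=1)
        stk = make_state(k=6)
        h1 = np.full_like(st1.rho, 0.3)
        hk = np.full_like(stk.rho, 0.3)
        assert firing_rate(stk, hk) == pytest.approx(firing_rate(st1, h1))

    @given(st.floats(-20.0, 20.0))
    def test_affine_map(self, pert):
        w = WeightDistribution(0.5, np.array([0.0 + 1e-9, 1.0, 2.0]),
                               np.array([0.3, 0.4, 0.3]))
        u_free = np.array([-65.0])
        u = u_free + pert
        ux = map_bin_voltages(u, u_free, w)
        assert ux[0, 1] == pytest.approx(u[0])
        assert ux[0, 0] == pytest.approx(u_free[0], abs=1e-6)
        assert ux[0, 2] - u_free[0] == pytest.approx(2 * pert, abs=1e-9)

    def test_mean_voltage_against_bruteforce(self, rng):
        grid = TStarGrid(10.0, 8)
        w = build_lognormal_bins(0.5, 4)
        st_ = PopulationState(grid=grid, weights=w)
        st_.rho = rng.uniform(0.1, 1.0, st_.rho.shape)
        st_.rho /= st_.rho.sum(axis=0)
        st_.u = rng.uniform(-80.0, -40.0, 8)
        st_.u_free = rng.uniform(-70.0, -60.0, 8)
        expected = 0.0
        norm = 0.0
        for i in range(8):
            for kk in range(4):
                ux = st_.u_free[i] + (st_.u[i] - st_.u_free[i]) * w.bin_scales[kk]
                expected += w.bin_masses[kk] * st_.rho[i, kk] * ux
                norm += w.bin_masses[kk] * st_.rho[i, kk]
        assert mean_voltage(st_) == pytest.approx(expected / norm, rel=1e-12)

    def test_uniform_voltage(self):
        st_ = make_state(k=3)
        st_.u[:] = -60.0
        st_.u_free[:] = -60.0
        assert mean_voltage(st_) == pytest.approx(-60.0)


class TestGrids:
    def test_probe_positions(self):
        g = TStarGrid(100.0, 100)
        p = g.probe_positions
        assert len(p) == 100 and p[0] == 0.0 and p[-1] < 100.0
        assert np.all(np.diff(p) > 0)

    def test_invalid(self):
        with pytest.raises(ValueError):
            TStarGrid(100.0, 1)
        with pytest.raises(ValueError):
            WeightDistribution(0.5, np.array([1.0]), np.array([0.5]))
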