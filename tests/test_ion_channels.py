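"""Channel kinetics, membrane equations, thresholds and reset rules."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cbrd_iid import _kernels as K
from cbrd_iid.ion_channels import (ChannelDef, ExcitatoryParams,
                                   InterneuronParams, advance_excitatory_membrane,
                                   advance_gates, apply_reset, channel_current,
                                   dendritic_synaptic_current, resting_state,
                                   somatic_synaptic_current, steady_gates,
                                   threshold_voltage)
from cbrd_iid.mc_oracle import simulate_ensemble
from cbrd_iid.network import NetworkConfig, OUParams, simulate
import dataclasses


DR = ChannelDef("DR", 0.76, -70.0)
M = ChannelDef("M", 0.4, -80.0)
KCH = ChannelDef("K", 40.0, -80.0)


class TestRateFunctions:
    def test_dr_symmetry_point(self):
        # a = b at U = -5 mV, so the activation steady state is 1/2
        _, x_inf, _, _ = K.dr_rates(-5.0)
        assert x_inf == pytest.approx(0.5)

    def test_kdr_symmetry_point(self):
        _, n_inf = K.kdr_rates(-10.0)
        assert n_inf == pytest.approx(0.5)

    def test_m_rates_at_minus_45(self):
        tau, x_inf = K.m_rates(-45.0)
        assert x_inf == pytest.approx(0.5)
        assert tau == pytest.approx(1.0 / 0.006 + 8.0, rel=1e-12)

    @given(st.floats(-120.0, 60.0))
    def test_rates_well_formed(self, u):
        for fn in (K.dr_rates, K.a_rates):
            tau_x, x_inf, tau_y, y_inf = fn(u)
            assert tau_x > 0 and tau_y > 0
            assert 0.0 <= x_inf <= 1.0 and 0.0 <= y_inf <= 1.0
        for fn in (K.m_rates, K.ahp_rates, K.kdr_rates):
            tau, x_inf = fn(u)
            assert tau > 0 and 0.0 <= x_inf <= 1.0


class TestChannelCurrent:
    def test_zero_at_reversal(self):
        assert channel_current(DR, -70.0, [0.5, 0.5]) == 0.0
        assert channel_current(KCH, -80.0, [0.9]) == 0.0

    def test_exponents(self):
        a = ChannelDef("A", 4.36, -70.0)
        i1 = channel_current(a, -50.0, [0.5, 0.5])
        expected = 4.36 * 0.5 ** 4 * 0.5 ** 3 * (-50.0 + 70.0)
        assert i1 == pytest.approx(expected)
        assert channel_current(KCH, -40.0, [0.5]) \
            == pytest.approx(40.0 * 0.5 ** 4 * 40.0)

    def test_unknown_channel(self):
        with pytest.raises(ValueError):
            ChannelDef("NaV", 1.0, 50.0)


class TestAdvanceGates:
    def test_fixed_point(self):
        g = steady_gates(-60.0, "E")
        for ch, idx in (("DR", (0, 1)), ("A", (2, 3))):
            c = ChannelDef(ch, 1.0, -70.0)
            out = advance_gates(c, -60.0, g[list(idx)], 1.0)
            np.testing.assert_allclose(out, g[list(idx)], rtol=1e-12)

    def test_long_step_reaches_steady_state(self):
        out = advance_gates(M, -45.0, [0.9], 1e6)
        assert out[0] == pytest.approx(0.5, abs=1e-6)

    @given(st.lists(st.floats(-100.0, 20.0), min_size=5, max_size=30))
    def test_gates_stay_bounded(self, voltages):
        g = np.array([0.5, 0.5])
        for u in voltages:
            g = advance_gates(DR, u, g, 0.5)
            assert np.all(g >= 0.0) and np.all(g <= 1.0)

    def test_rejects_bad_dt(self):
        with pytest.raises(ValueError):
            advance_gates(M, -45.0, [0.5], 0.0)


class TestThreshold:
    def test_asymptotes(self):
        assert threshold_voltage(1e9, "E") == pytest.approx(-40.0)
        assert threshold_voltage(1e9, "I") == pytest.approx(-50.0)

    def test_e_at_10ms(self):
        assert threshold_voltage(10.0, "E") == pytest.approx(-40.0 + 50.0 / np.e)

    def test_relaxation_from_reset(self):
        t = np.linspace(0.0, 60.0, 100)
        v = threshold_voltage(t, "I")
        assert v[0] == pytest.approx(-30.0)
        assert np.all(np.diff(v) < 0)


class TestSynapticCurrents:
    def test_somatic(self):
        assert somatic_synaptic_current(0.5, -65.0, -50.0) == pytest.approx(7.5)
        assert somatic_synaptic_current(0.5, -50.0, -50.0) == 0.0
        assert somatic_synaptic_current(0.5, -40.0, -50.0) < 0

    def test_dendritic_operator(self):
        p = ExcitatoryParams().membrane
        # stationary drive: derivative term vanishes
        out = dendritic_synaptic_current(2.0, 2.0, p, 0.1)
        assert out == pytest.approx((1.0 + p.ell / 2.0) * 2.0)
        # step of height 1: one-step overshoot of l*tau_m0/2/dt
        out = dendritic_synaptic_current(1.0, 0.0, p, 0.1)
        assert out == pytest.approx((1.0 + p.ell / 2.0) + p.ell * p.tau_m0 / 2.0 / 0.1)

    def test_degenerate_operator(self):
        p = dataclasses.replace(ExcitatoryParams(), ell=1e-12).membrane
        out = dendritic_synaptic_current(1.0, 0.0, p, 0.1)
        assert out == pytest.approx(1.0, abs=1e-9)


class TestMembrane:
    def test_resting_stationarity(self):
        # at the self-consistent equilibrium nothing moves
        p = ExcitatoryParams()
        u0, ud0 = resting_state(p, "E")
        n = 4
        u = np.full(n, u0)
        ud = np.full(n, ud0)
        gates = np.tile(steady_gates(u0, "E")[:, None], (1, n))
        dprev = np.zeros(n)
        tstar = np.full(n, 50.0)
        for _ in range(200):
            advance_excitatory_membrane(u, ud, gates, dprev, tstar,
                                        0.0, 0.0, 0.0, -70.0, 0.25, 0.0, p, 0.1)
        assert np.all(np.abs(u - u0) < 1e-6)
        assert np.all(np.abs(ud - ud0) < 1e-6)

    def test_steady_state_matches_linear_solve(self):
        # channels off: the 2x2 linear system has a closed-form fixed point
        p = dataclasses.replace(ExcitatoryParams(), g_dr=0.0, g_a=0.0,
                                g_m=0.0, g_ahp=0.0)
        i0 = 1.0
        g_cs = 2.0 * p.gamma / p.ell * p.g_l
        g_cd = 2.0 / p.ell * p.g_l
        a = np.array([[p.g_l + g_cs, -g_cs], [-g_cd, p.g_l + g_cd]])
        b = np.array([p.g_l * p.v_rest + i0, p.g_l * p.v_rest])
        u_exp, ud_exp = np.linalg.solve(a, b)
        n = 1
        u = np.array([p.v_rest])
        ud = np.array([p.v_rest])
        gates = np.zeros((6, n))
        dprev = np.zeros(n)
        tstar = np.full(n, 50.0)
        for _ in range(40000):
            advance_excitatory_membrane(u, ud, gates, dprev, tstar,
                                        0.0, 0.0, 0.0, -70.0, 0.25, i0, p, 0.1)
        assert u[0] == pytest.approx(u_exp, abs=1e-6)
        assert ud[0] == pytest.approx(ud_exp, abs=1e-6)

    def test_pinned_probe_is_immobile(self):
        p = ExcitatoryParams()
        u = np.array([p.v_reset])
        ud = np.array([p.v_rest])
        gates = np.full((6, 1), 0.3)
        dprev = np.zeros(1)
        tstar = np.array([0.5 * p.dt_ap])
        advance_excitatory_membrane(u, ud, gates, dprev, tstar,
                                    0.5, 0.5, 0.5, -50.0, 0.25, 5.0, p, 0.1)
        assert u[0] == p.v_reset and ud[0] == p.v_rest
        assert np.all(gates == 0.3)


class TestResets:
    def test_hard_and_incremental(self):
        gates = np.zeros((6, 3))
        gates[:, 2] = [0.9, 0.9, 0.9, 0.9, 0.0, 0.0]  # flux-peak probe
        apply_reset("E", gates, recycled=0, peak_idx=2)
        assert gates[K.GE_XDR, 0] == pytest.approx(0.262)
        assert gates[K.GE_YDR, 0] == pytest.approx(0.473)
        assert gates[K.GE_XA, 0] == pytest.approx(0.743)
        assert gates[K.GE_YA, 0] == pytest.approx(0.691)
        # M increment from x(t*_p) = 0 gives exactly the increment fraction
        assert gates[K.GE_XM, 0] == pytest.approx(0.175)
        assert gates[K.GE_W, 0] == pytest.approx(0.018)

    def test_saturating_increment(self):
        gates = np.zeros((6, 2))
        gates[K.GE_XM, 1] = 1.0
        apply_reset("E", gates, recycled=0, peak_idx=1)
        assert gates[K.GE_XM, 0] == pytest.approx(1.0)

    def test_silent_recycling_keeps_slow_gates(self):
        gates = np.zeros((6, 2))
        gates[K.GE_XM, 0] = 0.4
        gates[K.GE_W, 0] = 0.1
        apply_reset("E", gates, recycled=0, peak_idx=None)
        assert gates[K.GE_XM, 0] == pytest.approx(0.4)
        assert gates[K.GE_W, 0] == pytest.approx(0.1)

    def test_interneuron_reset(self):
        gates = np.zeros((1, 2))
        apply_reset("I", gates, recycled=1, peak_idx=0)
        assert gates[0, 1] == pytest.approx(0.45)


class TestSingleNeuronSanity:
    def test_excitatory_adapts(self):
        # deterministic E neuron under constant current: repetitive firing
        # with growing interspike intervals (spike-frequency adaptation)
        p = ExcitatoryParams()
        dt = 0.1
        wave = np.full(30000, 8.0)
        ens = simulate_ensemble(p, "E", 1, wave, dt, 0, sigma_v=0.0)
        isis = np.diff(ens.spike_times)
        assert ens.n_spikes >= 3
        assert np.all(np.diff(isis) > 0)

    def test_interneuron_does_not_adapt(self):
        p = InterneuronParams()
        dt = 0.1
        wave = np.full(30000, 2.5)
        ens = simulate_ensemble(p, "I", 1, wave, dt, 0, sigma_v=0.0)
        isis = np.diff(ens.spike_times)
        assert ens.n_spikes > 20
        # after the first interval the firing is strictly periodic
        assert np.ptp(isis[1:]) < 0.01 * np.mean(isis[1:])

    def test_population_resting_drift(self):
        # zero input: both populations stay at rest for 10 s
        cfg = NetworkConfig(duration=10000.0, burn_in=0.0, seed=0,
                            ou=OUParams(sigma=0.0), n_weight_bins=1)
        silent = {k: dataclasses.replace(v, g_max=0.0)
                  for k, v in cfg.synapses.items()}
        cfg = dataclasses.replace(cfg, synapses=silent)
        tr = simulate(cfg)
        assert np.ptp(tr["U_mean_E"]) < 0.01
        assert np.ptp(tr["U_mean_I"]) < 0.01
        # E sits far below threshold; I retains a tiny intrinsic hazard rate
        assert tr["nu_E"].max() < 1e-6 and tr["nu_I"].max() < 0.5
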