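"""Event detection/statistics, conductance decomposition, GHK fitting."""

import numpy as np
import pandas as pd
import pytest

from cbrd_iid.analysis import (ClampRecordingSet, DetectionThresholds,
                               conductance_ratios, decompose_conductances,
                               detect_events, event_statistics, fit_vgaba_ghk,
                               ghk_current, model_templates)
from cbrd_iid.framework import FixtureSpec, generate_fixture


def rate_trace(duration=60000.0, onsets=(), width=100.0, amp=50.0, dt=1.0):
    t = np.arange(0.0, duration, dt)
    nu = np.zeros_like(t)
    for o in onsets:
        nu[(t >= o) & (t < o + width)] = amp
    return {"time": t, "nu_I": nu, "nu_E": np.zeros_like(t)}


class TestDetection:
    def test_flat_trace(self):
        ev = detect_events(rate_trace())
        assert len(ev) == 0

    def test_planted_boxcars(self):
        onsets = [2000.0, 9000.0, 21000.0]
        ev = detect_events(rate_trace(onsets=onsets))
        assert len(ev) == 3
        np.testing.assert_allclose(ev["onset"], onsets, atol=1.0)
        np.testing.assert_allclose(ev["duration"], 100.0, atol=2.0)

    def test_merge_gap(self):
        # bursts closer than the merge gap collapse into one event
        ev = detect_events(rate_trace(onsets=[1000.0, 1140.0], width=100.0))
        assert len(ev) == 1
        ev2 = detect_events(rate_trace(onsets=[1000.0, 1400.0], width=100.0))
        assert len(ev2) == 2

    def test_min_duration(self):
        ev = detect_events(rate_trace(onsets=[1000.0], width=5.0))
        assert len(ev) == 0

    def test_classification(self):
        tr = rate_trace(onsets=[1000.0])
        tr["nu_E"] = np.where((tr["time"] >= 1020) & (tr["time"] < 1080), 30.0, 0.0)
        ev = detect_events(tr)
        assert list(ev["event_class"]) == ["IID2"]
        ev2 = detect_events(rate_trace(onsets=[1000.0]))
        assert list(ev2["event_class"]) == ["IID1"]

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_events({"time": np.array([]), "nu_I": np.array([])})


class TestStatistics:
    def test_periodic_events(self):
        ev = detect_events(rate_trace(onsets=np.arange(1000.0, 59000.0, 4000.0)))
        st = event_statistics(ev, 60000.0)
        assert st["cv_intervals"] == pytest.approx(0.0, abs=1e-9)

    def test_frequency_arithmetic(self):
        ev = pd.DataFrame({"onset": np.linspace(0, 59000, 12),
                           "duration": np.full(12, 100.0),
                           "peak_i_clamp": np.ones(12)})
        st = event_statistics(ev, 60000.0)
        assert st["frequency_hz"] == pytest.approx(0.2)

    def test_poisson_cv(self, rng):
        intervals = rng.exponential(3000.0, 400)
        onsets = np.cumsum(intervals)
        ev = pd.DataFrame({"onset": onsets, "duration": np.full(400, 50.0),
                           "peak_i_clamp": np.ones(400)})
        st = event_statistics(ev, onsets[-1] + 1000.0)
        assert st["cv_intervals"] == pytest.approx(1.0, abs=0.12)

    def test_single_event_flagged(self):
        ev = pd.DataFrame({"onset": [100.0], "duration": [50.0],
                           "peak_i_clamp": [1.0]})
        st = event_statistics(ev, 60000.0)
        assert not st["cv_defined"]
        assert np.isnan(st["cv_intervals"])


class TestConductanceRatios:
    def make_events(self, ampa, nmda, gaba):
        return pd.DataFrame({
            "onset": np.arange(len(ampa)) * 1000.0,
            "event_class": ["IID1"] * len(ampa),
            "peak_g_ampa": ampa, "peak_g_nmda": nmda, "peak_g_gaba": gaba,
        })

    def test_pure_gaba(self):
        out = conductance_ratios(self.make_events([0.0], [0.0], [2.0]))
        assert out["ampa_over_gaba"].iloc[0] == 0.0

    def test_planted_ratios(self):
        out = conductance_ratios(self.make_events([1.0, 2.0], [0.5, 1.0], [2.0, 4.0]))
        np.testing.assert_allclose(out["ampa_over_gaba"], 0.5)
        np.testing.assert_allclose(out["nmda_over_gaba"], 0.25)

    def test_scale_invariance(self):
        e1 = self.make_events([1.0], [0.5], [2.0])
        e2 = self.make_events([10.0], [5.0], [20.0])
        r1 = conductance_ratios(e1)["ampa_over_gaba"].iloc[0]
        r2 = conductance_ratios(e2)["ampa_over_gaba"].iloc[0]
        assert r1 == pytest.approx(r2)

    def test_zero_gaba_skipped(self):
        out = conductance_ratios(self.make_events([1.0, 1.0], [0.5, 0.5], [0.0, 2.0]))
        assert len(out) == 1


class TestDecomposition:
    def test_exact_recovery_noise_free(self):
        fx = generate_fixture(FixtureSpec(kind="clamp_recording"))
        templates = fx.ground_truth["templates"]
        out = decompose_conductances(fx, templates, bin_ms=1.0)
        np.testing.assert_allclose(out["g_ampa"], fx.ground_truth["g_ampa"],
                                   atol=1e-8)
        np.testing.assert_allclose(out["g_gaba"], fx.ground_truth["g_gaba"],
                                   atol=1e-8)
        np.testing.assert_allclose(out["g_nmda"], fx.ground_truth["g_nmda"],
                                   atol=1e-8)

    def test_gaba_isolated_at_glutamate_reversal(self):
        # recording at V = 0 only: the GABA template alone is nonzero there
        templates = model_templates(-50.0)
        f0 = templates.at(0.0)
        assert f0[0] == pytest.approx(0.0, abs=1e-9)
        assert f0[2] == pytest.approx(0.0, abs=1e-9)
        assert f0[1] == pytest.approx(50.0)

    def test_noise_bias_small(self):
        peak = 8.0 * 50.0  # max |current| scale of the default fixture
        biases = []
        for seed in range(40):
            fx = generate_fixture(FixtureSpec(kind="clamp_recording", seed=seed,
                                              noise_sd=0.05 * peak))
            out = decompose_conductances(fx, fx.ground_truth["templates"], 1.0)
            truth = fx.ground_truth["g_gaba"]
            sel = truth > 0.5 * truth.max()
            biases.append(np.mean(out["g_gaba"][sel] - truth[sel]) / truth.max())
        assert abs(np.mean(biases)) < 0.05

    def test_rank_deficiency_reported(self):
        fx = generate_fixture(FixtureSpec(kind="clamp_recording"))
        bad = ClampRecordingSet(np.array([-50.0, -50.0, -50.0]),
                                fx.currents[:, :3], fx.sample_interval)
        with pytest.raises(ValueError, match="rank deficient"):
            decompose_conductances(bad, fx.ground_truth["templates"], 1.0)


class TestGHK:
    def test_recovers_planted_reversal(self):
        pts, truth = generate_fixture(FixtureSpec(kind="iv_points"))
        fit = fit_vgaba_ghk(pts)
        assert fit["v_gaba"] == pytest.approx(truth["v_gaba"], abs=0.5)

    def test_symmetric_chloride(self):
        v = np.arange(-40.0, 41.0, 10.0)
        i = ghk_current(v, 0.3, 132.5, 132.5)
        fit = fit_vgaba_ghk(np.column_stack([v, i]))
        assert fit["v_gaba"] == pytest.approx(0.0, abs=0.5)

    def test_ohmic_iv_shares_root(self):
        # around the reversal the GHK curve is locally linear, so a linear
        # IV sampled near its zero crossing yields the same root
        v = np.arange(-65.0, -34.0, 5.0)
        i = 0.8 * (v + 50.0)  # linear IV reversing at -50
        fit = fit_vgaba_ghk(np.column_stack([v, i]))
        assert fit["v_gaba"] == pytest.approx(-50.0, abs=1.0)

    def test_near_reversal_reduces_to_nernst(self):
        # sampling only a narrow window around the reversal: the fitted
        # zero crossing collapses onto the Nernst potential
        cl_in = 20.0
        frt = 96485.332 / (8.314462 * 303.15) / 1000.0
        v_rev = np.log(cl_in / 132.5) / frt
        v = np.linspace(v_rev - 4.0, v_rev + 4.0, 9)
        i = ghk_current(v, 0.5, cl_in, 132.5)
        fit = fit_vgaba_ghk(np.column_stack([v, i]))
        assert fit["v_gaba"] == pytest.approx(v_rev, abs=0.2)

    def test_no_sign_change_rejected(self):
        v = np.arange(-40.0, 1.0, 10.0)
        i = np.abs(v) + 1.0
        with pytest.raises(ValueError, match="sign change"):
            fit_vgaba_ghk(np.column_stack([v, i]))
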