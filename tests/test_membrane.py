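"""Passive properties, capacitance estimation, resonance, peak metrics."""

import numpy as np
import pytest

import vestephys as vp
from vestephys import membrane as mem

from conftest import SIM_DT


def rc_model(r_in_gohm, cm_pf, e_rest=-70.0):
    return vp.CellModel(cm_pf, [vp.ConductanceSpec("gLeak", 1.0 / r_in_gohm,
                                                   e_rest)])


def cc_sweep(t, i_cmd, v, rate):
    return vp.Sweep(t, i_cmd, v, "current_clamp", rate)


class TestRestingPotential:
    def test_constant_baseline(self):
        t = np.arange(0, 200, 0.1)
        cmd = np.where(t >= 100, 10.0, 0.0)
        v = np.full(t.size, -87.0)
        assert mem.resting_potential(cc_sweep(t, cmd, v, 10.0)) == -87.0

    def test_noisy_baseline_mean(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 300, 0.05)
        v = -70.0 + rng.normal(0, 1.0, t.size)
        est = mem.resting_potential(cc_sweep(t, np.zeros(t.size), v, 20.0))
        assert est == pytest.approx(-70.0, abs=3 * 1.0 / np.sqrt(1000))

    def test_short_baseline_rejected(self):
        t = np.arange(0, 30, 0.1)
        with pytest.raises(ValueError):
            mem.resting_potential(cc_sweep(t, np.ones(t.size), t * 0, 10.0))

    def test_knockout_type_i_rests_less_negative_than_wildtype(
            self, type_i_wt, type_i_ko):
        assert vp.zero_current_potential(type_i_ko) \
            > vp.zero_current_potential(type_i_wt) + 10.0


class TestPassiveFit:
    @pytest.mark.parametrize("r_in", [0.05, 1.0, 3.0])
    def test_rc_recovery_within_two_percent(self, r_in):
        cm = 5.0
        model = rc_model(r_in, cm)
        amp = 5.0 / r_in * 1e-3 * 5  # ≈5 mV deflection
        rec = vp.simulate_current_clamp(model, [amp], vp.SimConfig(dt=0.002),
                                        baseline_dur=60.0,
                                        step_dur=max(20 * r_in * cm, 10.0),
                                        post_dur=5.0)
        p = mem.fit_passive_response(rec)
        assert p.r_in == pytest.approx(r_in, rel=0.02)
        assert p.tau_rc == pytest.approx(r_in * cm, rel=0.02)
        assert p.cm_est == pytest.approx(p.tau_rc / p.r_in, rel=1e-12)

    def test_all_large_responses_rejected(self):
        model = rc_model(1.0, 5.0)
        rec = vp.simulate_current_clamp(model, [100.0], vp.SimConfig(dt=0.01),
                                        baseline_dur=60, step_dur=50,
                                        post_dur=5)
        with pytest.raises(ValueError, match="smaller"):
            mem.fit_passive_response(rec)

    def test_type_i_knockout_preset_passive(self, type_i_ko):
        rec = vp.simulate_current_clamp(type_i_ko, [-5.0, 5.0],
                                        vp.SimConfig(dt=SIM_DT),
                                        baseline_dur=150, step_dur=300,
                                        post_dur=20)
        p = mem.fit_passive_response(rec)
        assert p.v_rest == pytest.approx(-63.0, abs=2.0)
        assert p.r_in == pytest.approx(1.4, rel=0.25)
        # the K_V7 foot at rest produces a strong delayed-rectifier sag, so
        # the single-exponential τ is convention-sensitive; factor-2 band
        assert 3.2 < p.tau_rc < 12.8


class TestCapacitanceTransient:
    def _vc_step_recording(self, cm, rs_gohm, rm_gohm, dv=-5.0, dt=5e-4):
        """Synthetic two-resistor transient with known parameters."""
        t = np.arange(0, 30, dt)
        v_pre, t_on = -94.0, 5.0
        cmd = np.where(t >= t_on, v_pre + dv, v_pre)
        tau = cm * rs_gohm * rm_gohm / (rs_gohm + rm_gohm)
        i = np.zeros(t.size)
        after = t >= t_on
        ts = t[after] - t_on
        i[after] = dv / (rs_gohm + rm_gohm) + dv * (1 / rs_gohm - 1 / (rs_gohm + rm_gohm)) \
            * np.exp(-ts / tau)
        sweep = vp.Sweep(t, cmd, i, "voltage_clamp", 1 / dt)
        return vp.Recording(vp.RecordingMeta(), vp.build_protocol("type_I"),
                            [sweep] + [sweep.copy()] * 15)

    def test_known_capacitance_recovered(self):
        rec = self._vc_step_recording(cm=6.0, rs_gohm=0.002, rm_gohm=0.5)
        assert mem.estimate_cm_transient(rec) == pytest.approx(6.0, rel=0.05)

    def test_scale_invariance_in_step_size(self):
        a = self._vc_step_recording(6.0, 0.002, 0.5, dv=-2.0)
        b = self._vc_step_recording(6.0, 0.002, 0.5, dv=-8.0)
        assert mem.estimate_cm_transient(a) == pytest.approx(
            mem.estimate_cm_transient(b), rel=1e-6)

    def test_type_ii_preset_capacitance(self, type_ii_wt):
        proto = vp.StepProtocol(holding=-94.0, prestep_v=-94.0, prestep_dur=2.0,
                                step_voltages=[-99.0], step_dur=20.0,
                                tail_v=-94.0, tail_dur=2.0, holding_dur=2.0)
        rec = vp.simulate_voltage_clamp(type_ii_wt, proto,
                                        vp.SimConfig(dt=5e-4, rs_artifact=True))
        assert mem.estimate_cm_transient(rec) == pytest.approx(
            type_ii_wt.cm, rel=0.15)

    def test_undersampled_transient_rejected(self):
        rec = self._vc_step_recording(6.0, 0.002, 0.5, dt=0.05)
        with pytest.raises(ValueError, match="undersampled"):
            mem.estimate_cm_transient(rec)


class TestResonance:
    def _sweep_from_damped_sine(self, fe, te, vp_amp=5.0, theta=-np.pi / 2,
                                dt=0.05, dur=400.0):
        t_step = np.arange(0, dur, dt)
        v_step = -60.0 + vp_amp * np.exp(-t_step / te) \
            * np.sin(2 * np.pi * fe * t_step * 1e-3 - theta)
        t = np.arange(0, dur + 100.0, dt)
        cmd = np.where(t >= 100.0, 20.0, 0.0)
        v = np.concatenate([np.full((t < 100.0).sum(), -65.0), v_step])
        return cc_sweep(t, cmd, v, 1 / dt)

    @pytest.mark.parametrize("fe", [5.0, 20.0, 35.0])
    @pytest.mark.parametrize("te", [5.0, 20.0, 50.0])
    def test_damped_sine_recovery_grid(self, fe, te):
        fit = mem.fit_resonance(self._sweep_from_damped_sine(fe, te))
        assert fit.f_e == pytest.approx(fe, rel=0.01)
        assert fit.tau_e == pytest.approx(te, rel=0.01)

    def test_overdamped_response_tends_to_half(self):
        t = np.arange(0, 500, 0.05)
        cmd = np.where(t >= 100.0, 10.0, 0.0)
        v = np.where(t >= 100.0, -70.0 + 8.0 * (1 - np.exp(-(t - 100.0) / 15.0)),
                     -70.0)
        fit = mem.fit_resonance(cc_sweep(t, cmd, v, 20.0))
        assert fit.q_e == pytest.approx(0.5, abs=0.02)

    def test_knockout_more_resonant_than_wildtype(self, type_ii_wt, type_ii_ko):
        fits = {}
        for name, model in (("wt", type_ii_wt), ("ko", type_ii_ko)):
            rec = vp.simulate_current_clamp(model, [20.0],
                                            vp.SimConfig(dt=SIM_DT),
                                            baseline_dur=150, step_dur=500,
                                            post_dur=20)
            fits[name] = mem.fit_resonance(rec.sweeps[0])
        assert fits["ko"].q_e > fits["wt"].q_e


class TestQualityFactor:
    def test_closed_form_value(self):
        assert mem.quality_factor(19.6, 20.0) == pytest.approx(1.329, abs=0.001)

    def test_unity_when_product_is_sqrt3_over_2(self):
        # π f τ = √3/2 → Q = 1
        fe = 10.0
        te = np.sqrt(3) / 2 / (np.pi * fe) * 1e3
        assert mem.quality_factor(fe, te) == pytest.approx(1.0, rel=1e-12)

    def test_overdamped_limit_and_lower_bound(self):
        assert mem.quality_factor(0.0, 10.0) == 0.5
        for fe in (0.0, 1.0, 50.0, 300.0):
            assert mem.quality_factor(fe, 7.0) >= 0.5


class TestPeakMetrics:
    def test_triangle_pulse_exact(self):
        dt = 0.05
        t = np.arange(0, 300, dt)
        cmd = np.where(t >= 100.0, 50.0, 0.0)
        v = np.full(t.size, -70.0)
        rise = (t >= 110.0) & (t < 120.0)
        fall = (t >= 120.0) & (t < 130.0)
        v[rise] = -70.0 + (t[rise] - 110.0)  # 10 mV triangle
        v[fall] = -70.0 + 10.0 - (t[fall] - 120.0)
        pm = mem.peak_metrics(cc_sweep(t, cmd, v, 1 / dt))
        assert pm.height == pytest.approx(10.0, abs=0.5)
        assert pm.time_to_peak == pytest.approx(20.0, abs=1.0)
        assert pm.width_half_max == pytest.approx(10.0, abs=1.0)

    def test_flat_response_flagged_absent(self):
        t = np.arange(0, 300, 0.1)
        cmd = np.where(t >= 100.0, 50.0, 0.0)
        pm = mem.peak_metrics(cc_sweep(t, cmd, np.full(t.size, -70.0), 10.0))
        assert pm.absent

    def test_wildtype_peaks_faster_than_knockout(self, type_ii_wt, type_ii_ko):
        t2p = {}
        for name, model in (("wt", type_ii_wt), ("ko", type_ii_ko)):
            rec = vp.simulate_current_clamp(model, [170.0],
                                            vp.SimConfig(dt=SIM_DT),
                                            baseline_dur=150, step_dur=300,
                                            post_dur=20)
            t2p[name] = mem.peak_metrics(rec.sweeps[0]).time_to_peak
        assert t2p["wt"] < t2p["ko"]
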