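"""Simulator: presets, oracle equivalence, gating invariants, noise."""

import numpy as np
import pytest

import vestephys as vp
from vestephys import synth
from vestephys.synth import IntegrationError

from conftest import SIM_DT, step_trace


class TestPresets:
    def test_type_i_wildtype_carries_gkl_table_means(self, type_i_wt):
        gkl = type_i_wt["gKL"]
        assert gkl.activation.v_half == -85.0
        assert gkl.activation.s == 4.3
        assert gkl.g_max == 270.0
        assert type_i_wt.cm == 6.1
        with pytest.raises(KeyError):
            type_i_wt["gA"]  # no A-current in type I cells

    def test_type_i_knockout_residual_rectifier(self, type_i_ko):
        kv7 = type_i_ko["gDR_Kv7"]
        assert kv7.activation.v_half == -40.2
        assert kv7.activation.s == 5.7
        assert kv7.g_max == 5.4

    def test_type_ii_knockout_is_kv7_only(self, type_ii_ko):
        names = {c.name for c in type_ii_ko.conductances}
        assert "gA" not in names and "gDR_Kv1.8" not in names
        assert "gDR_Kv7" in names

    def test_type_ii_wildtype_has_a_current_and_h_inf(self, type_ii_wt):
        ga = type_ii_wt["gA"]
        assert ga.inactivation.v_half == -42.0
        assert ga.inactivation.s == 11.0
        assert ga.inactivation.tau_fast == 23.0
        assert ga.inactivation.tau_fast < ga.inactivation.tau_slow

    def test_unknown_combination_lists_valid_keys(self):
        with pytest.raises(KeyError, match="type_I"):
            vp.make_preset("type_III", "+/+", "LES")

    def test_every_preset_builds_and_rests_in_range(self):
        for key in synth.preset_keys():
            model = vp.make_preset(*key)
            v0 = vp.zero_current_potential(model)
            assert -95.0 < v0 < -55.0, key


class TestOracleEquivalence:
    @pytest.mark.parametrize("preset", [
        ("type_I", "+/+", "LES"), ("type_II", "+/+", "striola"),
    ])
    def test_fixed_v_ode_matches_closed_form(self, preset):
        """The exponential-integrator trajectory at clamped V must equal the
        analytic activation × bi-exponential-inactivation step current."""
        model = vp.make_preset(*preset)
        kind = "type_I" if preset[0] == "type_I" else "type_II"
        proto = vp.build_protocol(kind)
        rec = vp.simulate_voltage_clamp(model, proto, vp.SimConfig(dt=SIM_DT))
        for v_step, sweep in zip(proto.step_voltages, rec.sweeps):
            sel = (sweep.time >= proto.t_step) & (sweep.time < proto.t_tail)
            t = sweep.time[sel] - proto.t_step
            i_ana = np.zeros_like(t)
            for c in model.conductances:
                st = synth._history_states(c, proto.holding, proto.prestep_v,
                                           proto.prestep_dur)
                i_ana += vp.analytic_step_current(c, v_step, t, *st)
            scale = max(np.sqrt(np.mean(i_ana ** 2)), 1e-9)
            rms = np.sqrt(np.mean((sweep.response[sel] - i_ana) ** 2)) / scale
            assert rms < 1e-3

    def test_analytic_limits(self):
        spec = vp.ConductanceSpec(
            "g", g_max=10.0, e_rev=-86.0,
            activation=vp.GateSpec(-30.0, 8.0, tau=2.0, power=3),
            inactivation=vp.InactivationSpec(-42.0, 11.0, z_total=0.4,
                                             f_fast=0.5, tau_fast=20.0,
                                             tau_slow=150.0),
        )
        t = np.array([1e5])
        i_inf = vp.analytic_step_current(spec, 30.0, t, m0=0.0)[0]
        expected = 10.0 * spec.activation.ss(30.0) \
            * (1.0 - spec.inactivation.z(30.0)) * (30.0 + 86.0)
        assert i_inf == pytest.approx(expected, rel=1e-9)
        # starting at steady state, the activation factor stays constant
        m_inf = float(spec.activation.gate_inf(30.0))
        t = np.linspace(0.0, 50.0, 11)
        i = vp.analytic_step_current(spec, 30.0, t, m0=m_inf, hf0=1.0, hs0=1.0)
        no_inact = vp.ConductanceSpec("g", 10.0, -86.0, spec.activation)
        i_flat = vp.analytic_step_current(no_inact, 30.0, t, m0=m_inf)
        np.testing.assert_allclose(i_flat, i_flat[0])
        assert np.all(np.diff(i) < 0)  # only inactivation evolves

    def test_cubed_activation_from_rest_matches_power_form(self):
        spec = vp.ConductanceSpec("g", 5.0, -86.0,
                                  vp.GateSpec(-20.0, 9.0, tau=2.11, power=3))
        t = np.linspace(0.0, 30.0, 301)
        i = vp.analytic_step_current(spec, 30.0, t, m0=0.0)
        m_inf = float(spec.activation.gate_inf(30.0))
        expected = 5.0 * (m_inf * (1 - np.exp(-t / 2.11))) ** 3 * (30.0 + 86.0)
        np.testing.assert_allclose(i, expected, rtol=1e-12)


class TestSimulatorBehavior:
    def test_zero_conductances_give_pure_leak(self):
        model = vp.CellModel(5.0, [vp.ConductanceSpec("gLeak", 2.0, -50.0)])
        proto = vp.build_protocol("type_II", step_voltages=[-124.0, -44.0, 6.0])
        rec = vp.simulate_voltage_clamp(model, proto, vp.SimConfig(dt=0.05))
        for v_step, sweep in zip(proto.step_voltages, rec.sweeps):
            sel = (sweep.time >= proto.t_step) & (sweep.time < proto.t_tail)
            np.testing.assert_allclose(sweep.response[sel],
                                       2.0 * (v_step + 50.0), rtol=1e-12)

    def test_type_i_prestep_shows_inward_transient(self, type_i_wt_rec):
        """Hyperpolarization to −124 mV through open g_K,L channels produces
        the hallmark decaying inward current."""
        proto = type_i_wt_rec.protocol
        sweep = type_i_wt_rec.sweeps[0]
        sel = (sweep.time >= proto.t_prestep) & (sweep.time < proto.t_step)
        i_pre = sweep.response[sel]
        assert i_pre[0] < -1000.0  # large inward at onset
        assert i_pre[-1] > i_pre[0]  # decays toward leak as channels close

    def test_gates_stay_in_unit_interval(self, type_ii_wt):
        proto = vp.build_protocol("type_II", step_voltages=[-124.0, -44.0, 26.0])
        for c in type_ii_wt.conductances:
            for seg_v in (-124.0, -44.0, 26.0, -64.0):
                st = synth._history_states(c, -64.0, seg_v, 500.0)
                assert all(0.0 <= x <= 1.0 for x in st)
        rec = vp.simulate_current_clamp(type_ii_wt, [100.0],
                                        vp.SimConfig(dt=SIM_DT),
                                        baseline_dur=50, step_dur=100,
                                        post_dur=20)
        v = rec.sweeps[0].response
        assert np.all(np.isfinite(v)) and np.all(np.abs(v) < 200)

    def test_steady_state_conductance_sum(self, type_ii_wt):
        """At strong depolarization the steady-state conductance approaches
        Σ g_max·(1−Z) of the activated K_V conductances."""
        model = type_ii_wt
        v = 30.0
        proto = vp.build_protocol("type_II", step_voltages=[v],
                                  step_dur=3000.0)
        rec = vp.simulate_voltage_clamp(model, proto, vp.SimConfig(dt=0.05))
        sweep = rec.sweeps[0]
        i_end = sweep.response[np.argmin(np.abs(sweep.time - (proto.t_tail - 1)))]
        i_expected = sum(c.ss_current(v) for c in model.conductances)
        assert i_end == pytest.approx(i_expected, rel=0.01)

    def test_dt_stability_guard(self, type_ii_wt):
        with pytest.raises(IntegrationError, match="too coarse"):
            vp.simulate_voltage_clamp(type_ii_wt, vp.build_protocol("type_II"),
                                      vp.SimConfig(dt=1.0))

    def test_current_clamp_rests_at_zero_current_potential(self, type_ii_ko):
        rec = vp.simulate_current_clamp(type_ii_ko, [0.0],
                                        vp.SimConfig(dt=SIM_DT),
                                        baseline_dur=100, step_dur=200,
                                        post_dur=10)
        v = rec.sweeps[0].response
        v0 = vp.zero_current_potential(type_ii_ko)
        assert np.max(np.abs(v - v0)) < 0.1

    def test_type_i_wildtype_rests_near_e_k(self, type_i_wt):
        v0 = vp.zero_current_potential(type_i_wt)
        assert abs(v0 - type_i_wt.e_k) < 3.0


class TestNoise:
    def test_zero_sd_identity_and_seed_determinism(self, type_i_ko_rec):
        cfg0 = vp.SimConfig(noise_sd=0.0, seed=3)
        out0 = vp.add_noise(type_i_ko_rec, cfg0)
        np.testing.assert_array_equal(out0.sweeps[0].response,
                                      type_i_ko_rec.sweeps[0].response)
        cfg = vp.SimConfig(noise_sd=5.0, seed=42)
        a = vp.add_noise(type_i_ko_rec, cfg)
        b = vp.add_noise(type_i_ko_rec, cfg)
        for sa, sb in zip(a.sweeps, b.sweeps):
            np.testing.assert_array_equal(sa.response, sb.response)

    def test_sample_sd_matches_requested(self, type_i_ko_rec):
        sd = 7.5
        noisy = vp.add_noise(type_i_ko_rec, vp.SimConfig(noise_sd=sd, seed=1))
        diff = np.concatenate([
            n.response - c.response
            for n, c in zip(noisy.sweeps, type_i_ko_rec.sweeps)
        ])
        assert diff.size >= 1e4
        assert np.std(diff) == pytest.approx(sd, rel=0.05)
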