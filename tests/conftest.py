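import numpy as np
import pytest

import vestephys as vp

SIM_DT = 0.02  # ms; exponential-integrator gate updates are exact at fixed V


@pytest.fixture(scope="session")
def type_i_wt():
    return vp.make_preset("type_I", "+/+", "LES")


@pytest.fixture(scope="session")
def type_i_ko():
    return vp.make_preset("type_I", "-/-", "LES")


@pytest.fixture(scope="session")
def type_ii_wt():
    return vp.make_preset("type_II", "+/+", "LES")


@pytest.fixture(scope="session")
def type_ii_ko():
    return vp.make_preset("type_II", "-/-", "LES")


@pytest.fixture(scope="session")
def type_i_wt_rec(type_i_wt):
    return vp.simulate_voltage_clamp(type_i_wt, vp.build_protocol("type_I"),
                                     vp.SimConfig(dt=SIM_DT))


@pytest.fixture(scope="session")
def type_i_ko_rec(type_i_ko):
    return vp.simulate_voltage_clamp(type_i_ko, vp.build_protocol("type_I"),
                                     vp.SimConfig(dt=SIM_DT))


@pytest.fixture(scope="session")
def type_ii_wt_rec(type_ii_wt):
    return vp.simulate_voltage_clamp(type_ii_wt, vp.build_protocol("type_II"),
                                     vp.SimConfig(dt=SIM_DT))


@pytest.fixture(scope="session")
def type_ii_ko_rec(type_ii_ko):
    return vp.simulate_voltage_clamp(type_ii_ko, vp.build_protocol("type_II"),
                                     vp.SimConfig(dt=SIM_DT))


def step_trace(recording, at_v=30.0):
    """(t, i) of the test-step segment nearest ``at_v``, blanked, t from onset."""
    proto = recording.protocol
    k = int(np.argmin(np.abs(np.asarray(proto.step_voltages) - at_v)))
    sweep = recording.sweeps[k]
    sel = (sweep.time >= proto.t_step + 0.5) & (sweep.time < proto.t_tail)
    return sweep.time[sel] - proto.t_step, sweep.response[sel]
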