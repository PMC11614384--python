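"""Conductance-based vestibular hair-cell simulator.

Generates voltage-clamp and current-clamp :class:`~vestephys.recording.Recording`
objects from cell presets keyed to hair-cell type, Kcna10 genotype and
utricular zone. Presets carry the population-mean conductance parameters of
the system this package analyzes: type I cells dominated by the large,
negatively activating g_K,L; type II cells with a fast-inactivating A-type
conductance (g_A) plus delayed rectifiers; a K_V7-like residual delayed
rectifier that survives Kcna10 knockout; a lumped HCN/Kir inward conductance;
and an ohmic leak calibrated so that resting potential and input resistance
approximate the measured passive properties.

Gating model
------------
Each conductance has an activation gate ``m`` obeying first-order kinetics
``dm/dt = (m_inf(V) - m)/tau`` with Boltzmann steady state
``m_inf = 1/(1 + exp((v_half - V)/s))``, raised to an integer power ``p``.
For single-gate conductances (g_K,L, the K_V7 rectifier) the conductance
steady state is therefore exactly Boltzmann; for the p = 3 type II
conductances the gate parameters are derived from the target
conductance-level Boltzmann by :func:`gate_from_gv` so a Boltzmann fit of
the simulated G–V recovers the table values closely.
Inactivation is a weighted pair of first-order gates (fast and slow) sharing
the steady state ``1 - Z(V)``; at a fixed voltage, starting from rest, the
total current then follows exactly

    I(t) = Imax * (1 - exp(-t/tau_w))**p
         * [1 - Z*(f*(1-exp(-t/tau_zf)) + (1-f)*(1-exp(-t/tau_zs)))] + I0

which is the closed form implemented independently in
:func:`analytic_step_current` and used as the integration oracle.

Time constants are voltage-independent by default (every fit in the analysis
modules is per-step at fixed voltage, so this loses nothing); a bell-shaped
tau(V) is available per gate for added realism.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .recording import (
    Recording,
    RecordingMeta,
    StepProtocol,
    Sweep,
    nernst_potential,
)

__all__ = [
    "GateSpec",
    "InactivationSpec",
    "ConductanceSpec",
    "CellModel",
    "SimConfig",
    "make_preset",
    "preset_keys",
    "simulate_voltage_clamp",
    "simulate_current_clamp",
    "analytic_step_current",
    "add_noise",
    "zero_current_potential",
]

E_K_DEFAULT = nernst_potential(165.0, 5.77, 25.0)  # ≈ −86.1 mV


def boltzmann_ss(v, v_half: float, s: float):
    """First-order Boltzmann steady state; s < 0 gives a falling curve."""
    return 1.0 / (1.0 + np.exp((v_half - np.asarray(v, dtype=float)) / s))


@dataclass
class GateSpec:
    """First-order gate: Boltzmann steady state and a time constant.

    ``s`` carries the direction (negative for conductances activated by
    hyperpolarization). ``tau_bell = (tau_max, v_peak, width)`` optionally
    makes tau voltage dependent with a Gaussian profile floored at
    ``0.1 * tau_max``.
    """

    v_half: float  # mV
    s: float  # mV
    tau: float  # ms
    power: int = 1
    tau_bell: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.power < 1:
            raise ValueError("power must be >= 1")

    def gate_inf(self, v):
        """Steady state of the gate variable m."""
        return boltzmann_ss(v, self.v_half, self.s)

    def ss(self, v):
        """Steady state of the conductance factor, m_inf ** power."""
        m = self.gate_inf(v)
        return m if self.power == 1 else m ** self.power

    def tau_of(self, v):
        if self.tau_bell is None:
            return np.broadcast_to(np.float64(self.tau), np.shape(v)).copy() \
                if np.shape(v) else float(self.tau)
        tau_max, v_peak, width = self.tau_bell
        tau = tau_max * np.exp(-(((np.asarray(v) - v_peak) / width) ** 2))
        return np.maximum(tau, 0.1 * tau_max)


def gate_from_gv(v_half: float, s: float, tau: float, power: int) -> GateSpec:
    """Gate-level Boltzmann parameters matching a target conductance G–V.

    For classic multi-gate (m^n) kinetics the conductance curve m_inf^n is
    steeper and right-shifted relative to the gate curve; this inverts the
    relation so a Boltzmann fit of the resulting G–V recovers approximately
    (v_half, s): the gate slope is ``s_m = 2 n (1 − 2^(−1/n)) s`` and the
    gate midpoint sits ``s_m · ln(m_half/(1 − m_half))`` below the
    conductance midpoint, matching value and slope at half-activation.
    """
    if power == 1:
        return GateSpec(v_half, s, tau, power=1)
    m_half = 2.0 ** (-1.0 / power)
    s_m = 2.0 * power * (1.0 - m_half) * s
    shift = s_m * np.log(m_half / (1.0 - m_half))
    return GateSpec(v_half - shift, s_m, tau, power=power)


@dataclass
class InactivationSpec:
    """Bi-exponential inactivation: fast/slow gates sharing 1 − Z(V).

    ``Z(V) = z_total * sigma(V)`` rises with depolarization toward the total
    steady-state inactivation depth ``z_total`` (< 1 means incomplete);
    ``f_fast`` is the fraction of the total carried by the fast gate.
    """

    v_half: float  # mV
    s: float  # mV, > 0 (inactivation deepens with depolarization)
    z_total: float  # 0 ≤ z < 1 at full depolarization... z=1 allowed for g_A
    f_fast: float
    tau_fast: float  # ms
    tau_slow: float  # ms

    def __post_init__(self) -> None:
        if not (0.0 <= self.z_total <= 1.0):
            raise ValueError("z_total must be in [0, 1]")
        if not (0.0 <= self.f_fast <= 1.0):
            raise ValueError("f_fast must be in [0, 1]")
        if self.tau_fast <= 0 or self.tau_slow <= 0:
            raise ValueError("inactivation taus must be positive")
        if self.tau_fast >= self.tau_slow:
            raise ValueError("tau_fast must be smaller than tau_slow")

    def z(self, v):
        return self.z_total * boltzmann_ss(v, self.v_half, self.s)

    def h_inf(self, v):
        return 1.0 - self.z(v)


@dataclass
class ConductanceSpec:
    """One membrane conductance: activation gate, optional inactivation.

    ``activation=None`` makes the conductance ohmic (leak).
    """

    name: str
    g_max: float  # nS
    e_rev: float  # mV
    activation: GateSpec | None = None
    inactivation: InactivationSpec | None = None

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ValueError("g_max must be non-negative")

    def ss_open_fraction(self, v):
        """Steady-state open fraction (activation × availability)."""
        frac = 1.0 if self.activation is None else self.activation.ss(v)
        if self.inactivation is not None:
            frac = frac * self.inactivation.h_inf(v)
        return frac

    def ss_current(self, v):
        """Steady-state current in pA at voltage v."""
        return self.g_max * self.ss_open_fraction(v) * (np.asarray(v) - self.e_rev)


@dataclass
class CellModel:
    """A conductance set plus membrane capacitance."""

    cm: float  # pF
    conductances: list[ConductanceSpec]
    e_k: float = E_K_DEFAULT  # mV
    label: str = ""

    def __post_init__(self) -> None:
        if self.cm <= 0:
            raise ValueError("cm must be positive")

    def __getitem__(self, name: str) -> ConductanceSpec:
        for c in self.conductances:
            if c.name == name:
                return c
        raise KeyError(name)

    def total_ss_current(self, v):
        return sum(c.ss_current(v) for c in self.conductances)

    def copy(self) -> "CellModel":
        return CellModel(
            self.cm,
            [dataclasses.replace(
                c,
                activation=dataclasses.replace(c.activation) if c.activation else None,
                inactivation=dataclasses.replace(c.inactivation) if c.inactivation else None,
            ) for c in self.conductances],
            self.e_k, self.label,
        )


@dataclass
class SimConfig:
    """Integration, noise and artifact settings."""

    dt: float = 0.005  # ms
    seed: int = 0
    noise_sd: float = 0.0  # pA (voltage clamp) or mV (current clamp)
    rs_artifact: bool = False
    rs_total: float = 10.0  # MΩ, used when rs_artifact is on
    rs_compensation: float = 0.8

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")


class IntegrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Presets: population-mean parameters per (cell type, genotype, zone).

# Type I activation (tail G–V) and passive properties; extrastriolar zones
# (LES, MES) share the extrastriola columns.
_TYPE_I = {
    # zone-group: genotype: dict
    ("extrastriola", "+/+"): dict(gkl=(-85.0, 4.3, 270.0), cm=6.1, v_rest=-84.0, r_in=0.044),
    ("extrastriola", "+/-"): dict(gkl=(-83.0, 5.2, 210.0), cm=5.8, v_rest=-88.0, r_in=0.055),
    ("extrastriola", "-/-"): dict(gkv7=(-40.2, 5.7, 5.4), cm=5.0, v_rest=-63.0, r_in=1.4),
    ("striola", "+/+"): dict(gkl=(-87.0, 4.3, 310.0), cm=7.4, v_rest=-87.0, r_in=0.050),
    ("striola", "+/-"): dict(gkl=(-88.0, 4.7, 270.0), cm=5.9, v_rest=-87.0, r_in=0.038),
    ("striola", "-/-"): dict(gkv7=(-38.0, 6.2, 6.5), cm=4.4, v_rest=-74.0, r_in=1.0),
}

# Type II whole-cell kinetics at +30 mV (tau_act, tau_inact_fast, fast
# prominence f, % inactivation / 100) and voltage dependence / densities
# (A-type density nS/pF, steady-state V_half, S, density). The residual
# (knockout) delayed rectifier defines the K_V7-like component in every
# genotype of the same zone.
_TYPE_II_KIN = {
    ("LES", "+/+"): (2.11, 23.0, 0.46, 0.45),
    ("LES", "+/-"): (1.64, 15.0, 0.53, 0.51),
    ("MES", "+/+"): (2.8, 50.0, 0.40, 0.42),
    ("MES", "+/-"): (2.2, 90.0, 0.42, 0.47),
    ("striola", "+/+"): (2.7, 50.0, 0.31, 0.39),
    ("striola", "+/-"): (2.9, 300.0, 0.30, 0.28),
}
_TYPE_II_GV = {
    ("LES", "+/+"): (4.0, -25.0, 8.7, 7.1),
    ("LES", "+/-"): (3.8, -26.8, 8.7, 4.9),
    ("MES", "+/+"): (4.1, -26.0, 8.3, 9.0),
    ("MES", "+/-"): (3.6, -27.0, 9.0, 5.9),
    ("striola", "+/+"): (5.0, -26.6, 8.2, 12.0),
    ("striola", "+/-"): (2.6, -28.0, 8.2, 10.0),
}
# K_V7-like residual rectifier per zone: density nS/pF, V_half, S, tau_act.
_TYPE_II_KV7 = {
    "LES": (1.8, -19.0, 12.1, 4.4),
    "MES": (2.5, -20.0, 10.7, 10.0),
    "striola": (3.9, -21.7, 10.5, 7.0),
}
# Passive targets (Table-style ES/striola split): cm, v_rest, r_in (GΩ).
_TYPE_II_PASSIVE = {
    ("extrastriola", "+/+"): (4.7, -71.0, 1.4),
    ("extrastriola", "+/-"): (4.6, -71.0, 1.2),
    ("extrastriola", "-/-"): (4.6, -76.0, 2.3),
    ("striola", "+/+"): (4.6, -73.1, 1.4),
    ("striola", "+/-"): (4.8, -71.0, 1.4),
    ("striola", "-/-"): (4.4, -68.0, 3.0),
}

# K_V7 activation is slow near rest (M-current-like); bell-shaped tau(V)
# peaking near −50 mV, scaled so tau(+30 mV) equals the knockout's measured
# activation time constant. This slow delayed rectifier is what lets
# high-input-resistance knockout cells ring (electrical resonance) while
# the large fast conductances of control cells damp their responses.
_KV7_BELL_PEAK = -50.0  # mV
_KV7_BELL_WIDTH = 55.0  # mV


def _kv7_gate(v_half: float, s: float, tau_at_30: float) -> GateSpec:
    tau_max = tau_at_30 / float(np.exp(-(((30.0 - _KV7_BELL_PEAK)
                                          / _KV7_BELL_WIDTH) ** 2)))
    return GateSpec(v_half, s, tau=tau_at_30, power=1,
                    tau_bell=(tau_max, _KV7_BELL_PEAK, _KV7_BELL_WIDTH))


# Steady-state inactivation (h_inf) of g_A; shared by the K_V1.8 rectifier.
_H_INF_A = (-42.0, 11.0)
# g_A activation from the same protocol set.
_ACT_A = (-23.0, 11.2)

_TAU_GKL = 80.0  # ms; not reported; chosen so 500 ms steps equilibrate while
#                  tail currents decay < 2% in the 1 ms measurement latency
_TAU_ZS = 200.0  # ms; slow inactivation time constant (not reported)

_GENOTYPES = ("+/+", "+/-", "-/-")
_ZONES = ("LES", "MES", "striola")
_ZONE_ALIASES = {"ES": "LES", "extrastriola": "LES", "les": "LES", "mes": "MES",
                 "S": "striola", "Striola": "striola"}


def preset_keys() -> list[tuple[str, str, str]]:
    return [(ct, g, z) for ct in ("type_I", "type_II")
            for g in _GENOTYPES for z in _ZONES]


def _es_group(zone: str) -> str:
    return "striola" if zone == "striola" else "extrastriola"


def _hcn_kir(cell_type: str) -> ConductanceSpec:
    # Lumped HCN/Kir inward conductance: opens below ~−80 mV, reverses at
    # the HCN reversal (−44 mV); carries the inward current at −124 mV.
    g = 2.0 if cell_type == "type_I" else 1.0
    return ConductanceSpec(
        "gHCNKir", g_max=g, e_rev=-44.0,
        activation=GateSpec(v_half=-100.0, s=-7.0, tau=30.0),
    )


def _calibrate_leak(conductances: list[ConductanceSpec], v_rest: float,
                    r_in: float) -> ConductanceSpec:
    """Ohmic leak sized so the model rests at ``v_rest`` with slope
    resistance ``r_in`` (GΩ) there.

    Closed-form: the leak conductance is the target slope conductance minus
    the slope contribution of the gated conductances at rest, and the leak
    reversal balances their standing current. When the gated conductances
    alone exceed the target slope (type I cells with g_K,L open at rest) a
    token 0.1 nS leak at 0 mV is used and the cell rests where g_K,L
    balances the inward currents, i.e. essentially at E_K.
    """
    def i_other(v):
        return sum(c.ss_current(v) for c in conductances)

    dv = 0.01
    slope_other = (i_other(v_rest + dv) - i_other(v_rest - dv)) / (2 * dv)  # nS
    g_leak = 1.0 / r_in - slope_other
    if g_leak < 0.05:
        return ConductanceSpec("gLeak", g_max=0.1, e_rev=0.0)
    e_leak = v_rest + i_other(v_rest) / g_leak
    return ConductanceSpec("gLeak", g_max=float(g_leak), e_rev=float(e_leak))


def _history_states(spec: ConductanceSpec, v_hold: float, prestep_v: float,
                    prestep_dur: float) -> tuple[float, float, float]:
    """Gate states (m, h_fast, h_slow) at the end of hold → prestep."""
    if spec.activation is None:
        m0 = 1.0
    else:
        a = spec.activation
        m_hold = float(a.gate_inf(v_hold))
        m_pre = float(a.gate_inf(prestep_v))
        m0 = m_pre + (m_hold - m_pre) * np.exp(-prestep_dur / float(a.tau_of(prestep_v)))
    if spec.inactivation is None:
        return m0, 1.0, 1.0
    ina = spec.inactivation
    h_hold = float(ina.h_inf(v_hold))
    h_pre = float(ina.h_inf(prestep_v))
    hf0 = h_pre + (h_hold - h_pre) * np.exp(-prestep_dur / ina.tau_fast)
    hs0 = h_pre + (h_hold - h_pre) * np.exp(-prestep_dur / ina.tau_slow)
    return m0, hf0, hs0


def _measured_pct_inact(comps: list[ConductanceSpec], v_hold: float = -64.0,
                        prestep: tuple[float, float] = (-124.0, 50.0),
                        v_step: float = 30.0, window: float = 200.0) -> float:
    """Percent inactivation the analysis would measure on a +30 mV step."""
    t = np.arange(0.0, window + 1e-9, 0.05)
    i = np.zeros_like(t)
    for c in comps:
        m0, hf0, hs0 = _history_states(c, v_hold, *prestep)
        i += analytic_step_current(c, v_step, t, m0, hf0, hs0)
    in_win = t >= 0.5
    peak = float(np.max(i[in_win]))
    return 100.0 * (peak - float(i[-1])) / peak


def _type_ii_kv_set(zone: str, genotype: str) -> list[ConductanceSpec]:
    """Decompose the zone/genotype whole-cell K_V current into components.

    g_A carries all inactivation (fully inactivating, fast fraction and
    τ_inact,fast at the population means); the K_V1.8 delayed rectifier and
    the K_V7 residual are non-inactivating. The g_A density is calibrated
    in closed form so that the *measured* percent inactivation of a 200 ms
    step to +30 mV (raw peak vs end-of-step current, including the
    activation/inactivation kinetic overlap and the baseline inactivation
    left by the standard 50 ms prestep) equals the population mean, while
    the end-of-step ('steady-state') conductance density stays at its
    population mean.
    """
    kv7_dens, kv7_vh, kv7_s, kv7_tau = _TYPE_II_KV7[zone]
    cm = _TYPE_II_PASSIVE[(_es_group(zone), genotype)][0]
    kv7 = ConductanceSpec(
        "gDR_Kv7", g_max=kv7_dens * cm, e_rev=E_K_DEFAULT,
        activation=_kv7_gate(kv7_vh, kv7_s, kv7_tau),
    )
    if genotype == "-/-":
        return [kv7]

    tau_act, tau_zf, f_w, z_w = _TYPE_II_KIN[(zone, genotype)]
    _, ss_vh, ss_s, ss_dens = _TYPE_II_GV[(zone, genotype)]
    tau_zs = max(_TAU_ZS, 2.0 * tau_zf)

    def open_frac_200(spec):
        m0, hf0, hs0 = _history_states(spec, -64.0, -124.0, 50.0)
        i200 = float(analytic_step_current(spec, 30.0, np.array([200.0]),
                                           m0, hf0, hs0)[0])
        return i200 / (spec.g_max * (30.0 - spec.e_rev))

    def build(theta: float) -> list[ConductanceSpec]:
        g_a = ConductanceSpec(
            "gA", g_max=theta * cm, e_rev=E_K_DEFAULT,
            activation=gate_from_gv(*_ACT_A, tau=tau_act, power=3),
            inactivation=InactivationSpec(*_H_INF_A, z_total=1.0, f_fast=f_w,
                                          tau_fast=tau_zf, tau_slow=tau_zs),
        )
        dr_stub = ConductanceSpec(
            "gDR_Kv1.8", g_max=1.0, e_rev=E_K_DEFAULT,
            activation=gate_from_gv(ss_vh, ss_s, tau=tau_act, power=3),
        )
        # size the rectifier so the summed 200 ms density hits the mean
        dr_dens = (ss_dens - theta * open_frac_200(g_a)
                   - kv7_dens * open_frac_200(kv7)) / open_frac_200(dr_stub)
        dr_stub.g_max = max(dr_dens, 0.0) * cm
        return [g_a, dr_stub, kv7]

    target = 100.0 * z_w

    def err(theta):
        return _measured_pct_inact(build(theta)) - target

    # largest g_A density that keeps the K_V1.8 rectifier non-negative
    probe = build(1.0)
    fa = open_frac_200(probe[0])
    fk = open_frac_200(kv7)
    theta_max = max((ss_dens - kv7_dens * fk) / fa, 0.1)
    if err(theta_max) > 0:
        theta = brentq(err, 0.05, theta_max)
    else:
        # target unreachable within 200 ms for this (slow) tau_zf; use the
        # deepest attainable inactivation
        theta = theta_max
    return build(theta)


def make_preset(cell_type: str, genotype: str, zone: str) -> CellModel:
    """Build a cell model from population-mean parameters.

    Parameters
    ----------
    cell_type : {"type_I", "type_II"}
    genotype : {"+/+", "+/-", "-/-"}
    zone : {"LES", "MES", "striola"} (aliases "ES"/"extrastriola" accepted)
    """
    zone = _ZONE_ALIASES.get(zone, zone)
    if cell_type not in ("type_I", "type_II") or genotype not in _GENOTYPES \
            or zone not in _ZONES:
        raise KeyError(
            f"unknown preset ({cell_type}, {genotype}, {zone}); "
            f"valid keys: {preset_keys()}"
        )
    label = f"{cell_type}:{genotype}:{zone}"
    if cell_type == "type_I":
        row = _TYPE_I[(_es_group(zone), genotype)]
        conds: list[ConductanceSpec] = []
        if "gkl" in row:
            vh, s, g = row["gkl"]
            conds.append(ConductanceSpec(
                "gKL", g_max=g, e_rev=E_K_DEFAULT,
                activation=GateSpec(vh, s, tau=_TAU_GKL, power=1),
            ))
        else:
            vh, s, g = row["gkv7"]
            conds.append(ConductanceSpec(
                "gDR_Kv7", g_max=g, e_rev=E_K_DEFAULT,
                activation=_kv7_gate(vh, s, 4.4),
            ))
        cm, v_rest, r_in = row["cm"], row["v_rest"], row["r_in"]
    else:
        conds = _type_ii_kv_set(zone, genotype)
        cm, v_rest, r_in = _TYPE_II_PASSIVE[(_es_group(zone), genotype)]
    conds.append(_hcn_kir(cell_type))
    conds.append(_calibrate_leak(conds, v_rest, r_in))
    return CellModel(cm=cm, conductances=conds, label=label)


# ---------------------------------------------------------------------------
# State handling

def _gate_states_ss(cell: CellModel, v: float) -> dict[str, np.ndarray]:
    """Steady-state gate values at voltage v, keyed by conductance name."""
    states = {}
    for c in cell.conductances:
        m = 1.0 if c.activation is None else float(c.activation.gate_inf(v))
        h = 1.0 if c.inactivation is None else float(c.inactivation.h_inf(v))
        states[c.name] = np.array([m, h, h])  # m, h_fast, h_slow
    return states


def analytic_step_current(
    spec: ConductanceSpec,
    v: float,
    t: np.ndarray,
    m0: float = 0.0,
    hf0: float = 1.0,
    hs0: float = 1.0,
) -> np.ndarray:
    """Closed-form current (pA) of one conductance at fixed voltage.

    First-order gates from arbitrary initial values:
    ``m(t) = m_inf + (m0 - m_inf) e^(−t/tau)``, raised to the gate power,
    times the fast/slow availability mixture. With ``m0 = 0`` and
    ``hf0 = hs0 = 1`` this is exactly the activation/bi-exponential-
    inactivation step-current form used by the kinetics fits.
    """
    t = np.asarray(t, dtype=float)
    if spec.activation is None:
        act = np.ones_like(t)
    else:
        a = spec.activation
        m_inf = float(a.gate_inf(v))
        tau = float(a.tau_of(v))
        m = m_inf + (m0 - m_inf) * np.exp(-t / tau)
        act = m ** a.power
    if spec.inactivation is None:
        h_mix = np.ones_like(t)
    else:
        ina = spec.inactivation
        h_inf = float(ina.h_inf(v))
        hf = h_inf + (hf0 - h_inf) * np.exp(-t / ina.tau_fast)
        hs = h_inf + (hs0 - h_inf) * np.exp(-t / ina.tau_slow)
        h_mix = ina.f_fast * hf + (1.0 - ina.f_fast) * hs
    return spec.g_max * act * h_mix * (v - spec.e_rev)


def _check_dt(cell: CellModel, dt: float) -> None:
    for c in cell.conductances:
        taus = []
        if c.activation is not None:
            taus.append(c.activation.tau if c.activation.tau_bell is None
                        else 0.1 * c.activation.tau_bell[0])
        if c.inactivation is not None:
            taus += [c.inactivation.tau_fast, c.inactivation.tau_slow]
        for tau in taus:
            if tau < 5.0 * dt:
                raise IntegrationError(
                    f"dt={dt} ms too coarse for {c.name} (tau={tau} ms < 5*dt)"
                )


def simulate_voltage_clamp(
    cell: CellModel,
    protocol: StepProtocol,
    config: SimConfig | None = None,
    meta: RecordingMeta | None = None,
) -> Recording:
    """Simulate the whole-cell current response to a step protocol.

    Gates are advanced with an exponential integrator
    ``m <- m_inf + (m - m_inf) exp(-dt/tau)`` (exact for first-order kinetics
    at clamped voltage); the current is the sum over conductances of
    ``g_max · m^p · (f·h_f + (1−f)·h_s) · (V − E_rev)``.
    """
    config = config or SimConfig()
    _check_dt(cell, config.dt)
    dt = config.dt
    steps = list(protocol.step_voltages)
    n_sweeps = len(steps)

    seg_durs = [protocol.holding_dur, protocol.prestep_dur,
                protocol.step_dur, protocol.tail_dur]
    seg_ns = [max(1, round(d / dt)) for d in seg_durs]
    n_total = sum(seg_ns)
    time = np.arange(n_total) * dt

    # state arrays across sweeps: per conductance m, hf, hs of shape (n_sweeps,)
    v0 = protocol.holding
    state = {c.name: np.tile(_gate_states_ss(cell, v0)[c.name][:, None],
                             (1, n_sweeps)) for c in cell.conductances}

    command = np.empty((n_sweeps, n_total))
    response = np.zeros((n_sweeps, n_total))

    seg_voltages = [
        np.full(n_sweeps, protocol.holding),
        np.full(n_sweeps, protocol.prestep_v),
        np.asarray(steps, dtype=float),
        np.full(n_sweeps, protocol.tail_v),
    ]

    idx = 0
    rs_extra = np.zeros((n_sweeps, n_total))
    v_prev = np.full(n_sweeps, v0)
    for v_seg, n_seg in zip(seg_voltages, seg_ns):
        # per-conductance constants for this fixed-voltage segment
        consts = []
        for c in cell.conductances:
            if c.activation is not None:
                a = c.activation
                m_inf = a.gate_inf(v_seg)
                am = np.exp(-dt / a.tau_of(v_seg))
            else:
                m_inf = am = None
            if c.inactivation is not None:
                ina = c.inactivation
                h_inf = ina.h_inf(v_seg)
                af = np.exp(-dt / ina.tau_fast)
                a_s = np.exp(-dt / ina.tau_slow)
            else:
                h_inf = af = a_s = None
            consts.append((c, m_inf, am, h_inf, af, a_s))

        if config.rs_artifact:
            rs_extra[:, idx:idx + n_seg] += _rs_transient(
                cell, config, v_prev, v_seg, state, np.arange(n_seg) * dt)

        for k in range(n_seg):
            i_tot = np.zeros(n_sweeps)
            for (c, m_inf, am, h_inf, af, a_s) in consts:
                m, hf, hs = state[c.name]
                if c.activation is not None:
                    act = m ** c.activation.power
                else:
                    act = 1.0
                if c.inactivation is not None:
                    h_mix = c.inactivation.f_fast * hf \
                        + (1.0 - c.inactivation.f_fast) * hs
                else:
                    h_mix = 1.0
                i_tot += c.g_max * act * h_mix * (v_seg - c.e_rev)
                # advance to the next sample
                if c.activation is not None:
                    state[c.name][0] = m_inf + (m - m_inf) * am
                if c.inactivation is not None:
                    state[c.name][1] = h_inf + (hf - h_inf) * af
                    state[c.name][2] = h_inf + (hs - h_inf) * a_s
            response[:, idx + k] = i_tot
        command[:, idx:idx + n_seg] = v_seg[:, None]
        v_prev = v_seg
        idx += n_seg

    response = response + rs_extra
    meta = meta or RecordingMeta()
    rate = 1.0 / dt  # kHz
    sweeps = [Sweep(time, command[i], response[i], "voltage_clamp", rate)
              for i in range(n_sweeps)]
    rec = Recording(meta, protocol, sweeps, label=cell.label)
    if config.noise_sd > 0:
        rec = add_noise(rec, config)
    return rec


def _rs_transient(cell, config, v_prev, v_new, state, t_seg):
    """Capacitive charging transient through the residual series resistance.

    Emulates the un-subtracted whole-cell transient at a voltage jump with
    the standard two-resistor model: excess current
    ΔV (1/Rs − 1/(Rs+Rm)) e^(−t/τ), τ = Cm·Rs·Rm/(Rs+Rm), where Rm is the
    instantaneous membrane resistance with gates frozen at their pre-jump
    values.
    """
    rs = config.rs_total * (1.0 - config.rs_compensation) * 1e-3  # GΩ
    if rs <= 0:
        return 0.0
    g_inst = np.zeros_like(np.asarray(v_new, dtype=float))
    for c in cell.conductances:
        m, hf, hs = state[c.name]
        act = 1.0 if c.activation is None else m ** c.activation.power
        h = 1.0 if c.inactivation is None else \
            c.inactivation.f_fast * hf + (1 - c.inactivation.f_fast) * hs
        g_inst = g_inst + c.g_max * act * h
    rm = 1.0 / np.maximum(g_inst, 1e-6)  # GΩ
    tau = cell.cm * rs * rm / (rs + rm)  # ms
    dv = np.asarray(v_new) - np.asarray(v_prev)
    ampl = dv * (1.0 / rs - 1.0 / (rs + rm))  # pA
    return ampl[:, None] * np.exp(-t_seg[None, :] / tau[:, None])


def zero_current_potential(cell: CellModel, lo: float = -120.0,
                           hi: float = 20.0) -> float:
    """Voltage where the steady-state whole-cell current vanishes."""
    f = cell.total_ss_current
    grid = np.linspace(lo, hi, 300)
    vals = np.array([f(v) for v in grid])
    sign_change = np.where(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        raise IntegrationError("no zero-current potential in range")
    i = sign_change[0]
    return brentq(f, grid[i], grid[i + 1])


def simulate_current_clamp(
    cell: CellModel,
    current_steps: Sequence[float],
    config: SimConfig | None = None,
    meta: RecordingMeta | None = None,
    baseline_dur: float = 100.0,
    step_dur: float = 400.0,
    post_dur: float = 100.0,
) -> Recording:
    """Simulate voltage responses to injected current steps.

    Integrates ``cm dV/dt = I_inj − ΣI_ion`` with an exponential update for
    V (exact for the instantaneous conductances with gates frozen over one
    dt) interleaved with the gate exponential integrator. The sweep starts
    at the model's zero-current potential (V_rest), holds the baseline, then
    applies the step and a recovery period.
    """
    config = config or SimConfig()
    _check_dt(cell, config.dt)
    dt = config.dt
    steps = list(current_steps)
    n_sweeps = len(steps)
    v_rest = zero_current_potential(cell)

    seg_ns = [max(1, round(d / dt)) for d in (baseline_dur, step_dur, post_dur)]
    n_total = sum(seg_ns)
    time = np.arange(n_total) * dt

    state = {c.name: np.tile(_gate_states_ss(cell, v_rest)[c.name][:, None],
                             (1, n_sweeps)) for c in cell.conductances}
    v = np.full(n_sweeps, v_rest)
    i_inj_segments = [np.zeros(n_sweeps), np.asarray(steps, dtype=float),
                      np.zeros(n_sweeps)]

    command = np.empty((n_sweeps, n_total))
    response = np.empty((n_sweeps, n_total))
    idx = 0
    for i_inj, n_seg in zip(i_inj_segments, seg_ns):
        for k in range(n_seg):
            response[:, idx + k] = v
            command[:, idx + k] = i_inj
            # sum of conductances and their reversal-weighted currents
            g_tot = np.zeros(n_sweeps)
            g_e = np.zeros(n_sweeps)
            for c in cell.conductances:
                m, hf, hs = state[c.name]
                act = 1.0 if c.activation is None else m ** c.activation.power
                h = 1.0 if c.inactivation is None else \
                    c.inactivation.f_fast * hf + (1 - c.inactivation.f_fast) * hs
                g = c.g_max * act * h
                g_tot += g
                g_e += g * c.e_rev
            # V relaxes toward (I_inj + Σ gE)/G with time constant cm/G
            v_inf = (i_inj + g_e) / np.maximum(g_tot, 1e-9)
            v = v_inf + (v - v_inf) * np.exp(-dt * g_tot / cell.cm)
            if np.any(~np.isfinite(v)) or np.any(np.abs(v) > 500):
                raise IntegrationError(
                    f"current-clamp integration diverged at t={time[idx + k]:.3f} ms"
                )
            # advance gates at the updated voltage
            for c in cell.conductances:
                if c.activation is None and c.inactivation is None:
                    continue
                m, hf, hs = state[c.name]
                if c.activation is not None:
                    a = c.activation
                    m_inf = a.gate_inf(v)
                    state[c.name][0] = m_inf + (m - m_inf) * np.exp(-dt / a.tau_of(v))
                if c.inactivation is not None:
                    ina = c.inactivation
                    h_inf = ina.h_inf(v)
                    state[c.name][1] = h_inf + (hf - h_inf) * np.exp(-dt / ina.tau_fast)
                    state[c.name][2] = h_inf + (hs - h_inf) * np.exp(-dt / ina.tau_slow)
        idx += n_seg

    meta = meta or RecordingMeta()
    rate = 1.0 / dt
    sweeps = [Sweep(time, command[i], response[i], "current_clamp", rate)
              for i in range(n_sweeps)]
    rec = Recording(meta, steps, sweeps, label=cell.label)
    if config.noise_sd > 0:
        rec = add_noise(rec, config)
    return rec


def add_noise(recording: Recording, config: SimConfig) -> Recording:
    """Add seeded Gaussian noise to every response trace."""
    if config.noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    out = recording.copy()
    if config.noise_sd == 0:
        return out
    rng = np.random.default_rng(config.seed)
    for sweep in out.sweeps:
        sweep.response = sweep.response + rng.normal(
            0.0, config.noise_sd, size=sweep.response.shape)
    return out
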