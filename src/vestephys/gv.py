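"""Conductance–voltage analysis: G–V curve construction and Boltzmann fits.

Tail G–V curves index the conductance activated by each test step from the
current 1 ms after the step ends, measured at a fixed tail potential; peak
and steady-state G–V curves divide step currents by driving force directly.
Curves are fit with the first-order Boltzmann

    G(V) = G_min + G_max / (1 + exp((V_half − V)/S))

where V_half is the midpoint and S the slope factor. Steady-state
inactivation (h_inf) curves use the falling Boltzmann with S reported
positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np
from scipy.optimize import least_squares

from .recording import Recording, StepProtocol

__all__ = [
    "GVCurve",
    "BoltzmannParams",
    "extract_tail_gv",
    "extract_peak_ss_gv",
    "PeakSSResult",
    "fit_boltzmann",
    "fit_inactivation_curve",
    "conductance_density",
]

BLANK_MS = 0.5  # capacitive-transient blanking at each segment start


class DegenerateDrivingForce(ValueError):
    pass


@dataclass
class GVCurve:
    step_v: np.ndarray  # mV
    g: np.ndarray  # nS
    kind: Literal["tail", "peak", "steady_state", "h_inf"]
    e_k: float
    measure_time: float = np.nan  # ms from step onset (or from step end, tail)

    def __post_init__(self) -> None:
        self.step_v = np.asarray(self.step_v, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.step_v.size != self.g.size:
            raise ValueError("step_v and g must have equal length")
        if not np.all(np.isfinite(self.g)):
            raise ValueError("conductances must be finite")


@dataclass
class BoltzmannParams:
    g_min: float  # nS
    g_max: float  # nS (amplitude above g_min)
    v_half: float  # mV
    s: float  # mV (reported positive for h_inf as well)
    rss: float
    n_points: int
    kind: str = "activation"
    degenerate: bool = False

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        sign = -1.0 if self.kind == "h_inf" else 1.0
        return self.g_min + self.g_max / (1.0 + np.exp(sign * (self.v_half - v) / self.s))


def _sample_at(sweep_time: np.ndarray, t: float) -> int:
    """Index of the sample nearest to time t (nearest-sample convention)."""
    return int(np.argmin(np.abs(sweep_time - t)))


def extract_tail_gv(recording: Recording, e_k: float | None = None) -> GVCurve:
    """Tail G–V: current 1 ms after each test step ends, over driving force.

    G = I(t_step_end + 1 ms) / (V_tail − E_K), plotted against the step
    voltage that preceded the tail.
    """
    protocol = recording.protocol
    if not isinstance(protocol, StepProtocol):
        raise ValueError("tail G–V needs a step-protocol recording")
    if protocol.tail_dur < 2.0:
        raise ValueError("tail segment must be at least 2 ms")
    e_k = recording.meta.e_k if e_k is None else e_k
    drive = protocol.tail_v - e_k
    if abs(drive) < 1.0:
        raise DegenerateDrivingForce(
            f"tail potential {protocol.tail_v} mV within 1 mV of E_K {e_k:.1f} mV"
        )
    t_meas = protocol.t_tail + 1.0
    g = np.array([s.response[_sample_at(s.time, t_meas)] / drive
                  for s in recording.sweeps])
    return GVCurve(np.asarray(protocol.step_voltages), g, "tail", e_k,
                   measure_time=1.0)


class PeakSSResult(NamedTuple):
    peak: GVCurve
    steady_state: GVCurve
    i_inward_124: float | None  # pA; summed HCN/Kir current when a −124 mV step exists


def extract_peak_ss_gv(recording: Recording, e_k: float | None = None,
                       use_fit: bool = True) -> PeakSSResult:
    """Peak and steady-state G–V curves from step currents.

    Peak conductance comes from the maximum of the fitted kinetic model when
    ``use_fit`` (the convention used for population comparisons; robust to
    noise), else from the raw maximum after capacitive blanking. Steady
    state is the current 1 ms before the step ends. Steps within 1 mV of
    E_K are excluded. When the protocol includes a step at −124 mV, the
    steady-state current there (inward; HCN + Kir) is also returned.
    """
    from . import kinetics  # deferred: kinetics is a sibling analysis module

    protocol = recording.protocol
    if not isinstance(protocol, StepProtocol):
        raise ValueError("peak/steady-state G–V needs a step-protocol recording")
    if protocol.step_dur < 200.0:
        raise ValueError("steady-state G–V needs steps of at least 200 ms")
    e_k = recording.meta.e_k if e_k is None else e_k

    step_vs, g_peak, g_ss = [], [], []
    i_124 = None
    for v_step, sweep in zip(protocol.step_voltages, recording.sweeps):
        i0 = _sample_at(sweep.time, protocol.t_step)
        i1 = _sample_at(sweep.time, protocol.t_tail)
        t_seg = sweep.time[i0:i1] - protocol.t_step
        i_seg = sweep.response[i0:i1]
        keep = t_seg >= BLANK_MS
        i_ss = sweep.response[_sample_at(sweep.time, protocol.t_tail - 1.0)]
        if abs(v_step - (-124.0)) < 0.5:
            i_124 = float(i_ss)
        drive = v_step - e_k
        if abs(drive) < 1.0:
            continue
        if use_fit and v_step > e_k:
            choice = kinetics.select_kinetic_model(t_seg[keep], i_seg[keep])
            model_i = choice.fit.predict(t_seg[keep])
            i_peak = float(np.max(model_i))
        else:
            i_peak = float(np.max(i_seg[keep])) if drive > 0 \
                else float(np.min(i_seg[keep]))
        step_vs.append(v_step)
        g_peak.append(i_peak / drive)
        g_ss.append(i_ss / drive)
    peak = GVCurve(np.array(step_vs), np.array(g_peak), "peak", e_k,
                   measure_time=np.nan)
    ss = GVCurve(np.array(step_vs), np.array(g_ss), "steady_state", e_k,
                 measure_time=protocol.step_dur - 1.0)
    return PeakSSResult(peak, ss, i_124)


def _boltzmann_residuals(params, v, g, sign):
    g_min, g_max, v_half, s = params
    model = g_min + g_max / (1.0 + np.exp(sign * (v_half - v) / s))
    return model - g


class FitFailure(RuntimeError):
    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


def fit_boltzmann(curve: GVCurve) -> BoltzmannParams:
    """Least-squares Boltzmann fit of a G–V curve.

    Rising Boltzmann for activation kinds; falling for ``h_inf``. Multi-start
    over midpoint guesses with S bounded to (0.5, 40) mV; V_half is
    initialized at the half-maximum crossing and S from the 10–90% rise
    width (a logistic rises 10→90% over ≈4.4 S).
    """
    v = np.asarray(curve.step_v, dtype=float)
    g = np.asarray(curve.g, dtype=float)
    if v.size < 5:
        raise ValueError("need at least 5 points to fit a Boltzmann")
    sign = -1.0 if curve.kind == "h_inf" else 1.0

    g_lo, g_hi = float(np.min(g)), float(np.max(g))
    span = g_hi - g_lo
    degenerate = span < 1e-3 * max(abs(g_hi), 1e-12) or span == 0.0
    if degenerate:
        return BoltzmannParams(g_lo, 0.0, np.nan, np.nan, 0.0, v.size,
                               kind=curve.kind, degenerate=True)

    # initial guesses from the empirical curve shape
    frac = (g - g_lo) / span
    frac = frac if sign > 0 else 1.0 - frac
    half_idx = int(np.argmin(np.abs(frac - 0.5)))
    v_half0 = v[half_idx]
    v10 = v[np.argmin(np.abs(frac - 0.1))]
    v90 = v[np.argmin(np.abs(frac - 0.9))]
    s0 = float(np.clip(abs(v90 - v10) / 4.4, 1.0, 30.0))

    lb = [0.0, 1e-9, v.min() - 50.0, 0.5]
    ub = [max(g_hi, 1e-9), 4.0 * max(span, 1e-9), v.max() + 50.0, 40.0]
    best = None
    for vh in (v_half0, v_half0 - 10.0, v_half0 + 10.0):
        x0 = np.clip([max(g_lo, 0.0), span, vh, s0], lb, ub)
        res = least_squares(_boltzmann_residuals, x0, args=(v, g, sign),
                            bounds=(lb, ub), method="trf")
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success and best.cost > 1e-6:
        raise FitFailure("Boltzmann fit did not converge", best)
    g_min, g_max, v_half, s = best.x
    return BoltzmannParams(float(g_min), float(g_max), float(v_half), float(s),
                           rss=float(2 * best.cost), n_points=v.size,
                           kind=curve.kind)


def fit_inactivation_curve(recording: Recording,
                           e_k: float | None = None) -> BoltzmannParams:
    """Steady-state inactivation (h_inf) curve from a conditioning protocol.

    For each conditioning voltage, channel availability is indexed by the
    peak current during the fixed test/tail step (capacitive blanking
    applied), normalized to the maximum (expected at the most negative
    conditioning voltage), and fit with a falling Boltzmann.
    """
    protocol = recording.protocol
    if not isinstance(protocol, StepProtocol):
        raise ValueError("h_inf analysis needs a step-protocol recording")
    e_k = recording.meta.e_k if e_k is None else e_k
    peaks = []
    for sweep in recording.sweeps:
        i0 = _sample_at(sweep.time, protocol.t_tail + BLANK_MS)
        i1 = _sample_at(sweep.time, protocol.t_end)
        peaks.append(float(np.max(sweep.response[i0:i1])))
    peaks = np.asarray(peaks)
    norm = peaks / peaks[0] if peaks[0] != 0 else peaks
    if np.argmax(peaks) != 0:
        import warnings
        warnings.warn("availability maximum not at the most negative "
                      "conditioning voltage; normalization may be biased")
    curve = GVCurve(np.asarray(protocol.step_voltages), norm, "h_inf", e_k)
    if curve.step_v.size == 1:
        return BoltzmannParams(0.0, float(norm[0]), np.nan, np.nan, 0.0, 1,
                               kind="h_inf", degenerate=True)
    return fit_boltzmann(curve)


def conductance_density(g_max: float, cm: float) -> float:
    """Conductance density in nS/pF."""
    if cm <= 0:
        raise ValueError("membrane capacitance must be positive")
    return g_max / cm
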