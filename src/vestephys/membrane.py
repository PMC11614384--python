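"""Current-clamp and passive membrane analyses.

Covers resting potential, input resistance and membrane time constant from
small current steps, capacitance from the capacitive transient of a small
voltage step, electrical resonance quantified by a damped-sinusoid fit

    V(t) = V_SS + V_p · exp(−t/τ_e) · sin(2π f_e t − θ)

over the window from the half-maximum of the initial depolarizing peak to
the end of the current step, and the derived quality factor

    Q_e = sqrt((π f_e τ_e)² + 0.25)

which tends to the overdamped limit 0.5 as f_e → 0. Some reported forms of
the damped sinusoid omit t inside the sine; the standard time-dependent
argument is used here (dimensional consistency).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from scipy.optimize import least_squares

from .recording import Recording, StepProtocol, Sweep

__all__ = [
    "PassiveProps",
    "ResonanceFit",
    "PeakMetrics",
    "resting_potential",
    "fit_passive_response",
    "estimate_cm_transient",
    "fit_resonance",
    "quality_factor",
    "peak_metrics",
]


@dataclass
class PassiveProps:
    v_rest: float  # mV
    r_in: float  # GΩ
    tau_rc: float  # ms
    cm_est: float  # pF, tau_rc / r_in by construction

    def __post_init__(self) -> None:
        if self.r_in <= 0 or self.tau_rc <= 0:
            raise ValueError("r_in and tau_rc must be positive")


@dataclass
class ResonanceFit:
    v_ss: float  # mV
    v_p: float  # mV
    tau_e: float  # ms
    f_e: float  # Hz
    theta: float  # rad
    q_e: float
    adj_r2: float
    window: tuple[float, float] = (np.nan, np.nan)  # ms, fit window
    no_peak: bool = False


@dataclass
class PeakMetrics:
    height: float  # mV above baseline
    time_to_peak: float  # ms from step onset
    width_half_max: float  # ms
    absent: bool = False


def _step_bounds(command: np.ndarray) -> tuple[int, int]:
    """First and one-past-last sample of the (single) command step."""
    base = command[0]
    on = np.nonzero(np.abs(command - base) > 1e-9)[0]
    if on.size == 0:
        raise ValueError("no step found in command trace")
    return int(on[0]), int(on[-1] + 1)


def resting_potential(sweep: Sweep, baseline_ms: float = 50.0) -> float:
    """Mean voltage over the final ``baseline_ms`` of zero-current baseline."""
    if sweep.mode != "current_clamp":
        raise ValueError("resting potential needs a current-clamp sweep")
    zero = np.abs(sweep.command) < 1e-9
    if np.all(zero):
        i_end = sweep.time.size
    else:
        i_end = int(np.nonzero(~zero)[0][0])
    t_end = sweep.time[i_end - 1] if i_end > 0 else sweep.time[0]
    if t_end - sweep.time[0] < baseline_ms:
        raise ValueError(f"needs ≥ {baseline_ms} ms of zero-current baseline")
    mask = zero & (sweep.time >= t_end - baseline_ms) & (sweep.time <= t_end)
    return float(np.mean(sweep.response[mask]))


def _exp_rise_fit(t, v, v0):
    """Single-exponential fit V(t) = v0 + dv (1 − e^(−t/τ)) over the step.

    In cells with delayed rectification near rest the response sags after an
    initial overshoot; the single-exponential convention (fit to the whole
    response) then reads out an effective τ between the instantaneous-R and
    slope-R charging time constants.
    """
    dv0 = v[-1] - v0
    tau0 = max((t[-1] - t[0]) / 5.0, 1e-3)

    def resid(x):
        dv, log_tau = x
        return v0 + dv * (1.0 - np.exp(-t / np.exp(log_tau))) - v

    best = None
    for f in (1.0, 0.2, 5.0):
        res = least_squares(resid, [dv0, np.log(tau0 * f)], method="lm")
        if best is None or res.cost < best.cost:
            best = res
    dv, log_tau = best.x
    return float(dv), float(np.exp(log_tau))


def fit_passive_response(recording: Recording,
                         max_dv: float = 15.0) -> PassiveProps:
    """R_in, τRC and derived capacitance from small current steps.

    Only responses with steady-state deflection under ``max_dv`` are used
    (larger steps engage voltage-gated conductances); the onset of each is
    fit with a single exponential, R_in = ΔV_SS/ΔI from the same step, and
    C = τRC/R_in. Qualifying sweeps are averaged.
    """
    if recording.mode != "current_clamp":
        raise ValueError("passive fit needs current-clamp recording")
    r_ins, taus, v_rests = [], [], []
    for sweep in recording.sweeps:
        i_on, i_off = _step_bounds(sweep.command)
        d_i = float(sweep.command[i_on] - sweep.command[0])
        if d_i == 0:
            continue
        v0 = resting_potential(sweep)
        # steady state from the final fifth of the step
        n_step = i_off - i_on
        v_ss = float(np.mean(sweep.response[i_off - max(n_step // 5, 1):i_off]))
        dv_ss = v_ss - v0
        if abs(dv_ss) >= max_dv or dv_ss == 0:
            continue
        t = sweep.time[i_on:i_off] - sweep.time[i_on]
        dv_fit, tau = _exp_rise_fit(t, sweep.response[i_on:i_off], v0)
        r_ins.append(dv_ss / d_i)  # mV/pA = GΩ
        taus.append(tau)
        v_rests.append(v0)
    if not r_ins:
        raise ValueError("no response under "
                         f"{max_dv} mV; deliver smaller current steps")
    r_in = float(np.mean(r_ins))
    tau_rc = float(np.mean(taus))
    return PassiveProps(float(np.mean(v_rests)), r_in, tau_rc, tau_rc / r_in)


def estimate_cm_transient(recording: Recording, min_tau_samples: int = 5) -> float:
    """Membrane capacitance from the whole-cell capacitive transient.

    Uses a small voltage step delivered negative to −90 mV (where the large
    type I conductance is mostly shut). The decay of the transient follows
    the two-resistor (series + membrane) model: fitting
    ``I(t) = A e^(−t/τ) + I_SS`` after the jump gives
    ``Rs = ΔV/ΔI(0)``, ``R_in = ΔV/ΔI_SS − Rs`` and
    ``C_m = τ (1/Rs + 1/R_in)``.
    """
    if recording.mode != "voltage_clamp":
        raise ValueError("capacitance transient needs voltage clamp")
    sweep = recording.sweeps[0]
    i_on, i_off = _step_bounds(sweep.command)
    v_pre = float(sweep.command[0])
    v_step = float(sweep.command[i_on])
    dv = v_step - v_pre
    if abs(dv) > 10.0 or max(v_pre, v_step) > -90.0:
        raise ValueError("need a ≤10 mV step delivered negative to −90 mV")
    i_pre = float(np.mean(sweep.response[max(0, i_on - 20):i_on]))
    t = sweep.time[i_on:i_off] - sweep.time[i_on]
    i_tr = sweep.response[i_on:i_off] - i_pre

    i_ss0 = float(np.mean(i_tr[-max(len(i_tr) // 5, 1):]))
    a0 = float(i_tr[0] - i_ss0)
    tau0 = max(t[1] - t[0], float(t[np.argmin(np.abs(i_tr - i_ss0 - a0 / np.e))]))

    def resid(x):
        a, log_tau, i_ss = x
        return a * np.exp(-t / np.exp(log_tau)) + i_ss - i_tr

    best = None
    for f in (1.0, 0.3, 3.0):
        res = least_squares(resid, [a0, np.log(tau0 * f), i_ss0], method="lm")
        if best is None or res.cost < best.cost:
            best = res
    a, log_tau, i_ss = best.x
    tau = float(np.exp(log_tau))
    if tau < min_tau_samples * sweep.dt:
        raise ValueError(
            f"transient undersampled: τ = {tau:.4f} ms < {min_tau_samples} samples"
        )
    rs = dv / (a + i_ss)  # GΩ (mV/pA)
    r_in = dv / i_ss - rs
    return float(tau * (1.0 / rs + 1.0 / r_in))


def quality_factor(f_e: float, tau_e: float) -> float:
    """Resonance quality factor from frequency (Hz) and decay time (ms)."""
    if f_e < 0 or tau_e <= 0:
        raise ValueError("need f_e ≥ 0 and tau_e > 0")
    x = np.pi * f_e * tau_e * 1e-3  # dimensionless
    return float(np.sqrt(x * x + 0.25))


def _smooth(v: np.ndarray, dt: float, window_ms: float = 1.0) -> np.ndarray:
    size = max(int(round(window_ms / dt)) | 1, 3)
    return median_filter(v, size=size, mode="nearest")


def fit_resonance(sweep: Sweep, step_window: tuple[float, float] | None = None
                  ) -> ResonanceFit:
    """Damped-sinusoid fit of a current-step voltage response.

    The fit window runs from the first half-maximum crossing of the initial
    depolarizing peak (located on a 1 ms median-smoothed copy; the fit uses
    raw samples) to the end of the step. If no peak is present the fit
    starts at step onset and the result is flagged. Multi-start over phase
    (and a frequency scan) avoids phase local minima.
    """
    if sweep.mode != "current_clamp":
        raise ValueError("resonance fit needs a current-clamp sweep")
    if step_window is None:
        i_on, i_off = _step_bounds(sweep.command)
    else:
        i_on = int(np.argmin(np.abs(sweep.time - step_window[0])))
        i_off = int(np.argmin(np.abs(sweep.time - step_window[1])))
    v = sweep.response
    dt = sweep.dt
    v_base = float(np.mean(v[max(0, i_on - int(20 / dt)):i_on])) if i_on else v[0]

    sm = _smooth(v[i_on:i_off], dt)
    peak_rel = int(np.argmax(sm))
    v_peak = sm[peak_rel]
    v_end = float(np.mean(sm[-max(len(sm) // 10, 1):]))
    no_peak = (v_peak - v_end) < 0.05 * max(v_peak - v_base, 1e-9) \
        or peak_rel >= len(sm) - 2
    if no_peak:
        i_start = i_on
    else:
        half = v_base + 0.5 * (v_peak - v_base)
        above = np.nonzero(sm[:peak_rel + 1] >= half)[0]
        i_start = i_on + (int(above[0]) if above.size else 0)

    t = sweep.time[i_start:i_off] - sweep.time[i_start]
    y = v[i_start:i_off]
    v_ss0 = float(np.mean(y[-max(len(y) // 10, 1):]))
    ampl0 = max(float(np.max(y) - v_ss0), 1e-3)
    tau0 = max((t[-1] - t[0]) / 4.0, 1.0)

    # frequency seed from the dominant Fourier component of the detrended fit
    # window, plus an overdamped candidate
    detr = y - v_ss0
    freqs = np.fft.rfftfreq(detr.size, d=dt * 1e-3)  # Hz
    spec = np.abs(np.fft.rfft(detr * np.hanning(detr.size)))
    f_fft = float(freqs[1 + np.argmax(spec[1:])]) if detr.size > 4 else 10.0
    f_candidates = {f_fft, 0.5 * f_fft, 2.0 * f_fft, 1.0}

    def resid(x):
        v_ss, v_p, log_tau, f_e, theta = x
        model = v_ss + v_p * np.exp(-t / np.exp(log_tau)) \
            * np.sin(2 * np.pi * f_e * t * 1e-3 - theta)
        return model - y

    lb = [-np.inf, 0.0, np.log(0.1), 0.0, -np.pi]
    ub = [np.inf, np.inf, np.log(1e4), 500.0, 2 * np.pi]
    best = None
    for f0 in f_candidates:
        for theta0 in (0.0, np.pi / 2, np.pi, 3 * np.pi / 2):
            x0 = np.clip([v_ss0, ampl0, np.log(tau0), f0, theta0], lb, ub)
            res = least_squares(resid, x0, bounds=(lb, ub), method="trf")
            if best is None or res.cost < best.cost:
                best = res
    v_ss, v_p, log_tau, f_e, theta = best.x
    tau_e = float(np.exp(log_tau))
    r2 = 1.0
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot > 0:
        r2 = 1.0 - float(np.sum(best.fun ** 2)) / ss_tot
        n = y.size
        r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 6)
    return ResonanceFit(float(v_ss), float(v_p), tau_e, float(f_e),
                        float(theta), quality_factor(f_e, tau_e), r2,
                        window=(float(sweep.time[i_start]),
                                float(sweep.time[i_off - 1])),
                        no_peak=no_peak)


def peak_metrics(sweep: Sweep) -> PeakMetrics:
    """Height, latency and half-width of the initial depolarizing transient."""
    if sweep.mode != "current_clamp":
        raise ValueError("peak metrics need a current-clamp sweep")
    i_on, i_off = _step_bounds(sweep.command)
    dt = sweep.dt
    v = sweep.response[i_on:i_off]
    t = sweep.time[i_on:i_off] - sweep.time[i_on]
    v_base = float(np.mean(sweep.response[max(0, i_on - int(20 / dt)):i_on])) \
        if i_on else float(v[0])
    sm = _smooth(v, dt)
    peak_rel = int(np.argmax(sm))
    v_peak = float(sm[peak_rel])
    v_end = float(np.mean(sm[-max(len(sm) // 10, 1):]))
    height = v_peak - v_base
    # monotone response: the "peak" sits at the end or barely exceeds it
    if peak_rel >= len(sm) - 2 or (v_peak - v_end) < 0.02 * max(abs(height), 1e-9):
        return PeakMetrics(np.nan, np.nan, np.nan, absent=True)
    half = v_base + 0.5 * height
    up = np.nonzero(sm[:peak_rel + 1] >= half)[0]
    down = np.nonzero(sm[peak_rel:] <= half)[0]
    t_up = t[up[0]] if up.size else t[0]
    t_down = t[peak_rel + down[0]] if down.size else t[-1]
    return PeakMetrics(float(height), float(t[peak_rel]),
                       float(t_down - t_up), absent=False)
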