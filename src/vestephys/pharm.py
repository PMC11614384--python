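"""Drug-subtraction analysis.

Isolates a drug-sensitive current as control − drug on matched sweeps,
computes percent block of steady-state current at a stated voltage, and
builds the drug-sensitive tail G–V curve (the XE991/K_V7 and
iberiotoxin/BK workflows). No rundown or drift correction is applied
between the control and drug epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import gv as _gv
from .recording import Recording, StepProtocol

__all__ = [
    "DrugComparison",
    "subtract_traces",
    "percent_block",
    "drug_sensitive_gv",
]

PAIR_TOL_MV = 1.0  # sweep pairing tolerance on step voltage


class ProtocolMismatch(ValueError):
    pass


@dataclass
class DrugComparison:
    control: Recording
    drug: Recording
    drug_name: str = ""
    dose: float = np.nan  # µM
    matched: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        pc, pd = self.control.protocol, self.drug.protocol
        if not (isinstance(pc, StepProtocol) and isinstance(pd, StepProtocol)):
            raise ProtocolMismatch("both recordings need step protocols")
        differing = [name for name in
                     ("holding", "prestep_v", "prestep_dur", "step_dur",
                      "tail_v", "tail_dur", "holding_dur")
                     if getattr(pc, name) != getattr(pd, name)]
        if differing:
            raise ProtocolMismatch(f"protocols differ in: {', '.join(differing)}")
        if not self.matched:
            drug_vs = np.asarray(pd.step_voltages)
            for i, v in enumerate(pc.step_voltages):
                j = int(np.argmin(np.abs(drug_vs - v)))
                if abs(drug_vs[j] - v) <= PAIR_TOL_MV:
                    self.matched.append((i, j))
            if len(self.matched) != len(pc.step_voltages):
                raise ProtocolMismatch("protocols differ in: step_voltages")


def subtract_traces(comparison: DrugComparison) -> Recording:
    """Per-sample control − drug current; the drug-sensitive component."""
    out = comparison.control.copy()
    for i, j in comparison.matched:
        sc = comparison.control.sweeps[i]
        sd = comparison.drug.sweeps[j]
        if sc.time.size != sd.time.size or abs(sc.dt - sd.dt) > 1e-9:
            raise ProtocolMismatch("protocols differ in: time base")
        out.sweeps[i].response = sc.response - sd.response
    label = comparison.drug_name or "drug"
    out.label = f"{label}-sensitive"
    return out


def percent_block(comparison: DrugComparison, at_v: float,
                  ss_window_ms: float = 10.0, noise_floor_pa: float = 1.0) -> float:
    """Percent block of steady-state current at the step nearest ``at_v``.

    Steady state is the mean of the final ``ss_window_ms`` of the step in
    each recording; block = 100·(I_control − I_drug)/I_control.
    """
    protocol = comparison.control.protocol
    steps = np.asarray(protocol.step_voltages)
    k = int(np.argmin(np.abs(steps - at_v)))
    i_ctrl = _ss_current(comparison.control, k, ss_window_ms)
    j = dict(comparison.matched)[k]
    i_drug = _ss_current(comparison.drug, j, ss_window_ms)
    if abs(i_ctrl) < noise_floor_pa:
        raise ValueError(
            f"control steady-state current {i_ctrl:.2f} pA below noise floor"
        )
    return 100.0 * (i_ctrl - i_drug) / i_ctrl


def _ss_current(recording: Recording, sweep_idx: int, window_ms: float) -> float:
    protocol = recording.protocol
    sweep = recording.sweeps[sweep_idx]
    mask = (sweep.time >= protocol.t_tail - window_ms) & (sweep.time < protocol.t_tail)
    return float(np.mean(sweep.response[mask]))


def drug_sensitive_gv(comparison: DrugComparison, e_k: float | None = None
                      ) -> tuple[_gv.GVCurve, _gv.BoltzmannParams]:
    """Tail G–V and Boltzmann fit of the subtracted (drug-sensitive) current."""
    diff = subtract_traces(comparison)
    curve = _gv.extract_tail_gv(diff, e_k)
    params = _gv.fit_boltzmann(curve)
    return curve, params
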