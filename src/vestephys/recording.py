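"""Data model for whole-cell patch-clamp recordings.

A :class:`Recording` bundles per-sweep time series (voltage-clamp current
responses or current-clamp voltage responses) with the stimulus protocol and
the cell/electrode metadata needed for electrochemical and electrode
corrections.

Units are fixed package-wide: mV, pA, ms, nS, pF, GΩ (series resistance is
kept in MΩ in metadata, as it is quoted in the field). Outward current is
positive.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "Sweep",
    "StepProtocol",
    "RecordingMeta",
    "Recording",
    "nernst_potential",
    "correct_potentials",
    "build_protocol",
    "read_recording",
    "write_recording",
]

# Physical constants (SI): gas constant, Faraday constant.
_R = 8.31446261815324
_F = 96485.33212

Mode = Literal["voltage_clamp", "current_clamp"]


class RecordingError(ValueError):
    """Invalid recording structure or metadata."""


def nernst_potential(k_in: float, k_out: float, temperature: float = 25.0) -> float:
    """Potassium equilibrium potential E_K in mV.

    Parameters
    ----------
    k_in, k_out : float
        Internal and external K+ concentrations in mM.
    temperature : float
        Bath temperature in °C.
    """
    if k_in <= 0 or k_out <= 0:
        raise ValueError("K+ concentrations must be positive")
    t_kelvin = temperature + 273.15
    return 1e3 * (_R * t_kelvin / _F) * np.log(k_out / k_in)


@dataclass
class Sweep:
    """One stimulus/response pair on a uniform time grid.

    ``command`` is mV in voltage clamp and pA in current clamp; ``response``
    is pA in voltage clamp and mV in current clamp.
    """

    time: np.ndarray
    command: np.ndarray
    response: np.ndarray
    mode: Mode
    sample_rate: float  # kHz

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.command = np.asarray(self.command, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.mode not in ("voltage_clamp", "current_clamp"):
            raise RecordingError(f"unknown mode {self.mode!r}")
        n = self.time.size
        if self.command.size != n or self.response.size != n:
            raise RecordingError("time, command and response must have equal length")
        if n < 2:
            raise RecordingError("sweep needs at least two samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise RecordingError("time must be strictly increasing")
        if (dt.max() - dt.min()) > 1e-6 * dt.mean():
            raise RecordingError("time grid must be uniform within 1 ppm")

    @property
    def dt(self) -> float:
        """Sample interval in ms."""
        return float(self.time[1] - self.time[0])

    def copy(self) -> "Sweep":
        return Sweep(
            self.time.copy(), self.command.copy(), self.response.copy(),
            self.mode, self.sample_rate,
        )


@dataclass
class StepProtocol:
    """Standard voltage-step protocol: hold → prestep → test step → tail.

    ``holding_dur`` is the pre-protocol baseline included at the start of
    each simulated/recorded sweep so that holding-level current is visible.
    """

    holding: float  # mV
    prestep_v: float  # mV
    prestep_dur: float  # ms
    step_voltages: Sequence[float]  # mV, ascending
    step_dur: float  # ms
    tail_v: float  # mV
    tail_dur: float  # ms
    holding_dur: float = 20.0  # ms

    def __post_init__(self) -> None:
        self.step_voltages = list(float(v) for v in self.step_voltages)
        if not self.step_voltages:
            raise RecordingError("step_voltages must be non-empty")
        if any(b < a for a, b in zip(self.step_voltages, self.step_voltages[1:])):
            raise RecordingError("step_voltages must be sorted ascending")
        for name in ("prestep_dur", "step_dur", "tail_dur", "holding_dur"):
            if getattr(self, name) <= 0:
                raise RecordingError(f"{name} must be positive")

    # segment boundary times within a sweep (ms from sweep start)
    @property
    def t_prestep(self) -> float:
        return self.holding_dur

    @property
    def t_step(self) -> float:
        return self.holding_dur + self.prestep_dur

    @property
    def t_tail(self) -> float:
        return self.t_step + self.step_dur

    @property
    def t_end(self) -> float:
        return self.t_tail + self.tail_dur

    def segments(self, step_v: float) -> list[tuple[float, float]]:
        """(voltage, duration) list for the sweep that steps to ``step_v``."""
        return [
            (self.holding, self.holding_dur),
            (self.prestep_v, self.prestep_dur),
            (step_v, self.step_dur),
            (self.tail_v, self.tail_dur),
        ]


@dataclass
class RecordingMeta:
    """Cell, solution and electrode metadata for one recording."""

    cell_type: Literal["type_I", "type_II"] = "type_I"
    genotype: Literal["+/+", "+/-", "-/-"] = "+/+"
    zone: Literal["LES", "MES", "striola"] = "LES"
    age: float = 30.0  # postnatal days
    temperature: float = 25.0  # °C
    rs_total: float = 10.0  # MΩ, measured after rupture
    rs_compensation: float = 0.8  # fraction compensated by the amplifier
    ljp: float = 4.0  # mV, liquid junction potential
    k_in: float = 165.0  # mM
    k_out: float = 5.77  # mM
    cm_reported: float | None = None  # pF, amplifier estimate if available

    def __post_init__(self) -> None:
        if not (0.0 <= self.rs_compensation < 1.0) and self.rs_compensation != 1.0:
            raise RecordingError("rs_compensation must be in [0, 1]")
        if self.k_in <= 0 or self.k_out <= 0:
            raise RecordingError("K+ concentrations must be positive")
        if self.age < 0:
            raise RecordingError("age must be non-negative")

    @property
    def rs_residual(self) -> float:
        """Uncompensated series resistance in MΩ."""
        return self.rs_total * (1.0 - self.rs_compensation)

    @property
    def e_k(self) -> float:
        return nernst_potential(self.k_in, self.k_out, self.temperature)


@dataclass
class Recording:
    """A set of sweeps sharing one protocol and one cell."""

    meta: RecordingMeta
    protocol: StepProtocol | list[float]
    sweeps: list[Sweep] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        if self.sweeps:
            mode = self.sweeps[0].mode
            rate = self.sweeps[0].sample_rate
            for s in self.sweeps:
                if s.mode != mode:
                    raise RecordingError("all sweeps must share one clamp mode")
                if s.sample_rate != rate:
                    raise RecordingError("all sweeps must share one sample rate")
        if isinstance(self.protocol, StepProtocol) and self.sweeps:
            if len(self.sweeps) != len(self.protocol.step_voltages):
                raise RecordingError("one sweep per protocol step expected")

    @property
    def mode(self) -> Mode:
        return self.sweeps[0].mode

    def copy(self) -> "Recording":
        proto = (
            dataclasses.replace(self.protocol)
            if isinstance(self.protocol, StepProtocol)
            else list(self.protocol)
        )
        return Recording(
            dataclasses.replace(self.meta), proto,
            [s.copy() for s in self.sweeps], self.label,
        )


def correct_potentials(recording: Recording) -> Recording:
    """Correct command potentials for residual series resistance and LJP.

    Per-sample membrane potential is ``command − I·Rs_residual − ljp`` with
    the residual series resistance ``Rs_total·(1 − Rs_compensation)``. The
    sign convention is the standard V_m = V_pipette − V_LJP; the input
    recording is left untouched.
    """
    if recording.mode != "voltage_clamp":
        raise RecordingError("series-resistance correction applies to voltage clamp only")
    out = recording.copy()
    rs_mohm = recording.meta.rs_residual
    for sweep in out.sweeps:
        # pA · MΩ = 1e-3 mV
        sweep.command = sweep.command - sweep.response * rs_mohm * 1e-3 - recording.meta.ljp
    out.label = (recording.label + " [corrected]").strip()
    return out


_PROTOCOL_KINDS = ("type_I", "type_II", "inactivation")


def build_protocol(kind: str, **overrides) -> StepProtocol:
    """Standard voltage protocols for type I / type II cells.

    ``type_I``: hold −74 mV, prestep −124 mV/200 ms (fully deactivates
    g_K,L), 500 ms test steps, 50 ms tail at −44 mV (HCN reversal, avoids
    HCN contamination). ``type_II``: hold −64, prestep −124/50 ms (removes
    baseline inactivation of g_A), 200 ms steps, same tail.
    ``inactivation``: 500 ms conditioning steps from −124 to 0 mV followed
    by a fixed −44 mV readout where peak tail current indexes channel
    availability.
    """
    if kind == "type_I":
        params = dict(
            holding=-74.0, prestep_v=-124.0, prestep_dur=200.0,
            step_voltages=list(np.arange(-124.0, 31.0, 10.0)),
            step_dur=500.0, tail_v=-44.0, tail_dur=50.0,
        )
    elif kind == "type_II":
        params = dict(
            holding=-64.0, prestep_v=-124.0, prestep_dur=50.0,
            step_voltages=list(np.arange(-124.0, 31.0, 10.0)),
            step_dur=200.0, tail_v=-44.0, tail_dur=50.0,
        )
    elif kind == "inactivation":
        # conditioning steps, then a fixed depolarized test step whose peak
        # (A-type transient on a conditioning-independent rectifier
        # background) indexes channel availability
        params = dict(
            holding=-64.0, prestep_v=-124.0, prestep_dur=50.0,
            step_voltages=list(np.arange(-124.0, 1.0, 10.0)),
            step_dur=500.0, tail_v=30.0, tail_dur=100.0,
        )
    else:
        raise ValueError(f"unknown protocol kind {kind!r}; valid: {_PROTOCOL_KINDS}")
    params.update(overrides)
    return StepProtocol(**params)


# ---------------------------------------------------------------------------
# On-disk format: one directory per recording, meta.json + sweep_###.csv.
# This stands in for proprietary acquisition formats.

def write_recording(recording: Recording, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta: dict = {f.name: getattr(recording.meta, f.name)
                  for f in dataclasses.fields(RecordingMeta)}
    if isinstance(recording.protocol, StepProtocol):
        proto = {f.name: getattr(recording.protocol, f.name)
                 for f in dataclasses.fields(StepProtocol)}
        proto_kind = "steps"
    else:
        proto = {"current_steps": list(recording.protocol)}
        proto_kind = "current"
    doc = {
        "meta": meta,
        "protocol": proto,
        "protocol_kind": proto_kind,
        "label": recording.label,
        "mode": recording.sweeps[0].mode if recording.sweeps else None,
        "sample_rate": recording.sweeps[0].sample_rate if recording.sweeps else None,
        "n_sweeps": len(recording.sweeps),
    }
    (path / "meta.json").write_text(json.dumps(doc, indent=1))
    for i, sweep in enumerate(recording.sweeps):
        arr = np.column_stack([sweep.time, sweep.command, sweep.response])
        np.savetxt(path / f"sweep_{i:03d}.csv", arr, delimiter=",",
                   header="time,command,response", comments="", fmt="%.17g")
    return path


def read_recording(path: str | Path) -> Recording:
    path = Path(path)
    meta_file = path / "meta.json"
    if not meta_file.exists():
        raise RecordingError(f"missing metadata file {meta_file}")
    try:
        doc = json.loads(meta_file.read_text())
    except json.JSONDecodeError as exc:
        raise RecordingError(f"malformed meta.json: {exc}") from exc
    try:
        meta = RecordingMeta(**doc["meta"])
    except (KeyError, TypeError) as exc:
        raise RecordingError(f"malformed metadata field: {exc}") from exc
    if doc.get("protocol_kind") == "steps":
        protocol: StepProtocol | list[float] = StepProtocol(**doc["protocol"])
    else:
        protocol = list(doc["protocol"]["current_steps"])
    sweeps = []
    mode = doc.get("mode") or "voltage_clamp"
    rate = doc.get("sample_rate") or 0.0
    for i in range(int(doc.get("n_sweeps", 0))):
        sweep_file = path / f"sweep_{i:03d}.csv"
        if not sweep_file.exists():
            raise RecordingError(f"missing sweep file {sweep_file.name}")
        arr = np.loadtxt(sweep_file, delimiter=",", skiprows=1)
        sweeps.append(Sweep(arr[:, 0], arr[:, 1], arr[:, 2], mode, rate))
    return Recording(meta, protocol, sweeps, doc.get("label", ""))
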