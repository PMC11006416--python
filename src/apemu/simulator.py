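"""Paced action-potential simulation with nine scalable current magnitudes.

This module is the data source for the whole package: it provides a
desk-scale stand-in for a full human ventricular ionic model, exposing the
same narrow interface (conductance scale factors in, sampled last-beat action
potential out) so that a detailed model could be swapped in behind it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import _model
from .errors import SimulationError, ValidationError

CONDUCTANCE_NAMES = ("gNa", "gNaL", "pCa", "gto", "gKr", "gKs", "gK1", "gNCX", "pNaK")


@dataclass(frozen=True)
class ConductanceSet:
    """Nine dimensionless scale factors multiplying baseline current magnitudes.

    Baseline is 1.0 for every entry; all workflows in this package use values
    in [0, 2].
    """

    gNa: float = 1.0
    gNaL: float = 1.0
    pCa: float = 1.0
    gto: float = 1.0
    gKr: float = 1.0
    gKs: float = 1.0
    gK1: float = 1.0
    gNCX: float = 1.0
    pNaK: float = 1.0

    def __post_init__(self):
        for name in CONDUCTANCE_NAMES:
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0.0:
                raise ValidationError(f"conductance scale {name}={v!r} must be finite and >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in CONDUCTANCE_NAMES], dtype=np.float64)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "ConductanceSet":
        arr = np.asarray(arr, dtype=np.float64)
        if arr.shape != (9,):
            raise ValidationError(f"expected 9 conductance scales, got shape {arr.shape}")
        return cls(**dict(zip(CONDUCTANCE_NAMES, arr.tolist())))

    def scaled(self, **factors: float) -> "ConductanceSet":
        """Return a copy with named entries multiplied by the given factors."""
        updates = {k: getattr(self, k) * v for k, v in factors.items()}
        return replace(self, **updates)


@dataclass(frozen=True)
class PacingProtocol:
    """Rectangular-pulse pacing at a fixed cycle length.

    stim_amplitude is the transmembrane current density magnitude in uA/cm^2
    (applied as an inward, depolarizing current).
    """

    cycle_length: float = 1000.0
    stim_duration: float = 1.0
    stim_amplitude: float = 60.0
    n_beats: int = 200
    dt_solver: float = 0.01
    dt_sample: float = 0.05
    steady_state_tol: float = 1e-4

    def __post_init__(self):
        if self.dt_solver > self.dt_sample:
            raise ValidationError("dt_solver must be <= dt_sample")
        if not self.stim_duration < self.cycle_length:
            raise ValidationError("stim_duration must be < cycle_length")
        if self.n_beats < 1:
            raise ValidationError("n_beats must be >= 1")
        ratio = self.dt_sample / self.dt_solver
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValidationError("dt_sample must be an integer multiple of dt_solver")


@dataclass
class APTrace:
    """Sampled transmembrane potential over (part of) one pacing cycle."""

    times: np.ndarray
    vm: np.ndarray
    cycle_length: float = 1000.0
    beat_index: int | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.vm = np.asarray(self.vm, dtype=np.float64)
        if self.times.ndim != 1 or self.times.shape != self.vm.shape or self.times.size < 2:
            raise ValidationError("times and vm must be 1-D, equal length >= 2")
        if not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")
        if not np.all(np.isfinite(self.vm)):
            raise ValidationError("vm must be finite")

    def __len__(self) -> int:
        return self.times.size

    def vm_at(self, t: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of vm at time(s) t (clamped at the ends)."""
        return np.interp(t, self.times, self.vm)

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, np.column_stack([self.times, self.vm]),
                   delimiter=",", header="time_ms,vm_mV", comments="")

    @classmethod
    def from_csv(cls, path: str | Path, cycle_length: float = 1000.0) -> "APTrace":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(times=data[:, 0], vm=data[:, 1], cycle_length=cycle_length)


# Baseline limit-cycle state at the default protocol (computed once by pacing
# the raw resting state for 400 beats; shipping it makes the default n_beats
# with early stopping converge in a handful of beats near baseline).
DEFAULT_INITIAL_STATE = np.array([
    -85.60625333, 0.001396883847, 0.9868079687, 0.9916190418, 0.002723591113,
    0.9999836994, 0.02144264443, 0.06039883221, 0.0005483015783, 0.9993207389,
    0.4168697374, 0.0001827646906,
])


def _run_beat(state: np.ndarray, g: np.ndarray, protocol: PacingProtocol,
              tables) -> tuple[np.ndarray, np.ndarray]:
    dt = protocol.dt_solver
    n_steps = int(round(protocol.cycle_length / dt))
    sample_every = int(round(protocol.dt_sample / dt))
    vm_out = np.empty(n_steps // sample_every + 1)
    t_fail = _model.integrate(state, g, dt, n_steps, -abs(protocol.stim_amplitude),
                              int(round(protocol.stim_duration / dt)), sample_every,
                              tables[0], tables[1], tables[2], vm_out)
    if t_fail >= 0.0:
        raise SimulationError(
            f"integration failure: non-finite or escaped voltage at t={t_fail:.3f} ms",
            t_fail=float(t_fail),
        )
    return state, vm_out


def integrate_beat(state: np.ndarray, conductances: ConductanceSet,
                   protocol: PacingProtocol) -> tuple[np.ndarray, APTrace]:
    """Advance the model by exactly one pacing cycle.

    Returns the updated state vector and the beat's sampled trace on
    [0, cycle_length]; t = 0 is stimulus onset.
    """
    state = np.array(state, dtype=np.float64)
    if state.shape != (_model.N_STATES,) or not np.all(np.isfinite(state)):
        raise ValidationError("state must be a finite vector of length 12")
    tables = _model.build_tables(protocol.dt_solver)
    g = conductances.as_array()
    state, vm = _run_beat(state, g, protocol, tables)
    times = np.arange(vm.size) * protocol.dt_sample
    return state, APTrace(times=times, vm=vm, cycle_length=protocol.cycle_length)


def simulate_ap(conductances: ConductanceSet,
                protocol: PacingProtocol = PacingProtocol(),
                initial_state: np.ndarray | None = None,
                return_last_two: bool = False):
    """Pace the model for protocol.n_beats and return the last beat's AP.

    State is carried across beats so the returned trace approximates the
    model's limit cycle; pacing stops early once the relative per-beat state
    change falls below protocol.steady_state_tol.

    With return_last_two=True a (last_trace, previous_trace) pair is returned
    (previous_trace is None if only one beat was run), as needed by the
    abnormality check on the last two consecutive APs.
    """
    state = np.array(DEFAULT_INITIAL_STATE if initial_state is None else initial_state,
                     dtype=np.float64)
    tables = _model.build_tables(protocol.dt_solver)
    g = conductances.as_array()
    scale = np.maximum(np.abs(state), 1e-3)
    prev_vm = None
    vm = None
    for beat in range(protocol.n_beats):
        before = state.copy()
        prev_vm = vm if beat > 0 else None
        state, vm = _run_beat(state, g, protocol, tables)
        delta = np.max(np.abs(state - before) / scale)
        scale = np.maximum(np.abs(state), 1e-3)
        if delta < protocol.steady_state_tol and beat >= 1:
            break
    times = np.arange(vm.size) * protocol.dt_sample
    last = APTrace(times=times, vm=vm, cycle_length=protocol.cycle_length, beat_index=beat)
    if return_last_two:
        prev = None
        if prev_vm is not None:
            prev = APTrace(times=times.copy(), vm=prev_vm,
                           cycle_length=protocol.cycle_length, beat_index=beat - 1)
        return last, prev
    return last


def batch_simulate(conductance_list: Iterable[ConductanceSet],
                   protocol: PacingProtocol = PacingProtocol()):
    """simulate_ap over a list; per-item failures are collected, not raised.

    Returns (traces, failures): traces[i] is the APTrace or None on failure,
    failures is a list of (index, exception).
    """
    conductance_list = list(conductance_list)
    if not conductance_list:
        raise ValidationError("conductance_list must be non-empty")
    traces: list[APTrace | None] = []
    failures: list[tuple[int, Exception]] = []
    for i, c in enumerate(conductance_list):
        try:
            traces.append(simulate_ap(c, protocol))
        except SimulationError as exc:
            traces.append(None)
            failures.append((i, exc))
    return traces, failures


def conductances_to_csv(sets: Sequence[ConductanceSet], path: str | Path) -> None:
    arr = np.array([c.as_array() for c in sets])
    np.savetxt(path, arr, delimiter=",", header=",".join(CONDUCTANCE_NAMES), comments="")


def conductances_from_csv(path: str | Path) -> list[ConductanceSet]:
    import pandas as pd

    df = pd.read_csv(path)
    missing = [n for n in CONDUCTANCE_NAMES if n not in df.columns]
    if missing:
        raise ValidationError(f"conductance CSV missing columns: {missing}")
    return [ConductanceSet(**{n: float(row[n]) for n in CONDUCTANCE_NAMES})
            for _, row in df.iterrows()]


def traces_to_hdf5(traces: Sequence[APTrace], path: str | Path) -> None:
    """Store a batch of traces sharing one grid: datasets `times` and `vm`."""
    import h5py

    traces = list(traces)
    if not traces:
        raise ValidationError("no traces to store")
    times = traces[0].times
    for tr in traces[1:]:
        if not np.array_equal(tr.times, times):
            raise ValidationError("batch HDF5 storage requires a shared time grid")
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=times)
        f.create_dataset("vm", data=np.array([tr.vm for tr in traces]))
        f.attrs["cycle_length"] = traces[0].cycle_length


def traces_from_hdf5(path: str | Path) -> list[APTrace]:
    import h5py

    with h5py.File(path, "r") as f:
        times = f["times"][:]
        vm = f["vm"][:]
        cl = float(f.attrs.get("cycle_length", 1000.0))
    return [APTrace(times=times.copy(), vm=row, cycle_length=cl) for row in vm]
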