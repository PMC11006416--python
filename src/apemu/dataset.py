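"""Supervised training-corpus construction: sample, simulate, filter, resample, split.

Conductance scale factors are drawn from Sobol' low-discrepancy sequences,
simulated to (approximate) steady state, screened for incomplete
repolarization, resampled onto the canonical non-uniform time grid and split
into training/validation subsets.

The canonical grid covers t in [-10, 1000] ms at three rates: 4 kHz on
[-10, -5), 10 kHz on [-5, 20) (depolarization phase) and 4 kHz on [20, 1000],
for 20 + 250 + 3921 = 4191 points.  The 10 ms pre-stimulus extension holds
the resting potential vm(0) constant and gives the emulator room to align
depolarization timing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import qmc

from .biomarkers import is_unrepolarized
from .errors import SimulationError, ValidationError
from .simulator import APTrace, ConductanceSet, PacingProtocol, simulate_ap

log = logging.getLogger(__name__)

#: the two sampling ranges used to build the full corpus
DEFAULT_RANGES = ((0.0, 2.0), (0.5, 1.5))


def canonical_grid() -> np.ndarray:
    """The canonical 4191-point non-uniform time grid in ms."""
    pre = np.arange(-10.0, -5.0, 0.25)          # [-10, -5) at 4 kHz
    depo = np.arange(-50, 200) * 0.1            # [-5, 20) at 10 kHz, exact ticks
    repo = 20.0 + 0.25 * np.arange(3921)        # [20, 1000] at 4 kHz
    return np.concatenate([pre, depo, repo])


CANONICAL_GRID = canonical_grid()


def sobol_conductance_samples(n: int, low: float, high: float,
                              seed: int | None = None,
                              scramble: bool = False) -> list[ConductanceSet]:
    """n nine-dimensional Sobol' points mapped affinely onto [low, high]^9.

    By default the unscrambled sequence (skip=0) is used, so the points are a
    deterministic function of (n, low, high); ``seed`` only takes effect with
    ``scramble=True``.
    """
    if not (0.0 <= low < high <= 2.0):
        raise ValidationError(f"require 0 <= low < high <= 2, got [{low}, {high}]")
    if n < 1:
        raise ValidationError("n must be >= 1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # non-power-of-two draws
        sampler = qmc.Sobol(d=9, scramble=scramble, seed=seed)
        pts = sampler.random(n)
    pts = low + (high - low) * pts
    return [ConductanceSet.from_array(p) for p in pts]


def extend_and_resample(trace: APTrace) -> APTrace:
    """Extend a [0, 1000] ms uniform trace to [-10, 1000] ms on the canonical grid.

    vm on [-10, 0) is held constant at vm(0); vm on [0, 1000] is linearly
    interpolated from the input samples.
    """
    t = trace.times
    if t[0] > 1e-9 or t[-1] < 1000.0 - 1e-9:
        raise ValidationError("input trace must cover [0, 1000] ms")
    dts = np.diff(t)
    if np.max(dts[(t[:-1] >= -5.0) & (t[:-1] < 20.0)], initial=0.0) > 0.1 + 1e-12:
        raise ValidationError(
            "input sampling coarser than the 10 kHz target in the depolarization window")
    grid = CANONICAL_GRID
    vm = np.empty_like(grid)
    neg = grid < 0.0
    vm[neg] = trace.vm_at(0.0)
    vm[~neg] = np.interp(grid[~neg], t, trace.vm)
    return APTrace(times=grid.copy(), vm=vm, cycle_length=trace.cycle_length,
                   beat_index=trace.beat_index)


@dataclass
class Dataset:
    """Training corpus of (conductances, AP) pairs on the canonical grid."""

    grid: np.ndarray
    vm: np.ndarray                 # (n, len(grid))
    conductances: np.ndarray       # (n, 9)
    split: np.ndarray              # (n,) array of 'train' / 'val'
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        n = self.vm.shape[0]
        if self.conductances.shape != (n, 9) or self.split.shape[0] != n:
            raise ValidationError("inconsistent dataset array shapes")

    def __len__(self) -> int:
        return self.vm.shape[0]

    def subset(self, label: str) -> "Dataset":
        m = self.split == label
        return Dataset(grid=self.grid, vm=self.vm[m], conductances=self.conductances[m],
                       split=self.split[m], provenance=dict(self.provenance))

    @property
    def samples(self):
        """Iterate (ConductanceSet, APTrace) pairs (a convenience view)."""
        for i in range(len(self)):
            yield (ConductanceSet.from_array(self.conductances[i]),
                   APTrace(times=self.grid, vm=self.vm[i]))

    # ---- persistence -----------------------------------------------------
    def to_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("grid", data=self.grid)
            f.create_dataset("vm", data=self.vm)
            f.create_dataset("conductances", data=self.conductances)
            f.create_dataset("split", data=np.char.encode(self.split.astype(str)))
            for k, v in self.provenance.items():
                f.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "Dataset":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(grid=f["grid"][:], vm=f["vm"][:],
                       conductances=f["conductances"][:],
                       split=np.char.decode(f["split"][:]),
                       provenance=dict(f.attrs))


def build_training_set(n_total: int = 4000,
                       ranges=DEFAULT_RANGES,
                       protocol: PacingProtocol = PacingProtocol(),
                       seed: int | None = None,
                       scramble: bool = False,
                       progress_every: int = 0) -> Dataset:
    """Simulate Sobol'-sampled conductance sets and keep the repolarized APs.

    n_total is divided equally over the sampling ranges.  Every generated
    sample ends up in exactly one of {kept, excluded-unrepolarized,
    excluded-simulator-failure}; the counts are recorded in the provenance.
    """
    if n_total < 1:
        raise ValidationError("n_total must be >= 1")
    per_range = n_total // len(ranges)
    counts = {"kept": 0, "unrepolarized": 0, "simulator_failure": 0}
    vms, gs = [], []
    for lo, hi in ranges:
        for cset in sobol_conductance_samples(per_range, lo, hi, seed=seed,
                                              scramble=scramble):
            try:
                raw = simulate_ap(cset, protocol)
            except SimulationError as exc:
                counts["simulator_failure"] += 1
                log.debug("sample dropped (simulator failure): %s", exc)
                continue
            if is_unrepolarized(raw):
                counts["unrepolarized"] += 1
                continue
            vms.append(extend_and_resample(raw).vm)
            gs.append(cset.as_array())
            counts["kept"] += 1
            if progress_every and counts["kept"] % progress_every == 0:
                log.info("kept %d samples", counts["kept"])
    vm = np.array(vms)
    g = np.array(gs)
    split = np.full(len(vms), "train", dtype=object)
    prov = {"ranges": np.array(ranges).ravel(), "seed": -1 if seed is None else seed,
            "scramble": scramble, **{f"n_{k}": v for k, v in counts.items()}}
    return Dataset(grid=CANONICAL_GRID.copy(), vm=vm, conductances=g,
                   split=split.astype(str), provenance=prov)


def train_val_split(dataset: Dataset, val_fraction: float = 0.2,
                    seed: int | None = None) -> Dataset:
    """Randomly label floor(val_fraction * n) samples as validation."""
    if not 0.0 < val_fraction < 1.0:
        raise ValidationError("val_fraction must be in (0, 1)")
    n = len(dataset)
    n_val = int(np.floor(val_fraction * n))
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)[:n_val]
    split = np.full(n, "train", dtype=object)
    split[idx] = "val"
    return Dataset(grid=dataset.grid, vm=dataset.vm, conductances=dataset.conductances,
                   split=split.astype(str),
                   provenance={**dataset.provenance, "val_fraction": val_fraction,
                               "split_seed": -1 if seed is None else seed})
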