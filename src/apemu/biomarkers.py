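"""Scalar action-potential biomarkers and repolarization-abnormality detection.

Seven standard AP descriptors are computed from a sampled trace: resting
membrane potential (RMP), maximum upstroke velocity (dVmMax), peak potential,
the action-potential durations APD40/APD50/APD90 and the triangulation
Tri90-40 = APD90 - APD40.  Conventions:

* RMP is the membrane potential at stimulus onset (the held pre-stimulus
  value; for traces starting at t = 0 this is the first sample).
* dVmMax is the maximum finite-difference derivative; its time defines the
  activation (depolarization reference) time.
* APDx is the time from activation until vm first falls below
  Peak - (x/100) * (Peak - RMP), with the crossing linearly interpolated.

Early afterdepolarizations (EAD) are flagged when, after the AP peak plus a
guard interval, the smoothed trace shows a depolarizing deflection: a local
minimum followed by a later rise of at least ``delta`` mV that reaches above
``v_gate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MissingAPDError, NoActionPotentialError, ValidationError
from .simulator import APTrace

BIOMARKER_NAMES = ("RMP", "dVmMax", "Peak", "APD40", "APD50", "APD90", "Tri90_40")

#: Experimental calibration ranges (mV, mV/ms, ms) for paced human
#: ventricular preparations at a 1000 ms cycle length.
DEFAULT_RANGES = {
    "RMP": (-95.0, -80.0),
    "dVmMax": (100.0, 1000.0),
    "Peak": (10.0, 55.0),
    "APD40": (85.0, 320.0),
    "APD50": (110.0, 350.0),
    "APD90": (180.0, 440.0),
    "Tri90_40": (50.0, 150.0),
}


@dataclass(frozen=True)
class BiomarkerSet:
    RMP: float
    dVmMax: float
    Peak: float
    APD40: float
    APD50: float
    APD90: float
    Tri90_40: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in BIOMARKER_NAMES], dtype=np.float64)

    @classmethod
    def from_array(cls, arr) -> "BiomarkerSet":
        return cls(**dict(zip(BIOMARKER_NAMES, np.asarray(arr, dtype=float).tolist())))


@dataclass(frozen=True)
class BiomarkerRanges:
    """Closed per-biomarker acceptance intervals."""

    bounds: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValidationError(f"range for {name}: min {lo} must be < max {hi}")

    @classmethod
    def from_biomarker_sets(cls, sets) -> "BiomarkerRanges":
        """Min/max envelope of a collection of BiomarkerSets (training ranges).

        Degenerate intervals (all samples equal) are widened symmetrically by
        a negligible margin to keep the min < max invariant.
        """
        arr = np.array([b.as_array() for b in sets])
        bounds = {}
        for i, n in enumerate(BIOMARKER_NAMES):
            lo, hi = float(arr[:, i].min()), float(arr[:, i].max())
            if not lo < hi:
                pad = 1e-9 * max(1.0, abs(lo))
                lo, hi = lo - pad, hi + pad
            bounds[n] = (lo, hi)
        return cls(bounds=bounds)


@dataclass(frozen=True)
class EADConfig:
    """Parameters of the EAD rule.

    The post-peak guard must clear the physiological phase-1 notch-and-dome
    morphology (the dome is a depolarizing deflection but not an EAD); with
    the built-in model the dome completes within ~60 ms of the peak, hence
    the 100 ms default.
    """

    delta: float = 1.0        # mV, minimum depolarizing deflection
    v_gate: float = -40.0     # mV, deflection must reach above this
    guard_ms: float = 100.0   # ms after the AP peak before searching
    smooth_points: int = 5    # moving-average window


DEFAULT_EAD_CONFIG = EADConfig()


def _interp_crossing(t0, v0, t1, v1, level):
    # falling crossing of `level` between two samples
    return t0 + (v0 - level) / (v0 - v1) * (t1 - t0)


def compute_biomarkers(trace: APTrace, upstroke_threshold: float = 10.0) -> BiomarkerSet:
    """Compute the seven AP biomarkers of a single-beat trace.

    Raises NoActionPotentialError when no stimulus-evoked upstroke is present
    (dVmMax below ``upstroke_threshold`` mV/ms) and MissingAPDError when a
    repolarization level is never reached within the trace.
    """
    t, v = trace.times, trace.vm
    if t[-1] < 999.0:
        raise ValidationError("trace must cover at least [0, ~1000] ms")
    # RMP: held pre-stimulus value
    i0 = int(np.searchsorted(t, 0.0))
    rmp = float(v[i0]) if t[i0] <= 0.0 or i0 == 0 else float(v[i0 - 1])

    dv = np.diff(v) / np.diff(t)
    k = int(np.argmax(dv))
    dvmax = float(dv[k])
    if dvmax < upstroke_threshold:
        raise NoActionPotentialError(
            f"no upstroke: max dVm/dt {dvmax:.2f} mV/ms below {upstroke_threshold}")
    t_act = float(t[k])

    peak = float(v.max())
    i_peak = int(np.argmax(v))
    amp = peak - rmp

    apd = {}
    for x in (40, 50, 90):
        level = peak - x / 100.0 * amp
        below = np.nonzero(v[i_peak:] < level)[0]
        if below.size == 0:
            raise MissingAPDError(f"APD{x}: level {level:.1f} mV never reached")
        j = i_peak + below[0]
        t_cross = _interp_crossing(t[j - 1], v[j - 1], t[j], v[j], level) if j > 0 else t[j]
        apd[x] = float(t_cross - t_act)

    return BiomarkerSet(RMP=rmp, dVmMax=dvmax, Peak=peak,
                        APD40=apd[40], APD50=apd[50], APD90=apd[90],
                        Tri90_40=apd[90] - apd[40])


def is_unrepolarized(trace: APTrace) -> bool:
    """True iff |vm(1000) - vm(0)| exceeds 10% of the trace amplitude.

    The amplitude is peak-to-trough (max - min) of the trace; the comparison
    is strict, so a difference of exactly 10% is not flagged.  Flagged traces
    are far from full repolarization and are excluded from training data.
    """
    t = trace.times
    if t[0] > 0.0 or t[-1] < 1000.0 - 1e-9:
        raise ValidationError("trace must cover [0, 1000] ms")
    v0 = float(trace.vm_at(0.0))
    v1 = float(trace.vm_at(1000.0))
    amp = float(trace.vm.max() - trace.vm.min())
    return abs(v1 - v0) > 0.10 * amp


def detect_ead(trace: APTrace, config: EADConfig = DEFAULT_EAD_CONFIG) -> bool:
    """Flag a depolarizing deflection during repolarization (phase 2/3).

    The trace is smoothed with a short moving average; starting a guard
    interval after the AP peak, an EAD is a local minimum followed by a later
    sample at least ``config.delta`` mV above it that also lies above
    ``config.v_gate``.
    """
    t, v = trace.times, trace.vm
    n = config.smooth_points
    if n > 1:
        kernel = np.ones(n) / n
        v = np.convolve(v, kernel, mode="same")
        # convolution edge effects: keep raw samples at the borders
        h = n // 2
        v[:h] = trace.vm[:h]
        v[-h:] = trace.vm[-h:]
    i_peak = int(np.argmax(v))
    start = int(np.searchsorted(t, t[i_peak] + config.guard_ms))
    seg = v[start:]
    if seg.size < 3:
        return False
    running_min = np.minimum.accumulate(seg)
    rise = seg - running_min
    return bool(np.any((rise >= config.delta) & (seg > config.v_gate)))


def within_ranges(b: BiomarkerSet, r: BiomarkerRanges) -> bool:
    """True iff every biomarker lies inside its closed [min, max] interval."""
    for name, (lo, hi) in r.bounds.items():
        val = getattr(b, name)
        if not (lo <= val <= hi):
            return False
    return True


def detect_abnormality(last_trace: APTrace, prev_trace: APTrace | None = None,
                       config: EADConfig = DEFAULT_EAD_CONFIG) -> bool:
    """Abnormality on the last (up to two) consecutive beats.

    True iff any provided beat shows an EAD or fails the repolarization
    criterion (see is_unrepolarized).
    """
    for tr in (last_trace, prev_trace):
        if tr is None:
            continue
        if is_unrepolarized(tr) or detect_ead(tr, config):
            return True
    return False


def biomarkers_to_csv(sets, path) -> None:
    import pandas as pd

    pd.DataFrame([{n: getattr(b, n) for n in BIOMARKER_NAMES} for b in sets]).to_csv(
        path, index=False)


def biomarkers_from_csv(path) -> list:
    import pandas as pd

    df = pd.read_csv(path)
    return [BiomarkerSet(**{n: float(row[n]) for n in BIOMARKER_NAMES})
            for _, row in df.iterrows()]
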