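"""Microelectrode-style recording preprocessing for inverse fitting.

Raw recordings are the last 10 consecutive beats of a paced measurement:
each beat carries a stimulus artifact in the first ~1.5 ms and additive
noise.  The pipeline is

1. blank the stimulus artifact: vm(t) := RMP for t in [0, 1.75] ms, where
   RMP is the sample closest to the end of the beat;
2. resample to 100 kHz and low-pass with a second-order Butterworth filter
   (2.5 kHz cutoff), applied forward-backward so no phase shift leaks into
   the depolarization timing;
3. average the filtered beats and resample the average onto the final
   two-rate grid: 100 kHz on [0, 15) ms, 1 kHz on [15, 1000] ms.

A synthetic-recording generator emulates the structure of experimental data
(artifact spike, beat-to-beat Gaussian noise, alignment jitter) so that the
pipeline can be tested end to end without real measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as _sig

from .biomarkers import BiomarkerRanges, BiomarkerSet
from .errors import ValidationError
from .simulator import APTrace, ConductanceSet, PacingProtocol, simulate_ap

ARTIFACT_BLANK_MS = 1.75
FILTER_FS_KHZ = 100.0
FILTER_CUTOFF_KHZ = 2.5
FINAL_FAST_END_MS = 15.0

#: across-beat standard-deviation warning levels (mV), before/after the peak
QC_SD_PRE_PEAK = 7.0
QC_SD_POST_PEAK = 2.0


@dataclass
class RawRecording:
    """Consecutive beats on one shared uniform raw grid."""

    times: np.ndarray            # (T,) ms
    beats: np.ndarray            # (n_beats, T) mV

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.beats = np.atleast_2d(np.asarray(self.beats, dtype=np.float64))
        if self.beats.shape[1] != self.times.size or self.beats.shape[0] < 1:
            raise ValidationError("beats must be (n_beats >= 1, len(times))")

    @property
    def n_beats(self) -> int:
        return self.beats.shape[0]

    def beat(self, k: int) -> APTrace:
        return APTrace(times=self.times.copy(), vm=self.beats[k].copy())

    def to_csv(self, path: str | Path) -> None:
        header = "time_ms," + ",".join(f"beat_{k+1}" for k in range(self.n_beats))
        np.savetxt(path, np.column_stack([self.times, self.beats.T]),
                   delimiter=",", header=header, comments="")

    @classmethod
    def from_csv(cls, path: str | Path) -> "RawRecording":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(times=data[:, 0], beats=data[:, 1:].T)


def blank_stimulus(beat: APTrace) -> APTrace:
    """Replace the stimulus-artifact window [0, 1.75] ms by the end-of-beat RMP."""
    vm = beat.vm.copy()
    rmp = vm[-1]
    mask = (beat.times >= 0.0) & (beat.times <= ARTIFACT_BLANK_MS)
    vm[mask] = rmp
    return APTrace(times=beat.times.copy(), vm=vm, cycle_length=beat.cycle_length)


def filter_beat(beat: APTrace) -> APTrace:
    """Resample to 100 kHz and zero-phase low-pass (2nd-order Butterworth, 2.5 kHz)."""
    t0, t1 = beat.times[0], beat.times[-1]
    n = int(round((t1 - t0) * FILTER_FS_KHZ)) + 1
    if n < 20:
        raise ValidationError("beat too short for the filter warm-up")
    t = t0 + np.arange(n) / FILTER_FS_KHZ
    vm = np.interp(t, beat.times, beat.vm)
    b, a = _sig.butter(2, FILTER_CUTOFF_KHZ / (FILTER_FS_KHZ / 2.0))
    vm = _sig.filtfilt(b, a, vm)
    return APTrace(times=t, vm=vm, cycle_length=beat.cycle_length)


def final_grid(t_end: float = 1000.0) -> np.ndarray:
    """{[0, 15) at 100 kHz} followed by {[15, t_end] at 1 kHz}."""
    fast = np.arange(0.0, FINAL_FAST_END_MS, 1.0 / FILTER_FS_KHZ)
    slow = np.arange(FINAL_FAST_END_MS, t_end + 1e-9, 1.0)
    return np.concatenate([fast, slow])


def average_and_resample(recording: RawRecording):
    """Pointwise beat average on the final two-rate grid, plus a QC report.

    All beats must share one grid (blanked and filtered upstream).  The QC
    report contains the per-time across-beat standard deviation and flags
    when it exceeds the expected variability bounds (7 mV before the AP
    peak, 2 mV after).
    """
    beats = recording.beats
    mean = beats.mean(axis=0)
    sd = beats.std(axis=0, ddof=0)
    grid = final_grid(min(1000.0, recording.times[-1]))
    vm = np.interp(grid, recording.times, mean)
    i_peak = int(np.argmax(mean))
    qc = {
        "n_beats": recording.n_beats,
        "max_sd_pre_peak": float(sd[:i_peak + 1].max()) if i_peak >= 0 else 0.0,
        "max_sd_post_peak": float(sd[i_peak:].max()),
        "flag_pre_peak": bool(sd[:i_peak + 1].max() > QC_SD_PRE_PEAK),
        "flag_post_peak": bool(sd[i_peak:].max() > QC_SD_POST_PEAK),
    }
    return APTrace(times=grid, vm=vm), qc


def preprocess_recording(recording: RawRecording):
    """Full pipeline: blank, filter, average, resample.  Returns (APTrace, QC)."""
    processed = []
    t = None
    for k in range(recording.n_beats):
        f = filter_beat(blank_stimulus(recording.beat(k)))
        processed.append(f.vm)
        t = f.times
    return average_and_resample(RawRecording(times=t, beats=np.array(processed)))


def qc_exclude_pair(control_bm: BiomarkerSet, drug_bm: BiomarkerSet,
                    training_ranges: BiomarkerRanges) -> bool:
    """Exclude a control/drug AP pair when either AP leaves the training ranges."""
    from .biomarkers import within_ranges

    return not (within_ranges(control_bm, training_ranges)
                and within_ranges(drug_bm, training_ranges))


def synthesize_recording(conductances: ConductanceSet,
                         drug=None,
                         noise_sd: float = 1.0,
                         jitter_sd: float = 0.1,
                         artifact_mv: float = 40.0,
                         latency_ms: float = 2.0,
                         n_beats: int = 10,
                         fs_khz: float = 10.0,
                         protocol: PacingProtocol = PacingProtocol(),
                         seed=None) -> RawRecording:
    """Simulated stand-in for a raw microelectrode recording.

    Each beat is the simulator's steady-state AP, delayed by ``latency_ms``
    (field stimulation of a tissue preparation fires the impaled cell after
    the stimulus artifact has decayed), plus an artifact spike in [0, 1.5]
    ms, independent Gaussian noise (noise_sd mV) and per-beat alignment
    jitter (jitter_sd ms).
    """
    from .pharmacology import apply_drug

    g = apply_drug(conductances, drug) if drug is not None else conductances
    clean = simulate_ap(g, protocol)
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, protocol.cycle_length + 1e-9, 1.0 / fs_khz)
    beats = np.empty((n_beats, t.size))
    for k in range(n_beats):
        shift = jitter_sd * rng.standard_normal() if jitter_sd > 0 else 0.0
        vm = np.interp(t + shift - latency_ms, clean.times, clean.vm)
        if artifact_mv:
            vm = vm + artifact_mv * ((t >= 0.0) & (t <= 1.5))
        if noise_sd > 0:
            vm = vm + noise_sd * rng.standard_normal(t.size)
        beats[k] = vm
    return RawRecording(times=t, beats=beats)


def qc_report_to_json(qc: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(qc, indent=2))
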