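"""Synthetic-drug modelling and population-of-models calibration.

A synthetic drug is a vector of per-target scaling factors s applied
multiplicatively to a cell's control conductance scales (s < 1 block, s = 1
no effect, s > 1 enhancement).  Concentration-response data are converted to
scaling factors with the pore-block model

    s = 1 / (1 + (C / IC50)^h).

The calibrated population is built by screening Sobol'-sequence conductance
samples in [0.5, 1.5]^9 through the simulator: members must show no
repolarization abnormality on the last two consecutive beats and must have
all seven biomarkers of the final beat inside the experimental calibration
ranges.

Estimated drug parameters are classified against reference scaling-factor
distributions (e.g. derived from channel-block assay posteriors): an
estimate s is a success iff s lies in the closed interval mu +/- (0.15 + sigma)
of the reference distribution.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np

from .biomarkers import (BiomarkerRanges, compute_biomarkers,
                         detect_abnormality, within_ranges)
from .errors import CalibrationFailureError, ValidationError
from .simulator import CONDUCTANCE_NAMES, ConductanceSet, PacingProtocol, simulate_ap

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticDrug:
    """Per-target scaling factors over the nine targets (untouched = 1)."""

    factors: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, s in self.factors.items():
            if name not in CONDUCTANCE_NAMES:
                raise ValidationError(f"unknown drug target {name!r}")
            if not np.isfinite(s) or s < 0.0:
                raise ValidationError(f"scaling factor for {name} must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.factors.get(n, 1.0) for n in CONDUCTANCE_NAMES])

    @property
    def targets(self) -> tuple:
        return tuple(n for n in CONDUCTANCE_NAMES if n in self.factors)


def random_drug(n_targets: int = 4, low: float = 0.5, high: float = 1.5,
                seed=None) -> SyntheticDrug:
    """Random drug: targets drawn without replacement, factors uniform in [low, high]."""
    if not 1 <= n_targets <= 9:
        raise ValidationError("n_targets must be in 1..9")
    if not 0.0 <= low < high:
        raise ValidationError("require 0 <= low < high")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    targets = rng.choice(len(CONDUCTANCE_NAMES), size=n_targets, replace=False)
    factors = rng.uniform(low, high, size=n_targets)
    return SyntheticDrug({CONDUCTANCE_NAMES[i]: float(s)
                          for i, s in zip(targets, factors)})


def apply_drug(g: ConductanceSet, drug: SyntheticDrug) -> ConductanceSet:
    """Element-wise product of control conductances and drug factors.

    Results outside the simulator's [0, 2] domain are clipped with a warning.
    """
    scaled = g.as_array() * drug.as_array()
    if np.any(scaled > 2.0):
        _warnings.warn("drugged conductance clipped to the simulator domain [0, 2]")
        scaled = np.minimum(scaled, 2.0)
    return ConductanceSet.from_array(scaled)


def table2_drugs() -> list[SyntheticDrug]:
    """The ten hERG-block / Ca-enhancement drugs of the EAD test grid.

    gKr scaling runs 0.05..0.14 in steps of 0.01, pCa 1.20..1.38 in steps
    of 0.02.
    """
    return [SyntheticDrug({"gKr": round(0.05 + 0.01 * k, 2),
                           "pCa": round(1.20 + 0.02 * k, 2)}) for k in range(10)]


@dataclass(frozen=True)
class DrugChannelEffect:
    """Concentration-response parameters for one drug-target pair."""

    concentration: float
    ic50: float
    hill: float
    unit: str = "nM"
    ic50_unit: str = "nM"

    def __post_init__(self):
        if self.ic50 <= 0 or self.hill <= 0 or self.concentration < 0:
            raise ValidationError("require IC50 > 0, hill > 0, concentration >= 0")


def pore_block(effect: DrugChannelEffect) -> float:
    """Pore-block scaling factor s = 1 / (1 + (C / IC50)^h)."""
    if effect.unit != effect.ic50_unit:
        raise ValidationError(
            f"unit mismatch: concentration in {effect.unit}, IC50 in {effect.ic50_unit}")
    return 1.0 / (1.0 + (effect.concentration / effect.ic50) ** effect.hill)


# ---------------------------------------------------------------------------
# population of models
# ---------------------------------------------------------------------------
@dataclass
class Population:
    """Calibrated synthetic cardiomyocytes with their baseline biomarkers."""

    members: list                     # list[ConductanceSet]
    biomarkers: list                  # list[BiomarkerSet]
    acceptance_rate: float = np.nan
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


def build_population(n: int = 100,
                     ranges: BiomarkerRanges | None = None,
                     sampler_bounds: tuple = (0.5, 1.5),
                     protocol: PacingProtocol = PacingProtocol(),
                     seed=None,
                     min_acceptance: float = 0.01,
                     max_candidates: int = 10_000) -> Population:
    """First n Sobol'-sequence candidates passing the calibration filters.

    A candidate is accepted iff the last two consecutive beats show no
    abnormality (no EAD, full repolarization) and the last beat's seven
    biomarkers all fall inside ``ranges`` (closed intervals).
    """
    from scipy.stats import qmc

    ranges = ranges or BiomarkerRanges()
    lo, hi = sampler_bounds
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", UserWarning)
        sampler = qmc.Sobol(d=9, scramble=False, seed=seed)
    members, bms = [], []
    tried = 0
    while len(members) < n:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", UserWarning)
            pt = sampler.random(1)[0]
        tried += 1
        cand = ConductanceSet.from_array(lo + (hi - lo) * pt)
        try:
            last, prev = simulate_ap(cand, protocol, return_last_two=True)
            if detect_abnormality(last, prev):
                ok = False
            else:
                bm = compute_biomarkers(last)
                ok = within_ranges(bm, ranges)
        except Exception:
            ok = False
        if ok:
            members.append(cand)
            bms.append(bm)
        if tried >= max_candidates and len(members) / tried < min_acceptance:
            raise CalibrationFailureError(
                f"acceptance rate {len(members)}/{tried} below {min_acceptance:.0%}")
    rate = len(members) / tried
    log.info("population of %d built from %d candidates (%.1f%% accepted)",
             n, tried, 100 * rate)
    return Population(members=members, biomarkers=bms, acceptance_rate=rate,
                      provenance={"bounds": (lo, hi), "candidates": tried})


# ---------------------------------------------------------------------------
# reference distributions and the success rule
# ---------------------------------------------------------------------------
@dataclass
class ReferenceDistribution:
    """Samples of one drug-target scaling factor with recomputed mu/sigma."""

    samples: np.ndarray
    drug: str = ""
    target: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.size == 0:
            raise ValidationError("reference distribution needs at least one sample")

    @property
    def mu(self) -> float:
        return float(self.samples.mean())

    @property
    def sigma(self) -> float:
        return float(self.samples.std(ddof=0))


def success_classify(s_est: float, dist: ReferenceDistribution,
                     margin: float = 0.15) -> bool:
    """Success iff s_est lies in the closed interval mu +/- (margin + sigma)."""
    half = margin + dist.sigma
    return bool(dist.mu - half <= s_est <= dist.mu + half)


def tabulate_success(flags_by_target: dict) -> dict:
    """Counts table mirroring a successful/unsuccessful/ratio summary.

    flags_by_target maps target name -> iterable of booleans (one per
    classified preparation/drug pair).
    """
    table = {}
    tot_s = tot_u = 0
    for target, flags in flags_by_target.items():
        flags = list(flags)
        s = sum(bool(f) for f in flags)
        u = len(flags) - s
        table[target] = {"successful": s, "unsuccessful": u,
                         "ratio": round(s / len(flags), 2) if flags else np.nan}
        tot_s += s
        tot_u += u
    total = tot_s + tot_u
    table["Total"] = {"successful": tot_s, "unsuccessful": tot_u,
                      "ratio": round(tot_s / total, 2) if total else np.nan}
    return table


def synthetic_reference_distribution(drug: str, target: str, concentration: float,
                                     ic50_median: float, hill: float = 1.0,
                                     n: int = 2000, spread: float = 0.3,
                                     seed=None) -> ReferenceDistribution:
    """Synthetic stand-in for an assay-derived scaling-factor distribution.

    IC50 samples are log-normal around ic50_median (geometric sd exp(spread));
    each is pushed through the pore-block model at the given concentration.
    """
    rng = np.random.default_rng(seed)
    ic50s = ic50_median * np.exp(spread * rng.standard_normal(n))
    s = 1.0 / (1.0 + (concentration / ic50s) ** hill)
    return ReferenceDistribution(samples=s, drug=drug, target=target)


def reference_distributions_from_csv(path) -> dict:
    """Load reference samples from CSV columns (drug, target, sample_value)."""
    import pandas as pd

    df = pd.read_csv(path)
    for col in ("drug", "target", "sample_value"):
        if col not in df.columns:
            raise ValidationError(f"reference CSV missing column {col!r}")
    out = {}
    for (drug, target), grp in df.groupby(["drug", "target"]):
        out[(drug, target)] = ReferenceDistribution(
            samples=grp["sample_value"].to_numpy(), drug=drug, target=target)
    return out
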