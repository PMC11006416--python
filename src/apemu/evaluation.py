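"""Evaluation metrics and forward/inverse experiment drivers.

Metrics: trace RMSE (mV, over a shared time grid), vector RMSE
(sqrt(||u - v||^2 / N)) for biomarker and conductance vectors, error vectors
e_n = x - x̂ (normalized-conductance scale) and e_s = s - ŝ (scaling-factor
scale), and confusion statistics for EAD classification.

The experiment drivers reproduce the package's forward evaluation (emulated
versus simulated drugged APs over a calibrated population, including EAD
confusion statistics) and inverse evaluation (conductance and scaling-factor
recovery from simulated control/drug AP pairs).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .biomarkers import compute_biomarkers, detect_ead, is_unrepolarized
from .dataset import extend_and_resample
from .emulator import (EmulatorWeights, NormalizedConductances, emulate_ap,
                       normalize)
from .errors import ValidationError
from .inverse import FitConfig, estimate_control, estimate_drug, scaling_factors
from .pharmacology import Population, SyntheticDrug, apply_drug
from .simulator import APTrace, CONDUCTANCE_NAMES, PacingProtocol, simulate_ap

log = logging.getLogger(__name__)


def rmse_trace(a: APTrace, b: APTrace, interpolate: bool = False) -> float:
    """Root-mean-squared voltage difference (mV) over a shared grid.

    With interpolate=True, b is linearly interpolated onto a's grid over the
    overlapping time support.
    """
    if interpolate:
        lo = max(a.times[0], b.times[0])
        hi = min(a.times[-1], b.times[-1])
        if hi <= lo:
            raise ValidationError("traces have no overlapping time support")
        m = (a.times >= lo) & (a.times <= hi)
        va = a.vm[m]
        vb = b.vm_at(a.times[m])
    else:
        if a.times.shape != b.times.shape or not np.allclose(a.times, b.times):
            raise ValidationError("traces are on different grids; pass interpolate=True")
        va, vb = a.vm, b.vm
    return float(np.sqrt(np.mean((va - vb) ** 2)))


def rmse_vector(u, v) -> float:
    """sqrt(sum((u_i - v_i)^2) / N) for equal-length vectors."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValidationError(f"length mismatch: {u.shape} vs {v.shape}")
    return float(np.sqrt(np.mean((u - v) ** 2)))


def error_vectors(x_est: NormalizedConductances, x_true: NormalizedConductances,
                  s_est=None, s_true=None) -> dict:
    """e_n = x - x̂ (and e_s = s - ŝ when scaling factors are given)."""
    out = {"e_n": np.asarray(x_est.x) - np.asarray(x_true.x)}
    if s_est is not None and s_true is not None:
        out["e_s"] = np.asarray(s_est) - np.asarray(s_true)
    return out


@dataclass(frozen=True)
class ConfusionStats:
    TP: int
    FN: int
    FP: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.FP + self.TN

    @property
    def sensitivity(self) -> float:
        """Percent of positive cases correctly classified, one decimal."""
        denom = self.TP + self.FN
        return round(100.0 * self.TP / denom, 1) if denom else float("nan")

    @property
    def specificity(self) -> float:
        denom = self.TN + self.FP
        return round(100.0 * self.TN / denom, 1) if denom else float("nan")

    @property
    def accuracy(self) -> float:
        return round(100.0 * (self.TP + self.TN) / self.total, 1) if self.total else float("nan")

    def as_dict(self) -> dict:
        return {"TP": self.TP, "FN": self.FN, "FP": self.FP, "TN": self.TN,
                "sensitivity": self.sensitivity, "specificity": self.specificity,
                "accuracy": self.accuracy}


def confusion_stats(true_flags, predicted_flags) -> ConfusionStats:
    t = np.asarray(list(true_flags), dtype=bool)
    p = np.asarray(list(predicted_flags), dtype=bool)
    if t.shape != p.shape:
        raise ValidationError("flag lists must have equal length")
    if t.size == 0:
        raise ValidationError("empty flag lists")
    return ConfusionStats(TP=int(np.sum(t & p)), FN=int(np.sum(t & ~p)),
                          FP=int(np.sum(~t & p)), TN=int(np.sum(~t & ~p)))


# ---------------------------------------------------------------------------
# experiment drivers
# ---------------------------------------------------------------------------
def run_forward_experiment(population: Population, drugs: list[SyntheticDrug],
                           weights: EmulatorWeights,
                           protocol: PacingProtocol = PacingProtocol()) -> dict:
    """Forward problem: emulate drugged APs and compare with simulation.

    For every (member, drug) pair the drugged conductances are simulated
    (ground truth) and emulated; simulated APs failing the repolarization
    criterion are discarded (as in the abnormal-AP test-data construction).
    The report carries per-AP RMSEs, biomarker mismatches for normal APs and
    EAD confusion statistics.
    """
    rmses, bm_err, true_ead, pred_ead = [], [], [], []
    n_discarded = 0
    for member in population.members:
        for drug in drugs:
            g_drug = apply_drug(member, drug)
            sim = simulate_ap(g_drug, protocol)
            if is_unrepolarized(sim):
                n_discarded += 1
                continue
            sim_c = extend_and_resample(sim)
            emu = emulate_ap(normalize(g_drug), sim_c.times, weights)
            rmses.append(rmse_trace(sim_c, emu))
            t_ead = detect_ead(sim_c)
            p_ead = detect_ead(emu)
            true_ead.append(t_ead)
            pred_ead.append(p_ead)
            if not t_ead and not p_ead:
                try:
                    db = (compute_biomarkers(emu).as_array()
                          - compute_biomarkers(sim_c).as_array())
                    bm_err.append(db)
                except Exception:
                    pass
    report = {
        "n_pairs": len(rmses),
        "n_discarded_unrepolarized": n_discarded,
        "rmse_mean": float(np.mean(rmses)) if rmses else float("nan"),
        "rmse_max": float(np.max(rmses)) if rmses else float("nan"),
        "rmse_all": [float(r) for r in rmses],
        "n_ead_true": int(np.sum(true_ead)),
        "confusion": confusion_stats(true_ead, pred_ead).as_dict() if rmses else None,
    }
    if true_ead and any(true_ead):
        ead_rmses = [r for r, f in zip(rmses, true_ead) if f]
        report["rmse_mean_ead"] = float(np.mean(ead_rmses))
    if bm_err:
        arr = np.array(bm_err)
        report["biomarker_rmse"] = {
            name: float(np.sqrt(np.mean(arr[:, k] ** 2)))
            for k, name in enumerate(("RMP", "dVmMax", "Peak", "APD40", "APD50",
                                      "APD90", "Tri90_40"))}
    return report


def run_inverse_experiment(population: Population, drugs: list[SyntheticDrug],
                           weights: EmulatorWeights,
                           cfg: FitConfig = FitConfig(),
                           protocol: PacingProtocol = PacingProtocol(),
                           fit_stride: int = 4,
                           iterations: int | None = None,
                           use_simulator_targets: bool = True) -> dict:
    """Inverse problem: estimate conductances and scaling factors per pair.

    Control and drugged APs (simulated by default, emulated when
    use_simulator_targets=False) are fitted with the estimate-control /
    estimate-drug workflow; errors e_n and e_s are accumulated per
    coordinate.  fit_stride subsamples the canonical grid for speed.
    """
    e_ctrl, e_drug, e_s = [], [], []
    for member in population.members:
        x_true_c = normalize(member)
        tgt_c = _fit_target(member, x_true_c, weights, protocol, fit_stride,
                            use_simulator_targets)
        fit_c = estimate_control(tgt_c, weights, cfg, iterations=iterations)
        e_ctrl.append(fit_c.x_hat.x - x_true_c.x)
        for drug in drugs:
            g_drug = apply_drug(member, drug)
            x_true_d = normalize(g_drug)
            tgt_d = _fit_target(g_drug, x_true_d, weights, protocol, fit_stride,
                                use_simulator_targets)
            fit_d = estimate_drug(tgt_d, fit_c.x_hat, weights, cfg,
                                  iterations=iterations)
            e_drug.append(fit_d.x_hat.x - x_true_d.x)
            s_est = scaling_factors(fit_c.x_hat, fit_d.x_hat, weights.g_ref)
            e_s.append(s_est - drug.as_array())
    report = {"n_members": len(population.members), "n_drugs": len(drugs)}
    for key, errs in (("control", e_ctrl), ("drug", e_drug), ("s", e_s)):
        if not errs:
            report[f"e_{key}"] = None
            continue
        arr = np.array(errs)
        report[f"e_{key}"] = {
            "per_coordinate_rmse": {n: float(np.sqrt(np.mean(arr[:, k] ** 2)))
                                    for k, n in enumerate(CONDUCTANCE_NAMES)},
            "per_coordinate_median": {n: float(np.median(arr[:, k]))
                                      for k, n in enumerate(CONDUCTANCE_NAMES)},
            "rmse_overall": float(np.sqrt(np.mean(arr ** 2))),
        }
    return report


def _fit_target(g, x_norm, weights, protocol, stride, use_simulator):
    if use_simulator:
        sim = extend_and_resample(simulate_ap(g, protocol))
        return APTrace(times=sim.times[::stride], vm=sim.vm[::stride])
    from .dataset import CANONICAL_GRID

    return emulate_ap(x_norm, CANONICAL_GRID[::stride], weights)


def save_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float))


def load_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
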