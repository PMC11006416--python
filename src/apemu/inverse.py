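"""Inverse problem: estimate conductance scale factors from a target AP.

Given a target trace V̂m on times T̂ inside the trained domain, the fitter
minimizes

    1/(2|T̂|) * sum_t (Vm(x, t - t0) - V̂m(t))^2  +  (λ/2) ||x - x̂||²

over the normalized conductances x (projected onto the feasible box
[-0.5, 0.5]^9 after every step) and a temporal offset t0 that absorbs
depolarization-timing mismatch.  Because multiple conductance sets can
produce near-identical APs, the quadratic prior around x̂ pins weakly
identifiable coordinates.

Pharmacological workflow: the control AP is fitted with x̂ = x0 = 0
(baseline), the drugged AP with x̂ = x0 = the control estimate, and per-target
drug scaling factors are the element-wise ratios of the denormalized drugged
and control conductances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam
from .emulator import (DEFAULT_G_REF, EmulatorWeights, NormalizedConductances,
                       backward, denormalize, forward)
from .errors import ValidationError
from .simulator import APTrace, ConductanceSet

log = logging.getLogger(__name__)


@dataclass
class FitConfig:
    lambda_x0: float = 10.0
    iterations: int = 10_000          # synthetic-data default
    iterations_control: int = 50_000  # experimental-style control fits
    iterations_drug: int = 25_000     # experimental-style drug fits
    lr_x: float = 2e-3
    lr_t0: float = 5e-2               # t0 is in ms, a different scale from x
    fit_t0: bool = True
    tol: float = 0.0                  # >0 enables early stop on objective change
    log_every: int = 0

    def __post_init__(self):
        if self.lambda_x0 < 0:
            raise ValidationError("lambda_x0 must be >= 0")
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")


@dataclass
class FitResult:
    x_hat: NormalizedConductances
    t0: float
    objective: float
    rmse: float                      # trace RMSE against the target, mV
    objective_trajectory: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {"x_hat": self.x_hat.x.tolist(), "t0": self.t0,
                "objective": self.objective, "rmse": self.rmse}


def _project(x: np.ndarray) -> np.ndarray:
    return np.clip(x, -0.5, 0.5)


def fit_ap(target: APTrace, x_init: NormalizedConductances,
           x_prior: NormalizedConductances, w: EmulatorWeights,
           cfg: FitConfig = FitConfig(), iterations: int | None = None) -> FitResult:
    """Projected-Adam minimization of the data + prior objective.

    ``iterations`` overrides cfg.iterations when given.  The target times,
    shifted by the current t0, are clamped to the trained domain [-10, 1000]
    ms (with a warning) before evaluation.
    """
    t_tgt = np.asarray(target.times, dtype=np.float64)
    v_tgt = np.asarray(target.vm, dtype=np.float64)
    if t_tgt[0] < -10.0 - 1e-9 or t_tgt[-1] > 1000.0 + 1e-9:
        raise ValidationError("target grid outside trained domain [-10, 1000] ms")
    n_iter = cfg.iterations if iterations is None else iterations

    dtype = w.dtype
    x = np.asarray(x_init.x, dtype=np.float64).copy()
    prior = np.asarray(x_prior.x, dtype=np.float64)
    t0 = 0.0
    n_t = t_tgt.size
    lam = cfg.lambda_x0

    opt = Adam([x], lr=cfg.lr_x)
    opt_t0 = Adam([np.zeros(1)], lr=cfg.lr_t0)
    t0_arr = opt_t0.params[0]

    traj = np.empty(n_iter)
    warned = False
    for it in range(n_iter):
        t_eval = t_tgt - t0_arr[0]
        clipped = np.clip(t_eval, -10.0, 1000.0)
        if not warned and np.any(clipped != t_eval):
            log.warning("shifted target times clamped to the trained domain")
            warned = True
        vm, cache = forward(w, x[None, :].astype(dtype), clipped, with_cache=True)
        diff = vm[0].astype(np.float64) - v_tgt
        data_term = float(np.sum(diff ** 2) / (2.0 * n_t))
        obj = data_term + 0.5 * lam * float(np.sum((x - prior) ** 2))
        traj[it] = obj
        if not np.isfinite(obj):
            raise ValidationError(f"non-finite objective at iteration {it}")

        grads = backward(w, cache, (diff / n_t)[None, :].astype(dtype),
                         need_weight_grads=False, need_input_grads=True)
        gx = grads["x"][0].astype(np.float64) + lam * (x - prior)
        opt.step([gx])
        x[:] = _project(x)
        if cfg.fit_t0:
            # dVm/dt_eval summed; t_eval = t - t0 so d/dt0 = -d/dt
            gt0 = -float(grads["t"].astype(np.float64).sum())
            opt_t0.step([np.array([gt0])])
        if cfg.log_every and it % cfg.log_every == 0:
            log.info("iter %d objective %.5f", it, obj)
        if cfg.tol > 0.0 and it > 10 and abs(traj[it - 1] - obj) < cfg.tol:
            traj = traj[:it + 1]
            break

    t_eval = np.clip(t_tgt - t0_arr[0], -10.0, 1000.0)
    vm = forward(w, x[None, :].astype(dtype), t_eval)[0].astype(np.float64)
    rmse = float(np.sqrt(np.mean((vm - v_tgt) ** 2)))
    data_term = float(np.sum((vm - v_tgt) ** 2) / (2.0 * n_t))
    obj = data_term + 0.5 * lam * float(np.sum((x - prior) ** 2))
    return FitResult(x_hat=NormalizedConductances(x), t0=float(t0_arr[0]),
                     objective=obj, rmse=rmse, objective_trajectory=traj)


ZERO_X = NormalizedConductances(np.zeros(9))


def estimate_control(trace: APTrace, w: EmulatorWeights,
                     cfg: FitConfig = FitConfig(),
                     iterations: int | None = None) -> FitResult:
    """Fit a control AP with baseline initial guess and prior (x0 = x̂ = 0)."""
    return fit_ap(trace, ZERO_X, ZERO_X, w, cfg, iterations=iterations)


def estimate_drug(trace: APTrace, x_control: NormalizedConductances,
                  w: EmulatorWeights, cfg: FitConfig = FitConfig(),
                  iterations: int | None = None) -> FitResult:
    """Fit a drugged AP using the control estimate as initial guess and prior."""
    return fit_ap(trace, x_control, x_control, w, cfg, iterations=iterations)


def scaling_factors(x_control: NormalizedConductances,
                    x_drug: NormalizedConductances,
                    g_ref: ConductanceSet = DEFAULT_G_REF) -> np.ndarray:
    """Per-target drug scaling factors s_i = (G_d)_i / (G_c)_i (physical scale)."""
    g_c = denormalize(x_control, g_ref).as_array()
    g_d = denormalize(x_drug, g_ref).as_array()
    zero = np.nonzero(g_c <= 0.0)[0]
    if zero.size:
        from .simulator import CONDUCTANCE_NAMES

        names = [CONDUCTANCE_NAMES[i] for i in zero]
        raise ValidationError(f"control conductance is zero for {names}; "
                              "scaling factor undefined")
    return g_d / g_c
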