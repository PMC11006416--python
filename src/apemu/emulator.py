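"""Two-stage neural emulator of the paced action potential.

An encoder network maps the nine normalized conductance scale factors to a
256-dimensional latent code plus three depolarization parameters (slope d1,
offset d2, amplitude d3).  A time-conditioned decoder network evaluates the
latent-parameterized function f_theta at any time t, and the emulated
transmembrane potential is

    Vm(t) = f_theta(t) + (d3 / 2) * tanh((d1 / 2) * (t - d2)),

so the cheap encoder runs once per AP while the decoder can be evaluated on
an arbitrary time grid.  Time enters the decoder as the first eight powers of
a log-warped normalized time that maps the trained domain [-10, 1000] ms
onto [-1, 1] while concentrating resolution on the millisecond-scale
depolarization (see ``normalized_time``).

The decoder works on the scale Vm / 100 internally so its targets are O(1);
all public interfaces are in mV.  Both networks are plain dense MLPs with ELU
activations (the decoder's last hidden layer is bounded by tanh before the
final linear map), implemented with explicit numpy forward/backward passes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._nn import (elu, elu_grad, init_layers, mlp_backward, mlp_forward,
                  softplus_grad)
from .errors import ValidationError
from .simulator import APTrace, ConductanceSet

LATENT_DIM = 256
N_TIME_FEATURES = 8
ENC_SIZES = (9, 256, 256, 256, LATENT_DIM + 3)
DEC_SIZES = (LATENT_DIM + N_TIME_FEATURES, 64, 64, 64, 64, 1)
ENC_ACTS = ("elu", "elu", "elu", "linear")
DEC_ACTS = ("elu", "elu", "elu", "tanh", "linear")

# Normalized time: the trained domain [-10, 1000] ms is warped
# logarithmically (u = log1p((t + 10)/tau), linearly extended below t = -10)
# and then mapped affinely onto [-1, 1].  The warp spends feature resolution
# where the AP has structure: the millisecond-scale depolarization occupies a
# finite fraction of the normalized axis instead of ~1% of a linear axis.
T_WARP_TAU = 10.0  # ms
_T_WARP_MAX = float(np.log1p(1010.0 / T_WARP_TAU))
# The slope and amplitude heads use bounded sigmoid parameterizations
# (positive by construction, and immune to the saturation death / runaway
# sharpening that an unbounded positive map suffers during optimization).
D1_MAX = 16.0      # 1/ms, upper bound of the depolarization slope
D2_SCALE = 5.0     # ms per raw unit of the encoder's offset output
D3_MAX = 2.0       # dimensionless (Vm/VM_SCALE), upper bound of the amplitude
VM_SCALE = 100.0   # mV; decoder-internal potential scale
# encoder-head bias initialization: start the depolarization term near a
# physiological upstroke (slope ~8/ms, offset ~0.8 ms, amplitude ~130 mV)
D_HEAD_BIAS_INIT = (0.0, 0.16, 0.62)

DEFAULT_G_REF = ConductanceSet()


@dataclass(frozen=True)
class NormalizedConductances:
    """Nine conductance coordinates mapped to the symmetric box [-0.5, 0.5]."""

    x: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=np.float64))
        if self.x.shape != (9,):
            raise ValidationError(f"expected 9 coordinates, got shape {self.x.shape}")
        if np.any(self.x < -0.5 - 1e-9) or np.any(self.x > 0.5 + 1e-9):
            raise ValidationError("normalized conductances must lie in [-0.5, 0.5]")


def normalize(g: ConductanceSet, g_ref: ConductanceSet = DEFAULT_G_REF) -> NormalizedConductances:
    """x_i = G_i / (2 * G_ref,i) - 0.5; x = 0 corresponds to baseline."""
    ref = g_ref.as_array()
    if np.any(ref <= 0.0):
        raise ValidationError("g_ref must be strictly positive")
    return NormalizedConductances(g.as_array() / (2.0 * ref) - 0.5)


def denormalize(x: NormalizedConductances, g_ref: ConductanceSet = DEFAULT_G_REF) -> ConductanceSet:
    ref = g_ref.as_array()
    if np.any(ref <= 0.0):
        raise ValidationError("g_ref must be strictly positive")
    return ConductanceSet.from_array((np.asarray(x.x) + 0.5) * 2.0 * ref)


@dataclass(frozen=True)
class LatentCode:
    """Encoder output: latent vector plus physical depolarization parameters."""

    theta: np.ndarray   # (256,)
    d1: float           # slope, 1/ms
    d2: float           # offset, ms
    d3: float           # amplitude, mV


class EmulatorWeights:
    """Parameters of the encoder/decoder pair plus normalization metadata."""

    def __init__(self, theta1, theta2, g_ref: ConductanceSet = DEFAULT_G_REF,
                 meta: dict | None = None):
        self.theta1 = theta1
        self.theta2 = theta2
        self.g_ref = g_ref
        self.meta = meta or {}
        self._validate()

    def _validate(self):
        for layers, sizes, name in ((self.theta1, ENC_SIZES, "encoder"),
                                    (self.theta2, DEC_SIZES, "decoder")):
            if len(layers) != len(sizes) - 1:
                raise ValidationError(f"{name}: expected {len(sizes)-1} layers")
            for k, (W, b) in enumerate(layers):
                if W.shape != (sizes[k], sizes[k + 1]) or b.shape != (sizes[k + 1],):
                    raise ValidationError(
                        f"{name} layer {k}: shape {W.shape}/{b.shape} != "
                        f"({sizes[k]}, {sizes[k+1]})")
                if not (np.all(np.isfinite(W)) and np.all(np.isfinite(b))):
                    raise ValidationError(f"{name} layer {k}: non-finite weights")

    @classmethod
    def initialize(cls, seed: int = 0, dtype=np.float64,
                   g_ref: ConductanceSet = DEFAULT_G_REF) -> "EmulatorWeights":
        rng = np.random.default_rng(seed)
        theta1 = init_layers(ENC_SIZES, rng, dtype)
        theta1[-1][1][LATENT_DIM:] = np.asarray(D_HEAD_BIAS_INIT, dtype=dtype)
        return cls(theta1, init_layers(DEC_SIZES, rng, dtype),
                   g_ref=g_ref, meta={"init_seed": seed})

    @property
    def dtype(self):
        return self.theta1[0][0].dtype

    def astype(self, dtype) -> "EmulatorWeights":
        cast = lambda layers: [(W.astype(dtype), b.astype(dtype)) for W, b in layers]
        return EmulatorWeights(cast(self.theta1), cast(self.theta2), self.g_ref,
                               dict(self.meta))

    def params(self):
        out = []
        for layers in (self.theta1, self.theta2):
            for W, b in layers:
                out.extend((W, b))
        return out

    def copy(self) -> "EmulatorWeights":
        cp = lambda layers: [(W.copy(), b.copy()) for W, b in layers]
        return EmulatorWeights(cp(self.theta1), cp(self.theta2), self.g_ref,
                               dict(self.meta))

    # ---- persistence: npz archive with a JSON metadata header ------------
    def save(self, path: str | Path) -> None:
        arrays = {}
        for name, layers in (("enc", self.theta1), ("dec", self.theta2)):
            for k, (W, b) in enumerate(layers):
                arrays[f"{name}_W{k}"] = W
                arrays[f"{name}_b{k}"] = b
        meta = dict(self.meta)
        meta.update({
            "enc_sizes": list(ENC_SIZES), "dec_sizes": list(DEC_SIZES),
            "t_warp_tau": T_WARP_TAU, "d2_scale": D2_SCALE,
            "vm_scale": VM_SCALE, "g_ref": self.g_ref.as_array().tolist(),
        })
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "EmulatorWeights":
        with np.load(path) as f:
            meta = json.loads(bytes(f["__meta__"]).decode())
            theta1 = [(f[f"enc_W{k}"], f[f"enc_b{k}"]) for k in range(len(ENC_SIZES) - 1)]
            theta2 = [(f[f"dec_W{k}"], f[f"dec_b{k}"]) for k in range(len(DEC_SIZES) - 1)]
        g_ref = ConductanceSet.from_array(meta.pop("g_ref"))
        return cls(theta1, theta2, g_ref=g_ref, meta=meta)


def normalized_time(t: np.ndarray) -> np.ndarray:
    """Log-warped, affinely normalized time; [-10, 1000] ms maps to [-1, 1]."""
    tw = np.asarray(t, dtype=np.float64) + 10.0
    u = np.where(tw >= 0.0, np.log1p(np.maximum(tw, 0.0) / T_WARP_TAU),
                 tw / T_WARP_TAU)
    return 2.0 * u / _T_WARP_MAX - 1.0


def normalized_time_grad(t: np.ndarray) -> np.ndarray:
    """d(normalized time)/dt in 1/ms."""
    tw = np.asarray(t, dtype=np.float64) + 10.0
    du = np.where(tw >= 0.0, 1.0 / (T_WARP_TAU + np.maximum(tw, 0.0)),
                  1.0 / T_WARP_TAU)
    return 2.0 * du / _T_WARP_MAX


def time_features(t: np.ndarray, dtype=np.float64) -> np.ndarray:
    """Powers 1..8 of the normalized time, shape (len(t), 8)."""
    tt = normalized_time(t).astype(dtype)
    return np.stack([tt ** p for p in range(1, N_TIME_FEATURES + 1)], axis=-1)


def _encode_raw(x_arr: np.ndarray, w: EmulatorWeights):
    """Encoder forward on a (B, 9) batch; returns outputs, cache, and d params."""
    out, cache = mlp_forward(x_arr, w.theta1, ENC_ACTS)
    theta = out[..., :LATENT_DIM]
    r1, r2, r3 = out[..., LATENT_DIM], out[..., LATENT_DIM + 1], out[..., LATENT_DIM + 2]
    d1 = D1_MAX * softplus_grad(r1)          # softplus_grad == logistic sigmoid
    d2 = D2_SCALE * r2
    d3 = D3_MAX * softplus_grad(r3)          # dimensionless (Vm / VM_SCALE units)
    return theta, (d1, d2, d3), (r1, r2, r3), cache


def encode(x: NormalizedConductances, w: EmulatorWeights) -> LatentCode:
    """Map normalized conductances to the latent code and depolarization params."""
    theta, (d1, d2, d3), _raw, _cache = _encode_raw(
        np.asarray(x.x, dtype=w.dtype)[None, :], w)
    return LatentCode(theta=np.asarray(theta[0], dtype=np.float64),
                      d1=float(d1[0]), d2=float(d2[0]), d3=float(VM_SCALE * d3[0]))


def forward(w: EmulatorWeights, x_arr: np.ndarray, t: np.ndarray,
            with_cache: bool = False):
    """Full emulator forward pass.

    x_arr : (B, 9) normalized conductances
    t     : (T,) times in ms
    Returns vm (B, T) in mV, and a cache for `backward` when requested.
    """
    dtype = w.dtype
    x_arr = np.asarray(x_arr, dtype=dtype)
    t = np.asarray(t, dtype=np.float64)
    B, T = x_arr.shape[0], t.shape[0]

    theta, (d1, d2, d3), raw, enc_cache = _encode_raw(x_arr, w)
    tf = time_features(t, dtype=dtype)                       # (T, 8)

    # The decoder's first layer separates into a per-sample term (latent
    # code, computed once per AP) and a per-time term, so the (B*T) x 264
    # product never materializes; layers 2+ run on the (B, T, 64) activations.
    W1, b1 = w.theta2[0]
    pre1 = (theta @ W1[:LATENT_DIM])[:, None, :] \
        + (tf @ W1[LATENT_DIM:] + b1)[None, :, :]            # (B, T, 64)
    h1 = elu(pre1)
    f_hat, dec_cache = mlp_forward(h1, w.theta2[1:], DEC_ACTS[1:])
    f_hat = f_hat[..., 0]

    arg = 0.5 * d1[:, None] * (t[None, :].astype(dtype) - d2[:, None])
    th = np.tanh(arg)
    u = 0.5 * d3[:, None] * th
    vm = VM_SCALE * (f_hat + u)
    if not with_cache:
        return vm
    cache = dict(enc_cache=enc_cache, dec_cache=dec_cache, raw=raw, t=t,
                 d=(d1, d2, d3), th=th, f_hat=f_hat, B=B, T=T,
                 theta=theta, tf=tf, pre1=pre1)
    return vm, cache


def backward(w: EmulatorWeights, cache: dict, grad_vm: np.ndarray,
             need_weight_grads: bool = True, need_input_grads: bool = False):
    """Reverse pass of `forward` for an upstream gradient dL/dvm of shape (B, T).

    Returns a dict with any of:
      'theta1', 'theta2' : per-layer (dW, db) lists
      'x'                : (B, 9) gradient w.r.t. normalized conductances
      't'                : (B, T) gradient w.r.t. time (through decoder and tanh)
    """
    dtype = w.dtype
    d1, d2, d3 = cache["d"]
    th = cache["th"]
    t = cache["t"]
    g = np.asarray(grad_vm, dtype=dtype) * VM_SCALE          # dL/d(f_hat + u)

    # decoder: generic reverse through layers 2+, then the split first layer
    g_dec_out = g[..., None]                                  # (B, T, 1)
    g_h1, dec_grads_rest = mlp_backward(g_dec_out, w.theta2[1:], DEC_ACTS[1:],
                                        cache["dec_cache"])
    g_pre1 = g_h1 * elu_grad(cache["pre1"])                   # (B, T, 64)
    theta = cache["theta"]
    tf = cache["tf"]
    W1, _b1 = w.theta2[0]
    g_pre1_sum_t = g_pre1.sum(axis=1)                         # (B, 64)
    dW1 = np.empty_like(W1)
    dW1[:LATENT_DIM] = theta.T @ g_pre1_sum_t
    dW1[LATENT_DIM:] = tf.T @ g_pre1.sum(axis=0)
    db1 = g_pre1_sum_t.sum(axis=0)
    dec_grads = [(dW1, db1)] + dec_grads_rest
    g_theta = g_pre1_sum_t @ W1[:LATENT_DIM].T                # (B, 256)

    # tanh depolarization term
    sech2 = 1.0 - th ** 2
    tmd = t[None, :].astype(dtype) - d2[:, None]
    g_d1 = (g * 0.5 * d3[:, None] * sech2 * 0.5 * tmd).sum(axis=1)
    g_d2 = (g * 0.5 * d3[:, None] * sech2 * (-0.5) * d1[:, None]).sum(axis=1)
    g_d3 = (g * 0.5 * th).sum(axis=1)

    # route into the encoder output
    r1, _r2, r3 = cache["raw"]
    g_enc_out = np.empty((cache["B"], LATENT_DIM + 3), dtype=dtype)
    g_enc_out[:, :LATENT_DIM] = g_theta
    s1 = softplus_grad(r1)
    s3 = softplus_grad(r3)
    g_enc_out[:, LATENT_DIM] = g_d1 * D1_MAX * s1 * (1.0 - s1)
    g_enc_out[:, LATENT_DIM + 1] = g_d2 * D2_SCALE
    g_enc_out[:, LATENT_DIM + 2] = g_d3 * D3_MAX * s3 * (1.0 - s3)
    g_x, enc_grads = mlp_backward(g_enc_out, w.theta1, ENC_ACTS, cache["enc_cache"])

    out = {}
    if need_weight_grads:
        out["theta1"] = enc_grads
        out["theta2"] = dec_grads
    if need_input_grads:
        out["x"] = g_x
        # dVm/dt: decoder part through the time features + tanh part
        tt = normalized_time(t)
        dtt = normalized_time_grad(t)
        dtf_dt = np.stack([p * tt ** (p - 1) * dtt
                           for p in range(1, N_TIME_FEATURES + 1)], axis=-1)
        g_tf = g_pre1 @ W1[LATENT_DIM:].T                     # (B, T, 8)
        dec_part = (g_tf * dtf_dt[None, :, :].astype(dtype)).sum(axis=-1)
        tanh_part = g * 0.5 * d3[:, None] * sech2 * 0.5 * d1[:, None]
        out["t"] = dec_part + tanh_part
    return out


def emulate_vm(x: NormalizedConductances, t, w: EmulatorWeights) -> np.ndarray:
    """Emulated transmembrane potential (mV) at time(s) t (ms).

    Values outside the trained domain [-10, 1000] ms are still returned but
    trigger an out-of-domain warning.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=np.float64))
    if np.any(t_arr < -10.0 - 1e-9) or np.any(t_arr > 1000.0 + 1e-9):
        warnings.warn("time outside trained domain [-10, 1000] ms; "
                      "extrapolated values are unreliable", stacklevel=2)
    vm = forward(w, np.asarray(x.x)[None, :], t_arr)[0]
    return vm if np.ndim(t) else float(vm[0])


def decoder_output(x: NormalizedConductances, t, w: EmulatorWeights) -> np.ndarray:
    """f_theta(t) in mV: the emulator output minus the depolarization term."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=np.float64))
    code = encode(x, w)
    vm = forward(w, np.asarray(x.x)[None, :], t_arr)[0]
    return vm - depolarization_term(code, t_arr)


def depolarization_term(code: LatentCode, t) -> np.ndarray:
    """(d3/2) * tanh((d1/2) * (t - d2)) in mV."""
    t = np.asarray(t, dtype=np.float64)
    return 0.5 * code.d3 * np.tanh(0.5 * code.d1 * (t - code.d2))


def emulate_ap(x: NormalizedConductances, time_grid, w: EmulatorWeights) -> APTrace:
    """Emulate an AP on an arbitrary grid within the trained domain."""
    grid = np.asarray(time_grid, dtype=np.float64)
    vm = emulate_vm(x, grid, w)
    return APTrace(times=grid, vm=np.asarray(vm, dtype=np.float64))
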