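"""Minimal dense-network machinery: ELU/tanh MLPs, backprop, Adam.

The two emulator networks are small enough that a hand-written forward and
reverse pass over explicit weight lists is simpler and lighter than pulling
in an autodiff framework; gradients are verified against central differences
in the test suite.
"""

from __future__ import annotations

import numpy as np


def elu(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0.0, z, np.expm1(np.minimum(z, 0.0)))


def elu_grad(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0.0, 1.0, np.exp(np.minimum(z, 0.0)))


def softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def softplus_grad(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def init_layers(sizes, rng: np.random.Generator, dtype=np.float64):
    """Fan-in uniform (Kaiming-style) initialization for a list of layer sizes."""
    layers = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        bound = 1.0 / np.sqrt(fan_in)
        W = rng.uniform(-bound, bound, size=(fan_in, fan_out)).astype(dtype)
        b = rng.uniform(-bound, bound, size=fan_out).astype(dtype)
        layers.append((W, b))
    return layers


def mlp_forward(x, layers, activations):
    """Forward pass; activations is a list like ['elu','elu','tanh','linear'].

    Returns (output, cache) where cache holds pre-activations and inputs for
    the backward pass.
    """
    h = x
    pre = []
    inputs = []
    for (W, b), act in zip(layers, activations):
        inputs.append(h)
        z = h @ W + b
        pre.append(z)
        if act == "elu":
            h = elu(z)
        elif act == "tanh":
            h = np.tanh(z)
        elif act == "linear":
            h = z
        else:  # pragma: no cover - guarded by construction
            raise ValueError(f"unknown activation {act!r}")
    return h, (pre, inputs)


def mlp_backward(grad_out, layers, activations, cache):
    """Backward pass.

    Returns (grad_input, grads) with grads a list of (dW, db) matching layers.
    """
    pre, inputs = cache
    grads = [None] * len(layers)
    g = grad_out
    for k in range(len(layers) - 1, -1, -1):
        W, _b = layers[k]
        act = activations[k]
        z = pre[k]
        if act == "elu":
            g = g * elu_grad(z)
        elif act == "tanh":
            g = g * (1.0 - np.tanh(z) ** 2)
        # 'linear': unchanged
        h_in = inputs[k]
        dW = h_in.reshape(-1, h_in.shape[-1]).T @ g.reshape(-1, g.shape[-1])
        db = g.reshape(-1, g.shape[-1]).sum(axis=0)
        grads[k] = (dW, db)
        g = g @ W.T
    return g, grads


class Adam:
    """First-order adaptive gradient optimizer over a flat list of arrays."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def flatten_params(layers_list):
    """Flat list of arrays from a list of layer lists."""
    out = []
    for layers in layers_list:
        for W, b in layers:
            out.extend((W, b))
    return out
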