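"""Differentiable building blocks for the phenotype models.

Model parameters are nested dicts of float64 numpy arrays. Forward passes are
written with :mod:`autograd.numpy` so that every composite loss in the package
has an exact reverse-mode gradient; optimization runs a hand-rolled Adam on
the flattened parameter vector.
"""

from __future__ import annotations

import numpy as onp
import autograd.numpy as anp
from autograd import value_and_grad
from autograd.misc import flatten
from autograd.scipy.special import erf

__all__ = [
    "gelu",
    "relu",
    "identity",
    "get_activation",
    "init_linear",
    "apply_linear",
    "dropout_mask",
    "Adam",
    "fit_adam",
    "clip_log_var",
]

_SQRT2 = onp.sqrt(2.0)


def gelu(x):
    """Exact Gaussian-error linear unit, 0.5*x*(1 + erf(x/sqrt(2)))."""
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def relu(x):
    return anp.maximum(x, 0.0)


def identity(x):
    return x


_ACTIVATIONS = {"gelu": gelu, "relu": relu, "linear": identity, "tanh": anp.tanh}


def get_activation(name):
    try:
        return _ACTIVATIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown activation {name!r}; choose from {sorted(_ACTIVATIONS)}"
        ) from None


def init_linear(rng, d_in, d_out, scale=None, zero=False):
    """Glorot-scaled dense layer parameters {W: (d_in, d_out), b: (d_out,)}."""
    if zero:
        W = onp.zeros((d_in, d_out))
    else:
        if scale is None:
            scale = onp.sqrt(2.0 / (d_in + d_out))
        W = scale * rng.standard_normal((d_in, d_out))
    return {"W": W, "b": onp.zeros(d_out)}


def apply_linear(params, x):
    return anp.dot(x, params["W"]) + params["b"]


def batch_norm(x, gamma, beta, mean=None, var=None, eps=1e-5):
    """Normalize over the batch axis; pass (mean, var) for eval-mode stats."""
    if mean is None:
        mean = anp.mean(x, axis=0)
        var = anp.var(x, axis=0)
    return gamma * (x - mean) / anp.sqrt(var + eps) + beta


def dropout_mask(rng, shape, rate):
    """Inverted-dropout mask; plain array so it is constant under the trace."""
    if rate <= 0.0:
        return onp.ones(shape)
    keep = (rng.random(shape) >= rate).astype(float)
    return keep / (1.0 - rate)


def clip_log_var(log_var, lo=-20.0, hi=20.0):
    """Clamp log-variances for numeric safety (exp stays finite and positive)."""
    return anp.clip(log_var, lo, hi)


class Adam:
    """Adam on a flat parameter vector (Kingma & Ba defaults)."""

    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps

    def init_state(self, flat):
        return {"m": onp.zeros_like(flat), "v": onp.zeros_like(flat), "t": 0}

    def step(self, flat, grad, state):
        state["t"] += 1
        t = state["t"]
        state["m"] = self.beta1 * state["m"] + (1 - self.beta1) * grad
        state["v"] = self.beta2 * state["v"] + (1 - self.beta2) * grad * grad
        m_hat = state["m"] / (1 - self.beta1**t)
        v_hat = state["v"] / (1 - self.beta2**t)
        return flat - self.lr * m_hat / (onp.sqrt(v_hat) + self.eps), state


def fit_adam(loss_fn, params, n_steps, lr=1e-3, callback=None):
    """Minimize ``loss_fn(params)`` for ``n_steps``; returns (params, losses).

    ``loss_fn`` must be an autograd-traceable scalar function of the nested
    parameter dict. ``callback(step, params, loss)`` runs after each update.
    """
    flat, unflatten = flatten(params)
    vg = value_and_grad(lambda f: loss_fn(unflatten(f)))
    opt = Adam(lr=lr)
    state = opt.init_state(flat)
    losses = []
    for step in range(n_steps):
        loss, grad = vg(flat)
        if not onp.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at step {step}: {loss}")
        flat, state = opt.step(flat, grad, state)
        losses.append(float(loss))
        if callback is not None:
            callback(step, unflatten(flat), float(loss))
    return unflatten(flat), losses
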