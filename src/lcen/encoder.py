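"""Variational encoder and latent-space regularizers.

The encoder is a fully connected trunk (default widths 512/256/128 with GELU,
batch normalization, and dropout 0.3 after the second and third layers)
feeding two linear heads that parameterize a diagonal-Gaussian posterior
q(z|x) = N(mu, diag(exp(log_var))) of dimension 64. Latent samples are drawn
with the reparameterization trick so gradients flow through the posterior
parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as onp
import autograd.numpy as anp

from .nn import (
    apply_linear,
    batch_norm,
    clip_log_var,
    dropout_mask,
    get_activation,
    init_linear,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EncoderSpec",
    "LatentPosterior",
    "init_encoder",
    "encode",
    "reparameterize",
    "kl_standard_normal",
    "kl_diag_gaussians",
    "latent_regularizer",
    "mi_lower_bound",
    "latent_total",
    "gaussian_log_density",
]

LOG_2PI = float(onp.log(2.0 * onp.pi))


def _as_float(x):
    """Coerce plain inputs to float arrays; leave traced values untouched."""
    return x if hasattr(x, "_value") else anp.asarray(x, dtype=float)


@dataclass
class EncoderSpec:
    """Architecture of the encoder; the last width is the latent dimension."""

    layer_widths: tuple = (512, 256, 128, 64)
    dropout_rate: float = 0.3
    dropout_after: tuple = (2, 3)  # 1-based trunk layer indices
    activation: str = "gelu"
    batch_norm: bool = True

    def __post_init__(self):
        self.layer_widths = tuple(int(w) for w in self.layer_widths)
        if not self.layer_widths:
            raise ValueError("layer_widths must be non-empty")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        get_activation(self.activation)

    @property
    def d_z(self):
        return self.layer_widths[-1]

    @property
    def trunk_widths(self):
        return self.layer_widths[:-1]


@dataclass
class LatentPosterior:
    """Per-subject variational parameters (mu, log sigma^2) and samples."""

    mu: onp.ndarray
    log_var: onp.ndarray
    samples: onp.ndarray | None = None

    def __post_init__(self):
        if isinstance(self.mu, onp.ndarray):  # skip checks on traced values
            if not (onp.all(onp.isfinite(self.mu)) and onp.all(onp.isfinite(self.log_var))):
                raise ValueError("posterior parameters must be finite")

    @property
    def sigma(self):
        return anp.exp(0.5 * self.log_var)

    @property
    def d_z(self):
        return self.mu.shape[-1]


def init_encoder(rng, d_x, spec):
    """Parameter dict for an encoder mapping d_x inputs to a d_z posterior."""
    params = {"trunk": []}
    width_in = d_x
    for width in spec.trunk_widths:
        layer = init_linear(rng, width_in, width)
        if spec.batch_norm:
            layer["gamma"] = onp.ones(width)
            layer["beta"] = onp.zeros(width)
        params["trunk"].append(layer)
        width_in = width
    params["mu"] = init_linear(rng, width_in, spec.d_z)
    params["log_var"] = init_linear(rng, width_in, spec.d_z, zero=True)
    return params


def _trunk_forward(x, spec, params, train, rng, bn_state):
    act = get_activation(spec.activation)
    h = x
    for idx, layer in enumerate(params["trunk"], start=1):
        h = apply_linear(layer, h)
        h = act(h)
        if spec.batch_norm:
            if train or bn_state is None:
                h = batch_norm(h, layer["gamma"], layer["beta"])
            else:
                mean, var = bn_state[idx - 1]
                h = batch_norm(h, layer["gamma"], layer["beta"], mean, var)
        if train and idx in spec.dropout_after and spec.dropout_rate > 0:
            if rng is None:
                raise ValueError("train-mode encoding needs an rng for dropout")
            h = h * dropout_mask(rng, h.shape, spec.dropout_rate)
    return h


def update_bn_state(x, spec, params, bn_state=None, momentum=0.9):
    """Refresh running batch-norm statistics with an untraced forward pass."""
    act = get_activation(spec.activation)
    stats = []
    h = onp.asarray(x, dtype=float)
    for idx, layer in enumerate(params["trunk"]):
        h = onp.dot(h, layer["W"]) + layer["b"]
        h = onp.asarray(act(h))
        mean, var = h.mean(axis=0), h.var(axis=0)
        if bn_state is not None:
            old_mean, old_var = bn_state[idx]
            mean = momentum * old_mean + (1 - momentum) * mean
            var = momentum * old_var + (1 - momentum) * var
        stats.append((mean, var))
        if spec.batch_norm:
            h = onp.asarray(
                batch_norm(h, layer["gamma"], layer["beta"], stats[-1][0], stats[-1][1])
            )
    return stats


def encode(x, spec, params, train=False, rng=None, bn_state=None):
    """Map a feature batch to its variational posterior.

    Eval-mode calls (``train=False``) are deterministic: dropout is off and
    batch statistics come from ``bn_state`` when provided.
    """
    x = anp.atleast_2d(x)
    d_in = params["trunk"][0]["W"].shape[0] if params["trunk"] else params["mu"]["W"].shape[0]
    if x.shape[1] != d_in:
        raise ValueError(f"encoder expects d_x={d_in}, got {x.shape[1]}")
    h = _trunk_forward(x, spec, params, train, rng, bn_state)
    mu = apply_linear(params["mu"], h)
    log_var = clip_log_var(apply_linear(params["log_var"], h))
    return LatentPosterior(mu=mu, log_var=log_var)


def reparameterize(post, noise_seed):
    """Draw z = mu + sigma * eps with eps ~ N(0, I) from the seeded stream."""
    rng = onp.random.default_rng(noise_seed)
    eps = rng.standard_normal(onp.shape(post.mu))
    z = post.mu + post.sigma * eps
    post.samples = z
    return z


def kl_diag_gaussians(mu_q, log_var_q, mu_p=0.0, log_var_p=0.0):
    """KL(q || p) for diagonal Gaussians, summed over dims, averaged over batch."""
    var_q = anp.exp(log_var_q)
    var_p = anp.exp(_as_float(log_var_p))
    per_dim = 0.5 * (
        log_var_p - log_var_q + (var_q + (mu_q - mu_p) ** 2) / var_p - 1.0
    )
    return anp.mean(anp.sum(anp.atleast_2d(per_dim), axis=1))


def kl_standard_normal(post):
    """Closed-form KL(q(z|x) || N(0, I)), batch-averaged; always >= 0."""
    return kl_diag_gaussians(post.mu, post.log_var)


def latent_regularizer(z, prior_draw, beta=1.0, variance_sign=1.0):
    """Variance-plus-proximity latent penalty.

    Sum over dimensions of the batch variance of z (sign selectable: the
    printed objective penalizes variance, the surrounding prose asks for
    diversity) plus ``beta`` times the mean squared distance to a standard
    normal prior draw paired row-by-row.
    """
    z = anp.atleast_2d(z)
    n = z.shape[0]
    if n < 2:
        logger.warning("latent_regularizer on a batch of 1: variance term is 0")
        var_term = 0.0
    else:
        var_term = anp.sum(anp.var(z, axis=0, ddof=1))
    prox = anp.mean(anp.sum((z - prior_draw) ** 2, axis=1))
    return variance_sign * var_term + beta * prox


def gaussian_log_density(x, mean, log_var=0.0):
    """Row-wise log N(x; mean, diag(exp(log_var))), summed over dimensions."""
    log_var = _as_float(log_var)
    quad = (x - mean) ** 2 / anp.exp(log_var)
    per_dim = -0.5 * (LOG_2PI + log_var + quad)
    return anp.sum(anp.atleast_2d(per_dim), axis=1)


def mi_lower_bound(x, post, decoder_loglik, n_samples=1, seed=0):
    """Variational lower bound on the latent-input mutual information.

    Monte-Carlo estimate of E_q[log p(x|z)] - E_q[log q(z|x)] using
    reparameterized samples; ``decoder_loglik(x, z)`` must return a per-subject
    log-likelihood vector. The corresponding penalty is the negated bound.
    """
    rng = onp.random.default_rng(seed)
    mu = anp.atleast_2d(post.mu)
    log_var = anp.atleast_2d(post.log_var)
    total = 0.0
    for _ in range(n_samples):
        eps = rng.standard_normal(onp.shape(mu))
        z = mu + anp.exp(0.5 * log_var) * eps
        ll = decoder_loglik(x, z)
        ll_arr = onp.asarray(getattr(ll, "_value", ll), dtype=float)
        if not onp.all(onp.isfinite(ll_arr)):
            bad = int(onp.flatnonzero(~onp.isfinite(ll_arr))[0])
            raise FloatingPointError(
                f"decoder log-likelihood non-finite at batch index {bad}"
            )
        log_q = gaussian_log_density(z, mu, log_var)
        total = total + anp.mean(ll - log_q)
    return total / n_samples


def latent_total(
    z,
    post,
    x,
    decoder_loglik=None,
    lam_mutual=0.1,
    beta=1.0,
    variance_sign=1.0,
    prior_draw=None,
    n_samples=1,
    seed=0,
):
    """Composite latent objective: R_latent + lam_mutual * R_mutual.

    Returns (total, components); components are the weighted terms and sum to
    the total.
    """
    if lam_mutual < 0 or beta < 0:
        raise ValueError("regularization weights must be non-negative")
    if prior_draw is None:
        prior_draw = onp.random.default_rng(seed).standard_normal(onp.shape(z))
    r_latent = latent_regularizer(z, prior_draw, beta=beta, variance_sign=variance_sign)
    components = {"latent": r_latent}
    if lam_mutual > 0:
        if decoder_loglik is None:
            raise ValueError("lam_mutual > 0 requires a decoder_loglik")
        bound = mi_lower_bound(x, post, decoder_loglik, n_samples=n_samples, seed=seed)
        components["mutual"] = lam_mutual * (-bound)
    else:
        components["mutual"] = 0.0
    total = components["latent"] + components["mutual"]
    return total, components
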