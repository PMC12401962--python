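"""Self-supervised pretraining: reconstruction, auxiliary-prior KL, contrast.

The encoder is initialized before supervised training by minimizing

    L = L_recon + lam_KL * L_KL + lam_contrast * L_contrast,

where L_recon reconstructs the input through a mirrored decoder, L_KL pulls
the posterior toward auxiliary diagonal-Gaussian priors, and L_contrast is an
InfoNCE objective over augmented positive pairs with in-batch negatives.
"""

from __future__ import annotations

import logging

import numpy as onp
import autograd.numpy as anp
from autograd import value_and_grad
from autograd.misc import flatten

from .encoder import EncoderSpec, encode, init_encoder, kl_diag_gaussians
from .nn import Adam, apply_linear, get_activation, init_linear

logger = logging.getLogger(__name__)

__all__ = [
    "init_input_decoder",
    "input_decoder_forward",
    "reconstruct_input",
    "kl_auxiliary",
    "augment",
    "contrastive_loss",
    "pretrain_objective",
    "pretrain",
]

AUGMENT_POLICIES = ("jitter", "mask", "scale")


def init_input_decoder(rng, spec, d_x):
    """Mirror of the encoder: widths reversed, ending in a linear map to d_x."""
    widths = list(reversed(spec.layer_widths))  # starts at d_z
    layers = []
    for w_in, w_out in zip(widths, widths[1:] + [d_x]):
        layers.append(init_linear(rng, w_in, w_out))
    return {"layers": layers}


def input_decoder_forward(z, dec_params, activation="gelu"):
    act = get_activation(activation)
    h = anp.atleast_2d(z)
    layers = dec_params["layers"]
    for layer in layers[:-1]:
        h = act(apply_linear(layer, h))
    return apply_linear(layers[-1], h)


def reconstruct_input(x, enc_spec, enc_params, dec_params, bn_state=None):
    """(x_hat, loss): decode the posterior mean back to feature space.

    loss = mean over subjects of the squared reconstruction norm.
    """
    post = encode(x, enc_spec, enc_params, train=False, bn_state=bn_state)
    x_hat = input_decoder_forward(post.mu, dec_params, enc_spec.activation)
    loss = anp.mean(anp.sum((anp.atleast_2d(x) - x_hat) ** 2, axis=1))
    return x_hat, loss


def kl_auxiliary(post, priors):
    """Sum over auxiliary priors of KL(q(z|x) || p_j), batch-averaged.

    Each prior is a (mean, log_var) pair of arrays broadcastable to d_z.
    """
    total = 0.0
    for mean, log_var in priors:
        mean = anp.asarray(mean, dtype=float)
        log_var = anp.asarray(log_var, dtype=float)
        for arr in (mean, log_var):
            if arr.ndim and arr.shape[-1] not in (1, post.d_z):
                raise ValueError(
                    f"prior dimension {arr.shape[-1]} does not match d_z={post.d_z}"
                )
        total = total + kl_diag_gaussians(post.mu, post.log_var, mean, log_var)
    return total


def augment(x, policy=("jitter",), seed=0, jitter_scale=0.05, mask_p=0.1, scale_range=(0.9, 1.1)):
    """Seeded feature augmentation for contrastive positive pairs.

    jitter: add N(0, (jitter_scale * column SD)^2) noise; mask: zero each
    feature independently with probability ``mask_p``; scale: multiply each
    subject by U(scale_range).
    """
    unknown = set(policy) - set(AUGMENT_POLICIES)
    if unknown:
        raise ValueError(f"unknown augmentation policies: {sorted(unknown)}")
    rng = onp.random.default_rng(seed)
    out = onp.array(x, dtype=float, copy=True)
    if "jitter" in policy:
        sd = out.std(axis=0)
        out = out + rng.standard_normal(out.shape) * (jitter_scale * sd)
    if "mask" in policy:
        out = out * (rng.random(out.shape) >= mask_p)
    if "scale" in policy:
        out = out * rng.uniform(*scale_range, size=(out.shape[0], 1))
    return out


def _row_normalize(z, eps=1e-12):
    norms = anp.sqrt(anp.sum(z**2, axis=1, keepdims=True))
    small = onp.asarray(getattr(norms, "_value", norms)) < eps
    if onp.any(small):
        logger.warning("zero-norm embedding in contrastive loss; epsilon-guarded")
    return z / anp.maximum(norms, eps)


def contrastive_loss(z, z_pos, z_negs=None, tau=0.1):
    """InfoNCE with cosine similarity.

    For each anchor i the positive is ``z_pos[i]``; negatives default to the
    other subjects' positive embeddings (in-batch negatives). ``z_negs`` may
    supply an explicit (K, d_z) negative bank instead.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    z = _row_normalize(anp.atleast_2d(z))
    z_pos = _row_normalize(anp.atleast_2d(z_pos))
    pos_sim = anp.sum(z * z_pos, axis=1) / tau
    if z_negs is None:
        sims = anp.dot(z, z_pos.T) / tau  # (n, n); diagonal is the positive
        n = z.shape[0]
        m = anp.max(sims, axis=1)
        logsumexp = m + anp.log(anp.sum(anp.exp(sims - m[:, None]), axis=1))
        return anp.mean(logsumexp - pos_sim)
    z_negs = _row_normalize(anp.atleast_2d(z_negs))
    neg_sims = anp.dot(z, z_negs.T) / tau  # (n, K)
    all_sims = anp.concatenate([pos_sim[:, None], neg_sims], axis=1)
    m = anp.max(all_sims, axis=1)
    logsumexp = m + anp.log(anp.sum(anp.exp(all_sims - m[:, None]), axis=1))
    return anp.mean(logsumexp - pos_sim)


def pretrain_objective(components, lam_kl=1.0, lam_contrast=1.0):
    """total = L_recon + lam_KL * L_KL + lam_contrast * L_contrast.

    ``components`` maps {"recon", "kl", "contrast"} to precomputed terms;
    returns (total, weighted components).
    """
    if lam_kl < 0 or lam_contrast < 0:
        raise ValueError("pretraining weights must be non-negative")
    weighted = {
        "recon": components.get("recon", 0.0),
        "kl": lam_kl * components.get("kl", 0.0),
        "contrast": lam_contrast * components.get("contrast", 0.0),
    }
    total = weighted["recon"] + weighted["kl"] + weighted["contrast"]
    return total, weighted


def pretrain(
    x,
    enc_spec=None,
    seed=0,
    epochs=20,
    batch_size=32,
    lr=1e-3,
    lam_kl=0.1,
    lam_contrast=0.1,
    tau=0.1,
    policy=("jitter", "mask"),
    priors=None,
):
    """Self-supervised initialization of the encoder.

    Returns (encoder_params, input_decoder_params, history) where history is
    a list of per-epoch dicts of loss components.
    """
    x = onp.asarray(x, dtype=float)
    n, d_x = x.shape
    if enc_spec is None:
        enc_spec = EncoderSpec()
    if priors is None:
        priors = [(onp.zeros(enc_spec.d_z), onp.zeros(enc_spec.d_z))]
    rng = onp.random.default_rng(seed)
    params = {
        "enc": init_encoder(rng, d_x, enc_spec),
        "dec": init_input_decoder(rng, enc_spec, d_x),
    }
    flat, unflatten = flatten(params)
    opt = Adam(lr=lr)
    state = opt.init_state(flat)
    history = []
    batch_size = min(batch_size, n)
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_terms = {"recon": 0.0, "kl": 0.0, "contrast": 0.0, "total": 0.0}
        n_batches = 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            if len(idx) < 2:
                continue
            xb = x[idx]
            view = augment(xb, policy, seed=int(rng.integers(2**31)))
            drop_rng = onp.random.default_rng(int(rng.integers(2**31)))
            terms_out = {}

            def loss_fn(f):
                p = unflatten(f)
                post = encode(xb, enc_spec, p["enc"], train=True, rng=drop_rng)
                x_hat = input_decoder_forward(post.mu, p["dec"], enc_spec.activation)
                recon = anp.mean(anp.sum((xb - x_hat) ** 2, axis=1))
                kl = kl_auxiliary(post, priors)
                post_v = encode(view, enc_spec, p["enc"], train=False)
                contrast = contrastive_loss(post.mu, post_v.mu, tau=tau)
                total, weighted = pretrain_objective(
                    {"recon": recon, "kl": kl, "contrast": contrast},
                    lam_kl=lam_kl,
                    lam_contrast=lam_contrast,
                )
                terms_out.update(weighted)
                return total

            val, grad = value_and_grad(loss_fn)(flat)
            if not onp.isfinite(val):
                raise FloatingPointError(f"non-finite pretraining loss at epoch {epoch}")
            flat, state = opt.step(flat, grad, state)
            for k in ("recon", "kl", "contrast"):
                epoch_terms[k] += float(getattr(terms_out[k], "_value", terms_out[k]))
            epoch_terms["total"] += float(val)
            n_batches += 1
        history.append(
            {"epoch": epoch, **{k: v / max(n_batches, 1) for k, v in epoch_terms.items()}}
        )
    params = unflatten(flat)
    return params["enc"], params["dec"], history
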