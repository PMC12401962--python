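"""Finite-difference gradient verification for composite objectives."""

from __future__ import annotations

import numpy as onp
import autograd.numpy as anp
from autograd import grad
from autograd.misc import flatten

__all__ = ["max_relative_grad_error", "composite_loss_suite"]


def max_relative_grad_error(loss_fn, params, n_coords=30, h=1e-5, seed=0):
    """Compare autograd's gradient with central finite differences.

    ``loss_fn`` maps a nested parameter structure to a scalar. A random subset
    of ``n_coords`` coordinates is probed; returns the maximum relative error
    max |g_ad - g_fd| / max(|g_ad|, |g_fd|, 1e-8).
    """
    flat, unflatten = flatten(params)
    g = grad(lambda f: loss_fn(unflatten(f)))(flat)
    rng = onp.random.default_rng(seed)
    coords = rng.choice(flat.size, size=min(n_coords, flat.size), replace=False)
    worst = 0.0
    for c in coords:
        e = onp.zeros_like(flat)
        e[c] = h
        fd = (loss_fn(unflatten(flat + e)) - loss_fn(unflatten(flat - e))) / (2 * h)
        fd = float(fd)
        denom = max(abs(float(g[c])), abs(fd), 1e-8)
        worst = max(worst, abs(float(g[c]) - fd) / denom)
    return worst


def composite_loss_suite(seed=0):
    """Every composite objective as a differentiable closure on the worked
    example, for gradient verification.

    Returns {name: (loss_fn, params)} covering the latent, decoding,
    attention, domain-regularization, multi-task, and pretraining objectives.
    All stochastic ingredients (reparameterization noise, prior draws,
    augmented views) are frozen so each closure is deterministic in its
    parameters.
    """
    from .attention import attention_forward, attention_objective, init_attention
    from .cogs import (
        TaskSpec,
        domain_regularizer,
        hierarchy_consistency,
        total_objective,
        uncertainty_loss,
    )
    from .data import smoothness_penalty
    from .decoder import DecoderSpec, decode, decode_loss, effective_adjacency, init_decoder, residual_refine
    from .encoder import (
        EncoderSpec,
        encode,
        gaussian_log_density,
        init_encoder,
        latent_regularizer,
        mi_lower_bound,
    )
    from .pretrain import (
        augment,
        contrastive_loss,
        init_input_decoder,
        input_decoder_forward,
        kl_auxiliary,
        pretrain_objective,
    )
    from .simulate import make_worked_example

    features, phenotypes, graph, truth = make_worked_example()
    x, y = features.values, phenotypes.values
    rng = onp.random.default_rng(seed)
    enc_spec = EncoderSpec(
        layer_widths=(3, 2), dropout_rate=0.0, dropout_after=(), batch_norm=False
    )
    dec_spec = DecoderSpec(hidden_widths=(2, 3), adjacency_mode="learnable")
    hierarchy = truth.level_map
    params = {
        "enc": init_encoder(rng, 3, enc_spec),
        "dec": init_decoder(rng, 2, 2, dec_spec),
        "att": init_attention(rng, 2, 2, hierarchy, level_width=3),
        "idec": init_input_decoder(rng, enc_spec, 3),
        "log_var_task": 0.1 * rng.standard_normal(3),
    }
    params["dec"]["adj_triu"] = 0.3 * rng.standard_normal(1)
    params["dec"]["res2"]["W"] = 0.1 * rng.standard_normal((3, 2))
    eps = rng.standard_normal((4, 2))
    prior_draw = rng.standard_normal((4, 2))
    view = augment(x, ("jitter",), seed=seed + 1)

    def zpost(p):
        post = encode(x, enc_spec, p["enc"])
        return post, post.mu + anp.exp(0.5 * post.log_var) * eps

    def latent_loss(p):
        post, z = zpost(p)

        def loglik(xx, zz):
            return gaussian_log_density(x, input_decoder_forward(zz, p["idec"], "gelu"))

        r_latent = latent_regularizer(z, prior_draw)
        bound = mi_lower_bound(x, post, loglik, seed=seed + 2)
        return r_latent + 0.5 * (-bound)

    def decoding_loss(p):
        _, z = zpost(p)
        A = effective_adjacency(None, dec_spec, p["dec"])
        y_pred = residual_refine(decode(z, None, dec_spec, p["dec"]), dec_spec, p["dec"])
        total, _ = decode_loss(
            y, y_pred, None, {"graph": 0.3, "sparsity": 0.2, "symmetry": 0.1}, adjacency=A
        )
        return total

    def attention_loss(p):
        post, z = zpost(p)
        A = effective_adjacency(None, dec_spec, p["dec"])
        y_final, state = attention_forward(z, p["att"], hierarchy, 2)
        total, _ = attention_objective(
            y, y_final,
            latent_regularizer(z, prior_draw),
            smoothness_penalty(y_final, A),
            state.alpha,
            {"latent": 0.2, "graph": 0.3, "attention": 0.1},
        )
        return total

    def domain_loss(p):
        _, z = zpost(p)
        A = effective_adjacency(None, dec_spec, p["dec"])
        y_pred = decode(z, None, dec_spec, p["dec"])
        total, _ = domain_regularizer(
            y_pred, z, A, {"smooth": 0.4, "disentangle": 0.5, "sparse": 0.6}
        )
        return total

    def multitask_loss(p):
        _, z = zpost(p)
        y_final, _ = attention_forward(z, p["att"], hierarchy, 2)
        spec_mt = TaskSpec.from_hierarchy(hierarchy)
        preds = {t: y_final[:, spec_mt.task_to_columns[t]] for t in spec_mt.tasks}
        trues = {t: y[:, spec_mt.task_to_columns[t]] for t in spec_mt.tasks}
        task_losses = [
            anp.mean(anp.sum((preds[t] - trues[t]) ** 2, axis=1)) if spec_mt.task_to_columns[t] else 0.0
            for t in spec_mt.tasks
        ]
        total, _ = total_objective(
            task_losses, [1.2, 0.8, 1.0],
            hierarchy_consistency(preds, spec_mt),
            uncertainty_loss(preds, trues, p["log_var_task"]),
            {"hierarchy": 0.5, "uncertainty": 0.7},
        )
        return total

    def pretraining_loss(p):
        post = encode(x, enc_spec, p["enc"])
        x_hat = input_decoder_forward(post.mu, p["idec"], "gelu")
        recon = anp.mean(anp.sum((x - x_hat) ** 2, axis=1))
        kl = kl_auxiliary(post, [(onp.zeros(2), onp.zeros(2))])
        post_v = encode(view, enc_spec, p["enc"])
        contrast = contrastive_loss(post.mu, post_v.mu, tau=0.5)
        total, _ = pretrain_objective(
            {"recon": recon, "kl": kl, "contrast": contrast}, lam_kl=0.5, lam_contrast=2.0
        )
        return total

    return {
        "latent": (latent_loss, params),
        "decoding": (decoding_loss, params),
        "attention": (attention_loss, params),
        "domain": (domain_loss, params),
        "multitask": (multitask_loss, params),
        "pretraining": (pretraining_loss, params),
    }
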