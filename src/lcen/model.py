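"""Assembled model: encoder, graph decoder, hierarchical attention, objectives.

The supervised loss combines the attention-path reconstruction objective,
the graph-decoding objective, the variational KL, and the optional COGS
terms; every weighted component is itemized so logged components always sum
to the logged total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as onp
import autograd.numpy as anp

from .attention import attention_forward, attention_objective, init_attention
from .cogs import (
    TaskSpec,
    adaptive_task_weights,
    hierarchy_consistency,
    total_objective,
    uncertainty_loss,
)
from .data import HierarchySpec, smoothness_penalty
from .decoder import (
    DecoderSpec,
    decode,
    effective_adjacency,
    init_decoder,
    residual_refine,
    structural_gaussian_nll,
)
from .encoder import (
    EncoderSpec,
    encode,
    init_encoder,
    kl_standard_normal,
    latent_regularizer,
)
from .cogs import disentangle_penalty

__all__ = ["ModelConfig", "init_model", "forward", "supervised_loss", "predict"]

DEFAULT_LAMBDAS = {
    "kl": 0.01,
    "latent": 0.0,
    "graph": 0.0,
    "attention": 0.0,
    "attention_entropy": 0.0,
    "decode": 1.0,
    "adj_sparsity": 0.0,
    "adj_symmetry": 0.0,
    "struct_nll": 0.0,
    "smooth": 0.0,
    "disentangle": 0.0,
    "sparse": 0.0,
    "hierarchy": 0.0,
    "uncertainty": 0.0,
    "weight_decay": 0.0,
}


@dataclass
class ModelConfig:
    """Everything needed to build and train one model."""

    encoder: EncoderSpec = field(default_factory=EncoderSpec)
    decoder: DecoderSpec = field(default_factory=DecoderSpec)
    hierarchy: HierarchySpec | None = None
    use_attention: bool = True
    level_width: int = 32
    shared_alpha: bool = True
    deterministic_latent: bool = False
    lambdas: dict = field(default_factory=dict)
    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10

    def __post_init__(self):
        unknown = set(self.lambdas) - set(DEFAULT_LAMBDAS)
        if unknown:
            raise ValueError(f"unknown loss weights: {sorted(unknown)}")
        merged = dict(DEFAULT_LAMBDAS)
        merged.update(self.lambdas)
        if any(v < 0 for v in merged.values()):
            raise ValueError("loss weights must be non-negative")
        self.lambdas = merged
        if self.use_attention and self.hierarchy is None:
            raise ValueError("use_attention requires a hierarchy")


def init_model(rng, d_x, d_y, config):
    params = {
        "encoder": init_encoder(rng, d_x, config.encoder),
        "decoder": init_decoder(rng, config.encoder.d_z, d_y, config.decoder),
    }
    if config.use_attention:
        params["attention"] = init_attention(
            rng, config.encoder.d_z, d_y, config.hierarchy, config.level_width
        )
        n_tasks = len(config.hierarchy.levels)
        params["log_var_task"] = onp.zeros(n_tasks)
    params["log_var_obs"] = onp.array(0.0)
    return params


def forward(params, x, config, graph=None, train=False, rng=None, eps=None, bn_state=None):
    """One full pass; returns a dict of intermediates."""
    post = encode(x, config.encoder, params["encoder"], train=train, rng=rng, bn_state=bn_state)
    if config.deterministic_latent or (not train and eps is None):
        z = post.mu
    else:
        if eps is None:
            eps = (rng or onp.random.default_rng(0)).standard_normal(onp.shape(getattr(post.mu, "_value", post.mu)))
        z = post.mu + post.sigma * eps
    y_graph = decode(z, graph, config.decoder, params["decoder"])
    if config.decoder.residual_block:
        y_graph = residual_refine(y_graph, config.decoder, params["decoder"])
    out = {"post": post, "z": z, "y_graph": y_graph, "alpha": None, "y_levels": None}
    if config.use_attention:
        d_y = params["decoder"]["out"]["W"].shape[1]
        y_final, state = attention_forward(
            z,
            params["attention"],
            config.hierarchy,
            d_y,
            activation=config.encoder.activation,
            shared_alpha=config.shared_alpha,
        )
        out.update({"y_final": y_final, "alpha": state.alpha, "y_levels": state.y_level})
    else:
        out["y_final"] = y_graph
    return out


def _task_slices(y, spec):
    return {t: y[:, spec.task_to_columns[t]] for t in spec.tasks}


def supervised_loss(
    params,
    x,
    y,
    config,
    graph=None,
    train=True,
    rng=None,
    eps=None,
    prior_draw=None,
    task_lambdas=None,
    bn_state=None,
):
    """(total, components) for one batch; weighted components sum to the total."""
    lam = config.lambdas
    out = forward(params, x, config, graph=graph, train=train, rng=rng, eps=eps, bn_state=bn_state)
    post, z = out["post"], out["z"]
    A_eff = effective_adjacency(graph, config.decoder, params["decoder"])
    components = {}

    if prior_draw is None:
        prior_draw = onp.random.default_rng(0).standard_normal(
            onp.shape(getattr(z, "_value", z))
        )
    latent_term = latent_regularizer(z, prior_draw) if lam["latent"] > 0 else 0.0
    graph_term = smoothness_penalty(out["y_final"], A_eff) if lam["graph"] > 0 else 0.0
    att_total, att_comp = attention_objective(
        y,
        out["y_final"],
        latent_term,
        graph_term,
        out["alpha"] if out["alpha"] is not None else onp.ones(1),
        lambdas={
            "latent": lam["latent"],
            "graph": lam["graph"],
            "attention": lam["attention"] if out["alpha"] is not None else 0.0,
        },
    )
    if task_lambdas is not None and config.use_attention:
        # gradient-adaptive multi-task weighting of the per-level errors
        spec_mt = TaskSpec.from_hierarchy(config.hierarchy)
        err = anp.atleast_2d(y) - out["y_final"]
        recon = 0.0
        for w, t in zip(task_lambdas, spec_mt.tasks):
            cols = spec_mt.task_to_columns[t]
            if cols:
                recon = recon + w * anp.mean(anp.sum(err[:, cols] ** 2, axis=1))
        components["reconstruction"] = recon
    else:
        components["reconstruction"] = att_comp["reconstruction"]
    components["latent"] = att_comp["latent"]
    components["graph"] = att_comp["graph"]
    components["attention"] = att_comp["attention"]

    if lam["attention_entropy"] > 0 and out["alpha"] is not None:
        from .attention import attention_entropy

        components["attention_entropy"] = lam["attention_entropy"] * attention_entropy(
            out["alpha"]
        )
    else:
        components["attention_entropy"] = 0.0

    components["kl"] = lam["kl"] * kl_standard_normal(post)

    if lam["decode"] > 0:
        components["decode"] = lam["decode"] * anp.mean(
            anp.sum((anp.atleast_2d(y) - out["y_graph"]) ** 2, axis=1)
        )
    else:
        components["decode"] = 0.0
    components["adj_sparsity"] = lam["adj_sparsity"] * anp.sum(anp.abs(A_eff))
    components["adj_symmetry"] = lam["adj_symmetry"] * anp.sum((A_eff - A_eff.T) ** 2)
    if lam["struct_nll"] > 0:
        components["struct_nll"] = lam["struct_nll"] * structural_gaussian_nll(
            y, z, config.decoder, params["decoder"],
            log_var_obs=params["log_var_obs"], graph=graph,
        )
    else:
        components["struct_nll"] = 0.0
    components["smooth"] = (
        lam["smooth"] * smoothness_penalty(out["y_graph"], A_eff) if lam["smooth"] > 0 else 0.0
    )
    components["disentangle"] = (
        lam["disentangle"] * disentangle_penalty(z) if lam["disentangle"] > 0 else 0.0
    )
    components["sparse"] = lam["sparse"] * anp.mean(
        anp.sum(anp.abs(out["y_final"]), axis=1)
    ) if lam["sparse"] > 0 else 0.0

    if config.use_attention and (lam["hierarchy"] > 0 or lam["uncertainty"] > 0):
        spec = TaskSpec.from_hierarchy(config.hierarchy)
        pred_by_task = _task_slices(out["y_final"], spec)
        true_by_task = _task_slices(anp.atleast_2d(y), spec)
        hier = hierarchy_consistency(pred_by_task, spec) if lam["hierarchy"] > 0 else 0.0
        unc = (
            uncertainty_loss(pred_by_task, true_by_task, params["log_var_task"])
            if lam["uncertainty"] > 0
            else 0.0
        )
        components["hierarchy"] = lam["hierarchy"] * hier
        components["uncertainty"] = lam["uncertainty"] * unc
    else:
        components["hierarchy"] = 0.0
        components["uncertainty"] = 0.0

    if lam["weight_decay"] > 0:
        wd = anp.sum(params["decoder"]["out"]["W"] ** 2) + anp.sum(
            params["decoder"]["pre"]["W"] ** 2
        )
        components["weight_decay"] = lam["weight_decay"] * wd
    else:
        components["weight_decay"] = 0.0

    total = 0.0
    for v in components.values():
        total = total + v
    return total, components


def predict(params, x, config, graph=None, bn_state=None):
    """Deterministic eval-mode phenotype predictions (posterior mean path)."""
    out = forward(params, x, config, graph=graph, train=False, bn_state=bn_state)
    return onp.asarray(out["y_final"])
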