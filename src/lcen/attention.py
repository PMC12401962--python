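"""Hierarchical attention over three abstraction levels.

Cognitive phenotypes are grouped into sensorimotor (level 1), cognitive
control (level 2), and executive (level 3) tiers. Each level projects the
latent code through its own matrix, scores the projection against a learnable
context vector, and predicts its own phenotype columns; a softmax over the
level scores yields attention weights that combine the per-level predictions
into the final output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as onp
import autograd.numpy as anp

from .data import HierarchySpec
from .nn import apply_linear, get_activation, init_linear

__all__ = [
    "LevelState",
    "init_attention",
    "level_projections",
    "attention_weights",
    "expand_to_full",
    "aggregate_predictions",
    "attention_objective",
]


@dataclass
class LevelState:
    """Per-level intermediates of one attention forward pass."""

    h: list  # per-level latent matrices (batch, level_width)
    alpha: object  # (L,) shared weights or (batch, L)
    y_level: list  # per-level predictions in full d_y space
    scores: object = None

    def __post_init__(self):
        alpha = onp.asarray(getattr(self.alpha, "_value", self.alpha), dtype=float)
        sums = alpha.sum(axis=-1)
        if onp.any(alpha < -1e-8) or not onp.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("attention weights must be non-negative and sum to 1")


def init_attention(rng, d_z, d_y, hierarchy, level_width=32):
    """Per-level projection, context vector, and prediction head parameters."""
    params = {"levels": {}}
    for level in hierarchy.levels:
        cols = hierarchy.level_dims[level]
        params["levels"][level] = {
            "proj": init_linear(rng, d_z, level_width),
            "u": rng.standard_normal(level_width) / onp.sqrt(level_width),
            "head": init_linear(rng, level_width, len(cols)),
        }
    return params


def level_projections(z, params, hierarchy, activation="gelu"):
    """h_l = f(W_l z + b_l), one projection per abstraction level."""
    act = get_activation(activation)
    z = anp.atleast_2d(z)
    return [
        act(apply_linear(params["levels"][level]["proj"], z))
        for level in hierarchy.levels
    ]


def attention_weights(h_list, u_list, shared_alpha=True):
    """Softmax attention over levels from context-vector compatibility scores.

    With ``shared_alpha`` (default) per-subject scores are averaged over the
    batch before the softmax, giving one weight per level; otherwise the
    softmax runs per subject.
    """
    scores = anp.stack(
        [anp.dot(h, u) for h, u in zip(h_list, u_list)], axis=-1
    )  # (batch, L)
    if shared_alpha:
        scores = anp.mean(scores, axis=0)
    shifted = scores - anp.max(scores, axis=-1, keepdims=True)
    expd = anp.exp(shifted)
    return expd / anp.sum(expd, axis=-1, keepdims=True)


def expand_to_full(y_head, cols, d_y):
    """Zero-fill a level's head output into the full phenotype space."""
    E = onp.zeros((len(cols), d_y))
    E[onp.arange(len(cols)), cols] = 1.0
    return anp.dot(y_head, E)


def level_predictions(z_or_h, params, hierarchy, d_y, h_list=None):
    """Per-level phenotype predictions mapped to full d_y space."""
    h_list = h_list if h_list is not None else z_or_h
    out = []
    for h, level in zip(h_list, hierarchy.levels):
        cols = hierarchy.level_dims[level]
        out.append(expand_to_full(apply_linear(params["levels"][level]["head"], h), cols, d_y))
    return out


def aggregate_predictions(y_levels, alpha):
    """Weighted sum of per-level predictions, y_final = sum_l alpha_l y^(l).

    ``y_levels`` must already live in the full phenotype space (zero-filled
    outside each level's columns). ``alpha`` is (L,) for shared weights or
    (batch, L) for per-subject weights.
    """
    alpha = anp.atleast_1d(alpha)
    stacked = anp.stack(y_levels, axis=-1)  # (batch, d_y, L)
    if alpha.ndim == 1:
        return anp.sum(stacked * alpha, axis=-1)
    return anp.sum(stacked * alpha[:, None, :], axis=-1)


def attention_objective(y_true, y_final, latent_term, graph_term, alpha, lambdas=None):
    """Composite supervised loss with attention-sparsity regularization.

    total = L_reconstruction + lam1 * R_latent + lam2 * R_graph
            + lam3 * sum_l |alpha_l|

    The attention term is computed literally; for softmax-derived weights it
    equals 1 exactly and contributes no gradient (an entropy penalty is
    available separately for users wanting effective sparsity pressure).
    Returns (total, components) with weighted components summing to the total.
    """
    lam = {"latent": 0.0, "graph": 0.0, "attention": 0.0}
    if lambdas:
        unknown = set(lambdas) - set(lam)
        if unknown:
            raise ValueError(f"unknown attention_objective weights: {sorted(unknown)}")
        lam.update(lambdas)
    if any(v < 0 for v in lam.values()):
        raise ValueError("attention_objective weights must be non-negative")
    y_true = anp.atleast_2d(y_true)
    y_final = anp.atleast_2d(y_final)
    alpha = anp.atleast_1d(alpha)
    r_attention = anp.sum(anp.abs(alpha)) if alpha.ndim == 1 else anp.mean(
        anp.sum(anp.abs(alpha), axis=1)
    )
    components = {
        "reconstruction": anp.mean(anp.sum((y_true - y_final) ** 2, axis=1)),
        "latent": lam["latent"] * latent_term,
        "graph": lam["graph"] * graph_term,
        "attention": lam["attention"] * r_attention,
    }
    total = sum(components.values())
    return total, components


def attention_entropy(alpha):
    """Shannon entropy of the attention weights (optional sparsity pressure)."""
    alpha = anp.atleast_1d(alpha)
    p = anp.clip(alpha, 1e-12, 1.0)
    ent = -anp.sum(p * anp.log(p), axis=-1)
    return anp.mean(ent)


def attention_forward(z, params, hierarchy, d_y, activation="gelu", shared_alpha=True):
    """Full attention pass: projections, weights, level predictions, aggregate.

    Returns (y_final, LevelState).
    """
    h_list = level_projections(z, params, hierarchy, activation)
    u_list = [params["levels"][level]["u"] for level in hierarchy.levels]
    alpha = attention_weights(h_list, u_list, shared_alpha=shared_alpha)
    y_levels = level_predictions(None, params, hierarchy, d_y, h_list=h_list)
    y_final = aggregate_predictions(y_levels, alpha)
    state = LevelState(h=h_list, alpha=alpha, y_level=y_levels)
    return y_final, state
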