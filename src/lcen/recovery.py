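"""Parameter recovery: learn the phenotype adjacency from a cohort.

Trains the encoder and the learnable-adjacency decoder jointly under the
structural Gaussian likelihood with an L1 sparsity penalty on the adjacency.
Recovery is evaluated against a known generating adjacency by ranking the
learned |A| entries (support AUROC) and by the principal angle between the
learned decoder loading span and span(W_true).
"""

from __future__ import annotations

import numpy as onp
from sklearn.metrics import roc_auc_score

from .decoder import DecoderSpec, adjacency_from_triu, constrain_adjacency
from .encoder import EncoderSpec
from .model import ModelConfig, init_model, supervised_loss
from .nn import fit_adam

__all__ = [
    "recovery_config",
    "recover_adjacency",
    "support_auroc",
    "principal_angle_deg",
]


def recovery_config(k=5, lam_sparsity=0.02, lr=0.02):
    """Compact configuration for adjacency recovery runs.

    Linear deterministic encoder to k latent dimensions, no residual block,
    learnable adjacency scored by the structural likelihood.
    """
    return ModelConfig(
        encoder=EncoderSpec(
            layer_widths=(k,), dropout_rate=0.0, dropout_after=(), batch_norm=False
        ),
        decoder=DecoderSpec(
            hidden_widths=(k, 8),
            residual_block=False,
            adjacency_mode="learnable",
            solver="closed_form",
        ),
        use_attention=False,
        deterministic_latent=True,
        lambdas={
            "kl": 0.0,
            "decode": 1.0,
            "struct_nll": 1.0,
            "adj_sparsity": lam_sparsity,
        },
        lr=lr,
    )


def recover_adjacency(features, phenotypes, k=5, seed=0, n_steps=1500, config=None):
    """Fit the learnable adjacency on a cohort; returns (A_hat, params, config).

    Full-batch Adam on the joint objective (decoding MSE + structural
    likelihood + adjacency L1); the structural term is what identifies A.
    """
    x = onp.asarray(getattr(features, "values", features), dtype=float)
    x = (x - x.mean(axis=0)) / onp.where(x.std(axis=0) == 0, 1.0, x.std(axis=0))
    y = onp.asarray(getattr(phenotypes, "values", phenotypes), dtype=float)
    cfg = config if config is not None else recovery_config(k=k)
    rng = onp.random.default_rng(seed)
    params = init_model(rng, x.shape[1], y.shape[1], cfg)

    def loss(p):
        total, _ = supervised_loss(p, x, y, cfg, graph=None, train=False)
        return total

    params, _ = fit_adam(loss, params, n_steps, lr=cfg.lr)
    d_y = y.shape[1]
    A_hat = onp.asarray(
        constrain_adjacency(
            adjacency_from_triu(params["decoder"]["adj_triu"], d_y), cfg.decoder.delta
        )
    )
    return A_hat, params, cfg


def effective_loadings(params):
    """Composite linear loading matrix W_d (d_y, d_z) of the decoder."""
    W = params["decoder"]["pre"]["W"] @ params["decoder"]["out"]["W"]
    return onp.asarray(W).T


def support_auroc(A_hat, A_true):
    """AUROC of ranking |A_hat| upper-triangle entries against true support."""
    d = A_true.shape[0]
    iu = onp.triu_indices(d, 1)
    labels = (onp.abs(A_true[iu]) > 0).astype(int)
    if labels.min() == labels.max():
        raise ValueError("true adjacency support is degenerate (all or no edges)")
    return float(roc_auc_score(labels, onp.abs(onp.asarray(A_hat)[iu])))


def principal_angle_deg(B_hat, W_true):
    """Largest principal angle (degrees) between column spans."""
    Qh, _ = onp.linalg.qr(onp.asarray(B_hat, dtype=float))
    Qt, _ = onp.linalg.qr(onp.asarray(W_true, dtype=float))
    s = onp.linalg.svd(Qh.T @ Qt, compute_uv=False)
    s = onp.clip(s, -1.0, 1.0)
    return float(onp.degrees(onp.arccos(s.min())))
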