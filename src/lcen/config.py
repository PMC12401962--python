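"""YAML run configuration with strict schema validation.

Every default is a named key; unknown keys raise. The file has up to three
sections: ``model`` (architecture and loss weights), ``train`` (seed and
split ratios), and ``pretrain`` (self-supervised settings).
"""

from __future__ import annotations

import hashlib
import json

import yaml

from .data import HierarchySpec
from .decoder import DecoderSpec
from .encoder import EncoderSpec
from .model import DEFAULT_LAMBDAS, ModelConfig

__all__ = ["load_config", "build_model_config", "config_hash", "DEFAULT_RUN"]

DEFAULT_RUN = {
    "train": {"seed": 0, "ratios": [0.7, 0.15, 0.15], "stratify_binary": True,
              "task_adaptive": False},
    "pretrain": {
        "epochs": 20, "batch_size": 32, "lr": 1e-3, "lam_kl": 0.1,
        "lam_contrast": 0.1, "tau": 0.1, "policy": ["jitter", "mask"],
    },
}

_MODEL_KEYS = {
    "encoder", "decoder", "hierarchy", "use_attention", "level_width",
    "shared_alpha", "deterministic_latent", "lambdas", "lr", "batch_size",
    "max_epochs", "patience",
}
_ENCODER_KEYS = {"layer_widths", "dropout_rate", "dropout_after", "activation", "batch_norm"}
_DECODER_KEYS = {
    "hidden_widths", "residual_block", "adjacency_mode", "solver",
    "unroll_steps", "delta", "activation",
}
_HIER_KEYS = {"level_dims", "task_edges", "n_levels"}


def _check_keys(section, d, allowed):
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {section}: {sorted(unknown)}")


def build_model_config(model_dict):
    """ModelConfig from a nested plain dict (e.g. the YAML ``model`` section)."""
    model_dict = dict(model_dict or {})
    _check_keys("model", model_dict, _MODEL_KEYS)
    enc_d = dict(model_dict.pop("encoder", {}) or {})
    _check_keys("model.encoder", enc_d, _ENCODER_KEYS)
    dec_d = dict(model_dict.pop("decoder", {}) or {})
    _check_keys("model.decoder", dec_d, _DECODER_KEYS)
    hier_d = model_dict.pop("hierarchy", None)
    hierarchy = None
    if hier_d is not None:
        hier_d = dict(hier_d)
        _check_keys("model.hierarchy", hier_d, _HIER_KEYS)
        hierarchy = HierarchySpec(**hier_d)
    lambdas = dict(model_dict.pop("lambdas", {}) or {})
    _check_keys("model.lambdas", lambdas, set(DEFAULT_LAMBDAS))
    return ModelConfig(
        encoder=EncoderSpec(**enc_d),
        decoder=DecoderSpec(**dec_d),
        hierarchy=hierarchy,
        lambdas=lambdas,
        **model_dict,
    )


def load_config(path):
    """Parse and validate a YAML config; returns (ModelConfig | None, run dict)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    _check_keys("config", raw, {"model", "train", "pretrain"})
    run = {k: dict(v) for k, v in DEFAULT_RUN.items()}
    for section in ("train", "pretrain"):
        overrides = dict(raw.get(section, {}) or {})
        _check_keys(section, overrides, set(run[section]))
        run[section].update(overrides)
    model_cfg = build_model_config(raw["model"]) if "model" in raw else None
    return model_cfg, run


def config_hash(obj):
    """Stable short hash of a config-like structure for run manifests."""

    def default(o):
        if hasattr(o, "__dict__"):
            return {k: v for k, v in vars(o).items()}
        if hasattr(o, "tolist"):
            return o.tolist()
        return str(o)

    blob = json.dumps(obj, sort_keys=True, default=default).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
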