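"""Checkpoint container: parameters in an .npz plus a JSON manifest."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as onp

__all__ = ["save_checkpoint", "load_checkpoint"]


def _flatten_tree(tree, prefix=""):
    flat = {}
    if isinstance(tree, dict):
        for k, v in tree.items():
            flat.update(_flatten_tree(v, f"{prefix}{k}/"))
    elif isinstance(tree, (list, tuple)):
        for i, v in enumerate(tree):
            flat.update(_flatten_tree(v, f"{prefix}#{i}/"))
    else:
        flat[prefix.rstrip("/")] = onp.asarray(tree)
    return flat


def _unflatten_tree(flat):
    root: dict = {}
    for key, value in flat.items():
        parts = key.split("/")
        node = root
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value

    def rebuild(node):
        if not isinstance(node, dict):
            return node
        if node and all(k.startswith("#") for k in node):
            return [rebuild(node[f"#{i}"]) for i in range(len(node))]
        # integer-keyed dicts (e.g. attention levels) survive the round trip
        return {
            (int(k) if k.lstrip("-").isdigit() else k): rebuild(v)
            for k, v in node.items()
        }

    return rebuild(root)


def save_checkpoint(path, params, manifest=None):
    """Write params to ``<path>.npz`` and a manifest to ``<path>.json``."""
    path = Path(path)
    flat = _flatten_tree(params)
    onp.savez(path.with_suffix(".npz"), **flat)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(manifest or {}, fh, indent=2, sort_keys=True)
    return path.with_suffix(".npz")


def load_checkpoint(path):
    """Returns (params, manifest) from a checkpoint base path."""
    path = Path(path)
    with onp.load(path.with_suffix(".npz")) as data:
        flat = {k: data[k] for k in data.files}
    manifest = {}
    mpath = path.with_suffix(".json")
    if mpath.exists():
        with open(mpath) as fh:
            manifest = json.load(fh)
    return _unflatten_tree(flat), manifest
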