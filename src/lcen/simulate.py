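"""Seeded synthetic cohorts with known ground truth.

The generator mirrors the decoder's structural equation so that parameter
recovery is well-posed: latent factors z* ~ N(0, I_k) drive phenotypes
through

    y = (I - A*)^{-1} (W* z* + eps_y),       eps_y ~ N(0, sd_y^2 I),

i.e. the fixed point of y = W* z* + A* y with per-node noise. Placing the
noise inside the propagation gives the phenotype covariance the sandwich
form (I - A*)^{-1} (W* W*^T + sd_y^2 I) (I - A*)^{-T} and makes the
adjacency identifiable from the residual structure; recovery is still
subject to rotation ambiguity of the latent factors (only span(W*) and the
support of A* are recoverable, not W* itself).

Features come from two modality blocks ("eeg_psd", "imaging"), each a linear
mixing of the same latent factors plus independent noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as onp

from .data import FeatureMatrix, HierarchySpec, PhenotypeGraph, PhenotypeMatrix

__all__ = ["GroundTruth", "simulate_cohort", "make_worked_example", "write_cohort"]

DEFAULT_SCENARIO = dict(n=800, d_x=40, d_y=10, k=5, edge_density=0.2, seed=7)


@dataclass
class GroundTruth:
    """Generating parameters of a simulated cohort."""

    W_true: onp.ndarray  # (d_y, k)
    A_true: onp.ndarray  # (d_y, d_y), symmetric, zero diagonal
    mixing: dict  # block name -> (d_block, k) map
    noise_sd_y: float
    noise_sd_x: float
    level_map: HierarchySpec = None
    seed: int = 0
    z_true: onp.ndarray = None

    def __post_init__(self):
        if onp.any(onp.diag(self.A_true) != 0):
            raise ValueError("A_true diagonal must be zero")
        if self.noise_sd_y < 0 or self.noise_sd_x < 0:
            raise ValueError("noise SDs must be non-negative")


def _default_hierarchy(d_y):
    groups = onp.array_split(onp.arange(d_y), 3)
    level_dims = {lv + 1: groups[lv].tolist() for lv in range(3)}
    return HierarchySpec(level_dims=level_dims, task_edges=[(3, 2), (2, 1)])


def _sample_adjacency(rng, d_y, edge_density, radius, min_weight=0.1, attempts=100):
    n_pairs = d_y * (d_y - 1) // 2
    m = int(round(edge_density * n_pairs))
    if m > n_pairs:
        raise ValueError(f"edge density {edge_density} infeasible for d_y={d_y}")
    iu = onp.triu_indices(d_y, 1)
    for _ in range(attempts):
        A = onp.zeros((d_y, d_y))
        if m > 0:
            chosen = rng.choice(n_pairs, size=m, replace=False)
            weights = rng.uniform(0.4, 0.8, size=m) * rng.choice([-1.0, 1.0], size=m)
            A[iu[0][chosen], iu[1][chosen]] = weights
            A = A + A.T
            rho = onp.max(onp.abs(onp.linalg.eigvalsh(A)))
            if rho > radius:
                A *= radius / rho
            if m and onp.min(onp.abs(A[iu[0][chosen], iu[1][chosen]])) < min_weight:
                continue  # rescale crushed an edge below detectability
        return A
    raise RuntimeError(
        f"could not sample an adjacency with density {edge_density} and "
        f"radius {radius} in {attempts} attempts"
    )


def simulate_cohort(
    n=800,
    d_x=40,
    d_y=10,
    k=5,
    edge_density=0.2,
    seed=7,
    noise_sd_y=0.3,
    noise_sd_x=0.1,
    radius=0.8,
    n_binary=0,
    level_signal=(1.0, 1.0, 1.0),
):
    """Simulate a cohort; returns (features, phenotypes, graph, truth).

    ``level_signal`` scales the loading rows of each abstraction level
    (e.g. (1, 0, 0) leaves only sensorimotor signal). ``n_binary`` converts
    that many trailing phenotype columns to {0,1} by thresholding at 0.
    """
    if n < 2 or k > d_x:
        raise ValueError("need n >= 2 and k <= d_x")
    rng = onp.random.default_rng(seed)
    hierarchy = _default_hierarchy(d_y)
    A = _sample_adjacency(rng, d_y, edge_density, radius)
    W = rng.standard_normal((d_y, k)) / onp.sqrt(k)
    for lv, scale in zip(hierarchy.levels, level_signal):
        W[hierarchy.level_dims[lv], :] *= scale
    z = rng.standard_normal((n, k))
    eps_y = noise_sd_y * rng.standard_normal((n, d_y))
    y = onp.linalg.solve(onp.eye(d_y) - A, (z @ W.T + eps_y).T).T
    d_eeg = max(1, int(round(0.6 * d_x)))
    blocks = [("eeg_psd", d_eeg), ("imaging", d_x - d_eeg)]
    mixing, cols = {}, []
    for name, width in blocks:
        M = rng.standard_normal((width, k))
        mixing[name] = M
        cols.append(z @ M.T + noise_sd_x * rng.standard_normal((n, width)))
    x = onp.concatenate(cols, axis=1)
    column_names = [
        f"{name}:f{i}" for name, width in blocks for i in range(width)
    ]
    kinds = ["continuous"] * d_y
    if n_binary > 0:
        y = y.copy()
        for j in range(d_y - n_binary, d_y):
            y[:, j] = (y[:, j] > 0).astype(float)
            kinds[j] = "binary"
    features = FeatureMatrix(
        values=x,
        modality_blocks=[
            (name, (start, start + width))
            for (name, width), start in zip(blocks, onp.cumsum([0] + [w for _, w in blocks[:-1]]))
        ],
        subject_ids=[f"s{i:04d}" for i in range(n)],
        column_names=column_names,
    )
    phenotypes = PhenotypeMatrix(values=y, column_kind=kinds)
    graph = PhenotypeGraph(adjacency=A, mode="fixed")
    truth = GroundTruth(
        W_true=W,
        A_true=A,
        mixing=mixing,
        noise_sd_y=noise_sd_y,
        noise_sd_x=noise_sd_x,
        level_map=hierarchy,
        seed=seed,
        z_true=z,
    )
    return features, phenotypes, graph, truth


def make_worked_example():
    """Tiny fixed instance (n=4, d_x=3, d_y=2, k=1) with hand-enterable numbers.

    The adjacency is [[0, 0.5], [0.5, 0]] and the loadings are [[1], [0]], so
    each subject's phenotypes are z* times (4/3, 2/3) — the 2x2 closed-form
    solve of the decoder's fixed point. Noiseless; byte-identical on every
    call.
    """
    z = onp.array([[1.0], [-1.0], [0.5], [2.0]])
    W = onp.array([[1.0], [0.0]])
    A = onp.array([[0.0, 0.5], [0.5, 0.0]])
    M = onp.array([[1.0], [-1.0], [0.5]])
    y = onp.linalg.solve(onp.eye(2) - A, (z @ W.T).T).T
    x = z @ M.T
    features = FeatureMatrix(
        values=x,
        modality_blocks=[("eeg_psd", (0, 2)), ("imaging", (2, 3))],
        subject_ids=["s0", "s1", "s2", "s3"],
        column_names=["eeg_psd:f0", "eeg_psd:f1", "imaging:f0"],
    )
    phenotypes = PhenotypeMatrix(values=y, column_names=["rt", "coord"])
    graph = PhenotypeGraph(adjacency=A, mode="fixed", edge_list=[(0, 1, 0.5)])
    hierarchy = HierarchySpec(
        level_dims={1: [0], 2: [1], 3: []}, task_edges=[(2, 1)]
    )
    truth = GroundTruth(
        W_true=W,
        A_true=A,
        mixing={"eeg_psd": M[:2], "imaging": M[2:]},
        noise_sd_y=0.0,
        noise_sd_x=0.0,
        level_map=hierarchy,
        seed=0,
        z_true=z,
    )
    return features, phenotypes, graph, truth


def write_cohort(out_dir, features, phenotypes, graph, truth):
    """Write features.tsv, phenotypes.tsv, graph.tsv, truth-manifest.json."""
    import pandas as pd
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fdf = pd.DataFrame(features.values, columns=features.column_names)
    fdf.insert(0, "subject_id", features.subject_ids)
    fdf.to_csv(out / "features.tsv", sep="\t", index=False)
    pdf = pd.DataFrame(phenotypes.values, columns=phenotypes.column_names)
    pdf.insert(0, "subject_id", features.subject_ids)
    pdf.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    with open(out / "graph.tsv", "w") as fh:
        for i, j, w in graph.edges():
            fh.write(f"{i}\t{j}\t{w:.10g}\n")
    manifest = {
        "seed": truth.seed,
        "noise_sd_y": truth.noise_sd_y,
        "noise_sd_x": truth.noise_sd_x,
        "W_true": truth.W_true.tolist(),
        "A_true": truth.A_true.tolist(),
        "level_dims": {str(k): v for k, v in truth.level_map.level_dims.items()},
        "task_edges": list(map(list, truth.level_map.task_edges)),
    }
    with open(out / "truth-manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
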