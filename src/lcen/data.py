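"""Core data model: feature tables, phenotype tables, and the phenotype graph.

Features and phenotypes travel as delimited text (TSV/CSV chosen by file
extension) with a header row whose first column holds subject identifiers.
Feature column names may carry a modality prefix, ``block:feature`` (e.g.
``eeg_psd:alpha_O1``); columns without a prefix fall into a single block named
``features``. The phenotype-dependency graph is a 3-column edge list
(node_i, node_j, weight) with 0-based node indices, undirected edges listed
once.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as onp
import autograd.numpy as anp
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "PhenotypeMatrix",
    "PhenotypeGraph",
    "HierarchySpec",
    "load_tables",
    "standardize_features",
    "graph_smoothness",
    "smoothness_penalty",
    "graph_penalties",
    "project_adjacency",
    "spectral_radius",
]


@dataclass
class FeatureMatrix:
    """Per-subject observed features with modality-block annotations."""

    values: onp.ndarray  # (n_subjects, d_x)
    modality_blocks: list = field(default_factory=list)  # [(name, (start, stop)), ...]
    subject_ids: list = field(default_factory=list)
    column_names: list = field(default_factory=list)

    def __post_init__(self):
        self.values = onp.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be a 2-D matrix")
        n, d = self.values.shape
        if not self.subject_ids:
            self.subject_ids = [f"s{i}" for i in range(n)]
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match row count")
        if len(set(self.subject_ids)) != n:
            dupes = sorted({s for s in self.subject_ids if self.subject_ids.count(s) > 1})
            raise ValueError(f"duplicate subject ids: {dupes}")
        if not self.modality_blocks:
            self.modality_blocks = [("features", (0, d))]
        width = sum(stop - start for _, (start, stop) in self.modality_blocks)
        if width != d:
            raise ValueError(
                f"modality blocks cover {width} columns but matrix has {d}"
            )
        if not onp.all(onp.isfinite(self.values)):
            raise ValueError("feature matrix contains NaN/Inf")

    @property
    def n_subjects(self):
        return self.values.shape[0]

    @property
    def d_x(self):
        return self.values.shape[1]


@dataclass
class PhenotypeMatrix:
    """Per-subject phenotype vectors; columns are continuous or binary."""

    values: onp.ndarray  # (n_subjects, d_y)
    column_names: list = field(default_factory=list)
    column_kind: list = field(default_factory=list)  # "continuous" | "binary"

    def __post_init__(self):
        self.values = onp.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("phenotype values must be (n, d_y) with d_y >= 1")
        d = self.values.shape[1]
        if not self.column_names:
            self.column_names = [f"y{j}" for j in range(d)]
        if not self.column_kind:
            self.column_kind = [
                "binary" if set(onp.unique(col)) <= {0.0, 1.0} else "continuous"
                for col in self.values.T
            ]
        if len(self.column_names) != d or len(self.column_kind) != d:
            raise ValueError("column annotations do not match d_y")
        for j, kind in enumerate(self.column_kind):
            if kind == "binary" and not set(onp.unique(self.values[:, j])) <= {0.0, 1.0}:
                raise ValueError(f"binary column {self.column_names[j]} has values outside {{0,1}}")
        if not onp.all(onp.isfinite(self.values)):
            raise ValueError("phenotype matrix contains NaN/Inf")

    @property
    def d_y(self):
        return self.values.shape[1]


@dataclass
class PhenotypeGraph:
    """Adjacency over phenotype dimensions, fixed or learnable.

    A fixed graph must already be symmetric with zero diagonal; run
    :func:`project_adjacency` on raw matrices first.
    """

    adjacency: onp.ndarray  # (d_y, d_y)
    mode: str = "fixed"  # "fixed" | "learnable"
    edge_list: list = field(default_factory=list)  # [(i, j, w), ...] for fixed graphs

    def __post_init__(self):
        self.adjacency = onp.asarray(self.adjacency, dtype=float)
        d = self.adjacency.shape[0]
        if self.adjacency.shape != (d, d):
            raise ValueError("adjacency must be square")
        if self.mode not in ("fixed", "learnable"):
            raise ValueError(f"unknown graph mode {self.mode!r}")
        if onp.any(onp.abs(onp.diag(self.adjacency)) > 0):
            raise ValueError("adjacency diagonal must be zero")
        if self.mode == "fixed":
            if not onp.allclose(self.adjacency, self.adjacency.T, atol=1e-12):
                raise ValueError("fixed adjacency must be symmetric")
            if self.edge_list:
                dense = onp.zeros_like(self.adjacency)
                for i, j, w in self.edge_list:
                    dense[int(i), int(j)] = w
                    dense[int(j), int(i)] = w
                if not onp.allclose(dense, self.adjacency, atol=1e-12):
                    raise ValueError("edge list does not densify to the adjacency")

    @property
    def d_y(self):
        return self.adjacency.shape[0]

    def edges(self):
        """Undirected edges (i, j, weight) with i < j and nonzero weight."""
        iu, ju = onp.nonzero(onp.triu(self.adjacency, 1))
        return [(int(i), int(j), float(self.adjacency[i, j])) for i, j in zip(iu, ju)]


@dataclass
class HierarchySpec:
    """Three-tier abstraction structure over phenotype columns.

    ``level_dims`` maps level (1 = sensorimotor, 2 = cognitive control,
    3 = executive) to the phenotype column indices it predicts; ``task_edges``
    are (parent_level, child_level) pairs forming a DAG.
    """

    level_dims: dict
    task_edges: list = field(default_factory=list)
    n_levels: int = 3

    def __post_init__(self):
        self.level_dims = {int(k): list(map(int, v)) for k, v in self.level_dims.items()}
        if len(self.level_dims) != self.n_levels:
            raise ValueError(
                f"expected {self.n_levels} levels, got {len(self.level_dims)}"
            )
        seen = []
        for cols in self.level_dims.values():
            seen.extend(cols)
        if len(seen) != len(set(seen)):
            raise ValueError("levels must partition disjoint phenotype columns")
        g = nx.DiGraph()
        g.add_nodes_from(self.level_dims)
        for p, c in self.task_edges:
            if p not in self.level_dims or c not in self.level_dims:
                raise ValueError(f"task edge ({p}, {c}) references unknown level")
            g.add_edge(p, c)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("task_edges must form a DAG")

    @property
    def levels(self):
        return sorted(self.level_dims)

    def covered_columns(self):
        return sorted(c for cols in self.level_dims.values() for c in cols)


def _read_table(path):
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    id_col = df.columns[0]
    ids = df[id_col].astype(str).tolist()
    body = df.drop(columns=[id_col])
    for col in body.columns:
        coerced = pd.to_numeric(body[col], errors="coerce")
        if coerced.isna().any() and not body[col].isna().any():
            row = int(coerced.isna().idxmax())
            raise ValueError(
                f"{path}: non-numeric cell at row {row}, column {col!r}"
            )
        body[col] = coerced
    if body.isna().any().any():
        raise ValueError(f"{path}: missing values are not supported")
    return ids, body


def _blocks_from_columns(columns):
    blocks = []
    for name in columns:
        block = name.split(":", 1)[0] if ":" in name else "features"
        if not blocks or blocks[-1][0] != block:
            blocks.append([block, 1])
        else:
            blocks[-1][1] += 1
    out, start = [], 0
    for name, width in blocks:
        out.append((name, (start, start + width)))
        start += width
    return out


def standardize_features(values):
    """Column-wise z-scoring; zero-variance columns map to all-zeros."""
    values = onp.asarray(values, dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    zero_var = sd == 0
    if onp.any(zero_var):
        logger.warning(
            "standardizing %d zero-variance feature column(s) to zeros",
            int(zero_var.sum()),
        )
        sd = onp.where(zero_var, 1.0, sd)
    return (values - mean) / sd


def load_graph_edgelist(path, d_y, delta=0.05):
    """Read a 3-column TSV edge list into a projected fixed graph."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] != 3:
        raise ValueError(f"{path}: graph file must have 3 columns (i, j, weight)")
    try:
        float(df.iloc[0, 2])
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)  # tolerate a header row
    adj = onp.zeros((d_y, d_y))
    edges = []
    for _, (i, j, w) in df.iterrows():
        i, j, w = int(i), int(j), float(w)
        if not (0 <= i < d_y and 0 <= j < d_y):
            raise ValueError(f"graph edge ({i}, {j}) outside 0..{d_y - 1}")
        if i == j:
            raise ValueError("self-loops are not allowed in the phenotype graph")
        adj[i, j] = w
        adj[j, i] = w
        edges.append((min(i, j), max(i, j), w))
    graph = project_adjacency(adj, delta)
    graph.edge_list = edges if onp.allclose(graph.adjacency, adj) else graph.edges()
    return graph


def load_tables(features_path, phenotypes_path, graph_path=None, delta=0.05):
    """Load and align a (features, phenotypes, graph) triplet by subject id.

    Features are standardized per column (mean 0, SD 1). Returns the graph as
    ``None`` when no path is given.
    """
    f_ids, f_body = _read_table(features_path)
    p_ids, p_body = _read_table(phenotypes_path)
    if f_ids != p_ids:
        missing_p = sorted(set(f_ids) - set(p_ids))
        missing_f = sorted(set(p_ids) - set(f_ids))
        if missing_p or missing_f:
            raise ValueError(
                "subject sets differ between tables; "
                f"only in features: {missing_p}; only in phenotypes: {missing_f}"
            )
        p_body = p_body.loc[[p_ids.index(s) for s in f_ids]].reset_index(drop=True)
    features = FeatureMatrix(
        values=standardize_features(f_body.to_numpy(dtype=float)),
        modality_blocks=_blocks_from_columns(list(f_body.columns)),
        subject_ids=f_ids,
        column_names=list(f_body.columns),
    )
    phenotypes = PhenotypeMatrix(
        values=p_body.to_numpy(dtype=float),
        column_names=list(p_body.columns),
    )
    graph = None
    if graph_path is not None:
        graph = load_graph_edgelist(graph_path, phenotypes.d_y, delta=delta)
    return features, phenotypes, graph


def as_adjacency(graph):
    """Dense adjacency from a PhenotypeGraph, traced value, or raw matrix."""
    if isinstance(graph, PhenotypeGraph):
        return graph.adjacency
    return graph if hasattr(graph, "_value") else anp.asarray(graph, dtype=float)


def smoothness_penalty(y, adjacency):
    """Graph smoothness of a prediction batch, traceable in both arguments.

    Sums ``|A_kl| * ||y[:, k] - y[:, l]||^2`` over undirected edges (k < l)
    and over the batch. Edge weights enter through their magnitude so that
    fixed and learnable adjacencies share one code path.
    """
    d = y.shape[1]
    mask = onp.triu(onp.ones((d, d)), 1)
    diff2 = anp.sum((y[:, :, None] - y[:, None, :]) ** 2, axis=0)
    return anp.sum(mask * anp.abs(adjacency) * diff2)


def graph_smoothness(y_hat, graph):
    """Smoothness of predicted phenotypes over the dependency graph."""
    y_hat = anp.atleast_2d(y_hat)
    if y_hat.shape[1] != graph.d_y:
        raise ValueError(
            f"phenotype batch has {y_hat.shape[1]} columns, graph expects {graph.d_y}"
        )
    return smoothness_penalty(y_hat, graph.adjacency)


def graph_penalties(graph):
    """(sparsity, asymmetry) = (entrywise L1 norm, squared Frobenius of A - A^T)."""
    A = as_adjacency(graph)
    return float(anp.sum(anp.abs(A))), float(anp.sum((A - A.T) ** 2))


def spectral_radius(A):
    A = onp.asarray(A, dtype=float)
    sym = onp.allclose(A, A.T, atol=1e-12)
    eig = onp.linalg.eigvalsh(A) if sym else onp.linalg.eigvals(A)
    return float(onp.max(onp.abs(eig))) if A.size else 0.0


def project_adjacency(raw, delta=0.05, mode="fixed"):
    """Symmetrize, zero the diagonal, and cap the spectral radius at 1 - delta.

    The cap makes the decoder's fixed-point equation well-posed (the Neumann
    series of A converges). Idempotent on already-valid graphs.
    """
    if not (0.0 < delta < 1.0):
        raise ValueError(f"delta must be in (0, 1), got {delta}")
    raw = onp.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
        raise ValueError("raw adjacency must be square")
    A = 0.5 * (raw + raw.T)
    onp.fill_diagonal(A, 0.0)
    rho = spectral_radius(A)
    if rho > 1.0 - delta:
        A = A * ((1.0 - delta) / rho)
    return PhenotypeGraph(adjacency=A, mode=mode)
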