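"""Cognitive optimization and generalization strategy (COGS) objectives.

Domain-aware regularization (graph smoothness, latent disentanglement,
prediction sparsity), gradient-magnitude adaptive multi-task weighting,
parent-child hierarchy consistency, and heteroscedastic uncertainty loss.

Note on the adaptive weights: the printed rule lambda_t = 1 / (E[||grad||^2]
+ eps) makes weights *decrease* with the task's gradient magnitude, although
the surrounding prose promises harder tasks more emphasis. The formula is
implemented as printed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as onp
import autograd.numpy as anp

from .data import PhenotypeGraph, as_adjacency, smoothness_penalty

logger = logging.getLogger(__name__)

__all__ = [
    "TaskSpec",
    "domain_regularizer",
    "disentangle_penalty",
    "adaptive_task_weights",
    "hierarchy_consistency",
    "uncertainty_loss",
    "total_objective",
]


@dataclass
class TaskSpec:
    """Multi-task structure: column partition, DAG, and weighting constants."""

    n_tasks: int
    task_to_columns: dict
    dag_edges: list = field(default_factory=list)
    ema_beta: float = 0.9
    epsilon: float = 1e-8

    def __post_init__(self):
        self.task_to_columns = {
            int(t): list(map(int, cols)) for t, cols in self.task_to_columns.items()
        }
        if len(self.task_to_columns) != self.n_tasks:
            raise ValueError("task_to_columns must define every task")
        if not (0.0 <= self.ema_beta < 1.0):
            raise ValueError("ema_beta must be in [0, 1)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        g = nx.DiGraph()
        g.add_nodes_from(self.task_to_columns)
        for p, c in self.dag_edges:
            if p not in self.task_to_columns or c not in self.task_to_columns:
                raise ValueError(f"dag edge ({p}, {c}) references unknown task")
            g.add_edge(p, c)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("task dag_edges must be acyclic")

    @classmethod
    def from_hierarchy(cls, hierarchy, **kw):
        """Tasks = abstraction levels (the default column partition)."""
        return cls(
            n_tasks=len(hierarchy.levels),
            task_to_columns={lv: hierarchy.level_dims[lv] for lv in hierarchy.levels},
            dag_edges=list(hierarchy.task_edges),
            **kw,
        )

    @property
    def tasks(self):
        return sorted(self.task_to_columns)


def disentangle_penalty(z):
    """Sum of squared off-diagonal covariances of the latent dimensions.

    Uses the unbiased batch covariance; a batch of 1 (or a single latent
    dimension) yields 0.
    """
    z = anp.atleast_2d(z)
    n, d = z.shape
    if n < 2:
        logger.warning("disentangle_penalty on a batch of 1 is 0")
        return 0.0
    if d < 2:
        return 0.0
    centered = z - anp.mean(z, axis=0)
    cov = anp.dot(centered.T, centered) / (n - 1)
    off = onp.ones((d, d)) - onp.eye(d)
    return anp.sum(off * cov**2)


def domain_regularizer(y_pred, z, graph, lambdas=None):
    """Domain-aware regularization bundle.

    total = lam_smooth * R_smooth + lam_disentangle * R_disentangle
            + lam_sparse * mean ||y_pred||_1

    with R_smooth the graph smoothness of the predictions and R_disentangle
    the squared off-diagonal latent covariance. Returns (total, components);
    the weighted components sum to the total.
    """
    lam = {"smooth": 0.0, "disentangle": 0.0, "sparse": 0.0}
    if lambdas:
        unknown = set(lambdas) - set(lam)
        if unknown:
            raise ValueError(f"unknown domain_regularizer weights: {sorted(unknown)}")
        lam.update(lambdas)
    if any(v < 0 for v in lam.values()):
        raise ValueError("domain_regularizer weights must be non-negative")
    y_pred = anp.atleast_2d(y_pred)
    A = as_adjacency(graph)
    components = {
        "smooth": lam["smooth"] * smoothness_penalty(y_pred, A),
        "disentangle": lam["disentangle"] * disentangle_penalty(z),
        "sparse": lam["sparse"] * anp.mean(anp.sum(anp.abs(y_pred), axis=1)),
    }
    total = components["smooth"] + components["disentangle"] + components["sparse"]
    return total, components


def adaptive_task_weights(grad_sq_norms, spec, ema_state=None):
    """Per-task loss weights inverse to smoothed gradient magnitudes.

    lambda_t = 1 / (EMA_t + eps), then rescaled to sum to n_tasks so the
    total loss scale stays stable. Returns (lambdas, new_ema_state), both
    arrays ordered by sorted task id.
    """
    stats = onp.asarray(grad_sq_norms, dtype=float)
    if stats.shape != (spec.n_tasks,):
        raise ValueError(f"expected {spec.n_tasks} statistics, got {stats.shape}")
    if onp.any(stats < 0):
        raise ValueError("gradient statistics must be non-negative")
    if ema_state is None:
        ema = stats.copy()
    else:
        ema = spec.ema_beta * onp.asarray(ema_state, dtype=float) + (1 - spec.ema_beta) * stats
    raw = 1.0 / (ema + spec.epsilon)
    lam = raw * (spec.n_tasks / raw.sum())
    return lam, ema


def _group_means(values, n_groups):
    """Column-group means: contiguous, nearly equal groups in column order."""
    groups = onp.array_split(onp.arange(values.shape[1]), n_groups)
    return anp.stack([anp.mean(values[:, g], axis=1) for g in groups], axis=1)


def hierarchy_consistency(y_pred_by_task, spec):
    """Parent-child consistency over the task DAG.

    Child predictions are aggregated into the parent's dimensionality by
    fixed column-group means before the squared comparison; batch-averaged.
    """
    total = 0.0
    for parent, child in spec.dag_edges:
        if parent not in y_pred_by_task or child not in y_pred_by_task:
            raise ValueError(f"predictions missing for edge ({parent}, {child})")
        y_p = anp.atleast_2d(y_pred_by_task[parent])
        y_c = anp.atleast_2d(y_pred_by_task[child])
        agg = _group_means(y_c, y_p.shape[1])
        total = total + anp.mean(anp.sum((y_p - agg) ** 2, axis=1))
    return total


def uncertainty_loss(y_pred_by_task, y_true_by_task, log_var_task):
    """Heteroscedastic multi-task loss with learnable per-task variances.

    sum_t [ (1 / 2 sigma_t^2) ||y_t - yhat_t||^2 + (1/2) log sigma_t^2 ],
    squared errors batch-averaged; log-variances clamped to [-10, 10].
    """
    log_var_task = anp.clip(anp.atleast_1d(log_var_task), -10.0, 10.0)
    tasks = sorted(y_pred_by_task)
    if len(tasks) != onp.shape(log_var_task)[0]:
        raise ValueError("one log-variance per task is required")
    total = 0.0
    for t, lv in zip(tasks, log_var_task):
        err = anp.atleast_2d(y_pred_by_task[t]) - anp.atleast_2d(y_true_by_task[t])
        sq = anp.mean(anp.sum(err**2, axis=1))
        total = total + 0.5 * sq / anp.exp(lv) + 0.5 * lv
    return total


def total_objective(task_losses, task_lambdas, hierarchy_term, uncertainty_term, lambdas=None):
    """Full COGS objective.

    total = sum_t lambda_t L_t + lam_hierarchy * R_hierarchy
            + lam_uncertainty * R_uncertainty

    Returns (total, components); components are weighted and sum to total.
    """
    lam = {"hierarchy": 0.0, "uncertainty": 0.0}
    if lambdas:
        unknown = set(lambdas) - set(lam)
        if unknown:
            raise ValueError(f"unknown total_objective weights: {sorted(unknown)}")
        lam.update(lambdas)
    if any(v < 0 for v in lam.values()):
        raise ValueError("total_objective weights must be non-negative")
    task_losses = list(task_losses)
    task_lambdas = list(task_lambdas)
    if len(task_losses) != len(task_lambdas):
        raise ValueError("one weight per task loss is required")
    multi = 0.0
    for w, loss in zip(task_lambdas, task_losses):
        multi = multi + w * loss
    components = {
        "multi_task": multi,
        "hierarchy": lam["hierarchy"] * hierarchy_term,
        "uncertainty": lam["uncertainty"] * uncertainty_term,
    }
    total = components["multi_task"] + components["hierarchy"] + components["uncertainty"]
    return total, components
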