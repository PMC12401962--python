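"""End-to-end training, evaluation metrics, splits, CV, and power analysis."""

from __future__ import annotations

import logging
import warnings

import numpy as onp
import pandas as pd
from autograd import value_and_grad
from autograd.misc import flatten
from scipy import stats as sstats
from sklearn.metrics import roc_auc_score

from .encoder import update_bn_state
from .model import ModelConfig, init_model, predict, supervised_loss
from .nn import Adam

logger = logging.getLogger(__name__)

__all__ = [
    "split_dataset",
    "train",
    "evaluate",
    "crossvalidate",
    "paired_ttest_power",
]


def _largest_remainder_sizes(n, ratios):
    raw = [n * r for r in ratios]
    sizes = [int(onp.floor(v)) for v in raw]
    remainder = n - sum(sizes)
    # leftover units go to the largest fractional parts; ties in list order
    order = sorted(range(len(ratios)), key=lambda i: (-(raw[i] - sizes[i]), i))
    for i in order[:remainder]:
        sizes[i] += 1
    return sizes


def split_dataset(n, ratios=(0.7, 0.15, 0.15), seed=0, stratify=None):
    """Disjoint, exhaustive (train, val, test) index sets.

    Sizes follow largest-remainder rounding with ties resolved in
    (train, val, test) order; the permutation is seeded. ``stratify`` may be
    a binary label vector: classes are then split separately while keeping
    the exact global sizes.
    """
    if n < 3:
        raise ValueError(f"cannot split n={n} < 3 samples")
    ratios = tuple(float(r) for r in ratios)
    if any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must be positive and sum to 1")
    sizes = _largest_remainder_sizes(n, ratios)
    rng = onp.random.default_rng(seed)
    if stratify is None:
        perm = rng.permutation(n)
        out, start = [], 0
        for s in sizes:
            out.append(onp.sort(perm[start : start + s]))
            start += s
        return tuple(out)
    labels = onp.asarray(stratify)
    parts = [[], [], []]
    remaining = list(sizes)
    classes = [onp.flatnonzero(labels == c) for c in onp.unique(labels)]
    for ci, idx in enumerate(classes):
        idx = rng.permutation(idx)
        if ci < len(classes) - 1:
            csizes = _largest_remainder_sizes(len(idx), ratios)
            csizes = [min(c, r) for c, r in zip(csizes, remaining)]
        else:
            csizes = list(remaining)  # absorb rounding so global sizes are exact
        start = 0
        for j, s in enumerate(csizes):
            parts[j].extend(idx[start : start + s])
            remaining[j] -= s
            start += s
    return tuple(onp.sort(onp.asarray(p, dtype=int)) for p in parts)


def train(
    features,
    phenotypes,
    graph=None,
    config=None,
    seed=0,
    init_params=None,
    task_adaptive=False,
    splits=None,
):
    """Supervised training with Adam, early stopping on validation loss.

    Returns (params, history) where history is a DataFrame with one row per
    epoch holding the train/validation totals and every weighted loss
    component; when attention is on, the alpha weights are logged per epoch.
    Aborts with the offending component name if any loss goes non-finite.
    """
    x = onp.asarray(getattr(features, "values", features), dtype=float)
    y = onp.asarray(getattr(phenotypes, "values", phenotypes), dtype=float)
    if config is None:
        raise ValueError("a ModelConfig is required")
    n, d_x = x.shape
    d_y = y.shape[1]
    rng = onp.random.default_rng(seed)
    if splits is None:
        idx_train, idx_val, _ = split_dataset(n, seed=seed)
    else:
        idx_train, idx_val = splits[0], splits[1]
    params = init_params if init_params is not None else init_model(rng, d_x, d_y, config)
    flat, unflatten = flatten(params)
    opt = Adam(lr=config.lr)
    state = opt.init_state(flat)
    bs = min(config.batch_size, len(idx_train))
    history_rows = []
    best_val, best_flat, since_best = onp.inf, flat.copy(), 0
    bn_state = None
    task_lambdas, task_ema = None, None

    for epoch in range(config.max_epochs):
        order = rng.permutation(idx_train)
        comp_sums: dict = {}
        total_sum, n_batches = 0.0, 0
        for start in range(0, len(order), bs):
            batch = order[start : start + bs]
            if len(batch) < 2:
                continue
            xb, yb = x[batch], y[batch]
            eps = rng.standard_normal((len(batch), config.encoder.d_z))
            drop_rng = onp.random.default_rng(int(rng.integers(2**31)))
            prior_draw = onp.random.default_rng(int(rng.integers(2**31))).standard_normal(
                (len(batch), config.encoder.d_z)
            )
            comp_out = {}

            def loss_fn(f):
                total, comps = supervised_loss(
                    unflatten(f), xb, yb, config, graph=graph, train=True,
                    rng=drop_rng, eps=eps, prior_draw=prior_draw,
                    task_lambdas=task_lambdas,
                )
                comp_out.update(comps)
                return total

            val, grad = value_and_grad(loss_fn)(flat)
            if not onp.isfinite(val):
                bad = [
                    k for k, v in comp_out.items()
                    if not onp.isfinite(float(getattr(v, "_value", v)))
                ]
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; first bad component: "
                    f"{bad[0] if bad else 'total'}"
                )
            flat, state = opt.step(flat, grad, state)
            for k, v in comp_out.items():
                comp_sums[k] = comp_sums.get(k, 0.0) + float(getattr(v, "_value", v))
            total_sum += float(val)
            n_batches += 1

        if task_adaptive and config.use_attention:
            # per-task squared gradient norms on the shared trunk, EMA-smoothed
            from .cogs import TaskSpec, adaptive_task_weights

            spec_mt = TaskSpec.from_hierarchy(config.hierarchy)
            gstats = []
            for t in spec_mt.tasks:
                cols = spec_mt.task_to_columns[t]

                def task_loss(f):
                    p = unflatten(f)
                    pred = predict(p, x[idx_train[:bs]], config, graph=graph)
                    err = pred[:, cols] - y[idx_train[:bs]][:, cols]
                    import autograd.numpy as anp

                    return anp.mean(anp.sum(err**2, axis=1)) if cols else 0.0

                if cols:
                    _, g = value_and_grad(task_loss)(flat)
                    gstats.append(float(onp.sum(g**2)))
                else:
                    gstats.append(0.0)
            task_lambdas, task_ema = adaptive_task_weights(gstats, spec_mt, task_ema)

        params_now = unflatten(flat)
        if config.encoder.batch_norm:
            bn_state = update_bn_state(
                x[idx_train], config.encoder, params_now["encoder"], bn_state
            )
        val_total, val_comps = supervised_loss(
            params_now, x[idx_val], y[idx_val], config, graph=graph, train=False,
            bn_state=bn_state,
        )
        val_total = float(val_total)
        row = {
            "epoch": epoch,
            "train_total": total_sum / max(n_batches, 1),
            "val_total": val_total,
        }
        for k, v in comp_sums.items():
            row[f"train_{k}"] = v / max(n_batches, 1)
        for k, v in val_comps.items():
            row[f"val_{k}"] = float(getattr(v, "_value", v))
        if config.use_attention:
            from .model import forward

            alpha = forward(params_now, x[idx_val[:4]], config, graph=graph, bn_state=bn_state)["alpha"]
            for li, a in enumerate(onp.atleast_1d(onp.asarray(alpha)).ravel()):
                row[f"alpha_{li + 1}"] = float(a)
        history_rows.append(row)

        if val_total < best_val - 1e-12:
            best_val, best_flat, since_best = val_total, flat.copy(), 0
        else:
            since_best += 1
            if since_best >= config.patience:
                logger.info("early stopping at epoch %d", epoch)
                break

    params = unflatten(best_flat)
    history = pd.DataFrame(history_rows)
    if config.encoder.batch_norm:
        bn_state = update_bn_state(x[idx_train], config.encoder, params["encoder"])
    return params, history, bn_state


def evaluate(params, features, phenotypes, config, graph=None, split=None, bn_state=None):
    """Per-column and aggregate metrics.

    Continuous columns: MAE and RMSE. Binary columns: accuracy, precision,
    recall, F1 (macro over columns), and AUROC from the raw predicted scores
    (class decided at 0.5). AUROC on a single-class column is reported as
    None with a warning rather than raising.
    """
    x = onp.asarray(getattr(features, "values", features), dtype=float)
    y = onp.asarray(getattr(phenotypes, "values", phenotypes), dtype=float)
    kinds = getattr(phenotypes, "column_kind", ["continuous"] * y.shape[1])
    names = getattr(phenotypes, "column_names", [f"y{j}" for j in range(y.shape[1])])
    if split is not None:
        x, y = x[split], y[split]
    pred = predict(params, x, config, graph=graph, bn_state=bn_state)
    per_column: dict = {}
    cont_mae, cont_rmse, bin_stats, aurocs = [], [], [], []
    for j, (name, kind) in enumerate(zip(names, kinds)):
        yj, pj = y[:, j], pred[:, j]
        if kind == "continuous":
            mae = float(onp.mean(onp.abs(yj - pj)))
            rmse = float(onp.sqrt(onp.mean((yj - pj) ** 2)))
            per_column[name] = {"mae": mae, "rmse": rmse}
            cont_mae.append(mae)
            cont_rmse.append(rmse)
        else:
            cls = (pj > 0.5).astype(float)
            tp = float(onp.sum((cls == 1) & (yj == 1)))
            fp = float(onp.sum((cls == 1) & (yj == 0)))
            fn = float(onp.sum((cls == 0) & (yj == 1)))
            acc = float(onp.mean(cls == yj))
            prec = tp / (tp + fp) if tp + fp > 0 else 0.0
            rec = tp / (tp + fn) if tp + fn > 0 else 0.0
            f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
            if len(onp.unique(yj)) < 2:
                warnings.warn(f"AUROC undefined for single-class column {name}")
                auc = None
            else:
                auc = float(roc_auc_score(yj, pj))
                aurocs.append(auc)
            per_column[name] = {
                "accuracy": acc, "precision": prec, "recall": rec, "f1": f1, "auroc": auc,
            }
            bin_stats.append((acc, prec, rec, f1))
    aggregate: dict = {}
    if cont_mae:
        aggregate["mae"] = float(onp.mean(cont_mae))
        aggregate["rmse"] = float(onp.mean(cont_rmse))
        # pooled RMSE over all continuous entries
        cont_idx = [j for j, k in enumerate(kinds) if k == "continuous"]
        aggregate["rmse_pooled"] = float(
            onp.sqrt(onp.mean((y[:, cont_idx] - pred[:, cont_idx]) ** 2))
        )
    if bin_stats:
        arr = onp.asarray(bin_stats)
        for i, key in enumerate(["accuracy", "precision", "recall", "f1"]):
            aggregate[key] = float(arr[:, i].mean())
        aggregate["auroc"] = float(onp.mean(aurocs)) if aurocs else None
    return {"per_column": per_column, "aggregate": aggregate}


def crossvalidate(features, phenotypes, graph=None, config=None, k=5, seed=0):
    """Seeded k-fold cross-validation; each fold trains a fresh model.

    Returns {"folds": [metrics...], "mean": ..., "sd": ...} with the SD the
    textbook (ddof=1) formula over folds.
    """
    x = onp.asarray(getattr(features, "values", features), dtype=float)
    n = x.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    rng = onp.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = onp.array_split(perm, k)
    fold_metrics = []
    for fi in range(k):
        test_idx = onp.sort(folds[fi])
        rest = onp.concatenate([folds[j] for j in range(k) if j != fi])
        n_val = max(2, int(round(0.15 * len(rest))))
        val_idx, train_idx = onp.sort(rest[:n_val]), onp.sort(rest[n_val:])
        params, _, bn_state = train(
            features, phenotypes, graph=graph, config=config,
            seed=seed + 1000 * (fi + 1), splits=(train_idx, val_idx),
        )
        m = evaluate(params, features, phenotypes, config, graph=graph,
                     split=test_idx, bn_state=bn_state)
        fold_metrics.append(m["aggregate"])
    keys = sorted({k2 for m in fold_metrics for k2 in m if m[k2] is not None})
    mean = {k2: float(onp.mean([m[k2] for m in fold_metrics if m.get(k2) is not None]))
            for k2 in keys}
    sd = {
        k2: float(onp.std([m[k2] for m in fold_metrics if m.get(k2) is not None], ddof=1))
        for k2 in keys
    }
    return {"folds": fold_metrics, "mean": mean, "sd": sd}


def paired_ttest_power(effect_size, alpha=0.05, power=0.8, two_tailed=True, max_n=10**6):
    """Smallest n for a paired t test to reach the requested power.

    Uses the noncentral t distribution with noncentrality d * sqrt(n) and
    n - 1 degrees of freedom.
    """
    if effect_size <= 0:
        raise ValueError("effect_size must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")

    def achieved(n):
        df = n - 1
        nc = effect_size * onp.sqrt(n)
        if two_tailed:
            crit = sstats.t.ppf(1 - alpha / 2, df)
            return float(
                1 - sstats.nct.cdf(crit, df, nc) + sstats.nct.cdf(-crit, df, nc)
            )
        crit = sstats.t.ppf(1 - alpha, df)
        return float(1 - sstats.nct.cdf(crit, df, nc))

    lo, hi = 2, 2
    while achieved(hi) < power:
        hi *= 2
        if hi > max_n:
            raise ValueError(f"power {power} unattainable with n <= {max_n}")
    while lo < hi:
        mid = (lo + hi) // 2
        if achieved(mid) >= power:
            hi = mid
        else:
            lo = mid + 1
    return int(lo)
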