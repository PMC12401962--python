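"""Statistical comparison protocol for paired run metrics.

Given two runs' per-fold (or per-seed) metric tables, each metric is
compared with a paired test: Shapiro-Wilk checks normality of the paired
differences and Levene homogeneity of variance; when both hold a two-tailed
paired t test is used, otherwise the Wilcoxon signed-rank test. P-values are
Holm-Bonferroni corrected across metrics.
"""

from __future__ import annotations

import numpy as onp
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

__all__ = ["compare_metric_tables", "compare_files"]


def compare_metric_tables(df_a, df_b, alpha=0.05):
    """Paired comparison of every shared numeric column; returns a DataFrame."""
    shared = [
        c for c in df_a.columns
        if c in df_b.columns and pd.api.types.is_numeric_dtype(df_a[c])
    ]
    if not shared:
        raise ValueError("no shared numeric metric columns to compare")
    if len(df_a) != len(df_b):
        raise ValueError("paired comparison requires equal row counts")
    rows = []
    for col in shared:
        a = onp.asarray(df_a[col], dtype=float)
        b = onp.asarray(df_b[col], dtype=float)
        diff = a - b
        if len(diff) < 3 or onp.allclose(diff, diff[0]):
            shapiro_p = onp.nan
            normal = True
        else:
            shapiro_p = float(sstats.shapiro(diff).pvalue)
            normal = shapiro_p >= alpha
        levene_p = float(sstats.levene(a, b).pvalue) if len(a) >= 2 else onp.nan
        if normal:
            test = "paired_t"
            res = sstats.ttest_rel(a, b)
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            test = "wilcoxon"
            res = sstats.wilcoxon(a, b)
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "metric": col,
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
                "shapiro_p": shapiro_p,
                "levene_p": levene_p,
                "test": test,
                "statistic": stat,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    valid = out["p_value"].notna()
    corrected = onp.full(len(out), onp.nan)
    out["significant_holm"] = False
    if valid.any():
        reject, p_holm, _, _ = multipletests(
            out.loc[valid, "p_value"], alpha=alpha, method="holm"
        )
        corrected[valid.to_numpy()] = p_holm
        out.loc[valid, "significant_holm"] = reject
    out["p_holm"] = corrected
    return out


def compare_files(path_a, path_b, alpha=0.05):
    sep_a = "\t" if str(path_a).endswith(".tsv") else ","
    sep_b = "\t" if str(path_b).endswith(".tsv") else ","
    return compare_metric_tables(
        pd.read_csv(path_a, sep=sep_a), pd.read_csv(path_b, sep=sep_b), alpha=alpha
    )
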