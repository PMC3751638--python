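"""Expression-matrix operations: global normalization, threshold-based
differential-expression calling, and per-gene Z scores.

The DE caller is a fold-change / p-value filter in the style of array-era
screens: a gene is called when |signed fold| >= fc_cut (default 1.7) and
the Welch two-sample t-test on log2 intensities gives p < p_cut (default
0.01), with no multiple-testing correction by default. The test statistic
is a documented stand-in for the original (unstated) array-software test
and can be swapped via the ``test`` argument.
"""
from __future__ import annotations

from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy import stats

from .models import ExpressionMatrix, signed_fold


def global_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample so its median equals the grand median of the
    input matrix. Values stay positive; gene/sample order is preserved."""
    values = matrix.values
    grand = float(np.median(values.to_numpy()))
    factors = grand / values.median(axis=0)
    return ExpressionMatrix(values=values * factors, groups=matrix.groups)


def welch_t_log2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Welch's unequal-variance t-test p-values on log2 intensities,
    row-wise; degenerate rows (zero variance, equal means) give p = 1."""
    res = stats.ttest_ind(np.log2(b), np.log2(a), axis=1, equal_var=False)
    return np.nan_to_num(res.pvalue, nan=1.0)


def differential_expression(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    fc_cut: float = 1.7,
    p_cut: float = 0.01,
    test: Callable[[np.ndarray, np.ndarray], np.ndarray] = welch_t_log2,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Call differential expression of group_b relative to group_a.

    Fold change is mean(B)/mean(A) on the linear scale, reported in the
    signed convention (ratio if >= 1 else -1/ratio). Returns a DataFrame
    indexed by gene_id with columns signed_fc, p_value, call (up/down/null)
    and, when ``bh_correct``, p_adj (calls then use the adjusted p).
    """
    if fc_cut < 1:
        raise ValueError("fc_cut must be >= 1")
    if not 0 < p_cut <= 1:
        raise ValueError("p_cut must lie in (0, 1]")
    a_cols = matrix.samples_in(group_a)
    b_cols = matrix.samples_in(group_b)
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError(
            f"both groups need >= 2 samples (got {group_a}: {len(a_cols)}, "
            f"{group_b}: {len(b_cols)})"
        )
    a = matrix.values[a_cols].to_numpy(dtype=float)
    b = matrix.values[b_cols].to_numpy(dtype=float)
    ratio = b.mean(axis=1) / a.mean(axis=1)
    sfc = signed_fold(ratio)
    p = np.asarray(test(a, b), dtype=float)
    out = pd.DataFrame(
        {"signed_fc": sfc, "p_value": p}, index=matrix.gene_ids.rename("gene_id")
    )
    p_for_call = p
    if bh_correct:
        m = len(p)
        order = np.argsort(p)
        ranked = p[order] * m / (np.arange(m) + 1)
        adj = np.empty(m)
        adj[order] = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
        out["p_adj"] = adj
        p_for_call = adj
    call = np.full(len(out), "null", dtype=object)
    call[(sfc >= fc_cut) & (p_for_call < p_cut)] = "up"
    call[(sfc <= -fc_cut) & (p_for_call < p_cut)] = "down"
    out["call"] = call
    return out


def called_genes(de_table: pd.DataFrame, direction: Literal["up", "down", "both"] = "both") -> set[str]:
    """Gene ids with a non-null call, optionally restricted by direction."""
    if direction == "both":
        mask = de_table["call"] != "null"
    else:
        mask = de_table["call"] == direction
    return set(de_table.index[mask])


def zscore_expression(condition_mean_expression: pd.Series) -> pd.Series:
    """Standardise log2 condition-mean expression across genes.

    Z = (log2 x - mean) / sd with ddof=1; an all-equal input yields all
    zeros by convention. Requires at least two genes.
    """
    x = pd.Series(condition_mean_expression, dtype=float)
    if len(x) < 2:
        raise ValueError("Z scores need at least two genes")
    if (x <= 0).any():
        raise ValueError("expression must be strictly positive")
    logx = np.log2(x)
    sd = logx.std(ddof=1)
    if sd == 0:
        return pd.Series(0.0, index=x.index, name="z")
    return ((logx - logx.mean()) / sd).rename("z")
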