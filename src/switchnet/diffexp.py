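"""Stage 1: expression filtering and case/control differential statistics.

Genes with no or low expression are removed first; the per-gene log2 fold
change (case mean minus control mean, log2 units) and a two-sided Welch
t-test p-value are then computed, Benjamini-Hochberg adjusted, and the
fold-change / FDR filter decides which genes enter the co-expression network.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["preprocess", "log2_fold_changes", "welch_p_values", "bh_fdr",
           "differential_analysis", "filter_genes"]


def _check_groups(expr: ExpressionMatrix, min_per_group: int = 2) -> None:
    n = expr.n_per_group()
    lacking = [g for g, c in n.items() if c < min_per_group]
    if lacking:
        raise ValueError(f"need >= {min_per_group} samples per group; "
                         f"got {n}")


def preprocess(expr: ExpressionMatrix, min_mean: float = 1.0,
               min_fraction_expressed: float = 0.5) -> ExpressionMatrix:
    """Drop genes with no or low expression.

    A gene is kept when the fraction of samples in which its expression is at
    least ``min_mean`` (log2 units) reaches ``min_fraction_expressed``.
    ``min_fraction_expressed=0`` keeps everything.
    """
    if min_mean < 0 or min_fraction_expressed < 0:
        raise ValueError("thresholds must be >= 0")
    frac = (expr.values >= min_mean).mean(axis=1)
    keep = frac >= min_fraction_expressed
    if not keep.any():
        raise ValueError("preprocess removed every gene; lower min_mean or "
                         "min_fraction_expressed")
    if (~keep).any():
        logger.info("preprocess dropped %d of %d genes", int((~keep).sum()), len(keep))
    return ExpressionMatrix(expr.values.loc[keep], expr.groups.copy(), expr.log2_scale)


def log2_fold_changes(expr: ExpressionMatrix) -> pd.Series:
    """Per-gene log2 fold change: mean over cases minus mean over controls."""
    case, ctrl = expr.case_samples, expr.control_samples
    if not case or not ctrl:
        raise ValueError("both groups must be present")
    return expr.values[case].mean(axis=1) - expr.values[ctrl].mean(axis=1)


def welch_p_values(expr: ExpressionMatrix) -> pd.Series:
    """Two-sided unequal-variance t-test p-value per gene.

    Degenerate genes (zero variance in both groups) get p = 1 when the group
    means are equal and p = 0 when they differ.
    """
    _check_groups(expr)
    case = expr.values[expr.case_samples].to_numpy()
    ctrl = expr.values[expr.control_samples].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant genes
        p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False).pvalue
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        equal = np.isclose(case.mean(axis=1), ctrl.mean(axis=1))
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    return pd.Series(p, index=expr.values.index, name="p_value")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to [0, 1]."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d vector")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_analysis(expr: ExpressionMatrix, fold_change: float = 2.0,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Full per-gene differential table with the retained flag.

    Retained <=> |log2fc| >= log2(fold_change) and BH q-value <= alpha.
    """
    if fold_change <= 1:
        raise ValueError("fold_change must be > 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    _check_groups(expr)
    case, ctrl = expr.case_samples, expr.control_samples
    lfc = log2_fold_changes(expr)
    p = welch_p_values(expr)
    q = bh_fdr(p.to_numpy())
    out = pd.DataFrame({
        "mean_case": expr.values[case].mean(axis=1),
        "mean_control": expr.values[ctrl].mean(axis=1),
        "log2fc": lfc,
        "p_value": p,
        "q_value": q,
    })
    out["retained"] = (out["log2fc"].abs() >= np.log2(fold_change)) & (out["q_value"] <= alpha)
    return out


def filter_genes(diff: pd.DataFrame, fold_change: float, alpha: float) -> list[str]:
    """Gene ids passing the fold-change + FDR filter at these thresholds."""
    if fold_change <= 1:
        raise ValueError("fold_change must be > 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    keep = (diff["log2fc"].abs() >= np.log2(fold_change)) & (diff["q_value"] <= alpha)
    return list(diff.index[keep])
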