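"""Differential-expression tests and qPCR validation statistics.

Probe-wise two-sample t-tests (Welch by default, pooled-variance optional)
for two-class designs and one-way ANOVA F-tests for multi-class designs,
with Benjamini–Hochberg FDR adjustment (or raw p values).  For qPCR
validation: per-sample ΔCt (mean target Ct minus mean reference Ct, so a
higher ΔCt means lower expression) and the Wilcoxon rank-sum test with
exact small-sample p values.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "two_class_t",
    "multi_class_f",
    "bh_adjust",
    "wilcoxon_rank_sum",
    "delta_ct",
]


def _class_arrays(matrix: ExpressionMatrix, labels: Sequence[str]) -> dict[str, np.ndarray]:
    labels = np.asarray(labels)
    if labels.shape[0] != len(matrix.sample_ids):
        raise ValueError("one class label per sample is required")
    x = matrix.values.to_numpy(dtype=float)
    out = {}
    for cls in sorted(pd.unique(labels)):
        cols = np.flatnonzero(labels == cls)
        if cols.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        out[str(cls)] = x[:, cols]
    return out


def two_class_t(
    matrix: ExpressionMatrix, labels: Sequence[str], *, equal_var: bool = False, adjust: bool = True
) -> pd.DataFrame:
    """Per-probe two-sample t-test between the two classes in ``labels``.

    Expects a log2-scale matrix.  Welch's unequal-variance statistic by
    default; ``equal_var=True`` selects the pooled-variance form (for which
    F = t² holds against the two-class ANOVA).  Probes with zero variance in
    both classes and equal means get statistic 0 and p = 1.  The sign
    convention is mean(first class) − mean(second class), classes taken in
    sorted label order, so swapping the class assignment negates t.
    """
    if matrix.scale != "log2":
        raise ValueError("two_class_t expects a log2-scale matrix")
    groups = _class_arrays(matrix, labels)
    if len(groups) != 2:
        raise ValueError(f"two-class design requires exactly 2 classes, got {len(groups)}")
    a, b = groups.values()
    res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    stat = np.asarray(res.statistic, dtype=float)
    pval = np.asarray(res.pvalue, dtype=float)
    df = np.asarray(res.df, dtype=float)
    degenerate = np.isnan(stat)  # zero variance in both classes AND equal means
    if degenerate.any():
        logger.warning("%d probes with zero variance in both classes; t set to 0, p to 1",
                       int(degenerate.sum()))
        stat[degenerate] = 0.0
        pval[degenerate] = 1.0
    out = pd.DataFrame(
        {
            "probe_id": matrix.probe_ids,
            "statistic": stat,
            "df1": df,
            "df2": np.nan,
            "p_value": pval,
        }
    )
    out["q_value"] = bh_adjust(out["p_value"].to_numpy()) if adjust else out["p_value"]
    return out


def multi_class_f(
    matrix: ExpressionMatrix, labels: Sequence[str], *, adjust: bool = True
) -> pd.DataFrame:
    """Per-probe one-way ANOVA F-test across k >= 2 classes.

    Degrees of freedom are (k−1, n−k).  Probes with zero between- and
    within-class variance get F = 0 and p = 1.
    """
    if matrix.scale != "log2":
        raise ValueError("multi_class_f expects a log2-scale matrix")
    groups = _class_arrays(matrix, labels)
    if len(groups) < 2:
        raise ValueError("multi-class design requires at least 2 classes")
    arrays = list(groups.values())
    k = len(arrays)
    n = sum(a.shape[1] for a in arrays)
    with np.errstate(invalid="ignore", divide="ignore"):
        fstat, pval = stats.f_oneway(*arrays, axis=1)
    fstat = np.asarray(fstat, dtype=float)
    pval = np.asarray(pval, dtype=float)
    degenerate = np.isnan(fstat)
    if degenerate.any():
        logger.warning("%d probes with no variance anywhere; F set to 0, p to 1",
                       int(degenerate.sum()))
        fstat[degenerate] = 0.0
        pval[degenerate] = 1.0
    out = pd.DataFrame(
        {
            "probe_id": matrix.probe_ids,
            "statistic": fstat,
            "df1": float(k - 1),
            "df2": float(n - k),
            "p_value": pval,
        }
    )
    out["q_value"] = bh_adjust(out["p_value"].to_numpy()) if adjust else out["p_value"]
    return out


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q values, in the input order.

    q_(i) = min_{j >= i} (p_(j) · m / j), clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank sum of x, p value).

    The p value comes from the exact permutation distribution when the
    combined sample size is at most 20 and there are no ties, and from the
    tie-corrected normal approximation otherwise.  Completely tied data
    (zero variance) give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    w = float(ranks[:n1].sum())
    has_ties = np.unique(combined).size < n
    if n <= 20 and not has_ties:
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
        return w, p
    u = w - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        return w, 1.0
    z = (u - mean_u) / np.sqrt(var_u)
    p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))))
    return w, p


def delta_ct(ct: pd.DataFrame, target: str, reference: str = "18S") -> pd.Series:
    """Per-sample ΔCt = mean(target replicate Ct) − mean(reference replicate Ct).

    ``ct`` has columns sample_id, target, replicate, ct (one row per
    replicate well; triplicates in a standard run).  Higher ΔCt means lower
    expression relative to the reference.
    """
    required = {"sample_id", "target", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns: {sorted(missing)}")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be > 0")
    means = ct.groupby(["sample_id", "target"])["ct"].mean().unstack("target")
    for name in (target, reference):
        if name not in means.columns:
            raise ValueError(f"no Ct rows for {name!r}")
        bad = means.index[means[name].isna()].tolist()
        if bad:
            raise ValueError(f"{name!r} not measured in samples: {bad[:5]}")
    out = means[target] - means[reference]
    out.name = f"delta_ct({target}-{reference})"
    return out
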