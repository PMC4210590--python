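"""Tissue-selectivity scoring and bidirectional-transcription calling.

Selectivity of a probe across N sample groups is measured as information
content (IC) in bits: with group means m_g normalized to p_g = m_g / Σ m_g,

    IC = log2(N) − H(p),    H(p) = −Σ_{p_g > 0} p_g · log2(p_g).

IC is 0 for a uniformly expressed probe and log2(N) for a probe expressed
in a single group; it is invariant to rescaling the means and to permuting
the group labels.  A UCR is called bidirectionally transcribed when both its
sense ("plus") and antisense ("minus") probes survive the retention filter.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix
from .synthetic import split_probe_id

__all__ = [
    "group_means",
    "information_content",
    "selectivity_table",
    "call_bidirectional",
]


def group_means(
    matrix: ExpressionMatrix, annotation: pd.DataFrame, level: str = "system"
) -> pd.DataFrame:
    """Arithmetic mean of linear-scale values per probe within each group.

    ``level`` picks the grouping column: ``"system"`` → ``system_group``,
    ``"tissue"`` → ``tissue``.  Returns a probes x groups DataFrame with a
    fixed, first-appearance group order.
    """
    if matrix.scale != "linear":
        raise ValueError("group means are computed on the linear scale")
    col = {"system": "system_group", "tissue": "tissue"}.get(level)
    if col is None:
        raise ValueError(f"level must be 'system' or 'tissue', got {level!r}")
    if col not in annotation.columns:
        raise ValueError(f"annotation lacks a {col!r} column")
    ann = annotation.set_index("sample_id")[col]
    missing = [s for s in matrix.sample_ids if s not in ann.index]
    if missing:
        raise ValueError(f"samples missing from annotation: {missing[:5]}")
    labels = ann.reindex(matrix.sample_ids)
    order = labels.drop_duplicates().tolist()
    means = matrix.values.T.groupby(labels.to_numpy()).mean().T
    means = means[order]
    if means.isna().any().any():
        raise ValueError("a group has no samples in the matrix")
    means.columns.name = col
    return means


def information_content(means: Sequence[float] | np.ndarray | pd.Series) -> float:
    """IC in bits of one probe's group-mean profile (see module docstring).

    Zero-mean groups contribute nothing to the entropy (p·log2 p → 0).
    """
    m = np.asarray(means, dtype=float)
    if m.ndim != 1 or m.size < 2:
        raise ValueError("need a 1-D profile over at least 2 groups")
    if (m < 0).any():
        raise ValueError("group means must be >= 0")
    total = m.sum()
    if total <= 0:
        raise ValueError("all group means are zero; IC is undefined")
    p = m / total
    nz = p > 0
    h = float(-(p[nz] * np.log2(p[nz])).sum())
    return float(np.log2(m.size) - h)


def selectivity_table(
    matrix: ExpressionMatrix, annotation: pd.DataFrame, level: str = "system"
) -> pd.DataFrame:
    """Per-probe selectivity, ranked from most to least tissue-selective.

    Columns: probe_id, ic_bits, top_group, rank, then one column per group
    mean.  Sorting is by IC descending with lexicographic probe-id
    tie-breaking; rank is the 1-based position.
    """
    means = group_means(matrix, annotation, level)
    if means.shape[1] < 2:
        raise ValueError("selectivity needs at least 2 groups")
    x = means.to_numpy(dtype=float)
    totals = x.sum(axis=1)
    if (totals <= 0).any():
        bad = means.index[totals <= 0][0]
        raise ValueError(f"probe {bad!r} has an all-zero group profile")
    p = x / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    ic = np.log2(means.shape[1]) + plogp.sum(axis=1)
    top = means.columns.to_numpy()[np.argmax(x, axis=1)]
    table = pd.DataFrame(
        {"probe_id": means.index, "ic_bits": ic, "top_group": top}
    ).join(means.reset_index(drop=True))
    table = table.sort_values(
        ["ic_bits", "probe_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table.insert(3, "rank", np.arange(1, len(table) + 1))
    return table


def call_bidirectional(
    retained_probe_ids: Iterable[str], catalog=None
) -> list[str]:
    """UCRs whose plus AND minus probes are both retained, sorted by id.

    If a catalog is given, every retained probe must belong to it.
    """
    by_ucr: dict[str, set[str]] = {}
    for pid in retained_probe_ids:
        ucr, strand = split_probe_id(pid)
        by_ucr.setdefault(ucr, set()).add(strand)
    if catalog is not None:
        known = set(catalog.ucr_ids)
        unknown = sorted(set(by_ucr) - known)
        if unknown:
            raise ValueError(f"retained probes reference UCRs absent from the catalog: {unknown[:5]}")
    return sorted(u for u, strands in by_ucr.items() if {"plus", "minus"} <= strands)
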