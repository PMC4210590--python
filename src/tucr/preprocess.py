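"""Probe-level preprocessing of strand-specific UCR array intensities.

The chain, in order: replicate-spot summarization → absent-call flooring →
detection (retention) filtering → quantile normalization → log2 transform.
Filtering runs before normalization so that probes called absent everywhere
do not distort the reference distribution.

A probe is retained when it is *present* (above the absent floor) in at
least 20% of samples AND at least 20% of samples deviate by more than a
1.5-fold change from that probe's median across all samples; both 20%
thresholds are inclusive and the fold-change test is two-sided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "FilterParams",
    "read_spot_table",
    "summarize_spots",
    "floor_absent",
    "detection_filter",
    "quantile_normalize",
    "log2_transform",
    "preprocess_pipeline",
]


@dataclass
class ExpressionMatrix:
    """Probes x samples expression values with a present/absent mask.

    ``values`` is a DataFrame indexed by probe id with one column per sample;
    ``scale`` records whether values are linear intensities or log2; the
    boolean ``detection`` frame (same shape) marks present calls.
    """

    values: pd.DataFrame
    scale: str = "linear"
    detection: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        if self.scale == "linear" and (self.values.to_numpy() < 0).any():
            raise ValueError("linear-scale intensities must be >= 0")
        if self.detection is None:
            self.detection = pd.DataFrame(
                True, index=self.values.index, columns=self.values.columns
            )
        elif not self.detection.index.equals(self.values.index) or not self.detection.columns.equals(
            self.values.columns
        ):
            raise ValueError("detection mask must share the value matrix's axes")

    @property
    def probe_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    def subset(self, probe_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[probe_ids].copy(), self.scale, self.detection.loc[probe_ids].copy()
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.scale, self.detection.copy())


@dataclass(frozen=True)
class FilterParams:
    """Retention-filter thresholds (inclusive fractions)."""

    present_frac: float = 0.20
    fc_frac: float = 0.20
    fold_change: float = 1.5
    floor: float | str = "auto"

    def __post_init__(self) -> None:
        for name in ("present_frac", "fc_frac"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.fold_change <= 1.0:
            raise ValueError(f"fold_change must be > 1, got {self.fold_change}")
        if self.floor != "auto" and float(self.floor) < 0:
            raise ValueError(f"floor must be >= 0 or 'auto', got {self.floor}")


def read_spot_table(path: str | Path) -> pd.DataFrame:
    spots = pd.read_csv(path, sep="\t")
    required = {"ucr_id", "strand", "sample_id", "replicate", "intensity", "flag"}
    missing = required - set(spots.columns)
    if missing:
        raise ValueError(f"spot table is missing columns: {sorted(missing)}")
    return spots


def summarize_spots(spots: pd.DataFrame) -> ExpressionMatrix:
    """Average replicate spots into one linear-scale value per (probe, sample).

    Spots with a negative quality flag are excluded before averaging.  A
    (probe, sample) cell left with no unflagged spots is set to 0 and marked
    absent, with a warning — not a hard error.
    """
    if (spots["intensity"] < 0).any():
        raise ValueError("spot intensities must be >= 0 (linear scale)")
    key = ["ucr_id", "strand", "sample_id", "replicate"]
    if spots.duplicated(key).any():
        raise ValueError("duplicate (ucr_id, strand, sample_id, replicate) spot rows")
    probe = spots["ucr_id"].astype(str) + "-" + spots["strand"].astype(str)
    df = spots.assign(probe_id=probe)
    good = df[df["flag"] >= 0]

    values = good.pivot_table(
        index="probe_id", columns="sample_id", values="intensity", aggfunc="mean"
    )
    # reindex over every probe/sample seen in the raw table, so fully flagged
    # cells surface as missing rather than silently disappearing
    all_probes = sorted(df["probe_id"].unique())
    all_samples = sorted(df["sample_id"].unique())
    values = values.reindex(index=all_probes, columns=all_samples)
    mask = values.notna()
    n_empty = int((~mask).to_numpy().sum())
    if n_empty:
        logger.warning(
            "%d (probe, sample) cells had no unflagged spots; set to 0 and marked absent",
            n_empty,
        )
        values = values.fillna(0.0)
    values.index.name = "probe_id"
    values.columns.name = "sample_id"
    mask.index.name = "probe_id"
    mask.columns.name = "sample_id"
    return ExpressionMatrix(values, "linear", mask)


def floor_absent(matrix: ExpressionMatrix, floor: float | str = "auto") -> ExpressionMatrix:
    """Threshold absent calls: values below the floor are raised to it.

    Cells below the floor are marked absent in the detection mask (on top of
    any cells already absent).  ``floor="auto"`` uses the 5th percentile of
    all values.
    """
    if matrix.scale != "linear":
        raise ValueError("floor_absent expects a linear-scale matrix")
    x = matrix.values.to_numpy(dtype=float)
    if floor == "auto":
        floor_value = float(np.percentile(x, 5))
    else:
        floor_value = float(floor)
        if floor_value < 0:
            raise ValueError(f"floor must be >= 0, got {floor_value}")
    below = x < floor_value
    out = np.where(below, floor_value, x)
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    detection = matrix.detection & pd.DataFrame(
        ~below, index=matrix.values.index, columns=matrix.values.columns
    )
    return ExpressionMatrix(values, "linear", detection)


def detection_filter(
    matrix: ExpressionMatrix, params: FilterParams = FilterParams()
) -> tuple[list[str], pd.DataFrame]:
    """Apply the dual retention rule; returns (retained probe ids, report).

    Rule 1 (presence): fraction of samples with a present call >= present_frac.
    Rule 2 (fold change): fraction of samples deviating more than
    ``fold_change``x (in either direction) from the probe's median across all
    samples (present and floored alike) >= fc_frac.  The report carries both
    fractions and per-rule verdicts for every probe.
    """
    if matrix.scale != "linear":
        raise ValueError("detection_filter expects a linear-scale matrix")
    x = matrix.values.to_numpy(dtype=float)
    mask = matrix.detection.to_numpy(dtype=bool)
    present_frac = mask.mean(axis=1)
    med = np.median(x, axis=1, keepdims=True)
    # value/median > fc or median/value > fc, written division-free so that
    # zero medians/values are handled exactly
    changed = (x > params.fold_change * med) | (params.fold_change * x < med)
    fc_frac = changed.mean(axis=1)
    pass_present = present_frac >= params.present_frac
    pass_fc = fc_frac >= params.fc_frac
    retained_mask = pass_present & pass_fc
    report = pd.DataFrame(
        {
            "probe_id": matrix.probe_ids,
            "present_frac": present_frac,
            "fc_frac": fc_frac,
            "pass_present": pass_present,
            "pass_fc": pass_fc,
            "retained": retained_mask,
        }
    )
    retained = [p for p, keep in zip(matrix.probe_ids, retained_mask) if keep]
    return retained, report


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Classic quantile normalization across samples.

    Each column is sorted, the reference distribution is the rank-wise mean of
    the sorted columns, and each column's values are replaced by the reference
    value at their rank; ties within a column receive the mean of the
    reference values over their tied ranks.  Afterwards every column has an
    identical sorted vector, hence identical mean.
    """
    x = matrix.values.to_numpy(dtype=float)
    n, m = x.shape
    if m < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(m):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = ref
        # average the reference over tied ranks
        out[:, j] = pd.Series(assigned).groupby(pd.Series(col)).transform("mean").to_numpy()
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values, matrix.scale, matrix.detection.copy())


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2 of a strictly positive linear matrix; the mask is unchanged."""
    if matrix.scale != "linear":
        raise ValueError("matrix is already on the log2 scale")
    x = matrix.values.to_numpy(dtype=float)
    if (x <= 0).any():
        raise ValueError("log2_transform requires strictly positive values; floor the matrix first")
    values = pd.DataFrame(np.log2(x), index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values, "log2", matrix.detection.copy())


@dataclass
class PreprocessResult:
    """Artifacts of the full preprocessing chain."""

    floored: ExpressionMatrix  # all probes, linear, floored
    normalized: ExpressionMatrix  # retained probes, linear, quantile-normalized
    log2: ExpressionMatrix  # retained probes, log2 of `normalized`
    retained: list[str]
    report: pd.DataFrame
    floor_value: float


def preprocess_pipeline(spots: pd.DataFrame, params: FilterParams = FilterParams()) -> PreprocessResult:
    """summarize → floor → filter → quantile-normalize → log2."""
    summarized = summarize_spots(spots)
    x = summarized.values.to_numpy(dtype=float)
    floor_value = float(np.percentile(x, 5)) if params.floor == "auto" else float(params.floor)
    floored = floor_absent(summarized, floor_value)
    retained, report = detection_filter(floored, params)
    kept = floored.subset(retained)
    normalized = quantile_normalize(kept) if len(retained) >= 1 and kept.values.shape[1] >= 2 else kept
    if floor_value > 0:
        log2 = log2_transform(normalized)
    else:
        # guard against zero cells when the user disables the floor
        shifted = ExpressionMatrix(normalized.values + 1.0, "linear", normalized.detection.copy())
        log2 = log2_transform(shifted)
    return PreprocessResult(floored, normalized, log2, retained, report, floor_value)
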