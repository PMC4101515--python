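"""Internal-standard normalization, QC feature filtering, and autoscaling.

Pipeline order matters: imputation happens on the normalized raw intensity
scale and autoscaling is applied strictly afterwards.  All standard
deviations use the sample convention (``ddof=1``).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, OrderingError
from .table import FeatureTable

__all__ = [
    "FilterReport",
    "normalize_internal_standard",
    "qc_filter",
    "autoscale",
    "apply_scaling",
]


@dataclass
class FilterReport:
    """Outcome of the QC-based feature filter."""

    removed_by_detection: list[str] = field(default_factory=list)
    removed_by_cv: list[str] = field(default_factory=list)
    cv_values: dict[str, float] = field(default_factory=dict)


def normalize_internal_standard(
    table: FeatureTable, is_feature: str
) -> FeatureTable:
    """Divide every row by its internal-standard intensity and drop that column.

    Missing cells stay missing.  A missing or zero internal-standard value in
    any row is a data error naming the offending sample.
    """
    j = table.feature_index(is_feature)
    is_col = table.values[:, j]
    for i, v in enumerate(is_col):
        if np.isnan(v):
            raise DataError(
                f"internal standard {is_feature!r} is missing in sample "
                f"{table.sample_ids[i]!r}"
            )
        if v == 0:
            raise DataError(
                f"internal standard {is_feature!r} is zero in sample "
                f"{table.sample_ids[i]!r}"
            )
    keep = [k for k in range(table.n_features) if k != j]
    values = table.values[:, keep] / is_col[:, None]
    return FeatureTable(
        values=values,
        sample_ids=list(table.sample_ids),
        feature_ids=[table.feature_ids[k] for k in keep],
        class_labels=table.class_labels.copy(),
        is_qc=table.is_qc.copy(),
    )


def qc_filter(
    table: FeatureTable,
    detection_min: float = 0.5,
    cv_max: float = 30.0,
) -> tuple[FeatureTable, FilterReport]:
    """Remove features poorly detected or poorly reproducible in QC samples.

    A feature is removed if it is observed (non-missing) in fewer than
    ``detection_min`` of the QC samples; among survivors, a feature is removed
    if its QC coefficient of variation (sample sd / mean * 100, observed QC
    values only) exceeds ``cv_max``.
    """
    qc_rows = table.is_qc
    n_qc = int(qc_rows.sum())
    if n_qc == 0:
        raise DataError("qc_filter requires at least one QC sample")
    qc_values = table.values[qc_rows]
    observed = ~np.isnan(qc_values)

    report = FilterReport()
    for j, fid in enumerate(table.feature_ids):
        col = qc_values[observed[:, j], j]
        if col.size >= 2:
            mean = col.mean()
            sd = col.std(ddof=1)
            report.cv_values[fid] = (
                float("nan") if mean == 0 else float(sd / mean * 100.0)
            )

    keep: list[int] = []
    for j, fid in enumerate(table.feature_ids):
        frac = observed[:, j].sum() / n_qc
        if frac < detection_min:
            report.removed_by_detection.append(fid)
            continue
        cv = report.cv_values.get(fid, float("nan"))
        if not np.isnan(cv) and cv > cv_max:
            report.removed_by_cv.append(fid)
            continue
        keep.append(j)

    filtered = FeatureTable(
        values=table.values[:, keep],
        sample_ids=list(table.sample_ids),
        feature_ids=[table.feature_ids[j] for j in keep],
        class_labels=table.class_labels.copy(),
        is_qc=table.is_qc.copy(),
    )
    return filtered, report


def _as_matrix(table_or_values) -> tuple[np.ndarray, list[str]]:
    if isinstance(table_or_values, FeatureTable):
        return table_or_values.values, list(table_or_values.feature_ids)
    x = np.asarray(table_or_values, dtype=float)
    return x, [f"column {j}" for j in range(x.shape[1])]


def autoscale(
    table_or_values,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center each column to mean 0 and scale to unit sample sd.

    Returns ``(scaled, means, sds)`` so that held-out samples can be scaled
    with training parameters via :func:`apply_scaling`.  Missing cells are an
    ordering error (impute first); a zero-variance column is a data error.
    """
    x, names = _as_matrix(table_or_values)
    if np.isnan(x).any():
        raise OrderingError(
            "autoscale requires a complete matrix; impute missing values first"
        )
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    for j, sd in enumerate(sds):
        if sd == 0:
            raise DataError(f"zero-variance feature {names[j]!r} cannot be autoscaled")
    return (x - means) / sds, means, sds


def apply_scaling(
    table_or_values, means: np.ndarray, sds: np.ndarray
) -> np.ndarray:
    """Scale a matrix with previously computed (training) parameters."""
    x, _ = _as_matrix(table_or_values)
    return (x - np.asarray(means)) / np.asarray(sds)
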