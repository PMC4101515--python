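"""Core data containers: the feature table and the masked (ground-truth) dataset.

Missing cells are represented by ``numpy.nan``.  A literal ``0.0`` is a true
zero intensity and is never treated as missing.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

__all__ = ["FeatureTable", "MaskedDataset"]


@dataclass
class FeatureTable:
    """Samples x features intensity matrix with sample/feature metadata.

    Parameters
    ----------
    values
        ``(n_samples, n_features)`` float array; ``nan`` marks a missing cell.
        Observed intensities must be nonnegative.
    sample_ids, feature_ids
        Unique string identifiers for rows and columns.
    class_labels
        One label per sample; empty string allowed only for QC samples.
    is_qc
        Boolean flag per sample marking pooled quality-control injections.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    class_labels: np.ndarray = field(default=None)
    is_qc: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D matrix")
        n_samples, n_features = self.values.shape
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if len(self.sample_ids) != n_samples:
            raise DataError(
                f"{len(self.sample_ids)} sample ids for {n_samples} rows"
            )
        if len(self.feature_ids) != n_features:
            raise DataError(
                f"{len(self.feature_ids)} feature ids for {n_features} columns"
            )
        if len(set(self.sample_ids)) != n_samples:
            raise DataError("duplicate sample ids")
        if len(set(self.feature_ids)) != n_features:
            raise DataError("duplicate feature ids")
        if self.is_qc is None:
            self.is_qc = np.zeros(n_samples, dtype=bool)
        self.is_qc = np.asarray(self.is_qc, dtype=bool)
        if self.is_qc.shape != (n_samples,):
            raise DataError("is_qc length must match sample count")
        if self.class_labels is None:
            self.class_labels = np.array([""] * n_samples, dtype=object)
        self.class_labels = np.asarray(self.class_labels, dtype=object)
        if self.class_labels.shape != (n_samples,):
            raise DataError("class_labels length must match sample count")
        for i, (lab, qc) in enumerate(zip(self.class_labels, self.is_qc)):
            if not qc and (lab is None or str(lab) == ""):
                raise DataError(
                    f"sample {self.sample_ids[i]!r} is not QC but has no class label"
                )
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise DataError("negative intensities are not allowed")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask, ``True`` where a cell is missing."""
        return np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            values=self.values.copy(),
            sample_ids=list(self.sample_ids),
            feature_ids=list(self.feature_ids),
            class_labels=self.class_labels.copy(),
            is_qc=self.is_qc.copy(),
        )

    def with_values(self, values: np.ndarray) -> "FeatureTable":
        """Return a new table sharing this table's metadata."""
        return FeatureTable(
            values=np.asarray(values, dtype=float).copy(),
            sample_ids=list(self.sample_ids),
            feature_ids=list(self.feature_ids),
            class_labels=self.class_labels.copy(),
            is_qc=self.is_qc.copy(),
        )

    def drop_qc(self) -> "FeatureTable":
        """Return the biological (non-QC) samples only."""
        keep = ~self.is_qc
        return FeatureTable(
            values=self.values[keep],
            sample_ids=[s for s, k in zip(self.sample_ids, keep) if k],
            feature_ids=list(self.feature_ids),
            class_labels=self.class_labels[keep],
            is_qc=self.is_qc[keep],
        )

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise DataError(f"unknown feature id {feature_id!r}") from None


@dataclass
class MaskedDataset:
    """A complete table with artificially deleted cells and their true values.

    ``table`` carries ``nan`` at every masked cell; ``true_values`` is the
    complete matrix, so imputation error can be scored exactly.
    """

    table: FeatureTable
    mask: np.ndarray
    true_values: np.ndarray
    mechanism: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.true_values = np.asarray(self.true_values, dtype=float)
        if self.mask.shape != self.table.values.shape:
            raise DataError("mask shape must match table shape")
        if self.true_values.shape != self.table.values.shape:
            raise DataError("true_values shape must match table shape")

    @property
    def masked_fraction(self) -> float:
        return float(self.mask.mean())

    @property
    def true_masked_values(self) -> np.ndarray:
        """True intensities at the masked cells, in mask scan order."""
        return self.true_values[self.mask]
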