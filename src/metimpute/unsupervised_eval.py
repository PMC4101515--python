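"""Cross-validated PCA scree analysis and Ward hierarchical clustering.

``cv_scree`` repeats k-fold cross-validation of a PCA model, recording per
fold the cumulative explained-variance (TEV) curve on the training folds and
the predictive Q^2 (1 - PRESS/TSS) on the held-out fold, and derives the
minimum number of components whose mean TEV reaches a threshold.  ``ward_hca``
plus ``cluster_purity`` score how well a Ward-linkage dendrogram cut at k
recovers the class structure.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .errors import ConfigurationError, DataError, OrderingError
from .table import FeatureTable

__all__ = [
    "ScreeResult",
    "PurityResult",
    "pca",
    "cv_scree",
    "ward_hca",
    "cluster_purity",
]


@dataclass
class ScreeResult:
    """Cross-validated scree curves and derived component counts.

    ``tev_curves`` has shape ``(n_repeats, n_folds, n_components)``;
    ``q2`` has shape ``(n_repeats, n_components)`` (PRESS/TSS pooled over
    folds within a repetition); ``min_components`` is derived per repetition
    from the across-folds mean TEV curve, ``min_components_per_fold`` from
    each fold's own curve.
    """

    tev_curves: np.ndarray
    q2: np.ndarray
    min_components: np.ndarray
    min_components_per_fold: np.ndarray
    threshold: float


@dataclass
class PurityResult:
    """Cluster assignments and class purity for a dendrogram cut."""

    assignments: np.ndarray
    per_cluster_purity: dict[int, float]
    overall_purity: float
    k: int


def _matrix(table_or_values) -> np.ndarray:
    if isinstance(table_or_values, FeatureTable):
        t = table_or_values.drop_qc() if table_or_values.is_qc.any() else table_or_values
        return t.values
    return np.asarray(table_or_values, dtype=float)


def pca(x: np.ndarray, n_components: int):
    """PCA of a centered (autoscaled) matrix via SVD.

    Returns ``(scores, loadings, explained_fractions)`` with orthonormal
    loadings ordered by decreasing variance; fractions are relative to the
    total variance, so they sum to 1 over the full rank.
    """
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    max_comp = min(n - 1, p) if n > 1 else p
    if not 1 <= n_components <= max_comp:
        raise ConfigurationError(
            f"n_components must be in [1, {max_comp}], got {n_components}"
        )
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = float((s * s).sum())
    fractions = (s * s) / total if total > 0 else np.zeros_like(s)
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components].T
    return scores, loadings, fractions[:n_components]


def _scale_train(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    m = x.mean(axis=0)
    s = x.std(axis=0, ddof=1)
    if np.any(s == 0):
        raise DataError("zero-variance feature in a training fold")
    return (x - m) / s, m, s


def cv_scree(
    table_or_values,
    n_folds: int = 10,
    n_repeats: int = 100,
    threshold: float = 0.8,
    seed: int = 0,
) -> ScreeResult:
    """Repeated k-fold cross-validated PCA scree analysis.

    For every repetition the samples are shuffled into ``n_folds`` folds; each
    fold in turn is held out, the remaining folds are autoscaled and a PCA is
    fitted; the cumulative explained-variance curve of the training model and
    the held-out reconstruction Q^2 per component count are recorded.
    """
    if not 0.0 < threshold <= 1.0:
        raise ConfigurationError("threshold must be in (0, 1]")
    if n_folds < 2:
        raise ConfigurationError("n_folds must be >= 2")
    x = _matrix(table_or_values)
    if np.isnan(x).any():
        raise OrderingError("cv_scree requires an imputed (complete) table")
    n, p = x.shape
    if n < n_folds:
        raise ConfigurationError(f"need at least n_folds={n_folds} samples")

    max_fold = -(-n // n_folds)  # ceil
    min_train = n - max_fold
    n_comp = min(min_train, p)
    rng = np.random.default_rng(seed)

    tev = np.zeros((n_repeats, n_folds, n_comp))
    q2 = np.zeros((n_repeats, n_comp))
    min_comp = np.zeros(n_repeats, dtype=int)
    min_comp_fold = np.zeros((n_repeats, n_folds), dtype=int)

    for r in range(n_repeats):
        perm = rng.permutation(n)
        folds = np.array_split(perm, n_folds)
        press = np.zeros(n_comp)
        tss_total = 0.0
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(perm, test_idx, assume_unique=True)
            z_train, m, s = _scale_train(x[train_idx])
            _, sv, vt = np.linalg.svd(z_train, full_matrices=False)
            ev = sv * sv
            total = ev.sum()
            curve = np.cumsum(ev)[:n_comp] / total
            if curve.size < n_comp:  # rank-deficient guard
                curve = np.pad(curve, (0, n_comp - curve.size), constant_values=1.0)
            tev[r, f] = curve
            min_comp_fold[r, f] = int(
                np.argmax(curve >= threshold - 1e-12) + 1
                if (curve >= threshold - 1e-12).any()
                else n_comp
            )
            z_test = (x[test_idx] - m) / s
            proj = z_test @ vt.T[:, :n_comp]
            tss = float((z_test * z_test).sum())
            press += tss - np.cumsum((proj * proj).sum(axis=0))
            tss_total += tss
        q2[r] = 1.0 - press / tss_total
        mean_curve = tev[r].mean(axis=0)
        hits = mean_curve >= threshold - 1e-12
        min_comp[r] = int(np.argmax(hits) + 1) if hits.any() else n_comp

    return ScreeResult(
        tev_curves=tev,
        q2=q2,
        min_components=min_comp,
        min_components_per_fold=min_comp_fold,
        threshold=threshold,
    )


def ward_hca(x) -> np.ndarray:
    """Agglomerative clustering with Ward's minimum-variance criterion on
    Euclidean distances.  Returns the SciPy linkage (merge) matrix."""
    x = _matrix(x)
    if np.isnan(x).any():
        raise OrderingError("ward_hca requires a complete (imputed) matrix")
    if x.shape[0] < 2:
        raise DataError("ward_hca needs at least 2 samples")
    return linkage(x, method="ward")


def cluster_purity(
    dendrogram: np.ndarray, class_labels, k: int | None = None
) -> PurityResult:
    """Cut a dendrogram into k clusters and score class purity.

    Per-cluster purity is the fraction of its samples belonging to its
    majority class; overall purity is the size-weighted mean.
    """
    labels = np.asarray(class_labels, dtype=object)
    n = labels.shape[0]
    if k is None:
        k = len(set(labels))
    if k < 1 or k > n:
        raise ConfigurationError(f"k must be in [1, {n}], got {k}")
    if n != np.asarray(dendrogram).shape[0] + 1:
        raise DataError("label count does not match the dendrogram")
    assignments = fcluster(dendrogram, t=k, criterion="maxclust")
    per_cluster: dict[int, float] = {}
    weighted = 0.0
    for c in np.unique(assignments):
        members = labels[assignments == c]
        _, counts = np.unique(members.astype(str), return_counts=True)
        purity = counts.max() / members.size
        per_cluster[int(c)] = float(purity)
        weighted += purity * members.size
    return PurityResult(
        assignments=assignments,
        per_cluster_purity=per_cluster,
        overall_purity=float(weighted / n),
        k=int(k),
    )
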