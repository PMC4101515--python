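"""The five missing-value substitutes and the NRMSE error metric.

Constant substitutes (zero / per-feature mean / per-feature median), kNN over
feature neighbours with partial Euclidean distances, and an iterative
random-forest scheme (missForest-style).  All imputers leave observed cells
bit-identical and operate on the unscaled intensity matrix; autoscaling
belongs strictly after imputation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .errors import ConfigurationError, DataError
from .table import FeatureTable, MaskedDataset

__all__ = [
    "ImputationConfig",
    "ImputationResult",
    "METHODS",
    "impute",
    "impute_zero",
    "impute_mean",
    "impute_median",
    "impute_knn",
    "impute_rf",
    "knn_neighbour_sets",
    "nrmse",
]

METHODS = ("zero", "mean", "median", "knn", "rf")


@dataclass(frozen=True)
class ImputationConfig:
    """Method selector and hyperparameters for :func:`impute`.

    ``k`` applies to kNN, ``n_trees``/``max_iter`` to the random-forest
    scheme.  ``knn_weighted`` switches neighbour averaging to inverse-distance
    weights (off by default: plain averaging).  ``knn_over='samples'``
    transposes the neighbour search to rows instead of feature columns.
    """

    method: str = "zero"
    k: int = 10
    n_trees: int = 100
    max_iter: int = 10
    seed: int = 0
    knn_weighted: bool = False
    knn_over: str = "features"

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ConfigurationError(
                f"method must be one of {METHODS}, got {self.method!r}"
            )
        if self.k < 1 or self.n_trees < 1:
            raise ConfigurationError("k and n_trees must be positive")
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be positive")
        if self.knn_over not in ("features", "samples"):
            raise ConfigurationError("knn_over must be 'features' or 'samples'")


@dataclass
class ImputationResult:
    """A completed table plus bookkeeping about how it was produced."""

    completed: FeatureTable
    method: str
    n_imputed: int
    convergence: list[float] = field(default_factory=list)
    fallback_count: int = 0


def impute(table: FeatureTable, config: ImputationConfig) -> ImputationResult:
    """Dispatch to the configured imputation method."""
    config.validate()
    if config.method == "zero":
        return impute_zero(table)
    if config.method == "mean":
        return impute_mean(table)
    if config.method == "median":
        return impute_median(table)
    if config.method == "knn":
        return impute_knn(table, config)
    return impute_rf(table, config)


def impute_zero(table: FeatureTable) -> ImputationResult:
    """Replace every missing cell with 0."""
    values = table.values.copy()
    mask = np.isnan(values)
    values[mask] = 0.0
    return ImputationResult(
        completed=table.with_values(values),
        method="zero",
        n_imputed=int(mask.sum()),
    )


def _column_stats(values: np.ndarray, reducer) -> np.ndarray:
    out = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        col = values[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            raise DataError(f"feature column {j} has no observed values")
        out[j] = reducer(obs)
    return out


def _constant_impute(table: FeatureTable, method: str, reducer) -> ImputationResult:
    values = table.values.copy()
    mask = np.isnan(values)
    if mask.any():
        fill = _column_stats(values, reducer)
        rows, cols = np.nonzero(mask)
        values[rows, cols] = fill[cols]
    return ImputationResult(
        completed=table.with_values(values),
        method=method,
        n_imputed=int(mask.sum()),
    )


def impute_mean(table: FeatureTable) -> ImputationResult:
    """Replace missing cells with the observed mean of their feature."""
    return _constant_impute(table, "mean", np.mean)


def impute_median(table: FeatureTable) -> ImputationResult:
    """Replace missing cells with the observed median of their feature."""
    return _constant_impute(table, "median", np.median)


# ---------------------------------------------------------------------------
# kNN over feature neighbours with partial distances
# ---------------------------------------------------------------------------

def _partial_distances(x: np.ndarray, f: int) -> np.ndarray:
    """Root-mean-square distance of column ``f`` to every other column over
    co-observed rows; ``nan`` where no rows are co-observed."""
    p = x.shape[1]
    obs = ~np.isnan(x)
    d = np.full(p, np.nan)
    for g in range(p):
        if g == f:
            continue
        both = obs[:, f] & obs[:, g]
        if not both.any():
            continue
        diff = x[both, f] - x[both, g]
        d[g] = np.sqrt(np.mean(diff * diff))
    return d


def knn_neighbour_sets(values: np.ndarray, k: int) -> dict[int, list[int]]:
    """The k nearest feature columns of every column with a missing cell.

    Distances are partial Euclidean (root mean square over co-observed rows);
    columns with no co-observed rows are excluded.  Ties break on the lower
    column index.  Exposed for oracle cross-checks.
    """
    x = np.asarray(values, dtype=float)
    p = x.shape[1]
    if k >= p:
        raise ConfigurationError(f"k={k} must be smaller than n_features={p}")
    out: dict[int, list[int]] = {}
    miss_cols = np.nonzero(np.isnan(x).any(axis=0))[0]
    for f in miss_cols:
        d = _partial_distances(x, f)
        valid = np.nonzero(~np.isnan(d))[0]
        order = valid[np.lexsort((valid, d[valid]))]
        out[int(f)] = [int(g) for g in order[:k]]
    return out


def impute_knn(table: FeatureTable, config: ImputationConfig) -> ImputationResult:
    """Impute each missing cell from its feature's k nearest feature columns.

    The imputed value is the (by default unweighted) mean of neighbour values
    in the same sample, over neighbours observed there.  If no neighbour is
    observed in that sample the feature's own observed mean is used and
    ``fallback_count`` incremented.
    """
    config.validate()
    x = table.values.copy()
    transposed = config.knn_over == "samples"
    work = x.T.copy() if transposed else x
    p = work.shape[1]
    if config.k >= p:
        raise ConfigurationError(
            f"k={config.k} must be smaller than the number of "
            f"{'samples' if transposed else 'features'} ({p})"
        )
    miss = np.isnan(work)
    for j in range(p):
        if miss[:, j].all():
            raise DataError(f"column {j} has no observed values")

    col_means = _column_stats(work, np.mean)
    neighbours = knn_neighbour_sets(work, config.k)
    filled = work.copy()
    fallback = 0
    for f, nbrs in neighbours.items():
        if nbrs and config.knn_weighted:
            d = _partial_distances(work, f)
        for s in np.nonzero(miss[:, f])[0]:
            avail = [g for g in nbrs if not miss[s, g]]
            if not avail:
                filled[s, f] = col_means[f]
                fallback += 1
            elif config.knn_weighted:
                w = 1.0 / np.maximum(d[avail], 1e-12)
                filled[s, f] = float(np.average(work[s, avail], weights=w))
            else:
                filled[s, f] = float(np.mean(work[s, avail]))

    values = filled.T if transposed else filled
    return ImputationResult(
        completed=table.with_values(values),
        method="knn",
        n_imputed=int(miss.sum()),
        fallback_count=fallback,
    )


# ---------------------------------------------------------------------------
# iterative random-forest imputation (missForest-style)
# ---------------------------------------------------------------------------

def impute_rf(table: FeatureTable, config: ImputationConfig) -> ImputationResult:
    """Iteratively re-impute each feature with a random-forest regression.

    Missing cells start at feature means; features are visited in order of
    increasing missingness; after each full sweep the relative change
    ``delta = sum((X_new - X_old)^2) / sum(X_new^2)`` is recorded and the
    procedure stops when delta increases (returning the pre-increase matrix)
    or when ``max_iter`` sweeps are reached.
    """
    config.validate()
    x = table.values
    n, p = x.shape
    if p < 2:
        raise DataError("random-forest imputation needs at least 2 features")
    miss = np.isnan(x)
    if not miss.any():
        return ImputationResult(
            completed=table.with_values(x),
            method="rf",
            n_imputed=0,
            convergence=[],
        )
    for j in range(p):
        if miss[:, j].all():
            raise DataError(f"feature {table.feature_ids[j]!r} has no observed values")

    current = x.copy()
    fill = _column_stats(x, np.mean)
    rows, cols = np.nonzero(miss)
    current[rows, cols] = fill[cols]

    miss_counts = miss.sum(axis=0)
    visit = [j for j in np.argsort(miss_counts, kind="stable") if miss_counts[j] > 0]

    seed_rng = np.random.default_rng(config.seed)
    tree_seeds = seed_rng.integers(0, 2**31 - 1, size=(config.max_iter, len(visit)))

    deltas: list[float] = []
    previous = current.copy()
    for it in range(config.max_iter):
        new = previous.copy()
        for vi, j in enumerate(visit):
            others = [g for g in range(p) if g != j]
            obs_rows = ~miss[:, j]
            # mtry = sqrt(p) and leaf size 5, the reference RF regression defaults
            rf = RandomForestRegressor(
                n_estimators=config.n_trees,
                max_features="sqrt",
                min_samples_leaf=5,
                random_state=int(tree_seeds[it, vi]),
                n_jobs=1,
            )
            rf.fit(new[obs_rows][:, others], x[obs_rows, j])
            new[miss[:, j], j] = rf.predict(new[miss[:, j]][:, others])
        denom = float((new * new).sum())
        delta = float(((new - previous) ** 2).sum() / denom) if denom else 0.0
        deltas.append(delta)
        if it > 0 and delta > deltas[-2]:
            # criterion fired: keep the matrix from the sweep before the rise
            return ImputationResult(
                completed=table.with_values(previous),
                method="rf",
                n_imputed=int(miss.sum()),
                convergence=deltas,
            )
        previous = new
    return ImputationResult(
        completed=table.with_values(previous),
        method="rf",
        n_imputed=int(miss.sum()),
        convergence=deltas,
    )


# ---------------------------------------------------------------------------
# error metric
# ---------------------------------------------------------------------------

def nrmse(result, truth: MaskedDataset) -> float:
    """Normalized RMSE over the masked cells.

    ``sqrt(mean((imputed - true)^2) / var(true))`` with the population
    variance (``ddof=0``) of the true masked values, so imputing their mean
    everywhere scores exactly 1.
    """
    if isinstance(result, ImputationResult):
        imputed = result.completed.values
    else:
        imputed = np.asarray(result, dtype=float)
    if imputed.shape != truth.true_values.shape:
        raise DataError("imputed matrix and truth have different shapes")
    if not truth.mask.any():
        raise DataError("nrmse is undefined for an empty mask")
    true_vals = truth.true_values[truth.mask]
    var = float(true_vals.var())
    if var == 0:
        raise DataError("nrmse undefined: true masked values have zero variance")
    err = imputed[truth.mask] - true_vals
    return float(np.sqrt(np.mean(err * err) / var))
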