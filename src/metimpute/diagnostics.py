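"""Per-feature/per-class distribution diagnostics and the method-comparison grid.

``group_summary`` reproduces the usual descriptive panel (skewness, excess
kurtosis, mean, median, sd, se, %missing, n observed) computed on observed
values only.  ``compare_methods`` runs every requested imputation method
through the full downstream evaluation (NRMSE, cross-validated scree, Ward
HCA purity, PC-LDA and PLS-DA bootstrap rates) and renders one grid.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError
from .imputation import METHODS, ImputationConfig, impute, nrmse
from .supervised_eval import bootstrap_evaluate
from .table import FeatureTable, MaskedDataset
from .unsupervised_eval import cluster_purity, cv_scree, ward_hca

__all__ = ["EvalConfig", "skewness", "kurtosis", "group_summary", "compare_methods"]


def skewness(values, adjusted: bool = False) -> float:
    """Third standardized moment g1 = m3 / m2^(3/2) (population moments).

    ``adjusted=True`` applies the Fisher-Pearson small-sample correction.
    Requires at least 3 observed values and nonzero variance.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 3:
        raise DataError("skewness needs at least 3 observed values")
    if v.var() == 0:
        raise DataError("skewness undefined for zero variance")
    return float(stats.skew(v, bias=not adjusted))


def kurtosis(values, adjusted: bool = False) -> float:
    """Excess kurtosis (normal -> 0) on population moments by default."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 4:
        raise DataError("kurtosis needs at least 4 observed values")
    if v.var() == 0:
        raise DataError("kurtosis undefined for zero variance")
    return float(stats.kurtosis(v, bias=not adjusted))


def group_summary(table: FeatureTable, adjusted_skew: bool = False) -> pd.DataFrame:
    """Descriptive statistics per (feature, class) over observed values only.

    Returns a DataFrame indexed by (feature, class) with columns
    ``n_observed, pct_missing, mean, median, sd, se, skewness, kurtosis``.
    Cells with too few observed values for a moment get ``NaN`` rather than an
    error.  QC samples are excluded.
    """
    t = table.drop_qc() if table.is_qc.any() else table
    classes = sorted({str(c) for c in t.class_labels})
    if not classes:
        raise DataError("no class labels present")
    rows = []
    for j, fid in enumerate(t.feature_ids):
        for cls in classes:
            sel = np.asarray([str(c) == cls for c in t.class_labels])
            col = t.values[sel, j]
            obs = col[~np.isnan(col)]
            n_obs = obs.size
            rec = {
                "feature": fid,
                "class": cls,
                "n_observed": n_obs,
                "pct_missing": 100.0 * (col.size - n_obs) / col.size,
                "mean": obs.mean() if n_obs else np.nan,
                "median": float(np.median(obs)) if n_obs else np.nan,
                "sd": obs.std(ddof=1) if n_obs >= 2 else np.nan,
            }
            rec["se"] = rec["sd"] / np.sqrt(n_obs) if n_obs >= 2 else np.nan
            if n_obs >= 3 and obs.var() > 0:
                rec["skewness"] = float(stats.skew(obs, bias=not adjusted_skew))
            else:
                rec["skewness"] = np.nan
            if n_obs >= 4 and obs.var() > 0:
                rec["kurtosis"] = float(stats.kurtosis(obs, bias=not adjusted_skew))
            else:
                rec["kurtosis"] = np.nan
            rows.append(rec)
    return pd.DataFrame(rows).set_index(["feature", "class"])


@dataclass(frozen=True)
class EvalConfig:
    """Downstream evaluation settings shared across imputation methods."""

    scree_folds: int = 10
    scree_repeats: int = 20
    scree_threshold: float = 0.8
    max_components: int = 15
    n_boot: int = 100
    knn_k: int = 10
    rf_trees: int = 100
    rf_max_iter: int = 10
    seed: int = 0


def compare_methods(
    dataset: MaskedDataset,
    methods=METHODS,
    config: EvalConfig = EvalConfig(),
) -> pd.DataFrame:
    """Score each imputation method on the full downstream evaluation.

    One row per method: NRMSE against the retained ground truth (NaN if the
    mask is empty), the mean minimum component count from the cross-validated
    scree, Ward-HCA purity at k = number of classes, and the bootstrap
    headline classification rate and selected component count for PC-LDA and
    PLS-DA.  All methods share identical fold/resample seeds so the
    comparison is paired.
    """
    for m in methods:
        if m not in METHODS:
            raise ConfigurationError(f"unknown imputation method {m!r}")
    table = dataset.table
    has_mask = bool(dataset.mask.any())
    rows = []
    for m in methods:
        icfg = ImputationConfig(
            method=m,
            k=config.knn_k,
            n_trees=config.rf_trees,
            max_iter=config.rf_max_iter,
            seed=config.seed,
        )
        result = impute(table, icfg)
        completed = result.completed
        bio = completed.drop_qc() if completed.is_qc.any() else completed
        scree = cv_scree(
            bio,
            n_folds=config.scree_folds,
            n_repeats=config.scree_repeats,
            threshold=config.scree_threshold,
            seed=config.seed + 1,
        )
        from .preprocessing import autoscale

        scaled, _, _ = autoscale(bio.values)
        purity = cluster_purity(ward_hca(scaled), bio.class_labels)
        boot_lda = bootstrap_evaluate(
            bio,
            classifier="pc_lda",
            max_components=config.max_components,
            n_boot=config.n_boot,
            seed=config.seed + 2,
        )
        boot_pls = bootstrap_evaluate(
            bio,
            classifier="pls_da",
            max_components=config.max_components,
            n_boot=config.n_boot,
            seed=config.seed + 2,
        )
        rows.append(
            {
                "method": m,
                "nrmse": nrmse(result, dataset) if has_mask else np.nan,
                "scree_min_components": float(scree.min_components.mean()),
                "hca_purity": purity.overall_purity,
                "pc_lda_rate": boot_lda.headline_rate,
                "pc_lda_components": boot_lda.selected_components,
                "pls_da_rate": boot_pls.headline_rate,
                "pls_da_components": boot_pls.selected_components,
            }
        )
    return pd.DataFrame(rows).set_index("method")
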