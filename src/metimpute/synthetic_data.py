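"""Synthetic multi-class metabolite tables with controlled missingness.

The generator emulates the structure of a GC-MS metabolomics feature table:
log-normal (right-skewed) intensities with feature-specific shape, blocks of
mutually correlated features, multiplicative class effects on a subset of
features, and optional pooled QC samples.  ``apply_missingness`` then deletes
a controlled fraction of cells — completely at random, preferentially at low
intensities (limit-of-detection censoring), or a mixture — while retaining the
ground truth for error scoring.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DataError
from .table import FeatureTable, MaskedDataset

__all__ = [
    "GeneratorConfig",
    "MissingnessSpec",
    "generate_complete",
    "apply_missingness",
]

MECHANISMS = ("MCAR", "LOD", "MIXED")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the complete-table generator.

    Each feature ``j`` draws a log-normal shape ``sigma_j`` uniformly from
    ``[sigma_min, skew_scale]`` (degenerate interval allowed), so larger
    ``skew_scale`` yields stronger positive skew.  ``class_effect`` scales the
    standard deviation of per-(class, feature) log-multipliers applied to a
    ``class_affected_fraction`` subset of features.  The first
    ``n_corr_blocks * block_size`` features share block-level latent factors
    with correlation ``block_rho`` on the log scale.  ``reflect_fraction`` of
    features are reflected about a high quantile to produce negative skews
    (floored at a tiny positive value to keep intensities positive).
    """

    n_per_class: int = 30
    n_classes: int = 3
    n_features: int = 52
    skew_scale: float = 0.9
    sigma_min: float = 0.3
    class_effect: float = 0.75
    class_affected_fraction: float = 0.8
    n_corr_blocks: int = 5
    block_size: int = 10
    block_rho: float = 0.85
    class_effect_individual: float = 0.4
    reflect_fraction: float = 0.0
    n_qc: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_class < 1 or self.n_classes < 1 or self.n_features < 1:
            raise ConfigurationError("all counts must be positive")
        if self.n_corr_blocks < 0 or self.block_size < 1:
            raise ConfigurationError("invalid correlation block shape")
        if self.n_corr_blocks * self.block_size > self.n_features:
            raise ConfigurationError(
                f"{self.n_corr_blocks} blocks of {self.block_size} features "
                f"exceed n_features={self.n_features}"
            )
        if not 0.0 <= self.block_rho < 1.0:
            raise ConfigurationError("block_rho must be in [0, 1)")
        if self.skew_scale < 0 or self.sigma_min < 0:
            raise ConfigurationError("skew parameters must be nonnegative")
        if self.sigma_min > self.skew_scale:
            raise ConfigurationError("sigma_min must not exceed skew_scale")
        if not 0.0 <= self.class_affected_fraction <= 1.0:
            raise ConfigurationError("class_affected_fraction must be in [0, 1]")
        if not 0.0 <= self.reflect_fraction <= 1.0:
            raise ConfigurationError("reflect_fraction must be in [0, 1]")
        if self.class_effect < 0:
            raise ConfigurationError("class_effect must be nonnegative")
        if self.n_qc < 0:
            raise ConfigurationError("n_qc must be nonnegative")


@dataclass(frozen=True)
class MissingnessSpec:
    """How to superimpose missing cells on a complete table.

    ``MCAR`` deletes cells uniformly at random; ``LOD`` deletes preferentially
    at low intensity using per-feature rank weights ``((n - rank)/n)**lod_power``;
    ``MIXED`` produces ``lod_weight`` of the deletions by the LOD mechanism and
    the rest MCAR.  The number of deleted cells is always exactly
    ``round(target_fraction * n_cells)``.
    """

    mechanism: str = "MCAR"
    target_fraction: float = 0.15
    lod_weight: float = 0.5
    lod_power: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ConfigurationError(
                f"mechanism must be one of {MECHANISMS}, got {self.mechanism!r}"
            )
        if not 0.0 <= self.target_fraction < 1.0:
            raise ConfigurationError("target_fraction must be in [0, 1)")
        if not 0.0 <= self.lod_weight <= 1.0:
            raise ConfigurationError("lod_weight must be in [0, 1]")
        if self.lod_power <= 0:
            raise ConfigurationError("lod_power must be positive")


def generate_complete(config: GeneratorConfig) -> FeatureTable:
    """Generate a complete (no missing cells) multi-class intensity table.

    Deterministic for a fixed config: identical config + seed gives
    bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_bio = config.n_per_class * config.n_classes
    p = config.n_features

    sigma = rng.uniform(config.sigma_min, config.skew_scale, size=p)
    mu = rng.uniform(2.0, 6.0, size=p)

    # members of a correlated block share a base scale and shape (with mild
    # jitter), as related metabolites do; this keeps neighbour averaging on a
    # common intensity scale
    for b in range(config.n_corr_blocks):
        cols = slice(b * config.block_size, (b + 1) * config.block_size)
        k = config.block_size
        mu[cols] = rng.uniform(2.0, 6.0) + rng.uniform(-0.45, 0.45, size=k)
        sigma[cols] = np.clip(
            rng.uniform(config.sigma_min, config.skew_scale)
            * rng.uniform(0.97, 1.03, size=k),
            config.sigma_min,
            max(config.skew_scale, config.sigma_min),
        )

    # latent standard normals with block correlation on the log scale
    z = rng.standard_normal((n_bio, p))
    rho = config.block_rho
    for b in range(config.n_corr_blocks):
        cols = slice(b * config.block_size, (b + 1) * config.block_size)
        shared = rng.standard_normal((n_bio, 1))
        z[:, cols] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * z[:, cols]

    # multiplicative class effects; members of a correlated block respond
    # together (block-level regulation), unblocked features independently
    n_blocked = config.n_corr_blocks * config.block_size
    log_effect = np.zeros((config.n_classes, p))
    block_effects = config.class_effect * rng.standard_normal(
        (config.n_classes, max(config.n_corr_blocks, 1))
    )
    block_affected = (
        rng.random(config.n_corr_blocks) < config.class_affected_fraction
    )
    for b in range(config.n_corr_blocks):
        if block_affected[b]:
            cols = slice(b * config.block_size, (b + 1) * config.block_size)
            shared = block_effects[:, b][:, None]
            individual = (
                config.class_effect
                * config.class_effect_individual
                * rng.standard_normal((config.n_classes, config.block_size))
            )
            log_effect[:, cols] = shared + individual
    free = np.arange(n_blocked, p)
    free_affected = free[rng.random(free.size) < config.class_affected_fraction]
    log_effect[:, free_affected] = config.class_effect * rng.standard_normal(
        (config.n_classes, free_affected.size)
    )

    class_idx = np.repeat(np.arange(config.n_classes), config.n_per_class)
    log_x = mu[None, :] + sigma[None, :] * z + log_effect[class_idx]
    x = np.exp(log_x)

    # optional reflection to create negatively skewed features
    n_reflect = int(round(config.reflect_fraction * p))
    if n_reflect:
        reflect = rng.permutation(p)[:n_reflect]
        for j in reflect:
            pivot = np.quantile(x[:, j], 0.995)
            floor = 1e-6 * max(pivot, 1.0)
            x[:, j] = np.maximum(floor, pivot + floor - x[:, j])

    values = x
    sample_ids = [f"S{i + 1:04d}" for i in range(n_bio)]
    class_labels = np.array(
        [f"class{c + 1}" for c in class_idx], dtype=object
    )
    is_qc = np.zeros(n_bio, dtype=bool)

    if config.n_qc:
        # pooled QC: per-feature median of the biological samples with mild
        # multiplicative injection noise
        pooled = np.median(x, axis=0)
        noise = np.exp(0.05 * rng.standard_normal((config.n_qc, p)))
        qc_values = pooled[None, :] * noise
        values = np.vstack([values, qc_values])
        sample_ids += [f"QC{i + 1:03d}" for i in range(config.n_qc)]
        class_labels = np.concatenate(
            [class_labels, np.array([""] * config.n_qc, dtype=object)]
        )
        is_qc = np.concatenate([is_qc, np.ones(config.n_qc, dtype=bool)])

    feature_ids = [f"met{j + 1:03d}" for j in range(p)]
    return FeatureTable(
        values=values,
        sample_ids=sample_ids,
        feature_ids=feature_ids,
        class_labels=class_labels,
        is_qc=is_qc,
    )


def _lod_weights(values: np.ndarray, power: float) -> np.ndarray:
    """Per-cell masking weight decreasing in within-feature intensity rank."""
    n, p = values.shape
    w = np.empty_like(values)
    for j in range(p):
        order = np.argsort(values[:, j], kind="stable")
        ranks = np.empty(n, dtype=float)
        ranks[order] = np.arange(n, dtype=float)
        w[:, j] = ((n - ranks) / n) ** power
    return w


def apply_missingness(table: FeatureTable, spec: MissingnessSpec) -> MaskedDataset:
    """Delete cells from a complete table, retaining the ground truth.

    Exactly ``round(target_fraction * n_cells)`` cells are masked, sampled
    without replacement with mechanism-specific weights.
    """
    spec.validate()
    if table.n_missing:
        raise DataError(
            f"table already contains {table.n_missing} missing cells; "
            "apply_missingness requires a complete table"
        )
    rng = np.random.default_rng(spec.seed)
    n, p = table.values.shape
    n_cells = n * p
    n_mask = int(round(spec.target_fraction * n_cells))

    flat_mask = np.zeros(n_cells, dtype=bool)
    if n_mask:
        if spec.mechanism == "MCAR":
            chosen = rng.choice(n_cells, size=n_mask, replace=False)
        elif spec.mechanism == "LOD":
            w = _lod_weights(table.values, spec.lod_power).ravel()
            chosen = rng.choice(n_cells, size=n_mask, replace=False, p=w / w.sum())
        else:  # MIXED
            n_lod = int(round(spec.lod_weight * n_mask))
            w = _lod_weights(table.values, spec.lod_power).ravel()
            chosen_lod = (
                rng.choice(n_cells, size=n_lod, replace=False, p=w / w.sum())
                if n_lod
                else np.empty(0, dtype=int)
            )
            remaining = np.setdiff1d(np.arange(n_cells), chosen_lod)
            chosen_mcar = rng.choice(
                remaining, size=n_mask - n_lod, replace=False
            )
            chosen = np.concatenate([chosen_lod, chosen_mcar])
        flat_mask[chosen] = True

    mask = flat_mask.reshape(n, p)
    masked = table.copy()
    masked.values[mask] = np.nan
    return MaskedDataset(
        table=masked,
        mask=mask,
        true_values=table.values.copy(),
        mechanism=spec.mechanism,
    )
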