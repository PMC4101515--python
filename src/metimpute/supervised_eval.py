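"""PC-LDA and PLS-DA classifiers with bootstrap out-of-bag validation.

Both classifiers autoscale with training parameters first.  PC-LDA projects
onto training PCA loadings and applies multi-class Fisher LDA with a pooled
within-class covariance; PLS-DA regresses a one-hot dummy response on the
scaled matrix with a classical NIPALS PLS2 (X and Y deflation) and classifies
by the largest predicted dummy entry.  ``bootstrap_evaluate`` draws resamples
with replacement, scores out-of-bag accuracy per component count, and selects
the first local maximum of the mean accuracy curve.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError
from .table import FeatureTable

__all__ = [
    "LdaFeasibility",
    "DummyCode",
    "BootstrapResult",
    "lda_feasible",
    "make_dummy",
    "pc_lda_train_predict",
    "pls_da_train_predict",
    "bootstrap_evaluate",
    "bootstrap_composition",
    "first_local_maximum",
]


@dataclass(frozen=True)
class LdaFeasibility:
    """Sample/group/feature counts for the direct-LDA feasibility rule."""

    n_samples: int
    n_groups: int
    n_features: int


def lda_feasible(f: LdaFeasibility) -> bool:
    """Whether plain LDA is admissible: (N_s - N_g - 1) > N_v."""
    if min(f.n_samples, f.n_groups, f.n_features) < 1:
        raise ConfigurationError("all counts must be positive")
    return (f.n_samples - f.n_groups - 1) > f.n_features


@dataclass
class DummyCode:
    """One-hot class coding with a fixed class order."""

    class_order: list[str]
    matrix: np.ndarray


def make_dummy(labels, class_order: list[str] | None = None) -> DummyCode:
    """One indicator column per class; classes ordered lexicographically
    unless an explicit order is given."""
    labels = np.asarray([str(x) for x in labels], dtype=object)
    if class_order is None:
        class_order = sorted(set(labels))
    index = {c: i for i, c in enumerate(class_order)}
    y = np.zeros((labels.shape[0], len(class_order)))
    for i, lab in enumerate(labels):
        if lab not in index:
            raise DataError(f"label {lab!r} not in class order {class_order}")
        y[i, index[lab]] = 1.0
    return DummyCode(class_order=list(class_order), matrix=y)


# ---------------------------------------------------------------------------
# internals shared by the public train/predict wrappers and the bootstrap
# ---------------------------------------------------------------------------

def _safe_scale(train: np.ndarray, test: np.ndarray):
    """Autoscale by training parameters; zero-variance training columns get
    unit sd (they carry no information in that resample)."""
    m = train.mean(axis=0)
    s = train.std(axis=0, ddof=1)
    s = np.where(s == 0, 1.0, s)
    return (train - m) / s, (test - m) / s


def _fit_lda(scores: np.ndarray, y_idx: np.ndarray, n_classes: int):
    """Pooled-covariance Gaussian LDA; returns per-class discriminant
    parameters (A, b) so that the discriminant values are scores @ A + b."""
    n, d = scores.shape
    means = np.vstack([scores[y_idx == c].mean(axis=0) for c in range(n_classes)])
    pooled = np.zeros((d, d))
    for c in range(n_classes):
        centered = scores[y_idx == c] - means[c]
        pooled += centered.T @ centered
    pooled /= max(n - n_classes, 1)
    pooled = pooled + 1e-8 * max(np.trace(pooled), 1e-300) * np.eye(d)
    inv = np.linalg.inv(pooled)
    priors = np.array([(y_idx == c).mean() for c in range(n_classes)])
    a = inv @ means.T                                     # (d, n_classes)
    b = -0.5 * np.einsum("cd,dc->c", means, a) + np.log(priors)
    return a, b


def _pc_lda_curve(
    z_train: np.ndarray,
    y_idx: np.ndarray,
    z_test: np.ndarray,
    comps: list[int],
    n_classes: int,
):
    """OOB predictions of PC-LDA for each component count in ``comps``."""
    _, sv, vt = np.linalg.svd(z_train, full_matrices=False)
    rank = int((sv > sv[0] * 1e-10).sum()) if sv.size else 0
    t_train = z_train @ vt.T
    t_test = z_test @ vt.T
    preds = {}
    for c in comps:
        c_eff = min(c, rank)
        a, b = _fit_lda(t_train[:, :c_eff], y_idx, n_classes)
        disc = t_test[:, :c_eff] @ a + b
        preds[c] = np.argmax(disc, axis=1)
    return preds


def _pls2_fit(
    z: np.ndarray,
    y: np.ndarray,
    n_components: int,
    tol: float = 1e-10,
    max_inner: int = 500,
):
    """Classical NIPALS PLS2 with X- and Y-deflation.

    Returns weights W, X-loadings P and Y-loadings Q (columns per component).
    """
    x = z.copy()
    yy = y.copy()
    n, p = x.shape
    w_list, p_list, q_list = [], [], []
    for _ in range(n_components):
        u = yy[:, int(np.argmax(yy.var(axis=0)))].copy()
        if not np.any(u):
            u = yy[:, 0] + 1e-12
        t_old = None
        for _ in range(max_inner):
            w = x.T @ u
            norm = np.linalg.norm(w)
            if norm == 0:
                w = np.zeros(p)
                break
            w /= norm
            t = x @ w
            tt = float(t @ t)
            if tt == 0:
                break
            q = yy.T @ t / tt
            qn = float(q @ q)
            u = yy @ q / qn if qn else t
            if t_old is not None and np.linalg.norm(t - t_old) < tol:
                break
            t_old = t
        t = x @ w
        tt = float(t @ t)
        if tt == 0:
            break
        p_load = x.T @ t / tt
        q_load = yy.T @ t / tt
        x = x - np.outer(t, p_load)
        yy = yy - np.outer(t, q_load)
        w_list.append(w)
        p_list.append(p_load)
        q_list.append(q_load)
    return (
        np.column_stack(w_list) if w_list else np.zeros((p, 0)),
        np.column_stack(p_list) if p_list else np.zeros((p, 0)),
        np.column_stack(q_list) if q_list else np.zeros((y.shape[1], 0)),
    )


def _pls_predict_curve(
    w: np.ndarray,
    p_load: np.ndarray,
    q_load: np.ndarray,
    z_test: np.ndarray,
    y_mean: np.ndarray,
    comps: list[int],
):
    """Predicted dummy matrices for each requested component count."""
    x = z_test.copy()
    yhat = np.tile(y_mean, (z_test.shape[0], 1))
    fitted = w.shape[1]
    out = {}
    want = sorted(set(comps))
    pos = 0
    for a in range(1, max(want) + 1 if want else 1):
        if a <= fitted:
            t = x @ w[:, a - 1]
            x = x - np.outer(t, p_load[:, a - 1])
            yhat = yhat + np.outer(t, q_load[:, a - 1])
        while pos < len(want) and want[pos] == a:
            out[a] = yhat.copy()
            pos += 1
    for a in want:
        out.setdefault(a, yhat.copy())
    return out


def _as_xy(table_or_values, labels=None):
    if isinstance(table_or_values, FeatureTable):
        t = table_or_values.drop_qc() if table_or_values.is_qc.any() else table_or_values
        if np.isnan(t.values).any():
            raise DataError("classification requires an imputed (complete) table")
        return t.values, np.asarray(t.class_labels, dtype=object)
    x = np.asarray(table_or_values, dtype=float)
    if labels is None:
        raise DataError("labels are required with a plain matrix")
    return x, np.asarray([str(v) for v in labels], dtype=object)


def pc_lda_train_predict(
    train, train_labels, test, n_pcs: int
):
    """Train PC-LDA (autoscale -> PCA -> pooled-covariance LDA) and predict.

    Returns predicted labels and the per-class discriminant score matrix for
    the test samples.
    """
    x_train, y_lab = _as_xy(train, train_labels)
    x_test = np.asarray(
        test.values if isinstance(test, FeatureTable) else test, dtype=float
    )
    dummy = make_dummy(y_lab)
    n_classes = len(dummy.class_order)
    if n_classes < 2:
        raise ConfigurationError("need at least 2 training classes")
    y_idx = np.argmax(dummy.matrix, axis=1)
    if n_pcs < 1 or n_pcs > min(x_train.shape[0] - 1, x_train.shape[1]):
        raise ConfigurationError(f"n_pcs={n_pcs} out of range for training data")
    z_train, z_test = _safe_scale(x_train, x_test)
    _, sv, vt = np.linalg.svd(z_train, full_matrices=False)
    t_train = z_train @ vt.T[:, :n_pcs]
    t_test = z_test @ vt.T[:, :n_pcs]
    a, b = _fit_lda(t_train, y_idx, n_classes)
    disc = t_test @ a + b
    pred = np.array([dummy.class_order[i] for i in np.argmax(disc, axis=1)], dtype=object)
    return pred, disc


def pls_da_train_predict(
    train, train_labels, test, n_components: int
):
    """Train PLS-DA (autoscale -> NIPALS PLS2 on dummy Y) and predict.

    Returns predicted labels and the predicted dummy matrix; argmax ties
    resolve to the earliest class in the class order.
    """
    x_train, y_lab = _as_xy(train, train_labels)
    x_test = np.asarray(
        test.values if isinstance(test, FeatureTable) else test, dtype=float
    )
    dummy = make_dummy(y_lab)
    if len(dummy.class_order) < 2:
        raise ConfigurationError("PLS-DA needs at least 2 classes")
    if n_components < 1 or n_components > min(x_train.shape[0] - 1, x_train.shape[1]):
        raise ConfigurationError(f"n_components={n_components} out of range")
    z_train, z_test = _safe_scale(x_train, x_test)
    y_mean = dummy.matrix.mean(axis=0)
    w, p_load, q_load = _pls2_fit(z_train, dummy.matrix - y_mean, n_components)
    yhat = _pls_predict_curve(w, p_load, q_load, z_test, y_mean, [n_components])[
        n_components
    ]
    pred = np.array([dummy.class_order[i] for i in np.argmax(yhat, axis=1)], dtype=object)
    return pred, yhat


def first_local_maximum(curve: np.ndarray) -> int:
    """1-based index of the first local maximum of an accuracy curve.

    Interior points must strictly exceed both neighbours; endpoints count only
    if strictly above their single neighbour.  When no strict local maximum
    exists (flat stretches, saturated plateaus) the smallest component count
    attaining the curve maximum is selected, which reduces to 1 for a
    constant curve.
    """
    c = np.asarray(curve, dtype=float)
    m = c.size
    if m == 1:
        return 1
    for i in range(m):
        if i == 0:
            if c[0] > c[1]:
                return 1
        elif i == m - 1:
            if c[-1] > c[-2]:
                return m
        elif c[i] > c[i - 1] and c[i] > c[i + 1]:
            return i + 1
    return int(np.argmax(c)) + 1


@dataclass
class BootstrapResult:
    """Out-of-bag accuracy by component count across bootstrap resamples."""

    accuracy: np.ndarray            # (n_boot, max_components), fractions
    mean_curve: np.ndarray          # percent per component count
    selected_components: int
    headline_rate: float            # percent at selected_components
    oob_fraction: float
    train_distinct_fraction: np.ndarray = field(default=None)
    redraw_count: int = 0
    classifier: str = ""


def bootstrap_composition(n: int, n_boot: int = 100, seed: int = 0):
    """Distinct-sample and out-of-bag fractions of plain bootstrap resamples.

    Uses the same resampling primitive as :func:`bootstrap_evaluate`; returns
    ``(distinct_fractions, oob_fractions)`` arrays of length ``n_boot``.
    """
    if n < 1 or n_boot < 1:
        raise ConfigurationError("n and n_boot must be positive")
    rng = np.random.default_rng(seed)
    distinct = np.empty(n_boot)
    oob = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        n_distinct = np.unique(idx).size
        distinct[b] = n_distinct / n
        oob[b] = 1.0 - n_distinct / n
    return distinct, oob


def bootstrap_evaluate(
    table_or_values,
    labels=None,
    classifier: str = "pc_lda",
    max_components: int = 15,
    n_boot: int = 100,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap out-of-bag validation of PC-LDA or PLS-DA.

    Each resample draws n samples with replacement as the training set and
    uses the out-of-bag samples as the test set; accuracy is scored for every
    component count from 1 to ``max_components``.  Resamples whose training
    set misses a class (or whose OOB set is empty) are redrawn and counted in
    ``redraw_count``.
    """
    if classifier not in ("pc_lda", "pls_da"):
        raise ConfigurationError(f"unknown classifier {classifier!r}")
    if n_boot < 1:
        raise ConfigurationError("n_boot must be >= 1")
    if max_components < 1:
        raise ConfigurationError("max_components must be >= 1")
    x, y_lab = _as_xy(table_or_values, labels)
    n = x.shape[0]
    dummy = make_dummy(y_lab)
    class_order = dummy.class_order
    n_classes = len(class_order)
    if n_classes < 2:
        raise ConfigurationError("need at least 2 classes")
    counts = dummy.matrix.sum(axis=0)
    if counts.min() < 3:
        raise DataError("every class needs at least 3 samples")
    y_idx = np.argmax(dummy.matrix, axis=1)
    max_components = min(max_components, x.shape[1])
    comps = list(range(1, max_components + 1))

    rng = np.random.default_rng(seed)
    accuracy = np.zeros((n_boot, max_components))
    distinct = np.zeros(n_boot)
    redraws = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            in_bag = np.zeros(n, dtype=bool)
            in_bag[idx] = True
            oob = np.nonzero(~in_bag)[0]
            if oob.size and np.unique(y_idx[idx]).size == n_classes:
                break
            redraws += 1
        distinct[b] = np.unique(idx).size / n
        z_train, z_test = _safe_scale(x[idx], x[oob])
        y_train = y_idx[idx]
        y_test = y_idx[oob]
        if classifier == "pc_lda":
            preds = _pc_lda_curve(z_train, y_train, z_test, comps, n_classes)
        else:
            y_mean = dummy.matrix[idx].mean(axis=0)
            w, p_load, q_load = _pls2_fit(
                z_train, dummy.matrix[idx] - y_mean, max_components
            )
            yhats = _pls_predict_curve(w, p_load, q_load, z_test, y_mean, comps)
            preds = {c: np.argmax(yhats[c], axis=1) for c in comps}
        for ci, c in enumerate(comps):
            accuracy[b, ci] = float(np.mean(preds[c] == y_test))

    mean_curve = accuracy.mean(axis=0) * 100.0
    selected = first_local_maximum(mean_curve)
    return BootstrapResult(
        accuracy=accuracy,
        mean_curve=mean_curve,
        selected_components=selected,
        headline_rate=float(mean_curve[selected - 1]),
        oob_fraction=float(1.0 - distinct.mean()),
        train_distinct_fraction=distinct,
        redraw_count=redraws,
        classifier=classifier,
    )
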