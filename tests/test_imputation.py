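import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metimpute.errors import ConfigurationError, DataError
from metimpute.imputation import (
    ImputationConfig,
    impute,
    impute_knn,
    impute_mean,
    impute_median,
    impute_rf,
    impute_zero,
    knn_neighbour_sets,
    nrmse,
)
from metimpute.synthetic_data import (
    GeneratorConfig,
    MissingnessSpec,
    apply_missingness,
    generate_complete,
)
from metimpute.table import MaskedDataset

from .conftest import make_table


def col(values):
    return make_table(np.asarray(values, dtype=float).reshape(-1, 1))


class TestConstantImputers:
    def test_zero_fills_zero(self):
        res = impute_zero(col([1.0, np.nan, 3.0]))
        np.testing.assert_array_equal(res.completed.values.ravel(), [1.0, 0.0, 3.0])
        assert res.n_imputed == 1

    def test_zero_all_missing_column(self):
        res = impute_zero(col([np.nan, np.nan]))
        np.testing.assert_array_equal(res.completed.values.ravel(), [0.0, 0.0])

    def test_mean_fill(self):
        res = impute_mean(col([2.0, 4.0, np.nan, 6.0]))
        assert res.completed.values[2, 0] == 4.0

    def test_mean_skewed(self):
        res = impute_mean(col([1.0, 2.0, np.nan, 9.0]))
        assert res.completed.values[2, 0] == 4.0

    def test_median_robust_to_skew(self):
        res = impute_median(col([1.0, 2.0, np.nan, 9.0]))
        assert res.completed.values[2, 0] == 2.0

    def test_median_odd_count(self):
        res = impute_median(col([1.0, 3.0, np.nan, 7.0, 9.0, 5.0]))
        assert res.completed.values[2, 0] == 5.0

    def test_symmetric_mean_equals_median(self):
        values = [1.0, 2.0, 3.0, 4.0, 5.0, np.nan]
        assert (
            impute_mean(col(values)).completed.values[5, 0]
            == impute_median(col(values)).completed.values[5, 0]
        )

    def test_no_missing_unchanged(self, tiny_table):
        full = impute_zero(tiny_table).completed
        for fn in (impute_zero, impute_mean, impute_median):
            res = fn(full)
            np.testing.assert_array_equal(res.completed.values, full.values)
            assert res.n_imputed == 0

    def test_all_missing_feature_error(self):
        t = make_table([[np.nan, 1.0], [np.nan, 2.0]])
        with pytest.raises(DataError):
            impute_mean(t)


def brute_force_neighbours(x, k):
    """Independent oracle: exhaustive partial-distance computation."""
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    out = {}
    for f in range(p):
        if not np.isnan(x[:, f]).any():
            continue
        cands = []
        for g in range(p):
            if g == f:
                continue
            pairs = [
                (x[i, f] - x[i, g]) ** 2
                for i in range(n)
                if not np.isnan(x[i, f]) and not np.isnan(x[i, g])
            ]
            if pairs:
                cands.append((np.sqrt(sum(pairs) / len(pairs)), g))
        cands.sort()
        out[f] = [g for _, g in cands[:k]]
    return out


@st.composite
def small_missing_tables(draw):
    n = draw(st.integers(min_value=3, max_value=8))
    p = draw(st.integers(min_value=2, max_value=6))
    seed = draw(st.integers(min_value=0, max_value=2**31 - 1))
    rng = np.random.default_rng(seed)
    x = np.round(rng.lognormal(1.0, 1.0, size=(n, p)), 3)
    holes = rng.random((n, p)) < 0.25
    # keep at least one observed value per column
    for j in range(p):
        if holes[:, j].all():
            holes[rng.integers(n), j] = False
    x[holes] = np.nan
    k = draw(st.integers(min_value=1, max_value=p - 1))
    return x, k


class TestKnn:
    def test_toy_example(self):
        # f2's nearest neighbour is f1 (distance 0 on co-observed rows)
        x = np.array([[1.0, 1.0, 10.0], [2.0, 2.0, 20.0], [3.0, np.nan, 30.0]])
        t = make_table(x)
        res = impute_knn(t, ImputationConfig(method="knn", k=1))
        assert res.completed.values[2, 1] == 3.0
        assert res.fallback_count == 0
        assert brute_force_neighbours(x, 1)[1] == [0]

    def test_no_missing_noop(self, rng):
        t = make_table(rng.lognormal(size=(10, 5)))
        res = impute_knn(t, ImputationConfig(method="knn", k=2))
        np.testing.assert_array_equal(res.completed.values, t.values)
        assert res.fallback_count == 0

    def test_fallback_to_column_mean(self):
        # neighbour of f0 is missing at row 2 -> fall back to f0's observed mean
        x = np.array([[1.0, 1.0], [5.0, 5.0], [np.nan, np.nan]])
        # f1 all-observed variant: make f1 missing at row 2 only for f0's hole
        x = np.array([[1.0, 1.0], [5.0, 5.0], [np.nan, np.nan]])
        t = make_table(x)
        res = impute_knn(t, ImputationConfig(method="knn", k=1))
        assert res.fallback_count >= 1
        assert res.completed.values[2, 0] == pytest.approx(3.0)

    def test_k_too_large(self, tiny_table):
        with pytest.raises(ConfigurationError):
            impute_knn(tiny_table, ImputationConfig(method="knn", k=3))

    @settings(max_examples=200, deadline=None)
    @given(small_missing_tables())
    def test_neighbour_sets_match_oracle(self, case):
        x, k = case
        assert knn_neighbour_sets(x, k) == brute_force_neighbours(x, k)

    def test_samples_orientation(self, rng):
        x = rng.lognormal(size=(12, 5))
        x[3, 2] = np.nan
        t = make_table(x)
        res = impute_knn(
            t, ImputationConfig(method="knn", k=3, knn_over="samples")
        )
        assert not np.isnan(res.completed.values).any()


class TestRf:
    def test_no_missing_noop(self, rng):
        t = make_table(rng.lognormal(size=(15, 4)))
        res = impute_rf(t, ImputationConfig(method="rf", n_trees=10))
        np.testing.assert_array_equal(res.completed.values, t.values)
        assert res.convergence == []

    def test_beats_mean_on_linear_structure(self, rng):
        # one feature is an exact linear function of another
        base = rng.lognormal(1.0, 0.8, size=(200, 5))
        x = np.column_stack([base, 2.0 * base[:, 0] + 1.0])
        mask = rng.random(x.shape) < 0.10
        for j in range(x.shape[1]):
            if mask[:, j].all():
                mask[0, j] = False
        truth = x.copy()
        x = x.copy()
        x[mask] = np.nan
        t = make_table(x)
        ds = MaskedDataset(table=t, mask=mask, true_values=truth, mechanism="MCAR")
        err_rf = nrmse(impute_rf(t, ImputationConfig(method="rf", n_trees=50, seed=0)), ds)
        err_mean = nrmse(impute_mean(t), ds)
        assert err_rf < err_mean

    def test_convergence_recorded_and_matrix_pre_increase(self, rng):
        base = rng.lognormal(1.0, 0.8, size=(80, 6))
        mask = rng.random(base.shape) < 0.15
        x = base.copy()
        x[mask] = np.nan
        t = make_table(x)
        res = impute_rf(t, ImputationConfig(method="rf", n_trees=20, seed=1))
        assert len(res.convergence) >= 1
        deltas = res.convergence
        if len(deltas) > 1 and deltas[-1] > deltas[-2]:
            # monotone decrease until the final increase -> returned matrix is
            # the one from the minimal-delta sweep
            assert all(a >= b for a, b in zip(deltas[:-2], deltas[1:-1]))

    def test_deterministic(self, rng):
        x = rng.lognormal(size=(40, 5))
        x[rng.random(x.shape) < 0.1] = np.nan
        t = make_table(x)
        cfg = ImputationConfig(method="rf", n_trees=15, seed=7)
        a = impute_rf(t, cfg)
        b = impute_rf(t, cfg)
        np.testing.assert_array_equal(a.completed.values, b.completed.values)
        assert a.convergence == b.convergence

    def test_feature_order_insensitive(self, rng):
        x = rng.lognormal(1.0, 0.5, size=(60, 5))
        mask = rng.random(x.shape) < 0.1
        truth = x.copy()
        x[mask] = np.nan
        perm = rng.permutation(5)
        t = make_table(x)
        tp = make_table(x[:, perm])
        ds = MaskedDataset(table=t, mask=mask, true_values=truth, mechanism="MCAR")
        dsp = MaskedDataset(
            table=tp, mask=mask[:, perm], true_values=truth[:, perm], mechanism="MCAR"
        )
        cfg = ImputationConfig(method="rf", n_trees=30, seed=2)
        e1 = nrmse(impute_rf(t, cfg), ds)
        e2 = nrmse(impute_rf(tp, cfg), dsp)
        # RF randomness differs under permutation; accuracy must be comparable
        assert e2 == pytest.approx(e1, abs=0.15)


class TestObservedPassThrough:
    @pytest.mark.parametrize("method", ["zero", "mean", "median", "knn", "rf"])
    def test_observed_cells_bit_identical(self, method, rng):
        x = rng.lognormal(1.0, 1.0, size=(30, 6))
        holes = rng.random(x.shape) < 0.2
        for j in range(6):
            if holes[:, j].all():
                holes[0, j] = False
        x[holes] = np.nan
        t = make_table(x)
        cfg = ImputationConfig(method=method, k=3, n_trees=10, seed=0)
        res = impute(t, cfg)
        obs = ~holes
        np.testing.assert_array_equal(res.completed.values[obs], x[obs])
        assert not np.isnan(res.completed.values).any()
        assert res.n_imputed == holes.sum()


class TestNrmse:
    @pytest.fixture
    def masked(self, rng):
        table = generate_complete(
            GeneratorConfig(n_per_class=20, n_features=10, n_corr_blocks=2, block_size=4, seed=4)
        )
        return apply_missingness(table, MissingnessSpec(target_fraction=0.2, seed=5))

    def test_perfect_imputation_zero(self, masked):
        assert nrmse(masked.true_values, masked) == 0.0

    def test_constant_true_mean_exactly_one(self, masked):
        imputed = masked.true_values.copy()
        imputed[masked.mask] = masked.true_masked_values.mean()
        assert nrmse(imputed, masked) == pytest.approx(1.0, abs=1e-12)

    def test_nonnegative(self, masked, rng):
        imputed = masked.true_values.copy()
        imputed[masked.mask] = rng.lognormal(size=masked.mask.sum())
        assert nrmse(imputed, masked) >= 0.0

    def test_empty_mask_error(self, masked):
        empty = MaskedDataset(
            table=masked.table,
            mask=np.zeros_like(masked.mask),
            true_values=masked.true_values,
            mechanism="MCAR",
        )
        with pytest.raises(DataError):
            nrmse(masked.true_values, empty)

    def test_zero_variance_error(self):
        t = make_table([[np.nan, 1.0], [np.nan, 2.0]])
        ds = MaskedDataset(
            table=t,
            mask=np.array([[True, False], [True, False]]),
            true_values=np.array([[3.0, 1.0], [3.0, 2.0]]),
            mechanism="MCAR",
        )
        with pytest.raises(DataError):
            nrmse(np.ones((2, 2)), ds)
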