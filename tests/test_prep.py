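"""Preparation pipeline: splitting, imputation, LOF, SMOTE, scaling, leakage."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.neighbors import LocalOutlierFactor

from ckdso import dataio, prep, synth


def _matrix(X, y, kinds=None):
    X = np.asarray(X, dtype=float)
    return dataio.DataMatrix(
        feature_names=[f"f{j}" for j in range(X.shape[1])],
        X=X,
        y=np.asarray(y, dtype=int),
        column_kinds=kinds or ["numeric"] * X.shape[1],
    )


# ------------------------------------------------------------------ split

def test_split_sizes_and_stratification():
    rng = np.random.default_rng(0)
    data = _matrix(rng.normal(size=(100, 3)), [0] * 60 + [1] * 40)
    train, test = prep.split_train_test(data, 0.8, seed=1)
    assert train.n_samples == 80 and test.n_samples == 20
    assert train.class_counts() == (48, 32)
    assert test.class_counts() == (12, 8)


def test_split_small_stratified():
    data = _matrix(np.arange(20).reshape(10, 2), [0] * 6 + [1] * 4)
    train, test = prep.split_train_test(data, 0.5, seed=0)
    assert train.class_counts() == (3, 2)
    assert test.class_counts() == (3, 2)


def test_split_deterministic():
    rng = np.random.default_rng(1)
    data = _matrix(rng.normal(size=(50, 2)), [0, 1] * 25)
    a1, b1 = prep.split_train_test(data, 0.8, seed=9)
    a2, b2 = prep.split_train_test(data, 0.8, seed=9)
    np.testing.assert_array_equal(a1.X, a2.X)
    np.testing.assert_array_equal(b1.X, b2.X)


# -------------------------------------------------------------- imputation

def test_numeric_mean_imputation():
    data = _matrix([[2], [np.nan], [4]], [0, 1, 0])
    state = prep.fit_imputer(data, prep.PrepConfig())
    assert state.numeric_means["f0"] == 3.0
    out = prep.apply_imputer(data, state, is_train=True)
    np.testing.assert_array_equal(out.X[:, 0], [2, 3, 4])


def test_categorical_backfill_on_train():
    data = _matrix([[0], [np.nan], [1], [np.nan]], [0, 1, 0, 1],
                   kinds=["categorical"])
    state = prep.fit_imputer(data, prep.PrepConfig())
    out = prep.apply_imputer(data, state, is_train=True)
    # missing takes next observed; trailing takes previous observed
    np.testing.assert_array_equal(out.X[:, 0], [0, 1, 1, 1])


def test_categorical_apply_uses_training_mode():
    train = _matrix([[0], [0], [1]], [0, 1, 0], kinds=["categorical"])
    state = prep.fit_imputer(train, prep.PrepConfig())
    test = _matrix([[np.nan], [1]], [0, 1], kinds=["categorical"])
    out = prep.apply_imputer(test, state, is_train=False)
    assert out.X[0, 0] == 0.0  # training mode, not test-partition backfill


def test_all_missing_column_errors():
    data = _matrix([[np.nan], [np.nan]], [0, 1])
    with pytest.raises(ValueError, match="f0"):
        prep.fit_imputer(data, prep.PrepConfig())


# --------------------------------------------------------------------- LOF

def test_lof_matches_independent_reference():
    """Agreement with sklearn's LOF to 1e-9 on random instances, n <= 50."""
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(10, 51))
        k = int(rng.integers(2, min(9, n - 1)))
        X = rng.normal(size=(n, int(rng.integers(1, 5))))
        ours = prep.lof_scores(X, k)
        ref = -LocalOutlierFactor(n_neighbors=k).fit(X).negative_outlier_factor_
        np.testing.assert_allclose(ours, ref, atol=1e-9)


def test_lof_line_with_far_point():
    X = np.array([[float(i)] for i in range(10)] + [[100.0]])
    scores = prep.lof_scores(X, k=3)
    assert np.argmax(scores) == 10
    assert scores[10] > 1.5


def test_lof_grid_boundary_effect():
    """Even a regular 3x3 grid is not scored uniformly 1: boundary effects
    push edge points above 1 and the centre below (values frozen from the
    independent reference implementation)."""
    grid = np.array([[i, j] for i in range(3) for j in range(3)], dtype=float)
    scores = prep.lof_scores(grid, k=3)
    np.testing.assert_allclose(scores[4], 0.7836, atol=1e-4)        # centre
    np.testing.assert_allclose(scores[[0, 2, 6, 8]], 0.9739, atol=1e-4)
    np.testing.assert_allclose(scores[[1, 3, 5, 7]], 1.1729, atol=1e-4)


def test_lof_cluster_swap_symmetry():
    rng = np.random.default_rng(5)
    a = rng.normal(size=(15, 2))
    X = np.vstack([a, a + 50.0])
    scores = prep.lof_scores(X, k=4)
    np.testing.assert_allclose(scores[:15], scores[15:], atol=1e-9)


def test_remove_outliers_ceiling_and_identity():
    rng = np.random.default_rng(2)
    data = _matrix(rng.normal(size=(200, 4)), [0, 1] * 100)
    cfg = prep.PrepConfig(lof_contamination=0.05, lof_neighbors=10)
    kept, flagged = prep.remove_outliers(data, cfg)
    assert len(flagged) == 10 and kept.n_samples == 190
    cfg0 = prep.PrepConfig(lof_contamination=0.0)
    kept0, flagged0 = prep.remove_outliers(data, cfg0)
    assert flagged0 == [] and kept0.n_samples == 200


def test_remove_outliers_finds_injected_rows():
    spec = synth.SyntheticSpec(
        n=100, d_informative=3, d_noise=7, n_categorical=0,
        outlier_count=5, missing_rate=0.0, typo_rate=0.0, seed=4,
    )
    table, log = synth.generate_cohort(spec)
    data = dataio.to_matrix(table)
    cfg = prep.PrepConfig(
        lof_contamination=0.05, lof_columns=tuple(log.lof_columns),
        lof_neighbors=20,
    )
    _, flagged = prep.remove_outliers(data, cfg)
    assert set(log.outlier_rows) <= set(flagged)


# -------------------------------------------------------------- duplicates

@pytest.mark.parametrize("copies,expect_removed", [(2, 1), (1, 0), (5, 4)])
def test_drop_duplicates_counting(copies, expect_removed):
    row = [1.0, 2.0]
    X = [row] * copies + [[3.0, 4.0], [5.0, 6.0]]
    y = [1] * copies + [0, 1]
    data = _matrix(X, y)
    out, removed = prep.drop_duplicates(data)
    assert removed == expect_removed
    assert out.n_samples == 3
    np.testing.assert_array_equal(out.X[0], row)  # first occurrence kept


def test_same_features_different_label_not_duplicate():
    data = _matrix([[1.0], [1.0]], [0, 1])
    out, removed = prep.drop_duplicates(data)
    assert removed == 0 and out.n_samples == 2


# ------------------------------------------------------------------- SMOTE

def test_smote_exact_balance_from_study_counts():
    rng = np.random.default_rng(8)
    n_pos, n_neg = 114, 184
    X = np.vstack([rng.normal(0, 1, (n_pos, 3)), rng.normal(3, 1, (n_neg, 3))])
    y = np.array([1] * n_pos + [0] * n_neg)
    out = prep.smote_balance(_matrix(X, y), k=5, seed=0)
    assert out.class_counts() == (184, 184)
    assert out.n_samples - (n_pos + n_neg) == 70


def test_smote_convex_combinations():
    """Every synthetic point solves x_new = x + u (x' - x) with u in [0,1]."""
    rng = np.random.default_rng(9)
    minority = rng.normal(size=(10, 2))
    majority = rng.normal(5, 1, size=(30, 2))
    data = _matrix(np.vstack([minority, majority]), [1] * 10 + [0] * 30)
    out = prep.smote_balance(data, k=3, seed=1)
    synth_rows = out.X[40:]
    for row in synth_rows:
        found = False
        for a in range(10):
            for b in range(10):
                if a == b:
                    continue
                diff = minority[b] - minority[a]
                num = row - minority[a]
                with np.errstate(divide="ignore", invalid="ignore"):
                    u = np.where(diff != 0, num / diff, np.nan)
                u_vals = u[~np.isnan(u)]
                if len(u_vals) and np.allclose(u_vals, u_vals[0], atol=1e-8):
                    if -1e-12 <= u_vals[0] <= 1 + 1e-12:
                        found = True
        assert found, f"synthetic row {row} is not an interpolation"


def test_smote_identity_when_balanced():
    data = _matrix(np.arange(40, dtype=float).reshape(20, 2), [0, 1] * 10)
    out = prep.smote_balance(data, k=3, seed=0)
    assert out.n_samples == 20


def test_smote_small_minority_errors():
    data = _matrix(np.arange(20, dtype=float).reshape(10, 2),
                   [1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
    with pytest.raises(ValueError, match="smaller"):
        prep.smote_balance(data, k=5, seed=0)


# ---------------------------------------------------------------- encoding

def test_onehot_binary_single_column():
    data = _matrix([[0.0], [1.0], [0.0]], [0, 1, 0], kinds=["boolean"])
    data.level_maps["f0"] = ["no", "yes"]
    state = prep.PrepState(config=prep.PrepConfig())
    prep.fit_encoder(data, state)
    out = prep.onehot_encode(data, state)
    assert out.feature_names == ["f0"]
    np.testing.assert_array_equal(out.X[:, 0], [0, 1, 0])


def test_onehot_multilevel_sums_to_one():
    data = _matrix([[0.0], [1.0], [2.0]], [0, 1, 0], kinds=["categorical"])
    data.level_maps["f0"] = ["a", "b", "c"]
    state = prep.PrepState(config=prep.PrepConfig())
    prep.fit_encoder(data, state)
    out = prep.onehot_encode(data, state)
    assert out.n_features == 3
    np.testing.assert_array_equal(out.X.sum(axis=1), [1, 1, 1])


def test_onehot_unseen_level_zero_vector_and_report():
    train = _matrix([[0.0], [1.0], [2.0]], [0, 1, 0], kinds=["categorical"])
    train.level_maps["f0"] = ["a", "b", "c", "d"]
    state = prep.PrepState(config=prep.PrepConfig())
    prep.fit_encoder(train, state)
    test = _matrix([[3.0]], [1], kinds=["categorical"])
    test.level_maps["f0"] = ["a", "b", "c", "d"]
    report = prep.PrepReport()
    out = prep.onehot_encode(test, state, report)
    np.testing.assert_array_equal(out.X[0], [0, 0, 0])
    assert report.unseen_levels == [(0, "f0", 3.0)]


# ----------------------------------------------------------------- zscore

def test_zscore_population_sigma():
    data = _matrix([[1.0], [2.0], [3.0]], [0, 1, 0])
    state = prep.fit_scaler(data, prep.PrepState(config=prep.PrepConfig()))
    out = prep.zscore(data, state)
    np.testing.assert_allclose(out.X[:, 0], [-1.2247, 0.0, 1.2247], atol=1e-4)


def test_zscore_train_moments():
    rng = np.random.default_rng(12)
    data = _matrix(rng.normal(3, 2, size=(100, 4)), [0, 1] * 50)
    state = prep.fit_scaler(data, prep.PrepState(config=prep.PrepConfig()))
    out = prep.zscore(data, state)
    assert np.abs(out.X.mean(axis=0)).max() < 1e-9
    np.testing.assert_allclose(out.X.std(axis=0, ddof=0), 1.0, atol=1e-9)


def test_zscore_constant_column_warns_and_zeroes():
    data = _matrix([[5.0, 1.0], [5.0, 2.0]], [0, 1])
    state = prep.fit_scaler(data, prep.PrepState(config=prep.PrepConfig()))
    with pytest.warns(UserWarning, match="constant"):
        out = prep.zscore(data, state)
    np.testing.assert_array_equal(out.X[:, 0], [0.0, 0.0])


# ---------------------------------------------------------------- pipeline

def test_pipeline_counts_match_injection_log():
    spec = synth.SyntheticSpec(
        n=200, d_informative=4, d_noise=8, n_categorical=1,
        minority_fraction=0.35, missing_rate=0.06, typo_rate=0.0,
        duplicate_count=0, outlier_count=8, seed=21,
    )
    table, log = synth.generate_cohort(spec)
    data = dataio.to_matrix(table)
    cfg = prep.PrepConfig(
        lof_contamination=8 / 200, lof_columns=tuple(log.lof_columns),
        seed=0, split_fraction=0.8,
    )
    # fit on the full cohort so report counts are comparable to the log
    state, out, report = prep.fit_pipeline(data, cfg)
    assert sum(report.imputed_cells.values()) == len(log.missing)
    assert set(log.outlier_rows) <= set(report.lof_flagged)
    neg, pos = out.class_counts()
    assert neg == pos


def test_pipeline_apply_is_deterministic_and_unfitted():
    spec = synth.SyntheticSpec(n=150, missing_rate=0.05, typo_rate=0.0,
                               outlier_count=0, seed=31)
    data = dataio.to_matrix(synth.generate_cohort(spec)[0])
    train, test = prep.split_train_test(data, 0.8, seed=1)
    cfg = prep.PrepConfig(lof_contamination=0.05, seed=1)
    state, _, _ = prep.fit_pipeline(train, cfg)
    out1 = prep.apply_pipeline(test, state)
    out2 = prep.apply_pipeline(test, state)
    np.testing.assert_array_equal(out1.X, out2.X)
    assert out1.n_samples == test.n_samples  # never filtered or resampled


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_leakage_guard(seed):
    """Any test row that would alter a statistic is detected by comparing
    the train-only state with a state fitted on train+test."""
    rng = np.random.default_rng(seed)
    train = _matrix(rng.normal(size=(30, 2)), [0, 1] * 15)
    test = _matrix(rng.normal(size=(10, 2)) + 1.0, [0, 1] * 5)
    cfg = prep.PrepConfig()
    st_train = prep.fit_imputer(train, cfg)
    combined = _matrix(
        np.vstack([train.X, test.X]), np.concatenate([train.y, test.y])
    )
    st_comb = prep.fit_imputer(combined, cfg)
    changes = [
        st_comb.numeric_means[c] != st_train.numeric_means[c]
        for c in st_train.numeric_means
    ]
    # the shifted test block always moves the mean
    assert any(changes)
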