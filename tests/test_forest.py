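import numpy as np
import pytest

import fluxforest as ff
from fluxforest.errors import PredictorError
from fluxforest.forest import (
    cross_validate,
    evaluate_mae,
    make_training_set,
    select_features,
    train,
)


def _toy_data(n=1200, n_noise=3, noise=0.0, seed=0):
    """Features that encode the label exactly (two-source style MDV)."""
    rng = np.random.default_rng(seed)
    y = rng.uniform(0, 1, n)
    X = np.column_stack([1 - y, y, np.zeros(n)])
    X = np.hstack([X, rng.uniform(0, 1, (n, n_noise))])
    if noise:
        X = X + rng.uniform(-noise, noise, X.shape)
    return X, y


# ---------------------------------------------------------------------------
# training-set extraction

def test_balanced_split_counts():
    rng = np.random.default_rng(1)
    y = rng.uniform(0, 1, 60000)
    X = rng.normal(size=(60000, 4))
    ds = make_training_set(X, y, n_bins=10, n_per_bin=1000, seed=2)
    n_total = ds.n_train + ds.n_test
    assert n_total == 10000
    assert abs(ds.n_train - 2 * ds.n_test) <= 1
    # per-bin counts uniform over train+test combined
    yy = np.concatenate([ds.y_train, ds.y_test])
    counts, _ = np.histogram(yy, bins=10, range=(0, 1))
    assert np.all(counts == 1000)
    # no sample reused
    assert len(set(map(tuple, np.vstack([ds.X_train, ds.X_test])))) == n_total


def test_empty_bin_errors():
    y = np.random.default_rng(0).uniform(0, 0.9, 1000)
    X = np.zeros((1000, 2))
    with pytest.raises(PredictorError, match=r"0\.90, 1\.00"):
        make_training_set(X, y, n_bins=10, n_per_bin=10)


def test_excluded_bins_are_skipped():
    y = np.random.default_rng(0).uniform(0, 0.9, 1000)
    X = np.zeros((1000, 2))
    ds = make_training_set(X, y, n_bins=10, n_per_bin=10, exclude_bins=[9])
    assert ds.n_train + ds.n_test == 90


def test_split_is_seed_reproducible():
    X, y = _toy_data()
    a = make_training_set(X, y, seed=7)
    b = make_training_set(X, y, seed=7)
    np.testing.assert_array_equal(a.X_train, b.X_train)
    np.testing.assert_array_equal(a.y_test, b.y_test)


# ---------------------------------------------------------------------------
# forest training and evaluation

def test_closed_form_features_are_recovered():
    X, y = _toy_data()
    ds = make_training_set(X, y, n_per_bin=100, seed=3)
    pred = train(ds, seed=3)
    assert evaluate_mae(pred, ds) < 0.02


def test_shuffled_labels_are_unlearnable():
    X, y = _toy_data(n=900)
    rng = np.random.default_rng(4)
    y_shuf = rng.permutation(y)
    pred = train((X, y_shuf), seed=4)
    Xt, yt = _toy_data(n=300, seed=5)
    mae = evaluate_mae(pred, (Xt, rng.permutation(yt)))
    # no better than predicting the median of a uniform label
    assert mae > 0.2


def test_too_few_training_points_refused():
    X, y = _toy_data(n=50)
    with pytest.raises(PredictorError, match="at least 100"):
        train((X, y))


def test_mtry_lowered_with_warning():
    X, y = _toy_data(n=200)
    with pytest.warns(UserWarning, match="mtry"):
        pred = train((X, y), mtry=50, seed=0)
    assert pred.metadata["mtry"] == X.shape[1]


def test_forest_is_seed_reproducible():
    X, y = _toy_data(n=400)
    p1 = train((X, y), seed=11)
    p2 = train((X, y), seed=11)
    Xt, _ = _toy_data(n=50, seed=12)
    np.testing.assert_array_equal(p1.predict(Xt), p2.predict(Xt))


def test_evaluate_mae_of_constant_predictor_on_uniform_labels():
    """Predicting 0.5 on uniform labels gives MAE = E|U-0.5| = 0.25."""
    rng = np.random.default_rng(6)
    y = rng.uniform(0, 1, 4000)
    X = np.zeros((4000, 3))  # featureless: forest must predict ~the median
    pred = train((X[:2000], y[:2000]), seed=6)
    mae = evaluate_mae(pred, (X[2000:], y[2000:]))
    assert mae == pytest.approx(0.25, abs=0.02)


def test_empty_test_set_rejected():
    X, y = _toy_data(n=200)
    pred = train((X, y), seed=0)
    with pytest.raises(PredictorError, match="empty"):
        evaluate_mae(pred, (X[:0], y[:0]))


# ---------------------------------------------------------------------------
# quantiles

def test_constant_labels_give_constant_quantiles():
    X = np.random.default_rng(0).normal(size=(200, 3))
    y = np.full(200, 0.42)
    pred = train((X, y), seed=0)
    q = pred.predict_quantiles(X[:10], (0.1, 0.5, 0.9))
    np.testing.assert_allclose(q, 0.42)


def test_quantiles_are_ordered_and_in_unit_interval():
    X, y = _toy_data(n=600, noise=0.05)
    pred = train((X, y), seed=1)
    q = pred.predict_quantiles(X[:100], (0.1, 0.5, 0.9))
    assert np.all(q[:, 0] <= q[:, 1] + 1e-12)
    assert np.all(q[:, 1] <= q[:, 2] + 1e-12)
    assert q.min() >= 0 and q.max() <= 1


def test_training_points_covered_by_own_interval():
    X, y = _toy_data(n=600, noise=0.02)
    pred = train((X, y), seed=2)
    q = pred.predict_quantiles(X[:100], (0.1, 0.9))
    covered = np.mean((y[:100] >= q[:, 0]) & (y[:100] <= q[:, 1]))
    assert covered >= 0.95


def test_manifest_mismatch_rejected():
    X, y = _toy_data(n=600)
    ds = make_training_set(X, y, n_per_bin=30, manifest=[f"f{i}" for i in range(6)])
    pred = train(ds, seed=0)
    with pytest.raises(PredictorError, match="manifest"):
        pred.predict(X[:5], manifest=["a"] * 6)


def test_predictor_save_load_roundtrip(tmp_path):
    X, y = _toy_data(n=600)
    ds = make_training_set(X, y, n_per_bin=30, manifest=[f"f{i}" for i in range(6)],
                           ratio_name="demo")
    pred = train(ds, seed=0)
    path = tmp_path / "pred.joblib"
    pred.save(path)
    again = ff.RatioPredictor.load(path)
    np.testing.assert_array_equal(pred.predict(X[:20]), again.predict(X[:20]))
    assert again.ratio_name == "demo"
    assert again.manifest == ds.manifest


# ---------------------------------------------------------------------------
# cross-validation and feature selection

def test_cross_validation_grid_shape_and_ties():
    X, y = _toy_data(n=450)
    best, table = cross_validate((X, y), (50, 100), (2, 4), k=3, seed=0)
    assert len(table) == 4
    assert set(table.columns) == {"ntree", "mtry", "cv_mae"}
    assert best in {(n, m) for n in (50, 100) for m in (2, 4)}
    # degenerate 1x1 grid returns itself
    best1, t1 = cross_validate((X, y), (50,), (2,), k=3, seed=0)
    assert best1 == (50, 2) and len(t1) == 1


def test_cross_validation_bad_args():
    X, y = _toy_data(n=300)
    with pytest.raises(PredictorError):
        cross_validate((X, y), (), (2,), k=3)
    with pytest.raises(PredictorError):
        cross_validate((X, y), (50,), (2,), k=1)


def test_feature_selection_keeps_informative_features():
    rng = np.random.default_rng(8)
    n = 900
    y = rng.uniform(0, 1, n)
    informative = np.column_stack([y, 1 - y]) + rng.normal(0, 0.01, (n, 2))
    noise = rng.uniform(0, 1, (n, 38))
    X = np.hstack([informative, noise])
    cols, table = select_features((X, y), fractions=(1.0, 0.25, 0.05), seed=8,
                                  mtry=5, k=3)
    assert {"fraction", "n_features", "cv_mae"} <= set(table.columns)
    kept = set(cols.tolist())
    assert {0, 1} <= kept or len(kept) >= 1 and table.cv_mae.min() < 0.05


def test_single_feature_dataset_keeps_everything():
    rng = np.random.default_rng(9)
    y = rng.uniform(0, 1, 300)
    X = y[:, None] + rng.normal(0, 0.01, (300, 1))
    cols, _ = select_features((X, y), seed=9, mtry=1, k=3)
    assert cols.tolist() == [0]


def test_more_training_data_does_not_hurt():
    """Test MAE at a large training size <= MAE at a small size (same test set)."""
    X, y = _toy_data(n=4000, noise=0.05, seed=13)
    Xt, yt = _toy_data(n=800, noise=0.05, seed=14)
    small = train((X[:150], y[:150]), seed=13)
    large = train((X, y), seed=13)
    assert evaluate_mae(large, (Xt, yt)) <= evaluate_mae(small, (Xt, yt)) + 0.005
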