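import numpy as np
import pandas as pd
import pytest

import geomicrobe as gm
from geomicrobe.models import PredictionSet


def _regression_toy(seed=0, n=200, p=10, active=3, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    X = (X - X.mean(0)) / X.std(0)
    beta = np.zeros((p, 2))
    beta[:active, 0] = [3.0, -2.0, 1.5][:active]
    beta[:active, 1] = [-1.0, 2.5, 0.5][:active]
    Y = X @ beta + noise * rng.normal(size=(n, 2))
    ids = [f"s{i}" for i in range(n)]
    Xdf = pd.DataFrame(X, index=ids, columns=[f"f{j}" for j in range(p)])
    coords = pd.DataFrame(Y, index=ids, columns=["latitude", "longitude"])
    return Xdf, coords, beta


# --- weights ---------------------------------------------------------------

def test_weights_formula():
    labels = ["X"] * 30 + ["Y"] * 70
    w = gm.compute_weights(labels)
    assert set(w[np.array(labels) == "X"].round(12)) == {0.7}
    assert set(w[np.array(labels) == "Y"].round(12)) == {0.3}


def test_weights_equal_city_sizes():
    w = gm.compute_weights(["A"] * 5 + ["B"] * 5 + ["C"] * 5 + ["D"] * 5)
    np.testing.assert_allclose(w, 1 - 1 / 4)


def test_weights_single_city_errors():
    with pytest.raises(ValueError, match="2 distinct"):
        gm.compute_weights(["only"] * 10)


# --- geo regression --------------------------------------------------------

def test_full_shrinkage_above_lambda_max():
    X, coords, _ = _regression_toy(noise=0.5)
    model = gm.fit_geo_regression(X, coords, lambda_override=1e6)
    assert np.allclose(model.coefficients.to_numpy(), 0.0)
    pred = model.predict(X)
    np.testing.assert_allclose(pred["latitude"], coords["latitude"].mean())
    np.testing.assert_allclose(pred["longitude"], coords["longitude"].mean())
    assert model.df == 0


def test_tiny_lambda_matches_ols():
    """Noiseless Y = X beta: the nearly-unpenalized fit recovers OLS."""
    X, coords, beta = _regression_toy(noise=0.0)
    model = gm.fit_geo_regression(X, coords, lambda_override=1e-8)
    ols = np.linalg.lstsq(
        np.c_[np.ones(len(X)), X.to_numpy()], coords.to_numpy(), rcond=None
    )[0]
    np.testing.assert_allclose(model.coefficients.to_numpy(), ols[1:], atol=1e-6)
    np.testing.assert_allclose(model.coefficients.to_numpy(), beta, atol=1e-6)


def test_one_se_rule_invariant_and_group_coupling():
    X, coords, _ = _regression_toy(noise=2.0, seed=3)
    model = gm.fit_geo_regression(X, coords, n_folds=5, seed=1)
    assert model.lambda_1se >= model.lambda_min
    # grouped penalty: a feature is zero or nonzero in both coordinates
    for i in range(model.coef_path.shape[2]):
        C = model.coef_path[:, :, i]  # 2 x p
        both = (C != 0).sum(axis=0)
        assert set(np.unique(both)) <= {0, 2}


def test_ungrouped_option_can_split_support():
    X, coords, _ = _regression_toy(noise=2.0, seed=3)
    m = gm.fit_geo_regression(X, coords, n_folds=5, seed=1, grouped=False)
    split = ((m.coef_path != 0).sum(axis=0) == 1).any()
    assert split  # some feature active in exactly one coordinate somewhere


def test_regression_invariant_to_feature_order():
    X, coords, _ = _regression_toy(noise=1.0, seed=5)
    m1 = gm.fit_geo_regression(X, coords, n_folds=5, seed=2)
    perm = list(np.random.default_rng(0).permutation(X.columns))
    m2 = gm.fit_geo_regression(X[perm], coords, n_folds=5, seed=2)
    p1 = m1.predict(X)
    p2 = m2.predict(X[perm])
    np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-6)


def test_regression_rejects_nonfinite_features():
    X, coords, _ = _regression_toy()
    X.iloc[0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        gm.fit_geo_regression(X, coords, lambda_override=1.0)


def test_informative_taxa_selected_on_synthetic_signal(small_world, small_features):
    meta = small_world["meta"]
    model = gm.fit_geo_regression(
        small_features,
        meta[["latitude", "longitude"]],
        n_folds=5,
        seed=0,
        groups=meta["city"],
    )
    selected = set(
        np.array(model.feature_ids)[
            np.abs(model.coefficients.to_numpy()).sum(axis=1) > 0
        ]
    )
    informative = set(small_world["truth"].informative_taxa) & set(model.feature_ids)
    assert len(selected & informative) >= 0.5 * len(informative)


# --- origin classifier -----------------------------------------------------

def _classifier_toy(seed=0, sep=4.0, n=60):
    rng = np.random.default_rng(seed)
    half = n // 2
    x = np.r_[rng.normal(-sep / 2, 1, half), rng.normal(sep / 2, 1, half)]
    X = pd.DataFrame({"f0": x}, index=[f"s{i}" for i in range(n)])
    y = pd.Series(["A"] * half + ["B"] * half, index=X.index)
    return X, y


def test_separable_classes_perfect_training_accuracy():
    X, y = _classifier_toy(sep=8.0)
    model = gm.fit_origin_classifier(X, y, n_folds=5, seed=0, n_lambdas=15)
    assert (model.predict(X) == y).all()
    assert model.lambda_1se >= model.lambda_min


def test_constant_features_give_weighted_priors():
    rng = np.random.default_rng(1)
    n = 40
    X = pd.DataFrame({"f0": np.zeros(n)}, index=[f"s{i}" for i in range(n)])
    y = pd.Series(["A"] * 10 + ["B"] * 30, index=X.index)
    w = gm.compute_weights(y)
    model = gm.fit_origin_classifier(X, y, weights=w, n_folds=5, seed=0, n_lambdas=8)
    proba = model.predict_proba(X)
    priors = np.array([w[y == c].sum() for c in model.classes])
    priors = priors / priors.sum()
    np.testing.assert_allclose(proba.iloc[0].to_numpy(), priors, atol=0.02)


def test_probability_rows_sum_to_one(small_features, small_world):
    meta = small_world["meta"]
    model = gm.fit_origin_classifier(
        small_features, meta["city"], n_folds=5, seed=0, n_lambdas=8
    )
    proba = model.predict_proba(small_features)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)


def test_equal_weights_match_unweighted_objective():
    """All-equal weights rescale loss and penalty identically, so the fit
    is unchanged."""
    X, y = _classifier_toy(sep=2.0, n=40)
    m1 = gm.fit_origin_classifier(
        X, y, weights=pd.Series(1.0, index=X.index), n_folds=5, seed=0,
        n_lambdas=8, tol=1e-8,
    )
    m2 = gm.fit_origin_classifier(
        X, y, weights=pd.Series(0.5, index=X.index), n_folds=5, seed=0,
        n_lambdas=8, tol=1e-8,
    )
    np.testing.assert_allclose(
        m1.coefficients.to_numpy(), m2.coefficients.to_numpy(), atol=1e-5
    )


def test_weighting_helps_minority_recall():
    """10:1 imbalance: weighted fit's minority recall >= unweighted (mean
    over seeds)."""
    rec_w, rec_u = [], []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        n_maj, n_min = 50, 5
        X = pd.DataFrame(
            {
                "f0": np.r_[
                    rng.normal(0, 1, n_maj),
                    rng.normal(1.5, 1, n_min),
                    rng.normal(4.0, 1, n_maj),
                ]
            },
            index=[f"s{i}" for i in range(2 * n_maj + n_min)],
        )
        y = pd.Series(["A"] * n_maj + ["B"] * n_min + ["C"] * n_maj, index=X.index)
        w = gm.compute_weights(y)
        mw = gm.fit_origin_classifier(X, y, weights=w, n_folds=5, seed=seed, n_lambdas=8)
        mu = gm.fit_origin_classifier(
            X, y, weights=pd.Series(1.0, index=X.index), n_folds=5, seed=seed, n_lambdas=8
        )
        rec_w.append((mw.predict(X)[y == "B"] == "B").mean())
        rec_u.append((mu.predict(X)[y == "B"] == "B").mean())
    assert np.mean(rec_w) >= np.mean(rec_u)


def test_classifier_requires_fold_coverage():
    X, y = _classifier_toy(n=10)
    with pytest.raises(ValueError, match="n_folds"):
        gm.fit_origin_classifier(X, y, n_folds=8, seed=0)


# --- random forest ---------------------------------------------------------

def test_rf_separable_oob_accuracy():
    rng = np.random.default_rng(2)
    X = pd.DataFrame(
        np.r_[rng.normal(-3, 1, (40, 3)), rng.normal(3, 1, (40, 3))],
        index=[f"s{i}" for i in range(80)],
    )
    y = pd.Series(["A"] * 40 + ["B"] * 40, index=X.index)
    rf = gm.fit_rf_downsampled(X, y, n_trees=100, seed=0)
    assert rf.oob_accuracy >= 0.95


def test_rf_permuted_labels_near_chance():
    accs = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(60, 4)), index=[f"s{i}" for i in range(60)])
        y = pd.Series(rng.permutation(["A"] * 20 + ["B"] * 20 + ["C"] * 20), index=X.index)
        rf = gm.fit_rf_downsampled(X, y, n_trees=60, seed=seed)
        accs.append(rf.oob_accuracy)
    assert abs(np.mean(accs) - 1 / 3) < 0.1


def test_rf_deterministic_and_singleton_class_errors():
    rng = np.random.default_rng(3)
    X = pd.DataFrame(rng.normal(size=(20, 3)), index=[f"s{i}" for i in range(20)])
    y = pd.Series(["A"] * 10 + ["B"] * 10, index=X.index)
    p1 = gm.fit_rf_downsampled(X, y, n_trees=25, seed=5).predict_proba(X)
    p2 = gm.fit_rf_downsampled(X, y, n_trees=25, seed=5).predict_proba(X)
    pd.testing.assert_frame_equal(p1, p2)
    y2 = y.copy()
    y2.iloc[0] = "C"
    with pytest.raises(ValueError, match="single sample"):
        gm.fit_rf_downsampled(X, y2, n_trees=5, seed=0)


# --- prediction bridging ---------------------------------------------------

def test_classifier_predictions_bridge_to_panel_coordinates():
    X, y = _classifier_toy(sep=8.0)
    model = gm.fit_origin_classifier(X, y, n_folds=5, seed=0, n_lambdas=10)
    panel = gm.CityPanel(
        pd.DataFrame(
            {
                "name": ["A", "B"],
                "latitude": [48.8, -33.9],
                "longitude": [2.3, 151.2],
                "continent": ["N1", "S2"],
                "protocol": ["paired_150"] * 2,
                "n_samples": [30, 30],
            },
            index=pd.Index(["A", "B"], name="city_id"),
        )
    )
    pred = gm.predict_origin(model, X, city_panel=panel)
    a_rows = pred.pred_city == "A"
    assert (pred.pred_latitude[a_rows] == 48.8).all()
    assert (pred.pred_longitude[~a_rows] == 151.2).all()
    np.testing.assert_allclose(pred.class_probabilities.sum(axis=1), 1.0, atol=1e-9)


def test_classifier_bridge_missing_city_errors():
    X, y = _classifier_toy(sep=8.0)
    model = gm.fit_origin_classifier(X, y, n_folds=5, seed=0, n_lambdas=10)
    panel = gm.CityPanel(
        pd.DataFrame(
            {
                "name": ["A"],
                "latitude": [0.0],
                "longitude": [0.0],
                "continent": ["N0"],
                "protocol": ["paired_150"],
                "n_samples": [30],
            },
            index=pd.Index(["A"], name="city_id"),
        )
    )
    with pytest.raises(ValueError, match="not in panel"):
        gm.predict_origin(model, X, city_panel=panel)


def test_regression_prediction_set_shape():
    X, coords, _ = _regression_toy(n=50)
    model = gm.fit_geo_regression(X, coords, lambda_override=1e6)
    pred = gm.predict_origin(model, X)
    assert isinstance(pred, PredictionSet)
    assert pred.pred_city is None
    assert len(pred.sample_ids) == 50
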