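"""Geolocation models: penalized coordinate regression and source classifiers.

Three models predict a sample's origin from standardized log2 abundance
features:

* **Multi-task Lasso regression** of (latitude, longitude). The penalty is
  grouped across the two responses — each feature's coefficient pair is
  penalized by its Euclidean norm — so a taxon enters or leaves both
  coordinates together. The regularization strength is chosen by internal
  K-fold cross-validation with the one-standard-error (1-SE) rule: the
  largest lambda whose CV error is within one SE of the minimum.
* **L1-penalized multinomial logistic regression** over cities, with
  per-sample weights ``w_i = 1 - n_city(i)/N`` to counter city-size
  imbalance; lambda again chosen by the 1-SE rule on weighted deviance.
* **Random forest with per-class down-sampling**: every tree sees a
  bootstrap in which each city is resampled down to the smallest city's
  size; out-of-bag predictions are retained.

Classifier predictions are bridged to coordinates by assigning the
predicted city's panel coordinates, which makes classification and
regression errors directly comparable in squared degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, lasso_path
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .abundance import FeatureMatrix
from .synthetic import CityPanel

COORD_COLUMNS = ("latitude", "longitude")


def _as_matrix(features) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(features, FeatureMatrix):
        return features.X.to_numpy(dtype=float), list(features.X.index), list(features.X.columns)
    df = pd.DataFrame(features)
    return df.to_numpy(dtype=float), list(df.index), list(df.columns)


def compute_weights(city_labels) -> pd.Series:
    """Per-sample weights ``1 - n_city/N``; samples of one city share a weight."""
    labels = pd.Series(city_labels)
    if labels.nunique() < 2:
        raise ValueError("sample weighting needs at least 2 distinct cities")
    counts = labels.value_counts()
    w = 1.0 - labels.map(counts) / len(labels)
    w.name = "weight"
    return w


def _cv_folds(labels: pd.Series | None, n: int, n_folds: int, seed):
    """Index folds for internal CV, stratified by city when label counts allow."""
    if labels is not None:
        min_count = labels.value_counts().min()
        if min_count >= n_folds:
            skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
            return list(skf.split(np.zeros(n), labels))
        warnings.warn(
            f"smallest city has {min_count} samples < {n_folds} folds; "
            "falling back to unstratified folds",
            stacklevel=3,
        )
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(kf.split(np.zeros(n)))


def _one_se_index(alphas: np.ndarray, mean: np.ndarray, se: np.ndarray) -> tuple[int, int]:
    """Indices of the CV-minimum lambda and the 1-SE lambda on a
    descending lambda path."""
    i_min = int(np.argmin(mean))
    threshold = mean[i_min] + se[i_min]
    i_1se = int(np.flatnonzero(mean <= threshold)[0])  # largest lambda first
    return i_min, i_1se


@dataclass
class GeoRegressionModel:
    """Fitted multi-task Lasso for (latitude, longitude)."""

    feature_ids: list[str]
    coefficients: pd.DataFrame  # features x (latitude, longitude)
    intercepts: np.ndarray  # (2,)
    lambda_path: np.ndarray
    cv_mse_mean: np.ndarray
    cv_mse_se: np.ndarray
    lambda_1se: float
    lambda_min: float
    grouped: bool
    seed: int | None
    coef_path: np.ndarray | None = None  # (2, p, n_lambdas) on the full data

    @property
    def df(self) -> int:
        """Number of features with a nonzero coefficient group."""
        return int((np.abs(self.coefficients.to_numpy()).sum(axis=1) > 0).sum())

    def coef_at(self, lam: float) -> pd.DataFrame:
        """Coefficients from the full-data path at the lambda closest to ``lam``."""
        if self.coef_path is None:
            raise ValueError("coefficient path was not stored")
        i = int(np.argmin(np.abs(np.log(self.lambda_path) - np.log(lam))))
        return pd.DataFrame(
            self.coef_path[:, :, i].T, index=self.feature_ids, columns=list(COORD_COLUMNS)
        )

    def predict(self, features) -> pd.DataFrame:
        X, ids, cols = _as_matrix(features)
        if cols != self.feature_ids:
            X = pd.DataFrame(X, index=ids, columns=cols)[self.feature_ids].to_numpy()
        Y = X @ self.coefficients.to_numpy() + self.intercepts
        return pd.DataFrame(Y, index=ids, columns=list(COORD_COLUMNS))

    def to_json(self, path: str) -> None:
        import json

        payload = {
            "model": "geo_regression",
            "feature_ids": self.feature_ids,
            "coefficients": self.coefficients.to_dict(orient="list"),
            "intercepts": list(map(float, self.intercepts)),
            "lambda_path": self.lambda_path.tolist(),
            "lambda_1se": self.lambda_1se,
            "lambda_min": self.lambda_min,
            "grouped": self.grouped,
            "seed": self.seed,
            "df": self.df,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _mt_lasso_path(Xc, Yc, alphas, grouped: bool, tol: float = 1e-6) -> np.ndarray:
    """Coefficient path, shape (2, p, n_alphas); grouped = multi-task penalty."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if grouped:
            _, coefs, _ = lasso_path(Xc, Yc, alphas=alphas, tol=tol, max_iter=5000)
            return coefs
        parts = []
        for k in range(Yc.shape[1]):
            _, ck, _ = lasso_path(Xc, Yc[:, k], alphas=alphas, tol=tol, max_iter=5000)
            parts.append(ck)
        return np.stack(parts, axis=0)


def fit_geo_regression(
    features,
    coords: pd.DataFrame,
    n_folds: int = 10,
    seed: int | None = None,
    groups=None,
    grouped: bool = True,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
    lambda_override: float | None = None,
) -> GeoRegressionModel:
    """Fit the coordinate regression with internal CV lambda selection.

    ``coords`` must carry 'latitude' and 'longitude' columns aligned with
    the feature rows. ``groups`` (city labels) stratifies the internal CV
    folds so each fold sees every city. ``lambda_override`` skips CV and
    fits at a fixed penalty. CV error is the per-sample squared error
    summed over the two coordinates.
    """
    X, ids, feature_ids = _as_matrix(features)
    if not np.isfinite(X).all():
        raise ValueError("features contain non-finite values")
    Y = coords.loc[ids, list(COORD_COLUMNS)].to_numpy(dtype=float)
    n, p = X.shape
    if lambda_override is None and n <= n_folds:
        raise ValueError("need more samples than CV folds")

    xm, ym = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - xm, Y - ym
    if grouped:
        lam_max = np.linalg.norm(Xc.T @ Yc, axis=1).max() / n
    else:
        lam_max = np.abs(Xc.T @ Yc).max() / n
    lam_max = max(lam_max, 1e-12)
    alphas = np.geomspace(lam_max, lambda_min_ratio * lam_max, n_lambdas)

    if lambda_override is not None:
        target = float(lambda_override)
        path_alphas = np.unique(np.append(alphas, target))[::-1]
        path_alphas = path_alphas[path_alphas >= target]
        coefs = _mt_lasso_path(Xc, Yc, path_alphas, grouped, tol=1e-12)
        coef = coefs[:, :, -1].T  # p x 2
        return GeoRegressionModel(
            feature_ids=feature_ids,
            coefficients=pd.DataFrame(coef, index=feature_ids, columns=list(COORD_COLUMNS)),
            intercepts=ym - xm @ coef,
            lambda_path=path_alphas,
            cv_mse_mean=np.array([]),
            cv_mse_se=np.array([]),
            lambda_1se=target,
            lambda_min=target,
            grouped=grouped,
            seed=seed,
            coef_path=coefs,
        )

    labels = pd.Series(groups, index=ids) if groups is not None else None
    folds = _cv_folds(labels, n, n_folds, seed)
    fold_mse = np.empty((len(folds), n_lambdas))
    for f, (tr, te) in enumerate(folds):
        xm_f, ym_f = X[tr].mean(axis=0), Y[tr].mean(axis=0)
        coefs = _mt_lasso_path(X[tr] - xm_f, Y[tr] - ym_f, alphas, grouped)
        # (n_te, 2, n_alphas)
        pred = np.einsum("ij,kjl->ikl", X[te] - xm_f, coefs) + ym_f[None, :, None]
        err = ((pred - Y[te][:, :, None]) ** 2).sum(axis=1)
        fold_mse[f] = err.mean(axis=0)
    cv_mean = fold_mse.mean(axis=0)
    cv_se = fold_mse.std(axis=0, ddof=1) / np.sqrt(len(folds))
    i_min, i_1se = _one_se_index(alphas, cv_mean, cv_se)

    coefs = _mt_lasso_path(Xc, Yc, alphas, grouped)
    coef = coefs[:, :, i_1se].T
    return GeoRegressionModel(
        feature_ids=feature_ids,
        coefficients=pd.DataFrame(coef, index=feature_ids, columns=list(COORD_COLUMNS)),
        intercepts=ym - xm @ coef,
        lambda_path=alphas,
        cv_mse_mean=cv_mean,
        cv_mse_se=cv_se,
        lambda_1se=float(alphas[i_1se]),
        lambda_min=float(alphas[i_min]),
        grouped=grouped,
        seed=seed,
        coef_path=coefs,
    )


@dataclass
class OriginClassifierModel:
    """Fitted L1 multinomial city classifier with per-sample weights."""

    classes: list[str]
    feature_ids: list[str]
    coefficients: pd.DataFrame  # features x classes
    intercepts: pd.Series  # per class
    lambda_path: np.ndarray
    cv_dev_mean: np.ndarray
    cv_dev_se: np.ndarray
    lambda_1se: float
    lambda_min: float
    weights_used: pd.Series | None
    seed: int | None

    def predict_proba(self, features) -> pd.DataFrame:
        X, ids, cols = _as_matrix(features)
        if cols != self.feature_ids:
            X = pd.DataFrame(X, index=ids, columns=cols)[self.feature_ids].to_numpy()
        logits = X @ self.coefficients.to_numpy() + self.intercepts.to_numpy()
        logits -= logits.max(axis=1, keepdims=True)
        P = np.exp(logits)
        P /= P.sum(axis=1, keepdims=True)
        return pd.DataFrame(P, index=ids, columns=self.classes)

    def predict(self, features) -> pd.Series:
        proba = self.predict_proba(features)
        # ties broken toward the first class in sorted order (idxmax on
        # sorted columns)
        return proba.idxmax(axis=1)

    def to_json(self, path: str) -> None:
        import json

        payload = {
            "model": "origin_classifier",
            "classes": self.classes,
            "feature_ids": self.feature_ids,
            "coefficients": self.coefficients.to_dict(orient="list"),
            "intercepts": self.intercepts.to_dict(),
            "lambda_path": self.lambda_path.tolist(),
            "lambda_1se": self.lambda_1se,
            "lambda_min": self.lambda_min,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _weighted_deviance(proba: np.ndarray, y_idx: np.ndarray, w: np.ndarray) -> float:
    p = np.clip(proba[np.arange(len(y_idx)), y_idx], 1e-12, 1.0)
    return float(-2.0 * np.sum(w * np.log(p)) / np.sum(w))


def _logreg_path(X, y, w, lambdas, seed, tol=1e-3, max_iter=300):
    """Warm-started saga fits along a descending lambda path.

    sklearn's objective is sum_i w_i * loss_i + (1/C) * |coef|_1; the
    glmnet-style per-observation penalty lambda maps to C = 1/(lambda * sum w).
    Returns the list of (coef, intercept) per lambda.
    """
    sw = np.sum(w)
    clf = LogisticRegression(
        l1_ratio=1.0,
        solver="saga",
        warm_start=True,
        random_state=seed,
        tol=tol,
        max_iter=max_iter,
        C=1.0,
    )
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for lam in lambdas:
            clf.C = 1.0 / (lam * sw)
            clf.fit(X, y, sample_weight=w)
            out.append((clf.coef_.copy(), clf.intercept_.copy(), clf.classes_.copy()))
    return out


def _expand_binary(coef, intercept, classes_fit):
    """sklearn encodes binary fits as one row (positive class, reference
    coding); expand to one row per class with the reference at zero."""
    if len(classes_fit) == 2 and coef.shape[0] == 1:
        coef = np.vstack([np.zeros_like(coef[0]), coef[0]])
        intercept = np.array([0.0, intercept[0]])
    return coef, intercept


def _proba_from(coef, intercept, classes_fit, classes_all, X):
    coef, intercept = _expand_binary(coef, intercept, classes_fit)
    logits = X @ coef.T + intercept
    logits -= logits.max(axis=1, keepdims=True)
    P = np.exp(logits)
    P /= P.sum(axis=1, keepdims=True)
    full = np.zeros((X.shape[0], len(classes_all)))
    pos = {c: i for i, c in enumerate(classes_all)}
    for j, c in enumerate(classes_fit):
        full[:, pos[c]] = P[:, j]
    return full


def fit_origin_classifier(
    features,
    city_labels,
    weights: pd.Series | None = None,
    n_folds: int = 10,
    seed: int | None = None,
    n_lambdas: int = 20,
    lambda_min_ratio: float = 1e-3,
    tol: float = 1e-3,
) -> OriginClassifierModel:
    """L1-penalized multinomial city classifier, lambda by the 1-SE rule.

    ``weights`` defaults to :func:`compute_weights` of the labels. The CV
    criterion is held-out weighted multinomial deviance; folds are
    stratified by city and must contain every city (an error suggests
    fewer folds otherwise).
    """
    X, ids, feature_ids = _as_matrix(features)
    labels = pd.Series(city_labels, index=ids).astype(str)
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 cities to fit a classifier")
    if weights is None:
        weights = compute_weights(labels)
    w = pd.Series(weights).loc[ids].to_numpy(dtype=float)
    y = labels.to_numpy()
    y_idx = np.searchsorted(np.array(classes), y)
    n = len(ids)

    min_count = labels.value_counts().min()
    if min_count < n_folds:
        raise ValueError(
            f"smallest city has {min_count} samples; cannot stratify {n_folds} "
            f"folds with every city present — use n_folds <= {min_count}"
        )

    # lambda_max from the unpenalized gradient at the intercept-only fit
    priors = np.array([w[y_idx == k].sum() for k in range(len(classes))]) / w.sum()
    if X.shape[1] == 0 or np.ptp(X, axis=0).max() == 0:
        # no usable features: the penalized optimum is the intercept-only
        # model whose probabilities are the weighted class priors
        return OriginClassifierModel(
            classes=classes,
            feature_ids=feature_ids,
            coefficients=pd.DataFrame(
                np.zeros((len(feature_ids), len(classes))),
                index=feature_ids,
                columns=classes,
            ),
            intercepts=pd.Series(np.log(np.clip(priors, 1e-12, None)), index=classes),
            lambda_path=np.array([np.inf]),
            cv_dev_mean=np.array([np.nan]),
            cv_dev_se=np.array([np.nan]),
            lambda_1se=np.inf,
            lambda_min=np.inf,
            weights_used=pd.Series(w, index=ids, name="weight"),
            seed=seed,
        )
    resid = priors[None, :].repeat(n, axis=0)
    resid[np.arange(n), y_idx] -= 1.0
    grad = X.T @ (resid * w[:, None]) / w.sum()
    lam_max = max(np.abs(grad).max(), 1e-12)
    lambdas = np.geomspace(lam_max, lambda_min_ratio * lam_max, n_lambdas)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_dev = np.empty((n_folds, n_lambdas))
    for f, (tr, te) in enumerate(skf.split(X, y)):
        fits = _logreg_path(X[tr], y[tr], w[tr], lambdas, seed, tol=tol)
        for a, (coef, intercept, cls_fit) in enumerate(fits):
            proba = _proba_from(coef, intercept, list(cls_fit), classes, X[te])
            fold_dev[f, a] = _weighted_deviance(proba, y_idx[te], w[te])
    cv_mean = fold_dev.mean(axis=0)
    cv_se = fold_dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
    i_min, i_1se = _one_se_index(lambdas, cv_mean, cv_se)

    fits = _logreg_path(X, y, w, lambdas[: i_1se + 1], seed, tol=tol)
    coef, intercept, cls_fit = fits[-1]
    coef, intercept = _expand_binary(coef, intercept, list(cls_fit))
    coef_full = np.zeros((len(feature_ids), len(classes)))
    icpt_full = np.zeros(len(classes))
    pos = {c: i for i, c in enumerate(classes)}
    for j, c in enumerate(cls_fit):
        coef_full[:, pos[c]] = coef[j]
        icpt_full[pos[c]] = intercept[j]
    return OriginClassifierModel(
        classes=classes,
        feature_ids=feature_ids,
        coefficients=pd.DataFrame(coef_full, index=feature_ids, columns=classes),
        intercepts=pd.Series(icpt_full, index=classes),
        lambda_path=lambdas,
        cv_dev_mean=cv_mean,
        cv_dev_se=cv_se,
        lambda_1se=float(lambdas[i_1se]),
        lambda_min=float(lambdas[i_min]),
        weights_used=pd.Series(w, index=ids, name="weight"),
        seed=seed,
    )


@dataclass
class DownsampledRF:
    """Random forest whose trees train on per-class balanced bootstraps."""

    classes: list[str]
    feature_ids: list[str]
    trees: list = field(repr=False, default_factory=list)
    oob_prediction: pd.Series | None = None
    oob_accuracy: float | None = None
    seed: int | None = None

    def predict_proba(self, features) -> pd.DataFrame:
        X, ids, cols = _as_matrix(features)
        if cols != self.feature_ids:
            X = pd.DataFrame(X, index=ids, columns=cols)[self.feature_ids].to_numpy()
        acc = np.zeros((X.shape[0], len(self.classes)))
        for tree in self.trees:
            acc += tree.predict_proba(X)
        acc /= len(self.trees)
        return pd.DataFrame(acc, index=ids, columns=self.classes)

    def predict(self, features) -> pd.Series:
        return self.predict_proba(features).idxmax(axis=1)


def fit_rf_downsampled(
    features, city_labels, n_trees: int = 200, seed: int | None = None
) -> DownsampledRF:
    """Random forest where each tree's bootstrap down-samples every class
    to the minority class size; out-of-bag predictions are retained."""
    X, ids, feature_ids = _as_matrix(features)
    labels = pd.Series(city_labels, index=ids).astype(str)
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 cities")
    counts = labels.value_counts()
    if counts.min() < 2:
        raise ValueError(f"class {counts.idxmin()!r} has a single sample")
    n_min = int(counts.min())
    class_idx = {c: np.flatnonzero(labels.to_numpy() == c) for c in classes}
    y = labels.to_numpy()

    rng = np.random.default_rng(seed)
    trees = []
    oob_votes = np.zeros((len(ids), len(classes)))
    for _ in range(n_trees):
        boot = np.concatenate(
            [rng.choice(class_idx[c], size=n_min, replace=True) for c in classes]
        )
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(0, 2**31 - 1))
        )
        tree.fit(X[boot], y[boot])
        trees.append(tree)
        oob = np.setdiff1d(np.arange(len(ids)), boot)
        if len(oob):
            proba = tree.predict_proba(X[oob])
            full = np.zeros((len(oob), len(classes)))
            for j, c in enumerate(tree.classes_):
                full[:, classes.index(c)] = proba[:, j]
            oob_votes[oob] += full
    has_oob = oob_votes.sum(axis=1) > 0
    oob_pred = pd.Series(
        [classes[i] for i in oob_votes.argmax(axis=1)], index=ids
    ).where(pd.Series(has_oob, index=ids))
    oob_acc = float((oob_pred[has_oob] == labels[has_oob]).mean()) if has_oob.any() else None
    return DownsampledRF(
        classes=classes,
        feature_ids=feature_ids,
        trees=trees,
        oob_prediction=oob_pred,
        oob_accuracy=oob_acc,
        seed=seed,
    )


@dataclass
class PredictionSet:
    """Per-sample origin predictions, optionally bridged to coordinates."""

    sample_ids: list[str]
    pred_latitude: pd.Series
    pred_longitude: pd.Series
    pred_city: pd.Series | None = None
    class_probabilities: pd.DataFrame | None = None

    def frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"pred_latitude": self.pred_latitude, "pred_longitude": self.pred_longitude}
        )
        if self.pred_city is not None:
            out["pred_city"] = self.pred_city
        return out


def predict_origin(model, features, city_panel: CityPanel | None = None) -> PredictionSet:
    """Predict sample origins; classifier predictions get their city's
    panel coordinates so their MSE is comparable to regression."""
    if isinstance(model, GeoRegressionModel):
        coords = model.predict(features)
        return PredictionSet(
            sample_ids=list(coords.index),
            pred_latitude=coords["latitude"],
            pred_longitude=coords["longitude"],
        )
    proba = model.predict_proba(features)
    cities = proba.idxmax(axis=1)
    if city_panel is None:
        raise ValueError("classifier predictions need a city panel for coordinates")
    missing = sorted(set(cities) - set(city_panel.city_ids))
    if missing:
        raise ValueError(f"predicted city not in panel: {missing}")
    lat = cities.map(lambda c: city_panel.coords_of(c)[0])
    lon = cities.map(lambda c: city_panel.coords_of(c)[1])
    return PredictionSet(
        sample_ids=list(proba.index),
        pred_latitude=lat.astype(float),
        pred_longitude=lon.astype(float),
        pred_city=cities,
        class_probabilities=proba,
    )
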