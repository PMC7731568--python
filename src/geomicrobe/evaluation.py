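"""Cross-validated evaluation of geolocation models.

Two designs mirror two questions:

* **Nested K-fold CV** (outer folds stratified by city) asks how well
  samples from *pre-trained* origins are located. Each outer training
  portion fits its own feature scaler and runs its own internal CV for
  lambda selection, so no statistic leaks from the held-out fold.
* **Leave-one-city-out (L1CO) CV** asks how well samples from *new*
  origins are located: all samples of one city are held out together and
  the model never sees that city. For a classifier this makes the
  confusion-matrix diagonal structurally zero.

Scores: per-coordinate MSE in squared degrees (total = latitude +
longitude), r-squared as the squared Pearson correlation between predicted
and true values, classification accuracy, and per-city squared errors for
downstream model comparison (one-sided Wilcoxon rank-sum per city with
Benjamini-Hochberg adjustment across cities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .abundance import NormalizedTable, make_features
from .models import (
    COORD_COLUMNS,
    PredictionSet,
    compute_weights,
    fit_geo_regression,
    fit_origin_classifier,
    fit_rf_downsampled,
    predict_origin,
)
from .synthetic import CityPanel


@dataclass
class ModelSpec:
    """What to fit inside each CV training portion."""

    kind: str = "regression"  # regression | classification | rf
    n_inner_folds: int = 10
    n_lambdas: int | None = None
    grouped: bool = True
    n_trees: int = 200

    def __post_init__(self) -> None:
        if self.kind not in ("regression", "classification", "rf"):
            raise ValueError(f"unknown model kind {self.kind!r}")


@dataclass
class EvaluationResult:
    mse_latitude: float
    mse_longitude: float
    mse_total: float
    r2_latitude: float
    r2_longitude: float
    accuracy: float | None = None
    per_city_sq_errors: dict[str, pd.DataFrame] = field(default_factory=dict)
    confusion: pd.DataFrame | None = None

    def summary(self) -> dict:
        out = {
            "mse_latitude": self.mse_latitude,
            "mse_longitude": self.mse_longitude,
            "mse_total": self.mse_total,
            "r2_latitude": self.r2_latitude,
            "r2_longitude": self.r2_longitude,
        }
        if self.accuracy is not None:
            out["accuracy"] = self.accuracy
        return out


def _r2(pred: np.ndarray, truth: np.ndarray) -> float:
    """Squared Pearson correlation; 0 (with a warning) for a constant
    predictor, where the correlation is undefined."""
    scale = max(np.abs(pred).max(), np.abs(truth).max(), 1.0)
    if np.std(pred) < 1e-12 * scale or np.std(truth) < 1e-12 * scale:
        warnings.warn("constant predictions: r^2 reported as 0", stacklevel=3)
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", scipy.stats.ConstantInputWarning)
        warnings.simplefilter("ignore", scipy.stats.NearConstantInputWarning)
        r, _ = scipy.stats.pearsonr(pred, truth)
    if not np.isfinite(r):
        warnings.warn("constant predictions: r^2 reported as 0", stacklevel=3)
        return 0.0
    return float(r * r)


def score_predictions(
    pred: PredictionSet,
    truth_coords: pd.DataFrame,
    truth_cities: pd.Series | None = None,
) -> EvaluationResult:
    """Score pooled predictions against true coordinates (and cities)."""
    ids = pred.sample_ids
    missing = [s for s in ids if s not in truth_coords.index]
    if missing:
        raise ValueError(f"predictions for unknown sample(s): {missing[:5]}")
    t_lat = truth_coords.loc[ids, "latitude"].to_numpy(dtype=float)
    t_lon = truth_coords.loc[ids, "longitude"].to_numpy(dtype=float)
    p_lat = pred.pred_latitude.loc[ids].to_numpy(dtype=float)
    p_lon = pred.pred_longitude.loc[ids].to_numpy(dtype=float)
    sq_lat = (p_lat - t_lat) ** 2
    sq_lon = (p_lon - t_lon) ** 2
    mse_lat, mse_lon = float(sq_lat.mean()), float(sq_lon.mean())

    per_city: dict[str, pd.DataFrame] = {}
    accuracy = None
    confusion = None
    if truth_cities is not None:
        tc = truth_cities.loc[ids].astype(str)
        errs = pd.DataFrame(
            {"sq_latitude": sq_lat, "sq_longitude": sq_lon, "sq_total": sq_lat + sq_lon},
            index=ids,
        )
        per_city = {c: errs.loc[tc.index[tc == c]] for c in sorted(tc.unique())}
        if pred.pred_city is not None:
            pc = pred.pred_city.loc[ids].astype(str)
            accuracy = float((pc.to_numpy() == tc.to_numpy()).mean())
            confusion = pd.crosstab(pc, tc, rownames=["predicted"], colnames=["true"])
    return EvaluationResult(
        mse_latitude=mse_lat,
        mse_longitude=mse_lon,
        mse_total=mse_lat + mse_lon,
        r2_latitude=_r2(p_lat, t_lat),
        r2_longitude=_r2(p_lon, t_lon),
        accuracy=accuracy,
        per_city_sq_errors=per_city,
        confusion=confusion,
    )


def _fit_and_predict(
    spec: ModelSpec,
    norm: NormalizedTable,
    meta: pd.DataFrame,
    train_ids: list[str],
    test_ids: list[str],
    panel: CityPanel,
    seed: int | None,
) -> PredictionSet:
    """Scaler + model on the training ids only; predictions for the test ids."""
    sub = lambda ids: NormalizedTable(  # noqa: E731
        values=norm.values.loc[ids],
        scaling_factors=norm.scaling_factors[ids],
        params=norm.params,
    )
    feats_tr = make_features(sub(train_ids))
    feats_te = make_features(sub(test_ids), scaler=feats_tr.scaler)
    cities_tr = meta.loc[train_ids, "city"].astype(str)
    kw = {}
    if spec.n_lambdas is not None:
        kw["n_lambdas"] = spec.n_lambdas
    if spec.kind == "regression":
        model = fit_geo_regression(
            feats_tr,
            meta.loc[train_ids, list(COORD_COLUMNS)],
            n_folds=spec.n_inner_folds,
            seed=seed,
            groups=cities_tr,
            grouped=spec.grouped,
            **kw,
        )
        return predict_origin(model, feats_te)
    if spec.kind == "classification":
        inner = min(spec.n_inner_folds, int(cities_tr.value_counts().min()))
        model = fit_origin_classifier(
            feats_tr,
            cities_tr,
            weights=compute_weights(cities_tr),
            n_folds=inner,
            seed=seed,
            **kw,
        )
        return predict_origin(model, feats_te, city_panel=panel)
    model = fit_rf_downsampled(feats_tr, cities_tr, n_trees=spec.n_trees, seed=seed)
    return predict_origin(model, feats_te, city_panel=panel)


def _pool(parts: list[PredictionSet]) -> PredictionSet:
    ids = [s for p in parts for s in p.sample_ids]
    lat = pd.concat([p.pred_latitude for p in parts])
    lon = pd.concat([p.pred_longitude for p in parts])
    city = None
    proba = None
    if all(p.pred_city is not None for p in parts):
        city = pd.concat([p.pred_city for p in parts])
    if all(p.class_probabilities is not None for p in parts):
        proba = pd.concat([p.class_probabilities for p in parts]).fillna(0.0)
    return PredictionSet(
        sample_ids=ids,
        pred_latitude=lat,
        pred_longitude=lon,
        pred_city=city,
        class_probabilities=proba,
    )


def panel_from_metadata(meta: pd.DataFrame) -> CityPanel:
    """City panel (coordinates, continents) recovered from sample metadata."""
    agg = {"latitude": "first", "longitude": "first", "continent": "first"}
    cities = meta.groupby("city").agg(agg)
    cities["name"] = cities.index
    cities["protocol"] = "paired_150"
    cities["n_samples"] = meta.groupby("city").size()
    return CityPanel(cities)


def nested_cv(
    norm: NormalizedTable,
    meta: pd.DataFrame,
    spec: ModelSpec,
    n_outer: int = 10,
    seed: int | None = None,
) -> tuple[PredictionSet, EvaluationResult]:
    """Nested CV with city-stratified outer folds; every sample is
    predicted exactly once by a model that never saw it."""
    ids = list(norm.values.index)
    cities = meta.loc[ids, "city"].astype(str)
    counts = cities.value_counts()
    if counts.min() < 2:
        raise ValueError("every city needs at least 2 samples")
    n_eff = min(n_outer, int(counts.min()))
    if n_eff < n_outer:
        warnings.warn(
            f"reducing outer folds to {n_eff} so every city appears in every fold",
            stacklevel=2,
        )
    panel = panel_from_metadata(meta)
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=n_eff, shuffle=True, random_state=seed)
    parts = []
    for f, (tr, te) in enumerate(skf.split(np.zeros(len(ids)), cities)):
        fold_seed = None if seed is None else seed + f
        parts.append(
            _fit_and_predict(
                spec,
                norm,
                meta,
                [ids[i] for i in tr],
                [ids[i] for i in te],
                panel,
                fold_seed,
            )
        )
    pooled = _pool(parts)
    result = score_predictions(pooled, meta[list(COORD_COLUMNS)], truth_cities=meta["city"])
    return pooled, result


def l1co_cv(
    norm: NormalizedTable,
    meta: pd.DataFrame,
    spec: ModelSpec,
    seed: int | None = None,
) -> tuple[PredictionSet, EvaluationResult]:
    """Leave-one-city-out CV: each city is predicted by a model trained on
    all other cities, emulating samples from a never-sampled origin."""
    ids = list(norm.values.index)
    cities = meta.loc[ids, "city"].astype(str)
    unique = sorted(cities.unique())
    if len(unique) < 3:
        raise ValueError("leave-one-city-out needs at least 3 cities")
    panel = panel_from_metadata(meta)
    parts = []
    for k, c in enumerate(unique):
        tr = [s for s in ids if cities[s] != c]
        te = [s for s in ids if cities[s] == c]
        fold_seed = None if seed is None else seed + k
        parts.append(_fit_and_predict(spec, norm, meta, tr, te, panel, fold_seed))
    pooled = _pool(parts)
    result = score_predictions(pooled, meta[list(COORD_COLUMNS)], truth_cities=meta["city"])
    return pooled, result


def compare_models_per_city(
    sq_errors_a: dict[str, pd.DataFrame],
    sq_errors_b: dict[str, pd.DataFrame],
    column: str = "sq_total",
) -> pd.DataFrame:
    """Per-city one-sided Wilcoxon rank-sum (model a's errors smaller),
    Benjamini-Hochberg adjusted across cities."""
    rows = []
    for c in sorted(set(sq_errors_a) | set(sq_errors_b)):
        if c not in sq_errors_a or c not in sq_errors_b:
            warnings.warn(f"city {c!r} missing from one model; skipped", stacklevel=2)
            continue
        a = sq_errors_a[c][column].to_numpy()
        b = sq_errors_b[c][column].to_numpy()
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"city {c!r} has <2 samples; skipped", stacklevel=2)
            continue
        method = "exact" if (len(a) < 50 and len(b) < 50) else "asymptotic"
        res = scipy.stats.mannwhitneyu(a, b, alternative="less", method=method)
        rows.append({"city": c, "p_value": float(res.pvalue)})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.set_index("city") if len(df) else df


def continent_assessment(
    pred_city: pd.Series, true_city: pd.Series, panel: CityPanel
) -> tuple[pd.Series, float]:
    """Fraction of predictions landing on the true city's continent,
    per true city and overall."""
    known = set(panel.city_ids)
    unknown = (set(pred_city.astype(str)) | set(true_city.astype(str))) - known
    if unknown:
        raise ValueError(f"city not in panel: {sorted(unknown)}")
    cont = {c: panel.continent_of(c) for c in known}
    same = pred_city.map(cont).to_numpy() == true_city.map(cont).to_numpy()
    per_city = (
        pd.Series(same, index=true_city.to_numpy()).groupby(level=0).mean().sort_index()
    )
    return per_city, float(same.mean())
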