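"""New-origin flagging from classification prediction ambiguity.

A city classifier can only name cities it was trained on, so a sample from
a genuinely new origin is silently assigned to the nearest pre-trained
city. The flag built here exploits how *confidently* that assignment is
made: the Simpson diversity index of a sample's class-probability vector,

    s = 1 - sum_k p_k^2,

is 0 for a confident one-hot prediction and approaches 1 - 1/K for a
maximally ambiguous one (it is the Gini impurity of the probability
vector). Held-out samples from pre-trained origins (nested K-fold CV) and
from withheld origins (leave-one-city-out CV) yield two empirical Simpson
distributions; a one-dimensional kernel-density Bayes classifier over
those two distributions then turns a mystery sample's ambiguity into a
posterior probability of being from a new origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats

from .evaluation import ModelSpec, l1co_cv, nested_cv

SETTING_PRETRAINED = "pretrained_10fold"
SETTING_NEW = "new_l1co"


def simpson_ambiguity(class_probabilities) -> float:
    """Simpson diversity / Gini impurity of one probability vector."""
    p = np.asarray(class_probabilities, dtype=float)
    if (p < 0).any():
        raise ValueError("probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"probabilities sum to {p.sum():.8f}, not 1")
    return float(1.0 - np.sum(p * p))


def build_ambiguity_dataset(
    norm,
    meta: pd.DataFrame,
    spec: ModelSpec | None = None,
    seed: int | None = None,
    n_outer: int = 10,
) -> pd.DataFrame:
    """Two Simpson values per sample: one from nested CV (pre-trained
    origin), one from leave-one-city-out CV (new origin).

    Returns a DataFrame with columns sample_id, setting, simpson
    (2N records for N samples).
    """
    spec = spec or ModelSpec(kind="classification")
    if spec.kind == "regression":
        raise ValueError("ambiguity needs a probabilistic classifier")
    pred_pre, _ = nested_cv(norm, meta, spec, n_outer=n_outer, seed=seed)
    pred_new, _ = l1co_cv(norm, meta, spec, seed=None if seed is None else seed + 10_000)
    rows = []
    for setting, pred in ((SETTING_PRETRAINED, pred_pre), (SETTING_NEW, pred_new)):
        proba = pred.class_probabilities
        for sid in pred.sample_ids:
            rows.append(
                {
                    "sample_id": sid,
                    "setting": setting,
                    "simpson": simpson_ambiguity(proba.loc[sid].to_numpy()),
                }
            )
    return pd.DataFrame(rows)


def silverman_bandwidth(x: np.ndarray, fallback: float = 1e-3) -> float:
    """Silverman's rule of thumb, 0.9 min(sd, IQR/1.34) n^(-1/5)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1) if len(x) > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        warnings.warn("zero-variance group: bandwidth fallback", stacklevel=3)
        return fallback
    return float(0.9 * spread * len(x) ** (-0.2))


@dataclass
class KDE1D:
    """Gaussian-kernel density with a fixed bandwidth."""

    points: np.ndarray
    bandwidth: float

    def pdf(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        z = (x[:, None] - self.points[None, :]) / self.bandwidth
        return scipy.stats.norm.pdf(z).mean(axis=1) / self.bandwidth

    def logpdf(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        z = (x[:, None] - self.points[None, :]) / self.bandwidth
        log_kernels = -0.5 * z * z - 0.5 * np.log(2 * np.pi)
        return (
            scipy.special.logsumexp(log_kernels, axis=1)
            - np.log(len(self.points))
            - np.log(self.bandwidth)
        )


@dataclass
class NoveltyModel:
    """KDE Bayes classifier over Simpson ambiguity values."""

    kde_new: KDE1D
    kde_pretrained: KDE1D
    prior_new: float
    prior_pretrained: float
    decision_threshold: float = 0.5

    def posterior_new(self, s) -> np.ndarray:
        # log-space evaluation so far-from-support queries do not underflow
        s = np.atleast_1d(np.asarray(s, dtype=float))
        log_new = np.log(self.prior_new) + self.kde_new.logpdf(s)
        log_pre = np.log(self.prior_pretrained) + self.kde_pretrained.logpdf(s)
        return scipy.special.expit(log_new - log_pre)

    def classify(self, s) -> np.ndarray:
        return self.posterior_new(s) >= self.decision_threshold

    def to_json(self, path: str) -> None:
        import json

        payload = {
            "model": "novelty_kde_bayes",
            "kde_new": {"points": self.kde_new.points.tolist(), "bandwidth": self.kde_new.bandwidth},
            "kde_pretrained": {
                "points": self.kde_pretrained.points.tolist(),
                "bandwidth": self.kde_pretrained.bandwidth,
            },
            "prior_new": self.prior_new,
            "prior_pretrained": self.prior_pretrained,
            "decision_threshold": self.decision_threshold,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def fit_kde_bayes(
    records: pd.DataFrame,
    priors: str = "empirical",
    bandwidth_rule: str = "silverman",
    decision_threshold: float = 0.5,
) -> NoveltyModel:
    """Fit the two per-setting kernel densities and class priors.

    ``priors='empirical'`` uses the record frequencies (by construction
    near 1/2 each); ``'equal'`` forces 1/2. Simpson values are clipped to
    [0, 1] before density estimation.
    """
    if bandwidth_rule != "silverman":
        raise ValueError("only the Silverman bandwidth rule is implemented")
    new = records.loc[records["setting"] == SETTING_NEW, "simpson"].to_numpy()
    pre = records.loc[records["setting"] == SETTING_PRETRAINED, "simpson"].to_numpy()
    if len(new) < 5 or len(pre) < 5:
        raise ValueError("need at least 5 records per setting")
    new, pre = np.clip(new, 0.0, 1.0), np.clip(pre, 0.0, 1.0)
    if priors == "empirical":
        p_new = len(new) / (len(new) + len(pre))
    elif priors == "equal":
        p_new = 0.5
    else:
        raise ValueError("priors must be 'empirical' or 'equal'")
    return NoveltyModel(
        kde_new=KDE1D(new, silverman_bandwidth(new)),
        kde_pretrained=KDE1D(pre, silverman_bandwidth(pre)),
        prior_new=p_new,
        prior_pretrained=1.0 - p_new,
        decision_threshold=decision_threshold,
    )


def evaluate_novelty_loo(
    records: pd.DataFrame,
    priors: str = "empirical",
    decision_threshold: float = 0.5,
) -> dict:
    """Leave-one-out evaluation of the ambiguity classifier.

    Each record is classified by a model refit without it. Sensitivity is
    the recall of the new-origin class, specificity the recall of the
    pre-trained class; ROC points sweep the posterior threshold.
    """
    if len(records) < 10:
        raise ValueError("need at least 10 records for leave-one-out evaluation")
    records = records.reset_index(drop=True)
    posteriors = np.empty(len(records))
    for i in range(len(records)):
        rest = records.drop(index=i)
        model = fit_kde_bayes(rest, priors=priors, decision_threshold=decision_threshold)
        posteriors[i] = model.posterior_new(records.loc[i, "simpson"])[0]
    is_new = (records["setting"] == SETTING_NEW).to_numpy()
    flagged = posteriors >= decision_threshold
    sensitivity = float(flagged[is_new].mean()) if is_new.any() else np.nan
    specificity = float((~flagged[~is_new]).mean()) if (~is_new).any() else np.nan
    accuracy = float((flagged == is_new).mean())

    thresholds = np.concatenate(([-np.inf], np.unique(posteriors), [np.inf]))
    roc = []
    for t in thresholds[::-1]:
        f = posteriors >= t
        tpr = float(f[is_new].mean()) if is_new.any() else 0.0
        fpr = float(f[~is_new].mean()) if (~is_new).any() else 0.0
        roc.append((fpr, tpr))
    return {
        "accuracy": accuracy,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "posteriors": posteriors,
        "roc": np.array(roc),
    }


def flag_new_origin(
    novelty_model: NoveltyModel, origin_classifier, features
) -> pd.DataFrame:
    """Flag samples as new-origin from their classification ambiguity.

    Returns a DataFrame (sample_id index) with the Simpson index, the
    posterior probability of a new origin, and the binary flag.
    """
    proba = origin_classifier.predict_proba(features)
    simpson = proba.apply(lambda row: simpson_ambiguity(row.to_numpy()), axis=1)
    posterior = novelty_model.posterior_new(simpson.to_numpy())
    return pd.DataFrame(
        {
            "simpson": simpson,
            "posterior_new": posterior,
            "flag_new_origin": posterior >= novelty_model.decision_threshold,
        },
        index=proba.index,
    )
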