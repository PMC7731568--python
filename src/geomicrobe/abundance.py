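"""Count-table processing: sparse-taxon filtering, cumulative sum scaling,
feature construction, cross-technology comparison and ordination.

CSS (cumulative sum scaling) corrects library-size differences using only
the lower-abundant part of each sample's count distribution: for sample *j*
the scaling factor is the sum of counts at or below the chosen quantile
(default the 50th percentile of that sample's *positive* counts), so that
a handful of dominant taxa cannot drive the normalization. Normalized
values are counts / factor x ``scale_constant``.

Model features are the log2 of normalized abundance (pseudocount 1), then
per-feature z-scored with statistics estimated on training data only; the
fitted scaler is applied unchanged to test data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.spatial.distance
import scipy.stats

from .tables import TaxaCountTable

logger = logging.getLogger(__name__)


@dataclass
class NormalizationParams:
    css_percentile: float = 0.5
    scale_constant: float = 1000.0
    min_reads: int = 100
    min_samples_exceed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.css_percentile < 1.0:
            raise ValueError("css_percentile must lie strictly inside (0, 1)")
        if self.scale_constant <= 0:
            raise ValueError("scale_constant must be positive")


@dataclass
class NormalizedTable:
    values: pd.DataFrame  # samples x taxa, nonnegative reals
    scaling_factors: pd.Series  # per sample
    params: NormalizationParams

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class Scaler:
    """Per-feature standardization statistics, fit on training data only."""

    feature_ids: list[str]
    means: np.ndarray
    sds: np.ndarray
    dropped: list[str] = field(default_factory=list)


@dataclass
class FeatureMatrix:
    X: pd.DataFrame  # samples x features, z-scored log2 abundance
    scaler: Scaler

    @property
    def feature_ids(self) -> list[str]:
        return list(self.X.columns)


def filter_taxa(
    table: TaxaCountTable, min_reads: int = 100, min_samples_exceed: int = 1
) -> TaxaCountTable:
    """Keep a taxon iff strictly more than ``min_samples_exceed`` samples
    have at least ``min_reads`` of it. Samples are unchanged."""
    if min_reads < 0 or min_samples_exceed < 0:
        raise ValueError("thresholds must be non-negative")
    hits = (table.counts >= min_reads).sum(axis=0)
    keep = hits.index[hits > min_samples_exceed]
    if len(keep) == 0:
        warnings.warn("filter_taxa removed every taxon", stacklevel=2)
    return TaxaCountTable(
        counts=table.counts[keep],
        rank=table.rank,
        lineage={t: table.lineage[t] for t in keep if t in table.lineage},
    )


def css_normalize(
    table: TaxaCountTable, params: NormalizationParams | None = None
) -> NormalizedTable:
    """Cumulative-sum-scaling normalization at ``params.css_percentile``.

    Per sample: the quantile is taken over the sample's positive counts
    (linear interpolation); the scaling factor sums all counts <= that
    quantile; values are counts / factor x scale_constant. All-zero
    samples are an error.
    """
    params = params or NormalizationParams()
    counts = table.counts.to_numpy(dtype=float)
    factors = np.empty(table.n_samples)
    for j, sid in enumerate(table.sample_ids):
        row = counts[j]
        pos = row[row > 0]
        if pos.size == 0:
            raise ValueError(f"sample {sid!r} has no positive counts")
        q = np.quantile(pos, params.css_percentile)
        factors[j] = row[row <= q].sum()
    values = counts / factors[:, None] * params.scale_constant
    return NormalizedTable(
        values=pd.DataFrame(values, index=table.sample_ids, columns=table.taxon_ids),
        scaling_factors=pd.Series(factors, index=table.sample_ids),
        params=params,
    )


def make_features(
    norm_table: NormalizedTable,
    scaler: Scaler | None = None,
    pseudocount: float = 1.0,
) -> FeatureMatrix:
    """log2(normalized + pseudocount), then per-feature z-score.

    Without a scaler the statistics are fit on the input (training data),
    dropping zero-variance features; with one, the input is projected onto
    the scaler's feature set (test data), erroring on missing features.
    """
    logv = np.log2(norm_table.values.to_numpy(dtype=float) + pseudocount)
    log_df = pd.DataFrame(
        logv, index=norm_table.sample_ids, columns=norm_table.taxon_ids
    )
    if scaler is None:
        means = log_df.mean(axis=0)
        sds = log_df.std(axis=0, ddof=0)
        dropped = list(sds.index[sds <= 0])
        if dropped:
            logger.warning(
                "dropping %d zero-variance feature(s): %s", len(dropped), dropped[:5]
            )
        kept = [c for c in log_df.columns if c not in set(dropped)]
        scaler = Scaler(
            feature_ids=kept,
            means=means[kept].to_numpy(),
            sds=sds[kept].to_numpy(),
            dropped=dropped,
        )
    missing = [f for f in scaler.feature_ids if f not in log_df.columns]
    if missing:
        raise ValueError(f"input lacks scaler feature(s): {missing}")
    Z = (log_df[scaler.feature_ids].to_numpy() - scaler.means) / scaler.sds
    X = pd.DataFrame(Z, index=log_df.index, columns=scaler.feature_ids)
    return FeatureMatrix(X=X, scaler=scaler)


def overlap_summary(
    taxa_a: set[str] | list[str],
    taxa_b: set[str] | list[str],
    denominator: str = "a",
) -> tuple[int, int]:
    """Overlap count and percent (nearest whole percent) of two taxon sets,
    relative to set ``a`` or ``b``."""
    a, b = set(taxa_a), set(taxa_b)
    denom = a if denominator == "a" else b
    if denominator not in ("a", "b"):
        raise ValueError("denominator must be 'a' or 'b'")
    if not denom:
        raise ValueError("empty denominator set")
    inter = len(a & b)
    percent = int(round(100.0 * inter / len(denom)))
    return inter, percent


def correlate_technologies(
    norm_a: NormalizedTable, norm_b: NormalizedTable
) -> tuple[float, tuple[float, float]]:
    """Pearson r (with Fisher-z 95% CI) over the flattened common
    (sample, taxon) normalized abundance pairs — the non-log scale."""
    samples = [s for s in norm_a.sample_ids if s in set(norm_b.sample_ids)]
    taxa = [t for t in norm_a.taxon_ids if t in set(norm_b.taxon_ids)]
    if len(samples) < 3 or len(taxa) < 3:
        raise ValueError("need at least 3 common samples and 3 common taxa")
    x = norm_a.values.loc[samples, taxa].to_numpy().ravel()
    y = norm_b.values.loc[samples, taxa].to_numpy().ravel()
    res = scipy.stats.pearsonr(x, y)
    if np.isclose(abs(res.statistic), 1.0):
        ci = (res.statistic, res.statistic)
    else:
        lo_hi = res.confidence_interval(0.95)
        ci = (float(lo_hi.low), float(lo_hi.high))
    return float(res.statistic), ci


def bray_curtis(norm_table: NormalizedTable) -> pd.DataFrame:
    """Bray-Curtis dissimilarity matrix: d(x,y) = sum|x-y| / sum(x+y)."""
    V = norm_table.values.to_numpy(dtype=float)
    if (V < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative values")
    zero_rows = np.flatnonzero(V.sum(axis=1) == 0)
    if len(zero_rows) >= 2:
        ids = [norm_table.sample_ids[i] for i in zero_rows]
        raise ValueError(f"Bray-Curtis undefined between all-zero samples: {ids}")
    D = scipy.spatial.distance.squareform(
        scipy.spatial.distance.pdist(V, metric="braycurtis")
    )
    return pd.DataFrame(D, index=norm_table.sample_ids, columns=norm_table.sample_ids)


def _gower_center(A: np.ndarray) -> np.ndarray:
    n = A.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ A @ J


def cailliez_constant(D: np.ndarray, tol: float = 1e-8) -> float:
    """Smallest additive constant making D + c (off-diagonal) Euclidean.

    Computed as the largest real eigenvalue of the 2n x 2n block matrix
    [[0, 2*D1], [-I, -4*D2]] with D1 = Gower-centered -(1/2) D^2 and
    D2 = Gower-centered -(1/2) D.
    """
    n = D.shape[0]
    B = _gower_center(D * D)
    eigvals = scipy.linalg.eigvalsh(B)
    if eigvals.min() >= -tol * max(1.0, abs(eigvals).max()):
        return 0.0
    delta1 = B
    delta2 = _gower_center(D)
    block = np.block(
        [[np.zeros((n, n)), 2.0 * delta1], [-np.eye(n), -4.0 * delta2]]
    )
    ev = scipy.linalg.eigvals(block)
    real = ev.real[np.abs(ev.imag) < 1e-8]
    return float(max(real.max(), 0.0))


def pcoa_cailliez(
    dissimilarity: pd.DataFrame | np.ndarray, eig_tol: float = 1e-9
) -> tuple[pd.DataFrame, np.ndarray, float]:
    """Principal coordinate analysis with the Cailliez correction.

    Returns (coordinates, explained-variance fractions, correction
    constant). When the input is non-Euclidean the constant c is added to
    every off-diagonal dissimilarity before classical scaling, so all
    corrected eigenvalues are nonnegative and pairwise distances in the
    full coordinate space reproduce the corrected dissimilarities.
    """
    if isinstance(dissimilarity, pd.DataFrame):
        ids = list(dissimilarity.index)
        D = dissimilarity.to_numpy(dtype=float)
    else:
        D = np.asarray(dissimilarity, dtype=float)
        ids = [f"s{i}" for i in range(D.shape[0])]
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    c = cailliez_constant(D)
    if c > 0:
        D = D + c
        np.fill_diagonal(D, 0.0)
    B = _gower_center(D * D)
    eigvals, eigvecs = scipy.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = max(1.0, abs(eigvals).max())
    pos = eigvals > eig_tol * scale
    lam = eigvals[pos]
    coords = eigvecs[:, pos] * np.sqrt(lam)
    total = eigvals[eigvals > 0].sum()
    explained = lam / total if total > 0 else np.zeros_like(lam)
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=ids, columns=axes), explained, c


def threshold_sweep(
    table_a: TaxaCountTable,
    table_b: TaxaCountTable,
    thresholds: list[int],
    min_sample_settings: list[int],
    params: NormalizationParams | None = None,
) -> pd.DataFrame:
    """Read-count threshold evaluation: for each (threshold, min-sample)
    setting, the number of table-a taxa surviving the filter and the
    cross-table Pearson r over the surviving common taxa."""
    if len(thresholds) == 0:
        raise ValueError("no thresholds given")
    if sorted(thresholds) != list(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    params = params or NormalizationParams()
    norm_b = css_normalize(table_b, params)
    rows = []
    for m in min_sample_settings:
        for t in thresholds:
            filt = filter_taxa(table_a, min_reads=t, min_samples_exceed=m)
            n_taxa = filt.n_taxa
            r = np.nan
            common_t = [x for x in filt.taxon_ids if x in set(table_b.taxon_ids)]
            common_s = [s for s in filt.sample_ids if s in set(table_b.sample_ids)]
            if n_taxa > 0 and len(common_t) >= 3 and len(common_s) >= 3:
                norm_a = css_normalize(filt, params)
                sub_a = NormalizedTable(
                    values=norm_a.values.loc[common_s, common_t],
                    scaling_factors=norm_a.scaling_factors[common_s],
                    params=params,
                )
                sub_b = NormalizedTable(
                    values=norm_b.values.loc[common_s, common_t],
                    scaling_factors=norm_b.scaling_factors[common_s],
                    params=params,
                )
                r, _ = correlate_technologies(sub_a, sub_b)
            rows.append(
                {
                    "min_reads": t,
                    "min_samples_exceed": m,
                    "n_taxa": n_taxa,
                    "pearson_r": r,
                }
            )
    return pd.DataFrame(rows)
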