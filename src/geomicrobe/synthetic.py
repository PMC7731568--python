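"""City-structured synthetic microbiome count data with known geographic signal.

The generator emulates the structure of an urban-microbiome source-attribution
study: a panel of training cities plus a held-out "mystery" panel of new
cities, a species-level count table whose informative taxa carry planted
log2-linear latitude/longitude gradients on top of city-specific signatures,
over-dispersed counts with variable library sizes and zero inflation, and an
optional single-end "protocol batch" city whose counts carry a systematic
shift on a random half of taxa.

The planted model for taxon *t* in a sample from city *c* is

    log2 intensity  mu_tc = baseline_t + b_lat,t * lat_c + b_lon,t * lon_c
                            + cityeffect_tc,

with cityeffect_tc ~ N(0, city_effect_sd) drawn once per (taxon, city).
Intensities are converted to per-sample multinomial-like expectations by
closing to the sampled library size; counts are negative binomial around
that expectation and independently zeroed with probability
``zero_inflation_prob`` (applied before library scaling, so zeroed taxa
free up reads for the rest).

Everything is deterministic under the seed, including the random nesting of
species into genera and families.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .tables import RANKS, TaxaCountTable

_CONTINENT_LON_EDGES = (-180.0, -60.0, 60.0, 180.0)


@dataclass
class CityPanel:
    """A set of cities with coordinates, continent labels and protocols."""

    cities: pd.DataFrame  # index city_id; name, latitude, longitude, continent, protocol, n_samples

    def __post_init__(self) -> None:
        required = {"name", "latitude", "longitude", "continent", "protocol", "n_samples"}
        missing = required - set(self.cities.columns)
        if missing:
            raise ValueError(f"city panel missing column(s) {sorted(missing)}")
        if self.cities.index.duplicated().any():
            raise ValueError("city ids must be unique")
        lat = self.cities["latitude"]
        lon = self.cities["longitude"]
        if (lat.abs() > 90).any() or (lon.abs() > 180).any():
            raise ValueError("coordinates outside [-90, 90] x [-180, 180]")

    @property
    def city_ids(self) -> list[str]:
        return list(self.cities.index)

    @property
    def n_cities(self) -> int:
        return len(self.cities)

    @property
    def total_samples(self) -> int:
        return int(self.cities["n_samples"].sum())

    def coords_of(self, city_id: str) -> tuple[float, float]:
        row = self.cities.loc[city_id]
        return float(row["latitude"]), float(row["longitude"])

    def continent_of(self, city_id: str) -> str:
        return str(self.cities.loc[city_id, "continent"])


@dataclass
class SyntheticTruth:
    """Ground-truth parameters of the generative model."""

    informative_taxa: list[str]
    latitude_slopes: dict[str, float]
    longitude_slopes: dict[str, float]
    city_effect_sd: float = 0.5
    zero_inflation_prob: float = 0.1
    library_size_range: tuple[int, int] = (50_000, 150_000)
    batch_shift: float = 2.0
    dispersion: float = 0.5
    n_species: int = 200
    n_genera: int = 60
    n_families: int = 25
    seed: int = 0
    baseline_log2_sd: float = 1.0

    def __post_init__(self) -> None:
        for t in self.informative_taxa:
            if not np.isfinite(self.latitude_slopes.get(t, 0.0)):
                raise ValueError(f"non-finite latitude slope for {t}")
            if not np.isfinite(self.longitude_slopes.get(t, 0.0)):
                raise ValueError(f"non-finite longitude slope for {t}")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("library_size_range must be a positive, ordered pair")
        if not 0.0 <= self.zero_inflation_prob <= 1.0:
            raise ValueError("zero_inflation_prob must be in [0, 1]")

    def to_json(self, path: str) -> None:
        payload = asdict(self)
        payload["library_size_range"] = list(self.library_size_range)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def default_truth(
    seed: int,
    n_species: int = 200,
    n_informative: int = 10,
    lat_slope: float = 0.05,
    lon_slope: float = 0.02,
    city_effect_sd: float = 0.5,
    zero_inflation_prob: float = 0.1,
    library_size_range: tuple[int, int] = (50_000, 150_000),
    batch_shift: float = 2.0,
) -> SyntheticTruth:
    """Standard study conditions: 200 species, 10 informative taxa with
    latitude slopes of +/-0.05 log2 units per degree (longitude +/-0.02,
    scaled for the wider coordinate range)."""
    rng = np.random.default_rng(seed)
    taxa = [f"s{i:03d}" for i in range(n_species)]
    informative = list(rng.choice(taxa, size=n_informative, replace=False))
    signs = rng.choice([-1.0, 1.0], size=n_informative)
    lat_slopes = {t: float(s * lat_slope) for t, s in zip(informative, signs)}
    lon_signs = rng.choice([-1.0, 1.0], size=n_informative)
    lon_slopes = {t: float(s * lon_slope) for t, s in zip(informative, lon_signs)}
    return SyntheticTruth(
        informative_taxa=informative,
        latitude_slopes=lat_slopes,
        longitude_slopes=lon_slopes,
        city_effect_sd=city_effect_sd,
        zero_inflation_prob=zero_inflation_prob,
        library_size_range=library_size_range,
        batch_shift=batch_shift,
        n_species=n_species,
        seed=seed,
    )


def _continent(lat: float, lon: float) -> str:
    """Assign one of six longitude-thirds x latitude-halves blocks."""
    ns = "N" if lat >= 0 else "S"
    for i in range(3):
        if lon <= _CONTINENT_LON_EDGES[i + 1]:
            return f"{ns}{i}"
    return f"{ns}2"


def generate_world(
    n_train_cities: int,
    n_mystery_cities: int,
    samples_per_city: int,
    seed: int,
    include_single_end: bool = False,
) -> tuple[CityPanel, CityPanel]:
    """Draw disjoint training and mystery city panels over the globe.

    Latitudes are drawn in [-55, 65] (the inhabited band), longitudes over
    the full circle. With ``include_single_end`` the last city of *each*
    panel is marked ``single_125`` (protocol heterogeneity exists on both
    sides of the train/mystery split, as in multi-center studies); all
    others are ``paired_150``.
    """
    if n_train_cities < 3:
        raise ValueError("need at least 3 training cities")
    if n_mystery_cities < 1:
        raise ValueError("need at least 1 mystery city")
    if samples_per_city < 2:
        raise ValueError("need at least 2 samples per city")
    rng = np.random.default_rng(seed)
    n = n_train_cities + n_mystery_cities
    lat = rng.uniform(-55.0, 65.0, size=n)
    lon = rng.uniform(-180.0, 180.0, size=n)

    def build(idx: range, prefix: str, offset: int) -> CityPanel:
        n_panel = len(idx)
        rows = []
        for k, i in enumerate(idx):
            cid = f"{prefix}{k:02d}"
            protocol = "paired_150"
            if include_single_end and k == n_panel - 1:
                protocol = "single_125"
            rows.append(
                {
                    "city_id": cid,
                    "name": f"city-{prefix}{k:02d}",
                    "latitude": float(lat[i]),
                    "longitude": float(lon[i]),
                    "continent": _continent(lat[i], lon[i]),
                    "protocol": protocol,
                    "n_samples": samples_per_city,
                }
            )
        return CityPanel(pd.DataFrame(rows).set_index("city_id"))

    train = build(range(n_train_cities), "C", 0)
    mystery = build(range(n_train_cities, n), "M", n_train_cities)
    return train, mystery


def _taxonomy(truth: SyntheticTruth) -> dict[str, str]:
    """Random fixed nesting of species into genera and families under the seed."""
    rng = np.random.default_rng([truth.seed, 0xA11])
    genus_of = rng.integers(0, truth.n_genera, size=truth.n_species)
    family_of_genus = rng.integers(0, truth.n_families, size=truth.n_genera)
    lineage = {}
    for i in range(truth.n_species):
        g = genus_of[i]
        f = family_of_genus[g]
        lineage[f"s{i:03d}"] = f"f{f:02d}|g{g:02d}|s{i:03d}"
    return lineage


def _stable_city_key(city_id: str) -> int:
    return zlib.crc32(city_id.encode())


def _expected_log2(truth: SyntheticTruth, taxa: list[str], panel: CityPanel) -> pd.DataFrame:
    """Per (city, taxon) expected log2 intensity before sampling noise."""
    rng = np.random.default_rng([truth.seed, 0xBA5E])
    baseline = rng.normal(0.0, truth.baseline_log2_sd, size=len(taxa))
    mu = pd.DataFrame(
        np.tile(baseline, (panel.n_cities, 1)),
        index=panel.city_ids,
        columns=taxa,
    )
    for t in truth.informative_taxa:
        if t not in mu.columns:
            raise ValueError(f"truth references unknown taxon {t!r}")
        b_lat = truth.latitude_slopes.get(t, 0.0)
        b_lon = truth.longitude_slopes.get(t, 0.0)
        mu[t] = mu[t] + b_lat * panel.cities["latitude"] + b_lon * panel.cities["longitude"]
    if truth.city_effect_sd > 0:
        for c in panel.city_ids:
            crng = np.random.default_rng([truth.seed, 0xC17E, _stable_city_key(c)])
            mu.loc[c] += crng.normal(0.0, truth.city_effect_sd, size=len(taxa))
    return mu


def _sample_counts(
    mu_city: np.ndarray,
    n_samples: int,
    truth: SyntheticTruth,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw NB counts around library-scaled intensities with zero inflation."""
    p = truth.n_species
    counts = np.zeros((n_samples, p), dtype=np.int64)
    lo, hi = truth.library_size_range
    for i in range(n_samples):
        intensity = np.exp2(mu_city)
        if truth.zero_inflation_prob > 0:
            dropped = rng.random(p) < truth.zero_inflation_prob
            intensity = np.where(dropped, 0.0, intensity)
        total = intensity.sum()
        if total == 0:
            continue
        lib = rng.integers(lo, hi + 1)
        mean = lib * intensity / total
        if truth.dispersion > 0:
            size = 1.0 / truth.dispersion
            with np.errstate(divide="ignore", invalid="ignore"):
                prob = size / (size + mean)
            draw = np.where(
                mean > 0, rng.negative_binomial(size, np.clip(prob, 1e-12, 1.0)), 0
            )
        else:
            draw = np.where(mean > 0, rng.poisson(mean), 0)
        counts[i] = draw
    return counts


def generate_counts(
    panel: CityPanel,
    truth: SyntheticTruth,
    batch: bool = False,
) -> tuple[TaxaCountTable, TaxaCountTable, TaxaCountTable]:
    """Generate species counts for a panel plus exact genus/family roll-ups.

    Returns ``(species, genus, family)`` tables. Sample ids are
    ``{city_id}_{k:02d}``. With ``batch=True`` the panel must contain
    exactly one ``single_125`` city; see :func:`generate_batch_city`.
    """
    if panel.n_cities == 0:
        raise ValueError("empty city panel")
    taxa = [f"s{i:03d}" for i in range(truth.n_species)]
    for t in truth.informative_taxa:
        if t not in taxa:
            raise ValueError(f"truth references unknown taxon {t!r}")
    lineage = _taxonomy(truth)
    mu = _expected_log2(truth, taxa, panel)

    batch_city = None
    if batch:
        single = panel.cities.index[panel.cities["protocol"] == "single_125"]
        if len(single) != 1:
            raise ValueError(
                f"batch generation requires exactly one single_125 city, found {len(single)}"
            )
        batch_city = single[0]
        shift_rng = np.random.default_rng([truth.seed, 0x5417])
        shifted = shift_rng.random(truth.n_species) < 0.5
        mu.loc[batch_city] = mu.loc[batch_city] + truth.batch_shift * shifted

    blocks = []
    sample_ids = []
    for c in panel.city_ids:
        n_c = int(panel.cities.loc[c, "n_samples"])
        crng = np.random.default_rng([truth.seed, 0xD0, _stable_city_key(c)])
        blocks.append(_sample_counts(mu.loc[c].to_numpy(), n_c, truth, crng))
        sample_ids.extend(f"{c}_{k:02d}" for k in range(n_c))
    counts = pd.DataFrame(np.vstack(blocks), index=sample_ids, columns=taxa)
    species = TaxaCountTable(counts=counts, rank="species", lineage=lineage)
    genus = species.aggregate("genus")
    family = species.aggregate("family")
    return species, genus, family


def generate_batch_city(panel: CityPanel, truth: SyntheticTruth) -> TaxaCountTable:
    """Species counts for a panel whose single-end city carries a protocol
    artifact: ``truth.batch_shift`` log2 units added to a random half of taxa
    before sampling. Errors unless exactly one panel city is ``single_125``."""
    species, _, _ = generate_counts(panel, truth, batch=True)
    return species


def panel_metadata(panel: CityPanel) -> pd.DataFrame:
    """Per-sample metadata table matching :func:`generate_counts` sample ids."""
    rows = []
    for c in panel.city_ids:
        info = panel.cities.loc[c]
        for k in range(int(info["n_samples"])):
            rows.append(
                {
                    "sample_id": f"{c}_{k:02d}",
                    "city": c,
                    "latitude": float(info["latitude"]),
                    "longitude": float(info["longitude"]),
                    "continent": info["continent"],
                    "paired_end": info["protocol"] == "paired_150",
                    "read_length_bp": 150 if info["protocol"] == "paired_150" else 125,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")
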