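import numpy as np
import pandas as pd
import pytest

import geomicrobe as gm


@pytest.fixture(scope="session")
def small_world():
    """A compact city-structured dataset used across CV-heavy tests:
    8 training cities x 10 samples, 120 species, default signal."""
    truth = gm.default_truth(seed=7, n_species=120)
    train, mystery = gm.generate_world(8, 4, 10, seed=7)
    species, genus, family = gm.generate_counts(train, truth)
    meta = gm.panel_metadata(train)
    return {
        "truth": truth,
        "train": train,
        "mystery": mystery,
        "species": species,
        "genus": genus,
        "family": family,
        "meta": meta,
    }


@pytest.fixture(scope="session")
def small_norm(small_world):
    filtered = gm.filter_taxa(small_world["species"], min_reads=100, min_samples_exceed=8)
    return gm.css_normalize(filtered)


@pytest.fixture(scope="session")
def small_features(small_norm):
    return gm.make_features(small_norm)


@pytest.fixture(scope="session")
def strong_city_norm():
    """Same world shape but with strong city signatures
    (city_effect_sd=1.5), the regime where pre-trained origins are
    classified confidently — required for ambiguity-based flagging."""
    truth = gm.default_truth(seed=7, n_species=120, city_effect_sd=1.5)
    train, _ = gm.generate_world(8, 4, 10, seed=7)
    species, _, _ = gm.generate_counts(train, truth)
    meta = gm.panel_metadata(train)
    filtered = gm.filter_taxa(species, min_reads=100, min_samples_exceed=8)
    return gm.css_normalize(filtered), meta


@pytest.fixture
def toy_counts():
    """5 samples x 6 taxa with lineage, hand-checkable."""
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.integers(0, 500, size=(5, 6)),
        index=[f"samp{i}" for i in range(5)],
        columns=[f"s{i:03d}" for i in range(6)],
    )
    lineage = {
        "s000": "f00|g00|s000",
        "s001": "f00|g00|s001",
        "s002": "f00|g01|s002",
        "s003": "f01|g02|s003",
        "s004": "f01|g02|s004",
        "s005": "f01|g03|s005",
    }
    return gm.TaxaCountTable(counts=counts, rank="species", lineage=lineage)
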