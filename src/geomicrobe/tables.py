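"""Taxa-by-sample count tables and their on-disk formats.

The central container is :class:`TaxaCountTable`: an integer count matrix
(samples x taxa) at a single taxonomic rank, with an optional lineage
string per taxon (pipe-separated ancestor ids, e.g. ``"f03|g21|s105"``)
that supports exact roll-up to coarser ranks.

Supported text formats:

* wide TSV — rows are taxa (``taxon_id``, ``lineage``, then one column per
  sample); the generic interchange format written by the simulator.
* Bracken per-sample reports — one TSV per sample with the standard
  Bracken columns; the ``new_est_reads`` column supplies the counts.
"""

from __future__ import annotations

import glob
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RANKS = ("species", "genus", "family", "order", "class", "phylum")

#: Bracken report header, in file order.
BRACKEN_COLUMNS = (
    "name",
    "taxonomy_id",
    "taxonomy_lvl",
    "kraken_assigned_reads",
    "added_reads",
    "new_est_reads",
    "fraction_total_reads",
)

_RANK_TO_LVL = {
    "species": "S",
    "genus": "G",
    "family": "F",
    "order": "O",
    "class": "C",
    "phylum": "P",
}


class FormatError(ValueError):
    """Raised when an input file does not match its declared format."""


@dataclass
class TaxaCountTable:
    """Integer count matrix at one taxonomic rank.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, index = sample ids,
        columns = taxon ids.
    rank
        Taxonomic rank of the columns; one of :data:`RANKS`.
    lineage
        Optional mapping taxon id -> pipe-separated lineage string whose
        last element is the taxon id itself.
    """

    counts: pd.DataFrame
    rank: str = "species"
    lineage: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}; expected one of {RANKS}")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate taxon ids: {dup}")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("count table contains negative entries")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def parent_ids(self) -> pd.Series:
        """Parent taxon id of every column, from the lineage strings."""
        parents = {}
        for t in self.counts.columns:
            lin = self.lineage.get(t)
            if lin is None or "|" not in lin:
                raise ValueError(f"taxon {t!r} has no parent lineage")
            parents[t] = lin.split("|")[-2]
        return pd.Series(parents)

    def aggregate(self, to_rank: str) -> "TaxaCountTable":
        """Roll counts up to a coarser rank by exact column sums.

        Requires lineage strings deep enough to reach ``to_rank``.
        Total counts are conserved exactly.
        """
        i_from, i_to = RANKS.index(self.rank), RANKS.index(to_rank)
        if i_to < i_from:
            raise ValueError(f"cannot aggregate {self.rank} down to {to_rank}")
        if i_to == i_from:
            return self
        table = self
        for _ in range(i_to - i_from):
            parents = table.parent_ids()
            grouped = table.counts.T.groupby(parents.reindex(table.counts.columns)).sum().T
            new_lineage = {}
            for t, lin in table.lineage.items():
                parts = lin.split("|")
                if len(parts) >= 2:
                    new_lineage[parts[-2]] = "|".join(parts[:-1])
            table = TaxaCountTable(
                counts=grouped,
                rank=RANKS[RANKS.index(table.rank) + 1],
                lineage=new_lineage,
            )
        return table

    # -- IO -------------------------------------------------------------

    def to_wide_tsv(self, path: str | os.PathLike) -> None:
        """Write as wide TSV: rows = taxa, columns = samples."""
        out = self.counts.T
        out.insert(0, "lineage", [self.lineage.get(t, t) for t in out.index])
        out.index.name = "taxon_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_wide_tsv(cls, path: str | os.PathLike, rank: str = "species") -> "TaxaCountTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if "lineage" not in df.columns:
            raise FormatError(f"{path}: wide TSV is missing the 'lineage' column")
        lineage = df["lineage"].astype(str).to_dict()
        counts = df.drop(columns="lineage").T
        counts = counts.astype(np.int64, errors="ignore")
        return cls(counts=counts, rank=rank, lineage=lineage)


def load_bracken_reports(
    paths: list[str], rank: str = "species"
) -> TaxaCountTable:
    """Assemble per-sample Bracken reports into one count table.

    Each file contributes one sample (named after the file stem); the
    union of taxa is taken, with zeros for taxa absent from a sample.
    Counts come from ``new_est_reads``, Bracken's re-estimated abundance.
    """
    lvl = _RANK_TO_LVL[rank]
    columns: dict[str, pd.Series] = {}
    for path in paths:
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in BRACKEN_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(
                f"{path}: not a Bracken report, missing column(s) {missing}"
            )
        df = df[df["taxonomy_lvl"].astype(str).str.strip() == lvl]
        sample = os.path.splitext(os.path.basename(path))[0]
        counts = df.set_index("name")["new_est_reads"]
        if (counts < 0).any():
            raise ValueError(f"{path}: negative count for sample {sample!r}")
        columns[sample] = counts
    if not columns:
        raise FormatError("no Bracken reports given")
    table = pd.DataFrame(columns).fillna(0).astype(np.int64).T
    return TaxaCountTable(counts=table, rank=rank, lineage={})


def load_abundance(
    path: str | os.PathLike | list[str],
    format: str = "wide_tsv",
    rank: str = "species",
) -> TaxaCountTable:
    """Load a count table from disk.

    ``format='bracken_reports'`` accepts a directory, a glob-expandable
    path, or an explicit list of per-sample report files.
    ``format='wide_tsv'`` accepts a single wide TSV matrix.
    """
    if format == "wide_tsv":
        return TaxaCountTable.from_wide_tsv(path, rank=rank)
    if format == "bracken_reports":
        if isinstance(path, (list, tuple)):
            files = [str(p) for p in path]
        elif os.path.isdir(path):
            files = sorted(
                glob.glob(os.path.join(str(path), "*.tsv"))
                + glob.glob(os.path.join(str(path), "*.bracken"))
            )
        else:
            files = sorted(glob.glob(str(path)))
        if not files:
            raise FormatError(f"no Bracken report files found at {path}")
        return load_bracken_reports(files, rank=rank)
    raise ValueError(f"unknown format {format!r}")


def load_metadata(path: str | os.PathLike) -> pd.DataFrame:
    """Read the sample metadata CSV (sample_id, city, latitude, longitude,
    continent, paired_end, read_length_bp), indexed by sample_id."""
    meta = pd.read_csv(path)
    required = {"sample_id", "city", "latitude", "longitude", "continent"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"{path}: metadata is missing column(s) {sorted(missing)}")
    return meta.set_index("sample_id")
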