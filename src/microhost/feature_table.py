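"""Feature tables (samples x taxa read counts) and sample metadata.

The canonical on-disk format is TSV: feature tables have sample ids in the
first column and semicolon-delimited lineages as column headers; metadata
tables carry ``sample_id``, ``host``, ``species`` and ``project_id``.
Counts are kept as integers; relative abundances are derived on demand so
that a table is never normalized twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .taxonomy import RANKS, SEP, Lineage, rank_depth

HOSTS = ("pet", "human")
SPECIES = ("cat", "dog", "human")
#: species -> host class implied by it
SPECIES_HOST = {"cat": "pet", "dog": "pet", "human": "human"}

METADATA_COLUMNS = ("sample_id", "host", "species", "project_id")


@dataclass
class FeatureTable:
    """A samples x taxa matrix of non-negative integer read counts.

    Columns of ``counts`` are serialized lineages truncated to ``level``;
    the index holds sample ids.
    """

    counts: pd.DataFrame
    level: str = "genus"
    lineages: list[Lineage] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        depth = rank_depth(self.level)  # validates the level
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate taxa at level {self.level}: {dups}")
        arr = self.counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts are not allowed")
        self.lineages = [Lineage.parse(c, level=self.level) for c in self.counts.columns]
        del depth

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample fractions of the sample's total reads."""
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            empty = totals.index[totals == 0].tolist()
            raise ValueError(f"samples with zero total reads: {empty}")
        return self.counts.div(totals, axis=0)

    def subset_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self.counts.loc[list(sample_ids)].copy(), self.level)

    def subset_taxa(self, taxa) -> "FeatureTable":
        return FeatureTable(self.counts.loc[:, list(taxa)].copy(), self.level)


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a metadata table.

    Accepts ``sample_id`` either as a column or as the index; returns a
    copy indexed by sample id with columns host/species/project_id.
    """
    md = metadata.copy()
    if "sample_id" in md.columns:
        md = md.set_index("sample_id")
    md.index = md.index.astype(str)
    missing = [c for c in ("host", "species", "project_id") if c not in md.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if md.index.has_duplicates:
        dups = md.index[md.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dups}")
    bad_host = set(md["host"]) - set(HOSTS)
    if bad_host:
        raise ValueError(f"unknown host classes {sorted(bad_host)}; expected {HOSTS}")
    bad_sp = set(md["species"]) - set(SPECIES)
    if bad_sp:
        raise ValueError(f"unknown species {sorted(bad_sp)}; expected {SPECIES}")
    implied = md["species"].map(SPECIES_HOST)
    mismatch = md.index[implied != md["host"]].tolist()
    if mismatch:
        raise ValueError(f"host inconsistent with species for samples: {mismatch}")
    return md[["host", "species", "project_id"]]


def align(table: FeatureTable, metadata: pd.DataFrame) -> None:
    """Raise if the table and metadata do not cover exactly the same samples."""
    t = set(table.sample_ids)
    m = set(metadata.index)
    only_t = sorted(t - m)
    only_m = sorted(m - t)
    if only_t or only_m:
        raise ValueError(
            f"sample sets differ: {only_t} only in feature table, {only_m} only in metadata"
        )


def read_feature_table(path, metadata_path) -> tuple[FeatureTable, pd.DataFrame]:
    """Read an aligned feature table + metadata pair from TSV files."""
    counts = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    counts.index = counts.index.astype(str)
    level = RANKS[len(counts.columns[0].split(SEP)) - 1] if len(counts.columns) else "genus"
    table = FeatureTable(counts, level=level)
    metadata = validate_metadata(pd.read_csv(metadata_path, sep="\t", comment="#"))
    align(table, metadata)
    return table, metadata.loc[table.sample_ids]


def write_feature_table(table: FeatureTable, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.counts.to_csv(path, sep="\t", index_label="sample_id")


def write_metadata(metadata: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    validate_metadata(metadata).to_csv(path, sep="\t", index_label="sample_id")


def aggregate_to_level(table: FeatureTable, level: str) -> FeatureTable:
    """Collapse a table to a higher rank by summing counts over lineage prefixes.

    Output taxa appear in order of first occurrence of each prefix, so
    aggregation is deterministic and per-sample totals are conserved.
    """
    k_from = rank_depth(table.level)
    k_to = rank_depth(level)
    if k_to > k_from:
        raise ValueError(
            f"cannot aggregate a {table.level}-level table down to {level}"
        )
    if k_to == k_from:
        return FeatureTable(table.counts.copy(), table.level)
    prefixes = [str(lin.truncate(level)) for lin in table.lineages]
    grouped = table.counts.T.groupby(pd.Index(prefixes, name="taxon"), sort=False).sum().T
    return FeatureTable(grouped, level)


def filter_rare(
    table: FeatureTable, metadata: pd.DataFrame, zero_fraction_threshold: float = 0.9
) -> FeatureTable:
    """Drop taxa that are near-universally absent in BOTH host classes.

    A taxon is removed iff the fraction of samples with zero reads is
    strictly greater than the threshold within the pet class and strictly
    greater within the human class.  Retained taxa keep their input order.
    """
    if not 0.0 <= zero_fraction_threshold <= 1.0:
        raise ValueError(f"threshold must be in [0,1], got {zero_fraction_threshold}")
    align(table, metadata)
    md = metadata.loc[table.sample_ids]
    rare_in_all = np.ones(table.n_taxa, dtype=bool)
    for host in HOSTS:
        ids = md.index[md["host"] == host]
        if len(ids) == 0:
            raise ValueError(f"no samples of host class {host!r}")
        zero_frac = (table.counts.loc[ids] == 0).mean(axis=0).to_numpy()
        rare_in_all &= zero_frac > zero_fraction_threshold
    kept = table.counts.columns[~rare_in_all]
    return table.subset_taxa(kept)
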