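"""Reading/writing count, metadata and trait tables, and city-year grouping.

On-disk conventions: all tables are plain TSV.  Count tables have samples as
rows (first column ``sample_id``) and rank-prefixed taxa (``o__``, ``f__``,
``s__``) as columns.  Metadata tables carry ``sample_id``, ``city`` and
``year``.  The unit of classification throughout the package is the
*city-year group* — samples collected in the same city but in different years
are deliberately treated as distinct classes to absorb batch effects — with
labels formatted ``CITY_YY`` (e.g. ``NYC_16``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

RANK_PREFIXES = {"order": "o__", "family": "f__", "species": "s__"}


@dataclass
class OtuTable:
    """Non-negative integer count matrix, samples x taxa."""

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray  # shape (n_samples, n_taxa), integer dtype

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValueError("duplicate taxon ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.isfinite(self.counts)):
                raise ValueError("counts must be finite")
            if not np.all(self.counts == np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.taxon_ids,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OtuTable":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy())

    def taxa_at_rank(self, rank: str) -> list[str]:
        """Taxon ids carrying the given rank's prefix (order/family/species)."""
        prefix = RANK_PREFIXES[rank]
        return [t for t in self.taxon_ids if t.startswith(prefix)]

    def subset_samples(self, keep: list[str]) -> "OtuTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in keep]
        return OtuTable(list(keep), list(self.taxon_ids), self.counts[idx])

    def subset_taxa(self, keep: list[str]) -> "OtuTable":
        pos = {t: j for j, t in enumerate(self.taxon_ids)}
        idx = [pos[t] for t in keep]
        return OtuTable(list(self.sample_ids), list(keep), self.counts[:, idx])


@dataclass
class GroupIndex:
    """Ordered city-year groups partitioning the samples."""

    groups: list[str]
    members: dict[str, list[str]]
    group_meta: dict[str, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        all_members = [s for g in self.groups for s in self.members[g]]
        if len(all_members) != len(set(all_members)):
            raise ValueError("groups do not partition the samples")

    @property
    def n_samples(self) -> int:
        return sum(len(self.members[g]) for g in self.groups)

    @property
    def group_of(self) -> dict[str, str]:
        return {s: g for g in self.groups for s in self.members[g]}

    def labels_for(self, sample_ids: list[str]) -> pd.Series:
        gof = self.group_of
        return pd.Series([gof[s] for s in sample_ids], index=sample_ids)

    def restrict(self, sample_ids: list[str]) -> "GroupIndex":
        keep = set(sample_ids)
        members = {g: [s for s in self.members[g] if s in keep]
                   for g in self.groups}
        groups = [g for g in self.groups if members[g]]
        return GroupIndex(groups, {g: members[g] for g in groups},
                          {g: self.group_meta.get(g, _parse_group(g))
                           for g in groups})


def group_label(city: str, year: int) -> str:
    return f"{city}_{int(year) % 100:02d}"


def _parse_group(label: str) -> tuple[str, int]:
    city, yy = label.rsplit("_", 1)
    return city, 2000 + int(yy)


def read_counts(path: str | Path) -> OtuTable:
    """Read a samples x taxa TSV count table, validating every cell.

    Negative, missing or non-numeric entries raise a ValueError naming the
    offending sample/taxon cell.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | ~np.isfinite(numeric)
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric or missing count at sample {df.index[i]!r}, "
            f"taxon {df.columns[j]!r}: {df.iat[i, j]!r}"
        )
    neg = numeric.to_numpy() < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValueError(
            f"negative count at sample {df.index[i]!r}, taxon {df.columns[j]!r}"
        )
    return OtuTable.from_frame(numeric.astype(np.int64))


def write_counts(table: OtuTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "city": str})
    return attach_group_labels(meta)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def attach_group_labels(meta: pd.DataFrame) -> pd.DataFrame:
    """Add/refresh the derived ``group`` = CITY_YY column."""
    required = {"sample_id", "city", "year"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if meta["city"].isna().any() or meta["year"].isna().any():
        bad = meta.loc[meta["city"].isna() | meta["year"].isna(), "sample_id"]
        raise ValueError(f"missing city/year for samples: {list(bad)[:5]}")
    meta = meta.copy()
    meta["year"] = meta["year"].astype(int)
    meta["group"] = [group_label(c, y) for c, y in zip(meta["city"], meta["year"])]
    return meta


def build_group_index(meta: pd.DataFrame) -> GroupIndex:
    """One group per distinct (city, year) pair, ordered lexicographically."""
    meta = attach_group_labels(meta)
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    groups = sorted(meta["group"].unique())
    members = {
        g: list(meta.loc[meta["group"] == g, "sample_id"]) for g in groups
    }
    group_meta = {
        g: (sub["city"].iloc[0], int(sub["year"].iloc[0]))
        for g, sub in meta.groupby("group")
    }
    return GroupIndex(groups, members, group_meta)
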