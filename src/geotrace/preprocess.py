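"""Depth filtering, ubiquity pre-filtering and log2-CPM normalization.

Extreme low-depth samples carry little compositional information and are
removed per city-year group: a sample is dropped when its total count over
*order*-rank taxa falls strictly below 20% of the group median of that total.
Taxa are then pre-filtered on ubiquity (fraction of retained samples with a
nonzero count, kept when strictly above 0.6), and counts are normalized to
log2 counts-per-million with the voom offsets, bounding values away from
-infinity:

    log2cpm = log2( (count + 0.5) / (library_size + 1) * 1e6 )
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import GroupIndex, OtuTable

logger = logging.getLogger(__name__)

# absolute guard so exact-boundary comparisons follow the stated strict
# inequalities rather than float rounding
_EPS = 1e-9


@dataclass
class FilterReport:
    """Per-group accounting of the low-depth sample filter."""

    group_median: pd.Series  # median order-level depth per group
    group_cutoff: pd.Series  # fraction x median, exactly
    removed: list[str]
    n_before: int
    n_after: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"median_order_sum": self.group_median, "cutoff": self.group_cutoff}
        ).rename_axis("group")


def order_sum_filter(
    table: OtuTable, index: GroupIndex, fraction: float = 0.2
) -> tuple[OtuTable, FilterReport]:
    """Remove samples whose order-rank count sum is below ``fraction`` x group median."""
    order_taxa = table.taxa_at_rank("order")
    if not order_taxa:
        raise ValueError("no order-rank taxa present; cannot depth-filter")
    sums = table.subset_taxa(order_taxa).counts.sum(axis=1)
    depth = pd.Series(sums, index=table.sample_ids, dtype=float)

    medians, cutoffs, removed = {}, {}, []
    for g in index.groups:
        members = [s for s in index.members[g] if s in depth.index]
        med = float(depth.loc[members].median())
        cut = fraction * med
        medians[g], cutoffs[g] = med, cut
        drop = [s for s in members if depth.loc[s] < cut - _EPS]
        kept = len(members) - len(drop)
        if kept < 2:
            logger.warning(
                "group %s would retain %d sample(s) after depth filtering; "
                "group kept unfiltered", g, kept,
            )
            drop = []
        removed.extend(drop)

    keep = [s for s in table.sample_ids if s not in set(removed)]
    report = FilterReport(
        group_median=pd.Series(medians),
        group_cutoff=pd.Series(cutoffs),
        removed=removed,
        n_before=table.n_samples,
        n_after=len(keep),
    )
    return table.subset_samples(keep), report


def ubiquity_filter(table: OtuTable, threshold: float = 0.6) -> set[str]:
    """Taxa present (count > 0) in strictly more than ``threshold`` of samples.

    A taxon at exactly the threshold is excluded.
    """
    if table.n_samples == 0:
        raise ValueError("empty table: no samples to compute ubiquity over")
    present = (table.counts > 0).sum(axis=0)
    keep_mask = present > threshold * table.n_samples + _EPS
    return {t for t, k in zip(table.taxon_ids, keep_mask) if k}


def log2_cpm(
    table: OtuTable,
    count_offset: float = 0.5,
    library_offset: float = 1.0,
) -> pd.DataFrame:
    """voom-style normalization: log2((c + 0.5) / (L + 1) * 1e6).

    The library size L is each sample's total count over the taxa present in
    ``table`` (i.e. over the current, possibly feature-selected, taxon set).
    """
    lib = table.counts.sum(axis=1).astype(float)
    if (lib <= 0).any():
        bad = table.sample_ids[int(np.argmax(lib <= 0))]
        raise ValueError(f"zero library size for sample {bad!r}")
    values = np.log2(
        (table.counts + count_offset) / (lib[:, None] + library_offset) * 1e6
    )
    return pd.DataFrame(
        values, index=pd.Index(table.sample_ids, name="sample_id"),
        columns=table.taxon_ids,
    )
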