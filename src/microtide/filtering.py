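"""Aggregating rare or unwanted taxa into an "Other" category.

A taxon is aggregated when its prevalence (share of libraries in which it is
present) falls below ``prev_cutoff`` percent, when its relative abundance is
below ``ra_cutoff`` percent in every library, or when it is listed explicitly.
Both rules are evaluated on the pre-filter table and the union is aggregated in
one pass, so the result does not depend on rule order.  Aggregated counts are
summed per library into the "Other" taxon (appended last; merged into an
existing "Other" if present) and ra/clr/bin are recomputed, since the number of
taxa entering the CLR geometric mean changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import MicroSet, clr_transform

logger = logging.getLogger("microtide")

__all__ = ["FilterSpec", "otu_filter"]

OTHER = "Other"


@dataclass
class FilterSpec:
    """Filtering rules for one pass of :func:`otu_filter`.

    Parameters
    ----------
    table : str or None
        Restrict to one OTU table (None = all tables).
    prev_cutoff : float
        Percent of libraries (0-100); taxa present in fewer are aggregated.
    ra_cutoff : float
        Percent relative abundance (0-100); taxa below it in *every* library
        are aggregated.
    aggregate_taxa : list of str
        Taxa forced into "Other" regardless of the cutoffs.
    """

    table: str | None = None
    prev_cutoff: float = 0.0
    ra_cutoff: float = 0.0
    aggregate_taxa: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for nm, v in [("prev_cutoff", self.prev_cutoff), ("ra_cutoff", self.ra_cutoff)]:
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{nm} must be in [0, 100], got {v}")


def _filter_one_table(ms: MicroSet, table: str, spec: FilterSpec) -> pd.DataFrame:
    taxa = ms.tables[table]
    libs = ms.libraries(table)
    cts = ms.wide(table, "cts").to_numpy()      # libs x taxa
    ra = ms.wide(table, "ra").to_numpy()
    n_lib = len(libs)

    unknown = [t for t in spec.aggregate_taxa if t not in taxa]
    if unknown:
        raise ValueError(f"aggregate_taxa not in table {table!r}: {unknown}")

    prevalence = 100.0 * (cts > 0).sum(axis=0) / n_lib
    low_prev = prevalence < spec.prev_cutoff
    low_ra = (ra < spec.ra_cutoff).all(axis=0)
    forced = np.array([t in spec.aggregate_taxa for t in taxa])
    agg = low_prev | low_ra | forced

    keep_taxa = [t for t, a in zip(taxa, agg) if not a and t != OTHER]
    agg_taxa = [t for t, a in zip(taxa, agg) if a and t != OTHER]
    had_other = OTHER in taxa

    if not keep_taxa:
        raise ValueError(f"table {table!r}: every taxon would be aggregated")

    keep_idx = [taxa.index(t) for t in keep_taxa]
    new_taxa = list(keep_taxa)
    new_cts = cts[:, keep_idx]
    other_cts = np.zeros(n_lib, dtype=new_cts.dtype)
    if had_other:
        other_cts = other_cts + cts[:, taxa.index(OTHER)]
    if agg_taxa:
        other_cts = other_cts + cts[:, [taxa.index(t) for t in agg_taxa]].sum(axis=1)
    if had_other or agg_taxa:
        new_taxa.append(OTHER)
        new_cts = np.column_stack([new_cts, other_cts])

    logger.info(
        "otu_filter %s: kept %d taxa, aggregated %d into %r "
        "(prev_cutoff=%g%%, ra_cutoff=%g%%, forced=%d)",
        table, len(keep_taxa), len(agg_taxa), OTHER,
        spec.prev_cutoff, spec.ra_cutoff, int(forced.sum()),
    )
    if agg_taxa:
        logger.info("otu_filter %s: aggregated taxa: %s", table, agg_taxa)

    depths = new_cts.sum(axis=1)
    clr = np.vstack([clr_transform(new_cts[i], depths[i]) for i in range(n_lib)])
    new_ra = 100.0 * new_cts / depths[:, None]

    clin = ms.clinical_frame(table)
    n_taxa = len(new_taxa)
    block = pd.DataFrame(
        {
            "Table": table,
            "Taxa": np.repeat(new_taxa, n_lib),
            "Lib": np.tile(libs, n_taxa),
            "cts": new_cts.T.ravel(),
            "Total": np.tile(depths, n_taxa),
            "ra": new_ra.T.ravel(),
            "clr": clr.T.ravel(),
            "bin": (new_cts.T.ravel() > 0).astype(np.int64),
        }
    )
    clin_rep = clin.loc[np.tile(libs, n_taxa)].reset_index(drop=True)
    return pd.concat([block, clin_rep], axis=1), new_taxa


def otu_filter(micro_set: MicroSet, spec: FilterSpec) -> MicroSet:
    """Aggregate rare/unwanted taxa into "Other" and recompute ra/clr/bin.

    Per-library sequencing depth is conserved, and applying the same spec twice
    gives the same result as applying it once.
    """
    targets = [spec.table] if spec.table is not None else list(micro_set.tables)
    for t in targets:
        if t not in micro_set.tables:
            raise KeyError(f"unknown OTU table {t!r}")
    blocks: list[pd.DataFrame] = []
    new_tables: dict[str, list[str]] = {}
    for nm in micro_set.tables:
        if nm in targets:
            block, taxa = _filter_one_table(micro_set, nm, spec)
            blocks.append(block)
            new_tables[nm] = taxa
        else:
            blocks.append(micro_set.table_data(nm).copy())
            new_tables[nm] = list(micro_set.tables[nm])
    data = pd.concat(blocks, ignore_index=True)
    return MicroSet(data=data, tables=new_tables,
                    clinical_cols=list(micro_set.clinical_cols))
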