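"""Abundance tables, taxonomy maps, and taxon classification.

The central container is :class:`AbundanceTable`: a taxa x samples count
matrix (wide format) with per-sample metadata (site, time point, wet/dry
condition) and a taxonomic-rank tag.  Tables aggregate upward through a
:class:`TaxonomyMap` (phylum > class > order > family > genus), normalize to
relative abundances, and classify taxa as microbial-community *core*
(present in every sample) and/or *rare biosphere* (relative abundance below
a threshold, 0.01 by default, in every sample).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "AbundanceTable",
    "TaxonomyMap",
    "CoreRBFlags",
    "read_abundance_table",
    "read_metadata",
    "aggregate_to_rank",
    "relative_abundance",
    "core_and_rare",
    "condition_partition",
]

#: Taxonomic ranks, highest to lowest.
RANKS: tuple[str, ...] = ("phylum", "class", "order", "family", "genus")


@dataclass
class AbundanceTable:
    """Taxa x samples abundance matrix with sample metadata.

    ``data`` rows are taxa, columns are sample IDs (convention:
    ``{site}{time}``, e.g. ``B1``).  ``meta`` is indexed by sample ID with
    columns ``site``, ``time`` and ``condition``; it may be None for tables
    without a study context.
    """

    data: pd.DataFrame
    rank: str = "genus"
    meta: pd.DataFrame | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate taxon identifier: {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        neg = self.data.lt(0)
        if neg.any().any():
            col = neg.any().idxmax()
            row = neg[col].idxmax()
            raise ValueError(f"negative count at taxon {row!r}, sample {col!r}")
        if self.meta is not None:
            missing = self.data.columns.difference(self.meta.index)
            if len(missing):
                raise ValueError(f"samples missing from metadata: {list(missing)}")

    @property
    def taxa(self) -> list:
        return list(self.data.index)

    @property
    def samples(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def relative(self) -> "AbundanceTable":
        """Column-normalized copy (idempotent)."""
        return relative_abundance(self)

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "taxon_id"
        out.to_csv(path, sep="\t")

    def __eq__(self, other) -> bool:  # value equality, for round-trip tests
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return (
            self.rank == other.rank
            and self.data.shape == other.data.shape
            and list(self.data.index) == list(other.data.index)
            and list(self.data.columns) == list(other.data.columns)
            and np.allclose(self.data.to_numpy(float), other.data.to_numpy(float))
        )


def relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Normalize each sample column to sum to 1."""
    totals = table.data.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[(totals <= 0).argmax()]
        raise ValueError(f"sample {bad!r} has zero total count; cannot normalize")
    return replace(table, data=table.data.div(totals, axis=1), normalized=True)


def read_abundance_table(
    path, format: str = "tsv", rank: str = "genus", meta: pd.DataFrame | None = None
) -> AbundanceTable:
    """Read a wide TSV (taxa rows, sample columns) or a BIOM 2.1 file."""
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "biom":
        import biom

        tab = biom.load_table(str(path))
        df = tab.to_dataframe(dense=True)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'biom'")
    return AbundanceTable(df, rank=rank, meta=meta)


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata TSV with columns sample_id, site, time, condition."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "site", "time", "condition"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    return meta.set_index("sample_id")


@dataclass
class TaxonomyMap:
    """Lineage per genus-level taxon across the five ranks.

    ``lineage`` is indexed by taxon (genus) ID with one column per rank in
    :data:`RANKS`; each genus maps to exactly one taxon at every higher rank,
    so rank cardinalities are non-increasing going up.
    """

    lineage: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.lineage.columns]
        if missing:
            raise ValueError(f"lineage is missing rank columns: {missing}")
        if self.lineage.index.duplicated().any():
            raise ValueError("duplicate taxon in taxonomy")
        # strict nesting: each taxon at a rank has a unique parent above it
        for child, parent in zip(RANKS[::-1], RANKS[-2::-1]):
            per_child = self.lineage.groupby(child, observed=True)[parent].nunique()
            if (per_child > 1).any():
                bad = per_child.idxmax()
                raise ValueError(
                    f"{child} {bad!r} maps to multiple {parent} taxa; "
                    "ranks must be strictly nested"
                )

    def n_taxa(self, rank: str) -> int:
        return int(self.lineage[rank].nunique())

    def mapping(self, rank: str) -> pd.Series:
        """genus-level taxon ID -> taxon at ``rank``."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return self.lineage[rank]

    def to_tsv(self, path) -> None:
        out = self.lineage[list(RANKS)].copy()
        out.index.name = "taxon_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "TaxonomyMap":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def aggregate_to_rank(
    table: AbundanceTable, taxonomy: TaxonomyMap, rank: str
) -> AbundanceTable:
    """Sum a genus-level table up to ``rank``; column sums are preserved."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    if rank == table.rank:
        return replace(table)
    mapping = taxonomy.mapping(rank)
    missing = table.data.index.difference(mapping.index)
    if len(missing):
        raise ValueError(f"taxa without a lineage: {sorted(missing)}")
    grouped = table.data.groupby(mapping.reindex(table.data.index)).sum()
    grouped = grouped.sort_index()
    return AbundanceTable(grouped, rank=rank, meta=table.meta,
                          normalized=table.normalized)


@dataclass
class CoreRBFlags:
    """Per-taxon core / rare-biosphere classification.

    ``is_core``: nonzero in every sample (present across space and time).
    ``is_rare``: relative abundance strictly below ``rb_threshold`` in every
    sample.  A taxon can be both (a "permanent rare" taxon).
    """

    is_core: pd.Series
    is_rare: pd.Series
    rb_threshold: float

    @property
    def core_taxa(self) -> list:
        return list(self.is_core.index[self.is_core])

    @property
    def rare_taxa(self) -> list:
        return list(self.is_rare.index[self.is_rare])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"is_core": self.is_core, "is_rare": self.is_rare})


def core_and_rare(
    table: AbundanceTable, rb_threshold: float = 0.01, mode: str = "per_sample"
) -> CoreRBFlags:
    """Classify taxa as core and/or rare biosphere.

    ``mode='per_sample'`` (default) requires relative abundance < threshold
    in *every* sample for rare status; ``mode='mean'`` applies the threshold
    to the across-sample mean instead.
    """
    if table.data.shape[1] < 1 or table.data.shape[0] < 1:
        raise ValueError("table must have at least one taxon and one sample")
    rel = table.data if table.normalized else relative_abundance(table).data
    counts = table.data
    is_core = (counts > 0).all(axis=1)
    if mode == "per_sample":
        is_rare = (rel < rb_threshold).all(axis=1)
    elif mode == "mean":
        is_rare = rel.mean(axis=1) < rb_threshold
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return CoreRBFlags(is_core, is_rare, rb_threshold)


def condition_partition(
    table: AbundanceTable, conditions: pd.Series | None = None
) -> dict:
    """Presence-based shared/unique taxon partition across conditions.

    Returns ``{"presence": {cond: set}, "shared": set, "unique": {cond: set}}``
    where *shared* is the intersection of all per-condition presence sets and
    *unique(c)* is presence(c) minus the union of every other condition.
    """
    if conditions is None:
        if table.meta is None or "condition" not in table.meta.columns:
            raise ValueError("no condition labels: pass `conditions` or table.meta")
        conditions = table.meta.loc[table.samples, "condition"]
    conditions = pd.Series(conditions)
    unlabeled = [s for s in table.samples if s not in conditions.index
                 or pd.isna(conditions[s])]
    if unlabeled:
        raise ValueError(f"samples without a condition label: {unlabeled}")
    presence: dict[str, set] = {}
    for cond, cols in conditions.groupby(conditions).groups.items():
        sub = table.data[list(cols)]
        presence[cond] = set(sub.index[(sub > 0).any(axis=1)])
    shared = set.intersection(*presence.values()) if presence else set()
    unique = {
        c: presence[c] - set.union(set(), *(presence[o] for o in presence if o != c))
        for c in presence
    }
    return {"presence": presence, "shared": shared, "unique": unique}
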