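"""Sample-by-taxon abundance tables and their I/O.

The :class:`AbundanceTable` is the hub object shared by the diversity,
neutral-model, assembly and network stages: a non-negative samples x taxa
count (or relative-abundance) matrix with optional per-sample metadata
(litter treatment, flooding level, ...).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AbundanceTable", "read_abundance_tsv", "read_abundance_biom"]


@dataclass
class AbundanceTable:
    """Samples x taxa abundance matrix with optional sample metadata.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows are samples, columns are taxa. Entries must be non-negative
        and every analysed sample must have a positive row sum.
    metadata : pandas.DataFrame, optional
        Indexed by sample id; typical columns are ``treatment``
        (CK / L / LR / M) and ``flooding`` (LO / ME / HI).
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if c.columns.has_duplicates:
            raise ValueError("duplicate taxon ids")
        if (c.to_numpy() < 0).any():
            raise ValueError("abundance table contains negative entries")
        if (c.sum(axis=1) <= 0).any():
            empty = c.index[c.sum(axis=1) <= 0].tolist()
            raise ValueError(f"samples with zero total abundance: {empty}")
        if self.metadata is not None:
            missing = c.index.difference(self.metadata.index)
            if len(missing):
                raise ValueError(f"samples missing from metadata: {list(missing)}")

    # -- basic accessors -------------------------------------------------
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

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalised abundances (each sample sums to 1)."""
        return self.counts.div(self.counts.sum(axis=1), axis=0)

    # -- transforms ------------------------------------------------------
    def select_samples(self, sample_ids) -> "AbundanceTable":
        sub = self.counts.loc[list(sample_ids)]
        sub = sub.loc[:, sub.sum(axis=0) > 0]
        meta = None
        if self.metadata is not None:
            meta = self.metadata.loc[sub.index]
        return AbundanceTable(sub, meta)

    def drop_empty_taxa(self) -> "AbundanceTable":
        return AbundanceTable(
            self.counts.loc[:, self.counts.sum(axis=0) > 0], self.metadata
        )

    def filter_prevalence(self, min_prevalence: float) -> "AbundanceTable":
        """Keep taxa detected in at least ``min_prevalence`` of samples."""
        prev = (self.counts > 0).mean(axis=0)
        return AbundanceTable(self.counts.loc[:, prev >= min_prevalence], self.metadata)

    def rarefy(self, depth: int | None = None, seed: int = 0) -> "AbundanceTable":
        """Subsample each sample without replacement to a common depth.

        Off by default in all analyses; provided for studies with very
        uneven sequencing depth. ``depth=None`` uses the minimum row sum.
        """
        counts = self.counts.to_numpy()
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("rarefaction requires integer counts")
        counts = np.round(counts).astype(np.int64)
        sums = counts.sum(axis=1)
        if depth is None:
            depth = int(sums.min())
        if (sums < depth).any():
            raise ValueError("rarefaction depth exceeds a sample's total count")
        rng = np.random.default_rng(seed)
        out = np.zeros_like(counts)
        for i in range(counts.shape[0]):
            pool = np.repeat(np.arange(counts.shape[1]), counts[i])
            picked = rng.choice(pool, size=depth, replace=False)
            out[i] = np.bincount(picked, minlength=counts.shape[1])
        table = pd.DataFrame(out, index=self.counts.index, columns=self.counts.columns)
        return AbundanceTable(table, self.metadata).drop_empty_taxa()

    def groups(self, columns=("treatment", "flooding")) -> dict[tuple, list[str]]:
        """Sample ids grouped by metadata factor levels."""
        if self.metadata is None:
            raise ValueError("no metadata attached")
        cols = [c for c in columns if c in self.metadata.columns]
        if not cols:
            raise ValueError(f"none of {columns} found in metadata")
        out: dict[tuple, list[str]] = {}
        for key, sub in self.metadata.loc[self.counts.index].groupby(cols, sort=True):
            key = key if isinstance(key, tuple) else (key,)
            out[key] = list(sub.index)
        return out

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="sample_id")


def read_abundance_tsv(path, metadata_csv=None, taxa_as_columns: bool = True) -> AbundanceTable:
    """Read an abundance table from TSV (samples x taxa by default).

    ``taxa_as_columns=False`` transposes the classic OTU-table layout
    (taxa as rows, samples as columns).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not taxa_as_columns:
        df = df.T
    meta = None
    if metadata_csv is not None:
        meta = pd.read_csv(metadata_csv, index_col=0)
    return AbundanceTable(df, meta)


def read_abundance_biom(path, metadata_csv=None) -> AbundanceTable:
    """Read a BIOM-format table (requires the ``biom-format`` package)."""
    try:
        import biom
    except ImportError as exc:  # pragma: no cover
        raise ImportError("BIOM input requires the biom-format package") from exc
    t = biom.load_table(path)
    df = pd.DataFrame(
        t.matrix_data.toarray().T,
        index=t.ids("sample"),
        columns=t.ids("observation"),
    )
    meta = pd.read_csv(metadata_csv, index_col=0) if metadata_csv else None
    return AbundanceTable(df, meta)
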