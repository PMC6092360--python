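"""Core data containers and table-level transforms.

The canonical in-memory layout is a pandas DataFrame of non-negative
integer read counts with OTUs as rows and samples as columns, wrapped in
:class:`OtuTable` together with optional taxonomy strings. Sample-level
metadata (successional period, water-column depth, sampling-event ordinal
and environmental variables) lives in :class:`SampleFrame`.

Rarefaction draws a without-replacement subsample of each sample's reads
(multivariate hypergeometric), so every column is normalized to a common
sequencing depth before any diversity or classification step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OtuTable",
    "SampleFrame",
    "FormatError",
    "read_otu_table",
    "write_otu_table",
    "read_sample_frame",
    "rarefy",
    "relative_abundance",
    "remove_singletons",
]

PERIOD_LEVELS = ("bloom", "post-bloom 1", "post-bloom 2")
DEPTH_LEVELS = ("surface", "middle", "bottom")


class FormatError(ValueError):
    """Raised when an input table violates the format contract."""


@dataclass
class OtuTable:
    """Integer OTU-by-sample count matrix with optional taxonomy.

    Parameters
    ----------
    counts
        DataFrame indexed by OTU id with sample ids as columns; values are
        non-negative integers (read counts).
    taxonomy
        Optional per-OTU semicolon-delimited rank string, indexed like
        ``counts``.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if not isinstance(c, pd.DataFrame):
            raise TypeError("counts must be a pandas DataFrame")
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate OTU ids: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if c.shape[1] < 2:
            raise FormatError("an OTU table needs at least 2 samples")
        arr = c.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise FormatError("counts must be integers")
            self.counts = c = c.astype(np.int64)
            arr = c.to_numpy()
        if arr.size and (arr < 0).any():
            raise FormatError("counts must be non-negative")
        if len(c) == 0:
            # empty tables arise from subcommunity splits; flagged, not fatal
            logger.warning("constructed an OtuTable with zero OTUs")
        elif (arr.sum(axis=0) == 0).any():
            bad = c.columns[arr.sum(axis=0) == 0].tolist()
            raise FormatError(f"samples with zero total reads: {bad}")
        if self.taxonomy is not None:
            self.taxonomy = self.taxonomy.reindex(c.index)

    @property
    def otu_ids(self) -> list:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.counts.columns.tolist()

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def select_otus(self, otu_ids) -> "OtuTable":
        """Subset to the given OTUs, keeping counts unchanged."""
        sub = self.counts.loc[list(otu_ids)]
        tax = self.taxonomy.loc[list(otu_ids)] if self.taxonomy is not None else None
        obj = object.__new__(OtuTable)
        obj.counts, obj.taxonomy = sub, tax
        if len(sub) == 0:
            logger.warning("subcommunity selection produced an empty table")
        return obj


@dataclass
class SampleFrame:
    """Per-sample design factors and environmental measurements.

    ``period`` is an ordered categorical (bloom < post-bloom 1 <
    post-bloom 2), ``depth`` a categorical water layer, ``date_index`` an
    integer sampling-event ordinal, and ``env`` a numeric DataFrame of
    environmental variables (NaN marks missing values; consumers drop
    affected samples pairwise and log the count).
    """

    period: pd.Series
    depth: pd.Series
    date_index: pd.Series
    env: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        idx = self.period.index
        for name in ("depth", "date_index"):
            s = getattr(self, name)
            if not s.index.equals(idx):
                raise FormatError(f"{name} index does not match period index")
        if self.period.isna().any() or self.depth.isna().any():
            raise FormatError("period and depth must be non-missing")
        if not isinstance(self.period.dtype, pd.CategoricalDtype):
            levels = [l for l in PERIOD_LEVELS if l in set(self.period)]
            levels = levels or sorted(set(self.period))
            self.period = pd.Series(
                pd.Categorical(self.period, categories=levels, ordered=True),
                index=idx,
            )
        if len(self.env) and not self.env.index.equals(idx):
            self.env = self.env.reindex(idx)

    @property
    def sample_ids(self) -> list:
        return self.period.index.tolist()

    def check_matches(self, table: OtuTable) -> None:
        missing = set(table.sample_ids) - set(self.sample_ids)
        if missing:
            raise FormatError(f"samples absent from metadata: {sorted(missing)}")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def read_otu_table(path, orientation: str = "otus_as_rows",
                   taxonomy_path=None) -> OtuTable:
    """Read a tab-separated count table.

    ``orientation`` is ``"otus_as_rows"`` (canonical), ``"samples_as_rows"``
    (transposed on read), or ``"auto"`` which requires ``taxonomy_path`` or
    falls back to otus-as-rows.
    """
    df = _read_tsv(path)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate ids in {path}: {dups}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            row = df.index[bad][0]
            raise FormatError(f"non-numeric cell at row {row!r}, column {col!r}")
        vals = pd.to_numeric(df[col])
        if not np.allclose(vals, np.round(vals)):
            row = df.index[~np.isclose(vals, np.round(vals))][0]
            raise FormatError(f"non-integer cell at row {row!r}, column {col!r}")
    df = df.astype(np.int64)
    if orientation == "samples_as_rows":
        df = df.T
    elif orientation == "auto":
        tax_ids: set = set()
        if taxonomy_path is not None:
            tax_ids = set(_read_tsv(taxonomy_path).index)
        if tax_ids and len(tax_ids & set(df.columns)) > len(tax_ids & set(df.index)):
            df = df.T
    elif orientation != "otus_as_rows":
        raise ValueError(f"unknown orientation: {orientation!r}")
    tax = None
    if taxonomy_path is not None:
        tax = _read_tsv(taxonomy_path).iloc[:, 0]
    return OtuTable(df, taxonomy=tax)


def write_otu_table(table: OtuTable, path) -> None:
    """Write counts as TSV (OTUs as rows); round-trips bit-identically."""
    table.counts.to_csv(path, sep="\t", index_label="otu_id")


def read_sample_frame(path, env_columns=None) -> SampleFrame:
    """Read sample metadata TSV with columns period, depth, date_index and
    any number of numeric environmental columns."""
    df = _read_tsv(path)
    for col in ("period", "depth", "date_index"):
        if col not in df.columns:
            raise FormatError(f"metadata missing required column {col!r}")
    env_cols = (list(env_columns) if env_columns is not None
                else [c for c in df.columns
                      if c not in ("period", "depth", "date_index")])
    env = df[env_cols].apply(pd.to_numeric, errors="coerce")
    return SampleFrame(period=df["period"], depth=df["depth"],
                       date_index=df["date_index"].astype(int), env=env)


def write_sample_frame(meta: SampleFrame, path) -> None:
    df = pd.concat(
        [meta.period.rename("period").astype(str),
         meta.depth.rename("depth"),
         meta.date_index.rename("date_index"),
         meta.env], axis=1)
    df.to_csv(path, sep="\t", index_label="sample_id")


def rarefy(table: OtuTable, depth: int, seed: int,
           drop_empty_otus: bool = False) -> OtuTable:
    """Subsample each sample to ``depth`` reads without replacement.

    Each sample's reads are drawn by a multivariate-hypergeometric draw
    from its observed counts, so expected post-rarefaction counts are
    ``depth * count / total``. The random stream for sample *j* is derived
    deterministically from ``(seed, j)``, making the result independent of
    sample order in the file.

    Parameters
    ----------
    depth
        Target reads per sample; must be ≥ 1 and ≤ every column total.
    drop_empty_otus
        If True, OTUs that end up with zero reads in every sample are
        removed (the removal count is logged).
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    totals = table.sample_totals
    short = totals[totals < depth]
    if len(short):
        raise ValueError(
            f"rarefaction depth {depth} exceeds totals of samples: "
            f"{short.index.tolist()}")
    out = np.empty_like(table.counts.to_numpy())
    for j, sample in enumerate(table.sample_ids):
        rng = np.random.default_rng([seed, j])
        col = table.counts[sample].to_numpy()
        out[:, j] = rng.multivariate_hypergeometric(col, depth)
    df = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    if drop_empty_otus:
        keep = df.sum(axis=1) > 0
        dropped = int((~keep).sum())
        if dropped:
            logger.info("rarefy: dropped %d OTUs with zero reads after "
                        "subsampling", dropped)
        df = df.loc[keep]
    tax = table.taxonomy.loc[df.index] if table.taxonomy is not None else None
    return OtuTable(df, taxonomy=tax)


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Per-sample proportions; every column sums to 1."""
    totals = table.sample_totals
    if (totals == 0).any():
        raise ValueError("cannot normalize a sample with zero total reads")
    return table.counts / totals


def remove_singletons(table: OtuTable, threshold: int = 1) -> OtuTable:
    """Drop OTUs whose whole-dataset read total is ≤ ``threshold``.

    With the default threshold of 1 this removes singletons, the usual
    guard against OTUs created by sequencing error.
    """
    keep = table.counts.sum(axis=1) > threshold
    dropped = int((~keep).sum())
    if dropped:
        logger.info("remove_singletons: dropped %d OTUs with total <= %d",
                    dropped, threshold)
    return table.select_otus(table.counts.index[keep])
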