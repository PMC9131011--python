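"""ASV feature tables, taxonomy maps and sample metadata.

Tables are tab-separated text on disk and pandas objects in memory.  The
canonical orientation is features (ASVs or aggregated taxa) as rows and
samples as columns, matching the way 16S count matrices are usually
exchanged.  Readers validate rather than coerce: duplicated IDs, negative
or fractional counts and ragged rows are hard errors that name the
offending row, because silent coercion upstream of compositional analysis
corrupts every downstream statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

RANKS = ("phylum", "class", "order", "family", "genus")
AGG_RANKS = ("genus", "family", "order", "phylum")
UNASSIGNED = "__unassigned__"


@dataclass
class FeatureTable:
    """Non-negative integer count matrix, features x samples.

    Parameters
    ----------
    data : pandas.DataFrame
        Integer counts with feature IDs as the index and sample IDs as
        columns.
    rank : str
        Taxonomic rank of the rows: ``"asv"`` or one of genus, family,
        order, phylum.
    """

    data: pd.DataFrame
    rank: str = "asv"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate feature ID: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample ID: {dup!r}")
        arr = self.data.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            frac = arr != np.floor(arr)
            if frac.any():
                i, _ = np.argwhere(frac)[0]
                raise ValueError(
                    f"non-integer count in feature {self.data.index[i]!r}"
                )
            self.data = self.data.astype(np.int64)
            arr = self.data.to_numpy()
        if arr.size and (arr < 0).any():
            i = np.argwhere(arr < 0)[0][0]
            raise ValueError(f"negative count in feature {self.data.index[i]!r}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def counts(self) -> np.ndarray:
        """Counts as an integer array, features x samples."""
        return self.data.to_numpy()


@dataclass
class TaxonomyMap:
    """Per-ASV lineage over the ranks phylum..genus.

    Empty strings denote a rank at which the ASV is unassigned.
    """

    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate ASV ID in taxonomy: {dup!r}")
        missing = [r for r in RANKS if r not in self.data.columns]
        if missing:
            raise ValueError(f"taxonomy missing rank columns: {missing}")
        self.data = self.data[list(RANKS)].fillna("").astype(str)

    def lineage(self, asv_id: str) -> dict[str, str]:
        return self.data.loc[asv_id].to_dict()

    def labels_at(self, rank: str, asv_ids) -> pd.Series:
        """Rank labels for the given ASVs; unassigned pooled under a
        reserved label so aggregation conserves column sums."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        missing = [a for a in asv_ids if a not in self.data.index]
        if missing:
            raise KeyError(f"taxonomy missing ASVs: {missing[:5]}")
        lab = self.data.loc[list(asv_ids), rank]
        return lab.where(lab != "", UNASSIGNED)


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path, index_col: str) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    seen: set[str] = set()
    for col in header:
        if col in seen:
            raise ValueError(f"{path}: duplicate column {col!r}")
        seen.add(col)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != index_col:
        raise ValueError(
            f"{path}: first column must be {index_col!r}, got {df.columns[0]!r}"
        )
    if df[index_col].duplicated().any():
        dup = df[index_col][df[index_col].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate {index_col} {dup!r}")
    return df.set_index(index_col).rename_axis(None)


def read_counts(path) -> FeatureTable:
    """Read a counts TSV (rows = features, first column ``asv_id``)."""
    df = _read_tsv(path, "asv_id")
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna()][0]
            raise ValueError(f"{path}: non-numeric count at row {row!r}, column {col!r}")
        if (vals != np.floor(vals)).any():
            row = df.index[vals != np.floor(vals)][0]
            raise ValueError(f"{path}: non-integer count at row {row!r}, column {col!r}")
        out[col] = vals.astype(np.int64)
    return FeatureTable(out, rank="asv")


def write_counts(table: FeatureTable, path) -> None:
    table.data.rename_axis("asv_id").to_csv(path, sep="\t")


def read_taxonomy(path) -> TaxonomyMap:
    return TaxonomyMap(_read_tsv(path, "asv_id"))


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    tax.data.rename_axis("asv_id").to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata keyed by ``sample_id``.

    The ``group`` column must be present, binary and complete; other
    columns are parsed numerically where possible, with empty cells kept
    as missing.
    """
    df = _read_tsv(path, "sample_id")
    if "group" not in df.columns:
        raise ValueError(f"{path}: metadata must contain a 'group' column")
    if (df["group"] == "").any():
        row = df.index[df["group"] == ""][0]
        raise ValueError(f"{path}: missing group label for sample {row!r}")
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        raw = df[col].replace("", np.nan)
        num = pd.to_numeric(raw, errors="coerce")
        out[col] = raw if num.isna().sum() > raw.isna().sum() else num
    return out


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.rename_axis("sample_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# core operations


def filter_by_prevalence(table: FeatureTable, fraction: float = 0.10) -> FeatureTable:
    """Keep features detected (count >= 1) in at least floor(fraction * n)
    samples.

    With 184 samples and the default 10% this keeps features present in
    18 or more samples.  Ties at the threshold are kept; feature order and
    the sample set are unchanged.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if table.n_samples == 0 or table.n_features == 0:
        raise ValueError("cannot filter an empty table")
    threshold = int(np.floor(fraction * table.n_samples))
    threshold = max(threshold, 1)
    prevalence = (table.counts() > 0).sum(axis=1)
    keep = prevalence >= threshold
    return replace(table, data=table.data.loc[keep])


def aggregate_to_rank(table: FeatureTable, tax: TaxonomyMap, rank: str) -> FeatureTable:
    """Sum ASV counts over shared rank labels.

    ASVs unassigned at `rank` are pooled into a reserved ``__unassigned__``
    feature rather than dropped, so column sums are conserved exactly —
    CLR transforms and diversity indices depend on per-sample totals.
    """
    if rank not in AGG_RANKS:
        raise ValueError(f"rank must be one of {AGG_RANKS}, got {rank!r}")
    if table.rank != "asv":
        raise ValueError("aggregation starts from an ASV-level table")
    labels = tax.labels_at(rank, table.feature_ids)
    grouped = table.data.groupby(labels.to_numpy(), sort=False).sum()
    grouped.index.name = None
    return FeatureTable(grouped, rank=rank)


def relative_abundance(table: FeatureTable) -> pd.DataFrame:
    """Per-sample proportions; every column sums to 1.

    Raises if any sample has zero total, naming the sample.
    """
    totals = table.data.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise ValueError(f"sample {bad!r} has zero total count")
    return table.data / totals
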