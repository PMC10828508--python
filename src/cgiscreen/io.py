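"""Readers, writers and validated containers for pooled-screen tables.

All tabular inputs of the pipeline pass through this module: sgRNA read-count
tables (guides x samples), the library definition (guide -> gene), the sample
sheet (condition / timepoint / replicate per sequenced sample), and gene-set
collections in GMT format. Every reader validates structural invariants and
raises :class:`ValidationError` with the offending identifier rather than
silently coercing malformed input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "CountMatrix",
    "LibraryDefinition",
    "SampleSheet",
    "GeneSetCollection",
    "read_count_table",
    "read_library_table",
    "read_sample_sheet",
    "read_gene_sets",
    "write_results_table",
    "read_results_table",
]


class ValidationError(ValueError):
    """An input table violates a structural invariant."""


def _delimiter(path, dialect: str | None) -> str:
    if dialect is not None:
        return dialect
    return "," if str(path).lower().endswith(".csv") else "\t"


@dataclass(frozen=True)
class CountMatrix:
    """Nonnegative integer read counts, guides (rows) x samples (columns)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        dup_g = df.index[df.index.duplicated()]
        if len(dup_g):
            raise ValidationError(f"duplicate guide id: {dup_g[0]!r}")
        dup_s = df.columns[df.columns.duplicated()]
        if len(dup_s):
            raise ValidationError(f"duplicate sample id: {dup_s[0]!r}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("count table contains non-numeric entries")
        bad = ~np.isfinite(values) | (values < 0) | (values != np.floor(values))
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid count {values[g, s]!r} at guide {df.index[g]!r}, "
                f"sample {df.columns[s]!r} (must be a nonnegative integer)"
            )
        object.__setattr__(self, "counts", df.astype(np.int64))

    @property
    def guide_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass(frozen=True)
class LibraryDefinition:
    """sgRNA library: one row per guide with its target gene symbol."""

    table: pd.DataFrame  # columns: guide_id, gene [, spacer]

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in ("guide_id", "gene"):
            if col not in df.columns:
                raise ValidationError(f"library table lacks column {col!r}")
            df[col] = df[col].astype(str).str.strip()
        dup = df["guide_id"][df["guide_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate guide_id in library: {dup.iloc[0]!r}")
        empty = df["gene"] == ""
        if empty.any():
            raise ValidationError(
                f"empty gene symbol for guide {df.loc[empty, 'guide_id'].iloc[0]!r}"
            )
        object.__setattr__(self, "table", df.reset_index(drop=True))

    @property
    def guide_ids(self) -> list[str]:
        return list(self.table["guide_id"])

    @property
    def genes(self) -> list[str]:
        return sorted(self.table["gene"].unique())

    @property
    def n_genes(self) -> int:
        return self.table["gene"].nunique()

    @property
    def gene_of(self) -> pd.Series:
        """guide_id -> gene mapping."""
        return self.table.set_index("guide_id")["gene"]

    def guides_per_gene_hist(self) -> dict[int, int]:
        """Histogram {guides per gene: number of genes}."""
        counts = self.table.groupby("gene").size().value_counts().sort_index()
        return {int(k): int(v) for k, v in counts.items()}


_TP_LABEL = re.compile(r"^[Tt](\d+)$")


def _normalize_timepoint(value) -> int:
    if isinstance(value, str):
        m = _TP_LABEL.match(value.strip())
        if m:
            return int(m.group(1))
        value = value.strip()
    try:
        tp = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"non-numeric timepoint: {value!r}") from None
    if not np.isfinite(tp) or tp != int(tp) or tp < 0:
        raise ValidationError(f"timepoint must be a nonnegative integer day: {value!r}")
    return int(tp)


@dataclass(frozen=True)
class SampleSheet:
    """Sample annotations: condition, timepoint (days since T0), replicate."""

    table: pd.DataFrame  # columns: sample_id, condition, timepoint, replicate

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in ("sample_id", "condition", "timepoint", "replicate"):
            if col not in df.columns:
                raise ValidationError(f"sample sheet lacks column {col!r}")
        df["sample_id"] = df["sample_id"].astype(str).str.strip()
        df["condition"] = df["condition"].astype(str).str.strip()
        df["replicate"] = df["replicate"].astype(str).str.strip()
        df["timepoint"] = [_normalize_timepoint(v) for v in df["timepoint"]]
        dup = df["sample_id"][df["sample_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate sample_id: {dup.iloc[0]!r}")
        if not (df["timepoint"] == 0).any():
            raise ValidationError("sample sheet has no T0 (timepoint 0) sample")
        object.__setattr__(self, "table", df.reset_index(drop=True))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def conditions(self) -> list[str]:
        return sorted(self.table.loc[self.table["timepoint"] > 0, "condition"].unique())

    @property
    def t0_sample_ids(self) -> list[str]:
        return list(self.table.loc[self.table["timepoint"] == 0, "sample_id"])

    def non_t0(self) -> pd.DataFrame:
        return self.table[self.table["timepoint"] > 0]

    def sample_for(self, condition: str, timepoint: int, replicate: str) -> str:
        mask = (
            (self.table["condition"] == condition)
            & (self.table["timepoint"] == timepoint)
            & (self.table["replicate"] == replicate)
        )
        hits = self.table.loc[mask, "sample_id"]
        if len(hits) == 0:
            raise ValidationError(
                f"no sample for condition={condition!r}, timepoint={timepoint}, "
                f"replicate={replicate!r}"
            )
        return hits.iloc[0]

    def check_against(self, counts: CountMatrix) -> None:
        """Raise if any declared sample is absent from the count matrix."""
        missing = set(self.sample_ids) - set(counts.sample_ids)
        if missing:
            raise ValidationError(f"samples missing from count table: {sorted(missing)}")


@dataclass(frozen=True)
class GeneSetCollection:
    """Named, nonempty sets of gene symbols (e.g. pathways, MoA terms)."""

    sets: Mapping[str, frozenset]
    annotations: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValidationError(f"gene set {name!r} is empty")
        object.__setattr__(self, "sets", dict(self.sets))
        object.__setattr__(self, "annotations", dict(self.annotations))

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def sizes(self) -> dict[str, int]:
        return {name: len(members) for name, members in self.sets.items()}


def read_count_table(path, dialect: str | None = None) -> CountMatrix:
    """Read a guides x samples read-count table (first column = guide id)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_delimiter(path, dialect), index_col=0)
    df.index = df.index.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValidationError(f"non-numeric count column {col!r} in {path.name}")
    return CountMatrix(df)


def read_library_table(path, dialect: str | None = None) -> LibraryDefinition:
    """Read a library definition with columns guide_id, gene [, spacer]."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path, dialect))
    return LibraryDefinition(df)


def read_sample_sheet(path, dialect: str | None = None) -> SampleSheet:
    """Read a sample sheet with columns sample_id, condition, timepoint, replicate."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path, dialect))
    return SampleSheet(df)


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file (name <tab> description <tab> member genes...)."""
    sets: dict[str, frozenset] = {}
    annotations: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has no member genes"
                )
            name, desc = parts[0].strip(), parts[1].strip()
            members = frozenset(g.strip() for g in parts[2:] if g.strip())
            if not members:
                raise ValidationError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
            annotations[name] = desc
    return GeneSetCollection(sets, annotations)


def write_results_table(table: pd.DataFrame, path) -> None:
    """Write a result table as TSV with header.

    Floats are written with full round-trip precision so that
    ``read_results_table(write_results_table(x)) == x`` to better than 1e-12.
    """
    if table is None or len(table) == 0:
        raise ValidationError("refusing to write an empty result table")
    table.to_csv(path, sep="\t", index=False)


def read_results_table(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t")
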