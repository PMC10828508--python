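"""Depth normalization and log2 fold-change (LFC) fitness estimates.

Raw counts are scaled so every sample sums to a common target depth
(counts-per-ten-million by default), then each guide's abundance at a
timepoint is expressed as a log2 fold change relative to the T0 baseline.
Gene-level fitness is the unweighted mean of a gene's guide LFCs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, LibraryDefinition, SampleSheet, ValidationError

__all__ = [
    "NormalizedCounts",
    "GuideFitness",
    "GeneFitness",
    "depth_normalize",
    "compute_guide_lfc",
    "gene_level_lfc",
    "low_abundance_guides",
    "guide_fitness_to_long",
]

DEFAULT_TARGET_DEPTH = 1e7
DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_LOW_ABUNDANCE_MIN = 30.0

#: names of the (condition, timepoint, replicate) column levels of LFC frames
LFC_LEVELS = ("condition", "timepoint", "replicate")


@dataclass(frozen=True)
class NormalizedCounts:
    """Depth-normalized counts; each sample column sums to ``target_depth``."""

    values: pd.DataFrame
    target_depth: float


@dataclass(frozen=True)
class GuideFitness:
    """Guide x (condition, timepoint, replicate) LFC matrix (log2 vs T0)."""

    lfc: pd.DataFrame
    pseudocount: float


@dataclass(frozen=True)
class GeneFitness:
    """Gene x (condition, timepoint, replicate) mean LFC matrix."""

    lfc: pd.DataFrame


def depth_normalize(
    counts: CountMatrix, target_depth: float = DEFAULT_TARGET_DEPTH
) -> NormalizedCounts:
    """Scale each sample so its column sum equals ``target_depth``."""
    if target_depth <= 0:
        raise ValidationError("target_depth must be positive")
    df = counts.counts
    depths = df.sum(axis=0)
    zero = depths[depths == 0]
    if len(zero):
        raise ValidationError(f"sample {zero.index[0]!r} has zero total reads")
    values = df * (target_depth / depths)
    return NormalizedCounts(values.astype(float), float(target_depth))


def compute_guide_lfc(
    norm: NormalizedCounts,
    sheet: SampleSheet,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> GuideFitness:
    """log2((normalized count + pseudocount) / (T0 baseline + pseudocount)).

    Multiple T0 samples are averaged into a single baseline before the ratio.
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    values = norm.values
    missing = set(sheet.sample_ids) - set(values.columns)
    if missing:
        raise ValidationError(f"samples missing from count table: {sorted(missing)}")
    baseline = values[sheet.t0_sample_ids].mean(axis=1) + pseudocount
    columns: dict[tuple, pd.Series] = {}
    for row in sheet.non_t0().itertuples(index=False):
        key = (row.condition, int(row.timepoint), row.replicate)
        columns[key] = np.log2((values[row.sample_id] + pseudocount) / baseline)
    lfc = pd.DataFrame(columns)
    lfc.columns = pd.MultiIndex.from_tuples(lfc.columns, names=LFC_LEVELS)
    return GuideFitness(lfc, float(pseudocount))


def gene_level_lfc(gf: GuideFitness, lib: LibraryDefinition) -> GeneFitness:
    """Average guide LFCs within each gene (unweighted mean)."""
    gene_of = lib.gene_of
    orphans = sorted(set(gf.lfc.index) - set(gene_of.index))
    if orphans:
        raise ValidationError(f"guides absent from library: {orphans}")
    genes = gene_of.reindex(gf.lfc.index)
    out = gf.lfc.groupby(genes.values).mean()
    out.index.name = "gene"
    return GeneFitness(out)


def low_abundance_guides(
    norm: NormalizedCounts,
    sheet: SampleSheet,
    min_t0: float = DEFAULT_LOW_ABUNDANCE_MIN,
) -> pd.Series:
    """Boolean flag per guide: T0 baseline abundance below ``min_t0``.

    Flagged guides are excluded from trend fitting downstream but are never
    dropped from output tables.
    """
    baseline = norm.values[sheet.t0_sample_ids].mean(axis=1)
    return baseline < min_t0


def guide_fitness_to_long(gf: GuideFitness) -> pd.DataFrame:
    """Long-format view: guide, condition, timepoint, replicate, lfc."""
    long = gf.lfc.stack(LFC_LEVELS, future_stack=True).rename("lfc").reset_index()
    long = long.rename(columns={long.columns[0]: "guide"})
    return long
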