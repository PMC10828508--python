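"""Evaluation machinery for screen performance.

Covers the signal-to-noise ratio against a gold-standard hit set, library hit
rates, rescoring of gene subsets from larger screens (with subset-level BH),
a random-library null distribution, sign-matched hit overlap between screen
platforms, the CERES-based essential-gene standard, the single/multi-guide
support classification for essential-gene interactions, and guide selection
by profile correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .fitness import GuideFitness
from .io import LibraryDefinition, ValidationError
from .qc import essential_dropout_auc  # noqa: F401  (re-exported convenience)
from .scoring import bh_adjust, call_hits
from .enrichment import hypergeom_upper

__all__ = [
    "SNRRow",
    "NullDistribution",
    "EssentialStandardConfig",
    "SupportCall",
    "OverlapResult",
    "snr_report",
    "gold_standard_hits",
    "library_hit_rate",
    "subset_rescore",
    "random_subset_null",
    "hit_overlap_test",
    "define_essential_standard",
    "essential_guide_support",
    "select_top_guides",
]


@dataclass(frozen=True)
class SNRRow:
    """Signal-to-noise ratio of one screen against a gold-standard set."""

    screen: str
    gold_genes: frozenset
    mu: float
    sigma: float
    snr: float
    background_size: int


@dataclass(frozen=True)
class NullDistribution:
    """Hit counts over random gene subsets, with an empirical p-value."""

    n_iterations: int
    counts: np.ndarray
    observed: int
    empirical_p: float


@dataclass(frozen=True)
class EssentialStandardConfig:
    """Thresholds defining the cross-cell-line essential-gene standard."""

    ceres_threshold: float = -1.0
    fraction_threshold: float = 0.6

    def __post_init__(self) -> None:
        if not 0 < self.fraction_threshold < 1:
            raise ValidationError("fraction_threshold must be in (0, 1)")


@dataclass(frozen=True)
class SupportCall:
    """Guide support classification for one gene-compound interaction."""

    gene: str
    compound: str
    support_class: str  # multi_guide | single_guide | unsupported
    flagged_guides: tuple = field(default_factory=tuple)


@dataclass(frozen=True)
class OverlapResult:
    """Sign-matched hit overlap between two screens."""

    overlap: int
    n_a: int
    n_b: int
    universe_size: int
    p: float


def snr_report(
    cgi: pd.Series,
    gold: set,
    screen: str = "",
    signed: bool = False,
) -> SNRRow:
    """SNR = mean gold-standard CGI magnitude / background noise sd.

    The background set is the middle 80% of the screen's CGI distribution
    (values between the 10th and 90th percentiles, inclusive). By default mu
    is the mean |CGI| over gold genes, which stays positive for mixed-sign
    gold sets; ``signed=True`` uses the plain mean instead.
    """
    values = cgi.dropna()
    if len(values) < 20:
        raise ValidationError("need >= 20 genes for an SNR estimate")
    gold_present = set(gold) & set(values.index)
    if not gold_present:
        raise ValidationError("gold-standard set has no genes in the CGI table")
    arr = values.to_numpy(dtype=float)
    q10, q90 = np.percentile(arr, [10, 90])
    background = arr[(arr >= q10) & (arr <= q90)]
    sigma = float(np.std(background, ddof=1))
    if sigma == 0:
        raise ValidationError("background CGI standard deviation is zero")
    gold_values = values.loc[sorted(gold_present)]
    mu = float(gold_values.mean()) if signed else float(gold_values.abs().mean())
    return SNRRow(
        screen=screen,
        gold_genes=frozenset(gold_present),
        mu=mu,
        sigma=sigma,
        snr=mu / sigma,
        background_size=len(background),
    )


def gold_standard_hits(scalable_hits: pd.DataFrame, gw_hits: pd.DataFrame) -> set:
    """Sign-matched intersection of scalable and genome-wide hits.

    ``scalable_hits`` may span several timepoints (columns ``gene``, ``hit``
    and optionally ``timepoint``); a gene qualifies if it is a hit at any
    timepoint with the same sign as its genome-wide hit.
    """
    scal = scalable_hits[scalable_hits["hit"] != 0]
    signs_by_gene = scal.groupby("gene")["hit"].agg(lambda s: frozenset(s))
    gw = gw_hits[gw_hits["hit"] != 0].set_index("gene")["hit"]
    gold = {
        gene
        for gene, sign in gw.items()
        if gene in signs_by_gene.index and sign in signs_by_gene.loc[gene]
    }
    if not gold:
        warnings.warn("gold standard is empty (no sign-matched overlapping hits)")
    return gold


def library_hit_rate(hit_table: pd.DataFrame, library_size: int) -> pd.DataFrame:
    """Hit counts and rates per screen, plus a union-across-timepoints row.

    Rate = (number of significant hits) / library size. When the table has a
    ``timepoint`` column, one extra row per compound (timepoint = "union")
    counts unique gene hits across all timepoints.
    """
    if library_size <= 0:
        raise ValidationError("library_size must be positive")
    df = hit_table.copy()
    group_cols = [c for c in ("compound", "timepoint") if c in df.columns]
    if not group_cols:
        df["compound"], group_cols = "screen", ["compound"]
    rows = []
    for keys, g in df.groupby(group_cols):
        keys = keys if isinstance(keys, tuple) else (keys,)
        n_hits = int((g["hit"] != 0).sum())
        if n_hits > library_size:
            raise ValidationError("more hits than library genes")
        rows.append(
            dict(zip(group_cols, keys))
            | {
                "n_hits": n_hits,
                "n_negative": int((g["hit"] == -1).sum()),
                "n_positive": int((g["hit"] == 1).sum()),
                "hit_rate": n_hits / library_size,
            }
        )
    out = pd.DataFrame(rows)
    if "timepoint" in df.columns and "compound" in df.columns:
        for compound, g in df.groupby("compound"):
            union = g.loc[g["hit"] != 0, "gene"].nunique()
            rows.append(
                {
                    "compound": compound,
                    "timepoint": "union",
                    "n_hits": union,
                    "n_negative": g.loc[g["hit"] == -1, "gene"].nunique(),
                    "n_positive": g.loc[g["hit"] == 1, "gene"].nunique(),
                    "hit_rate": union / library_size,
                }
            )
        out = pd.DataFrame(rows)
    return out


def subset_rescore(
    gw_table: pd.DataFrame,
    subset: set,
    cgi_cutoff: float = 0.7,
    fdr_cutoff: float = 0.1,
) -> pd.DataFrame:
    """Re-apply BH and hit calling on a gene subset of a larger screen.

    Raw p-values are untouched; only the multiple-testing correction is
    recomputed at the subset's size, so a genome-wide screen is not penalized
    for tests outside the subset.
    """
    genes = set(gw_table["gene"])
    missing = sorted(set(subset) - genes)
    if missing:
        raise ValidationError(f"subset genes missing from table: {missing[:10]}")
    sub = gw_table[gw_table["gene"].isin(subset)].copy().reset_index(drop=True)
    sub["fdr"] = bh_adjust(sub["p"].to_numpy())
    return call_hits(sub, cgi_cutoff, fdr_cutoff)


def random_subset_null(
    gw_table: pd.DataFrame,
    observed_hits: int,
    n_genes: int = 1011,
    n_iter: int = 1000,
    seed: int | None = None,
    cgi_cutoff: float = 0.7,
    fdr_cutoff: float = 0.1,
) -> NullDistribution:
    """Null distribution of hit counts over random gene subsets.

    Each iteration draws ``n_genes`` genes without replacement, rescored with
    subset-level BH; empirical_p = (1 + #{null >= observed}) / (1 + n_iter).
    """
    genes = gw_table["gene"].to_numpy()
    if n_genes > len(genes):
        raise ValidationError("n_genes exceeds the gene universe")
    rng = np.random.default_rng(seed)
    p = gw_table["p"].to_numpy(dtype=float)
    cgi = gw_table["cgi"].to_numpy(dtype=float)
    counts = np.empty(n_iter, dtype=int)
    for i in range(n_iter):
        idx = rng.choice(len(genes), size=n_genes, replace=False)
        fdr = bh_adjust(p[idx])
        counts[i] = int(((np.abs(cgi[idx]) > cgi_cutoff) & (fdr < fdr_cutoff)).sum())
    empirical_p = (1 + int((counts >= observed_hits).sum())) / (1 + n_iter)
    return NullDistribution(
        n_iterations=n_iter, counts=counts, observed=observed_hits, empirical_p=empirical_p
    )


def hit_overlap_test(
    hits_a: pd.DataFrame, hits_b: pd.DataFrame, universe_size: int
) -> OverlapResult:
    """Sign-matched overlap of two hit tables with a hypergeometric p-value.

    Overlap counts genes that are hits in both tables with the same sign; the
    p-value treats one hit set as draws and the other as population successes.
    """
    a = hits_a.loc[hits_a["hit"] != 0].set_index("gene")["hit"]
    b = hits_b.loc[hits_b["hit"] != 0].set_index("gene")["hit"]
    if universe_size < max(len(a), len(b)):
        raise ValidationError("universe smaller than a hit set")
    shared = a.index.intersection(b.index)
    overlap = int((a.loc[shared] == b.loc[shared]).sum())
    p = hypergeom_upper(min(overlap, min(len(a), len(b))), len(a), len(b), universe_size)
    return OverlapResult(
        overlap=overlap, n_a=len(a), n_b=len(b), universe_size=universe_size, p=p
    )


def define_essential_standard(
    ceres: pd.DataFrame,
    cfg: EssentialStandardConfig | None = None,
) -> set:
    """Genes essential across cell lines by the CERES dependency criterion.

    A gene qualifies when its CERES score is below ``ceres_threshold`` in
    strictly more than ``fraction_threshold`` of the cell lines with data
    (missing values leave the denominator).
    """
    cfg = cfg or EssentialStandardConfig()
    if ceres.size == 0:
        raise ValidationError("empty CERES matrix")
    below = (ceres < cfg.ceres_threshold).sum(axis=1)
    observed = ceres.notna().sum(axis=1)
    frac = below / observed.replace(0, np.nan)
    return set(frac.index[frac > cfg.fraction_threshold])


def essential_guide_support(
    guide_lfc: GuideFitness,
    lib: LibraryDefinition,
    interactions: list[tuple[str, str]],
    control_label: str = "DMSO",
) -> list[SupportCall]:
    """Classify interactions as single- or multi-guide supported.

    Per gene: (1) residuals of each guide's replicate-mean control LFC to the
    gene-mean control LFC at every timepoint, (2) one pooled sd of those
    residuals, (3) uncorrected differential (compound - control) LFC per guide
    and timepoint, (4) a guide is flagged when its |differential| exceeds that
    sd at two or more timepoints, (5) class by number of flagged guides.
    """
    # replicate-mean LFC per (condition, timepoint)
    mean_lfc = guide_lfc.lfc.T.groupby(level=["condition", "timepoint"]).mean().T
    gene_of = lib.gene_of
    calls = []
    for gene, compound in interactions:
        guides = sorted(gene_of.index[gene_of == gene])
        if not guides:
            raise ValidationError(f"gene {gene!r} has no guides in the library")
        cond_cols = mean_lfc.columns
        tps = sorted(
            set(t for c, t in cond_cols if c == control_label)
            & set(t for c, t in cond_cols if c == compound)
        )
        if len(tps) < 2:
            raise ValidationError(
                f"gene {gene!r} / compound {compound!r}: need >= 2 shared timepoints"
            )
        dmso = mean_lfc.loc[guides, [(control_label, t) for t in tps]]
        residuals = dmso - dmso.mean(axis=0)
        sd = float(np.std(residuals.to_numpy().ravel(), ddof=1))
        comp = mean_lfc.loc[guides, [(compound, t) for t in tps]]
        differential = comp.to_numpy() - dmso.to_numpy()
        flagged = tuple(
            g
            for g, row in zip(guides, np.abs(differential) > sd)
            if int(row.sum()) >= 2
        )
        if len(flagged) >= 2:
            cls = "multi_guide"
        elif len(flagged) == 1:
            cls = "single_guide"
        else:
            cls = "unsupported"
        calls.append(SupportCall(gene=gene, compound=compound, support_class=cls,
                                 flagged_guides=flagged))
    return calls


def select_top_guides(
    profiles: pd.DataFrame,
    lib: LibraryDefinition,
    k: int = 3,
) -> LibraryDefinition:
    """Keep each gene's k guides with the most correlated interaction profiles.

    ``profiles`` has one row per guide and one column per screen. Per gene the
    pairwise Pearson correlations among its guides' profiles are summed per
    guide; the k highest-scoring guides are retained, ties broken by
    lexicographic guide id. Constant profiles contribute correlation 0 (with a
    warning).
    """
    gene_of = lib.gene_of
    kept = []
    for gene in lib.genes:
        guides = sorted(gene_of.index[gene_of == gene])
        profiled = [g for g in guides if g in profiles.index]
        if len(profiled) < k:
            raise ValidationError(f"gene {gene!r} has {len(profiled)} profiled guides (< {k})")
        sub = profiles.loc[profiled].T
        corr = sub.corr()
        if corr.isna().any().any():
            warnings.warn(f"constant profile among guides of {gene!r}; correlations set to 0")
            corr = corr.fillna(0.0)
        np.fill_diagonal(corr.values, 0.0)
        scores = corr.sum(axis=1)
        ranked = sorted(profiled, key=lambda g: (-scores.loc[g], g))
        kept.extend(ranked[:k])
    table = lib.table[lib.table["guide_id"].isin(kept)].reset_index(drop=True)
    return LibraryDefinition(table)
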