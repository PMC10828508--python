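"""Chemical-genetic interaction (CGI) scoring.

The CGI score of a gene at a timepoint is the corrected differential LFC
between the compound and control arms of a screen. Per replicate pair the
treated/control guide LFC vectors are put through an MA transform (M =
treated - control, A = their mean) and an intensity-dependent trend in M is
removed with a loess fit against A; corrected M values are averaged across
replicates and then across a gene's guides. Significance uses a one-sample
moderated t-test: per-gene guide variances are shrunk toward an
empirical-Bayes prior (d0, s0^2) estimated by moment matching on log
variances, p-values are Benjamini-Hochberg adjusted per screen (one screen =
one compound x timepoint), and hits require |CGI| > 0.7 and FDR < 0.1.

Sign convention: negative CGI = the knockout sensitizes the cell to the
compound; positive CGI = the knockout suppresses or masks the compound's
fitness effect. A CGI of -1 means a twofold larger fitness defect under
compound than under vehicle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from . import fitness
from .fitness import compute_guide_lfc, depth_normalize, low_abundance_guides
from .io import CountMatrix, LibraryDefinition, SampleSheet, ValidationError

__all__ = [
    "EBPrior",
    "ScoreConfig",
    "ScreenResults",
    "ma_loess_normalize",
    "estimate_eb_prior",
    "aggregate_gene_cgi",
    "bh_adjust",
    "call_hits",
    "score_screens",
    "D0_CAP",
]

#: prior degrees of freedom are capped here when the between-gene spread of
#: log variances is at (or below) the pure-sampling minimum
D0_CAP = 1e6

DEFAULT_CGI_CUTOFF = 0.7
DEFAULT_FDR_CUTOFF = 0.1
DEFAULT_SPAN = 0.4
DEFAULT_MIN_GUIDES_FOR_FIT = 30
DEFAULT_BINS = 64


@dataclass(frozen=True)
class EBPrior:
    """Empirical-Bayes variance prior: degrees of freedom and scale."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0 and self.s0_sq > 0):
            raise ValidationError("EBPrior requires d0 > 0 and s0_sq > 0")


@dataclass(frozen=True)
class ScoreConfig:
    """Tunable parameters of the scoring pipeline."""

    control_label: str = "DMSO"
    cgi_cutoff: float = DEFAULT_CGI_CUTOFF
    fdr_cutoff: float = DEFAULT_FDR_CUTOFF
    span: float = DEFAULT_SPAN
    pseudocount: float = fitness.DEFAULT_PSEUDOCOUNT
    target_depth: float = fitness.DEFAULT_TARGET_DEPTH
    smoother: str = "loess"  # "loess" or "binned"
    low_abundance_min: float = fitness.DEFAULT_LOW_ABUNDANCE_MIN
    min_guides_for_fit: int = DEFAULT_MIN_GUIDES_FOR_FIT


@dataclass(frozen=True)
class ScreenResults:
    """Output of :func:`score_screens`."""

    gene_table: pd.DataFrame
    guide_table: pd.DataFrame
    priors: dict = field(default_factory=dict)
    config: ScoreConfig = field(default_factory=ScoreConfig)


def _loess_trend(a: np.ndarray, m: np.ndarray, a_eval: np.ndarray, span: float) -> np.ndarray:
    """Tricube-weighted local linear trend of M on A, evaluated at a_eval."""
    if np.ptp(a) == 0:  # all abscissae identical: no trend to resolve
        return np.full(len(a_eval), float(np.median(m)))
    delta = 0.01 * float(np.ptp(a)) if len(a) > 500 else 0.0
    fit = lowess(m, a, frac=span, it=3, delta=delta, return_sorted=True)
    xs, ys = fit[:, 0], fit[:, 1]
    # collapse duplicated abscissae so interpolation is well defined
    if len(xs) > 1 and np.any(np.diff(xs) == 0):
        ux, inv = np.unique(xs, return_inverse=True)
        uy = np.bincount(inv, weights=ys) / np.bincount(inv)
        xs, ys = ux, uy
    return np.interp(a_eval, xs, ys)


def _binned_trend(
    a: np.ndarray, m: np.ndarray, a_eval: np.ndarray, bins: int = DEFAULT_BINS
) -> np.ndarray:
    """Equal-width-bin median trend with linear interpolation between centers."""
    lo, hi = float(a.min()), float(a.max())
    if hi == lo:
        return np.full(len(a_eval), float(np.median(m)))
    edges = np.linspace(lo, hi, bins + 1)
    idx = np.clip(np.digitize(a, edges) - 1, 0, bins - 1)
    centers, medians = [], []
    for b in range(bins):
        mask = idx == b
        if mask.any():
            centers.append(0.5 * (edges[b] + edges[b + 1]))
            medians.append(float(np.median(m[mask])))
    return np.interp(a_eval, np.array(centers), np.array(medians))


def ma_loess_normalize(
    lfc_treated: pd.Series,
    lfc_control: pd.Series,
    span: float = DEFAULT_SPAN,
    min_guides_for_fit: int = DEFAULT_MIN_GUIDES_FOR_FIT,
    fit_mask: pd.Series | None = None,
    smoother: str = "loess",
    bins: int = DEFAULT_BINS,
) -> pd.DataFrame:
    """MA transform and trend correction of one treated/control LFC pair.

    Returns a frame indexed by guide with columns ``m`` (treated - control),
    ``a`` (mean of the two), ``trend`` (fitted trend at the guide's A) and
    ``m_corrected`` (m - trend, the guide-level CGI score). Guides excluded
    from the fit (``fit_mask`` False, e.g. low T0 abundance) still receive a
    correction evaluated at their A.
    """
    if not 0 < span <= 1:
        raise ValidationError(f"span must be in (0, 1], got {span}")
    if not lfc_treated.index.equals(lfc_control.index):
        raise ValidationError("treated and control LFC vectors have mismatched guides")
    m = lfc_treated - lfc_control
    a = 0.5 * (lfc_treated + lfc_control)
    usable = np.isfinite(m.to_numpy()) & np.isfinite(a.to_numpy())
    if fit_mask is not None:
        usable &= fit_mask.reindex(m.index).fillna(False).to_numpy(dtype=bool)
    a_fit, m_fit = a.to_numpy()[usable], m.to_numpy()[usable]
    a_eval = a.to_numpy()
    if usable.sum() < min_guides_for_fit:
        finite_m = m.to_numpy()[np.isfinite(m.to_numpy())]
        trend = np.full(len(a_eval), float(np.median(m_fit if usable.any() else finite_m)))
    elif smoother == "loess":
        trend = _loess_trend(a_fit, m_fit, a_eval, span)
    elif smoother == "binned":
        trend = _binned_trend(a_fit, m_fit, a_eval, bins)
    else:
        raise ValidationError(f"unknown smoother {smoother!r}")
    out = pd.DataFrame(
        {"m": m, "a": a, "trend": trend, "m_corrected": m - trend, "used_in_fit": usable},
        index=m.index,
    )
    out.index.name = "guide"
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if -dif / y < 1e-8:
            break
    return float(y)


def estimate_eb_prior(sample_variances, df_per_gene) -> EBPrior:
    """Moment-match a scaled inverse-chi-square variance prior.

    Under the hierarchical model s_g^2 | sigma_g^2 ~ sigma_g^2 chi^2_d / d and
    sigma_g^2 ~ s0^2 d0 / chi^2_{d0}, log s_g^2 follows a shifted log-F whose
    mean and variance are matched (via digamma/trigamma) to the empirical
    moments across genes. When the empirical spread of log variances does not
    exceed the pure chi-square sampling contribution, d0 is capped at
    :data:`D0_CAP` (effectively an infinite prior).
    """
    s2 = np.asarray(sample_variances, dtype=float)
    df = np.broadcast_to(np.asarray(df_per_gene, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (df >= 1)
    if not ok.any():
        raise ValidationError("all sample variances are zero or invalid")
    if ok.sum() < 8:
        raise ValidationError(
            f"need >= 8 genes with positive variance, got {int(ok.sum())}"
        )
    s2, df = s2[ok], df[ok]
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0).mean())
    if evar > 0:
        d0 = min(2.0 * _trigamma_inverse(evar), D0_CAP)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = D0_CAP
        s0_sq = float(np.exp(emean))
    return EBPrior(d0=d0, s0_sq=s0_sq)


def aggregate_gene_cgi(
    gd: pd.DataFrame,
    lib: LibraryDefinition,
    prior: EBPrior,
) -> pd.DataFrame:
    """Average guide-level CGI scores per gene and apply the moderated t-test.

    ``gd`` must be indexed by guide with a ``m_corrected`` column (one value
    per guide, already averaged across replicates). Genes with fewer than two
    finite guide values are flagged and assigned p = 1 rather than dropped.
    """
    if "m_corrected" not in gd.columns:
        raise ValidationError("guide table lacks column 'm_corrected'")
    gene_of = lib.gene_of
    orphans = sorted(set(gd.index) - set(gene_of.index))
    if orphans:
        raise ValidationError(f"guides absent from library: {orphans}")
    genes = gene_of.reindex(gd.index)
    grouped = gd["m_corrected"].groupby(genes.values)
    agg = grouped.agg(
        cgi="mean", s2=lambda v: v.var(ddof=1), n_guides=lambda v: int(v.notna().sum())
    )
    agg.index.name = "gene"
    flagged = agg["n_guides"] < 2

    d_g = (agg["n_guides"] - 1).clip(lower=0).astype(float)
    s2 = agg["s2"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        s_tilde_sq = (prior.d0 * prior.s0_sq + d_g * s2) / (prior.d0 + d_g)
        t_mod = agg["cgi"] / np.sqrt(s_tilde_sq / agg["n_guides"])
    df_total = prior.d0 + d_g
    p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)

    out = pd.DataFrame(
        {
            "gene": agg.index,
            "cgi": agg["cgi"].to_numpy(),
            "n_guides": agg["n_guides"].to_numpy(),
            "t_mod": t_mod.to_numpy(),
            "df_total": df_total.to_numpy(),
            "p": p,
            "flagged": flagged.to_numpy(),
        }
    ).reset_index(drop=True)
    out.loc[out["flagged"], ["t_mod", "df_total"]] = np.nan
    out.loc[out["flagged"], "p"] = 1.0
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with monotonicity enforcement."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p must be a 1-d vector")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adjusted, 0.0, 1.0)
    return out


def call_hits(
    table: pd.DataFrame,
    cgi_cutoff: float = DEFAULT_CGI_CUTOFF,
    fdr_cutoff: float = DEFAULT_FDR_CUTOFF,
) -> pd.DataFrame:
    """Annotate hit direction: -1 / +1 when |CGI| > cutoff and FDR < cutoff."""
    if "fdr" not in table.columns:
        raise ValidationError("hit calling requires an 'fdr' column (run bh_adjust)")
    out = table.copy()
    sig = out["fdr"] < fdr_cutoff
    out["hit"] = np.where(
        sig & (out["cgi"] < -cgi_cutoff),
        -1,
        np.where(sig & (out["cgi"] > cgi_cutoff), 1, 0),
    )
    return out


def score_screens(
    counts: CountMatrix,
    sheet: SampleSheet,
    lib: LibraryDefinition,
    config: ScoreConfig | None = None,
) -> ScreenResults:
    """Run the full scoring chain from raw counts to hit-annotated CGI tables.

    Per (compound, timepoint): treated replicate r is paired with control
    replicate r, each pair is MA/loess corrected, corrected M is averaged
    across replicates per guide, genes are aggregated with the moderated
    t-test (variance prior estimated across genes within the screen), and BH
    adjustment plus hit calling are applied per screen.
    """
    cfg = config or ScoreConfig()
    sheet.check_against(counts)
    norm = depth_normalize(counts, cfg.target_depth)
    lowab = low_abundance_guides(norm, sheet, cfg.low_abundance_min)
    gf = compute_guide_lfc(norm, sheet, cfg.pseudocount)
    gene_of = lib.gene_of

    non_t0 = sheet.non_t0()
    compounds = sorted(set(non_t0["condition"]) - {cfg.control_label})
    if not compounds:
        raise ValidationError(
            f"no non-control condition found (control_label={cfg.control_label!r})"
        )
    if cfg.control_label not in set(non_t0["condition"]):
        raise ValidationError(f"control condition {cfg.control_label!r} has no samples")

    gene_frames, guide_frames, priors = [], [], {}
    for compound in compounds:
        screens = non_t0[non_t0["condition"] == compound]
        for timepoint in sorted(screens["timepoint"].unique()):
            reps = sorted(screens.loc[screens["timepoint"] == timepoint, "replicate"])
            per_rep = []
            for rep in reps:
                treated = gf.lfc[(compound, timepoint, rep)]
                try:
                    control = gf.lfc[(cfg.control_label, timepoint, rep)]
                except KeyError:
                    raise ValidationError(
                        f"missing control sample for {cfg.control_label!r} "
                        f"T{timepoint} replicate {rep!r}"
                    ) from None
                per_rep.append(
                    ma_loess_normalize(
                        treated,
                        control,
                        span=cfg.span,
                        min_guides_for_fit=cfg.min_guides_for_fit,
                        fit_mask=~lowab,
                        smoother=cfg.smoother,
                    )
                )
            stacked = pd.concat(per_rep, keys=reps, names=["replicate", "guide"])
            by_guide = stacked.groupby(level="guide")[["m", "a", "m_corrected"]].mean()
            by_guide = by_guide.reindex(gf.lfc.index)

            grouped = by_guide["m_corrected"].groupby(gene_of.reindex(by_guide.index).values)
            gene_var = grouped.var(ddof=1)
            gene_df = grouped.count() - 1
            if not ((gene_var > 0) & (gene_df >= 1)).any():
                # degenerate screen (e.g. treated counts identical to control):
                # every gene has zero guide spread, so no evidence of signal
                warnings.warn(
                    f"screen ({compound}, T{timepoint}): all guide variances are "
                    "zero; using a point-mass prior (no hits can be called)"
                )
                prior = EBPrior(d0=D0_CAP, s0_sq=1e-12)
            else:
                prior = estimate_eb_prior(gene_var, df_per_gene=gene_df)
            priors[(compound, int(timepoint))] = prior

            gene_table = aggregate_gene_cgi(by_guide, lib, prior)
            gene_table["fdr"] = bh_adjust(gene_table["p"].to_numpy())
            gene_table = call_hits(gene_table, cfg.cgi_cutoff, cfg.fdr_cutoff)
            gene_table.insert(1, "compound", compound)
            gene_table.insert(2, "timepoint", int(timepoint))
            gene_frames.append(gene_table)

            guide_table = by_guide.reset_index().rename(columns={"index": "guide"})
            guide_table.insert(1, "gene", gene_of.reindex(by_guide.index).to_numpy())
            guide_table.insert(2, "compound", compound)
            guide_table.insert(3, "timepoint", int(timepoint))
            guide_table["low_abundance"] = lowab.reindex(by_guide.index).to_numpy()
            guide_frames.append(guide_table)

    return ScreenResults(
        gene_table=pd.concat(gene_frames, ignore_index=True),
        guide_table=pd.concat(guide_frames, ignore_index=True),
        priors=priors,
        config=cfg,
    )


def hit_summary(gene_table: pd.DataFrame) -> pd.DataFrame:
    """Negative/positive hit counts per (compound, timepoint) screen."""
    def _counts(g):
        return pd.Series(
            {
                "n_negative": int((g["hit"] == -1).sum()),
                "n_positive": int((g["hit"] == 1).sum()),
                "n_hits": int((g["hit"] != 0).sum()),
            }
        )

    return (
        gene_table.groupby(["compound", "timepoint"])
        .apply(_counts, include_groups=False)
        .reset_index()
    )
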