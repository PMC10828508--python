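"""Gene-set enrichment statistics for CGI hit profiles.

Three related analyses: (1) fold enrichment of a compound's mode-of-action
(MoA) gene set among its hits, FE = (n/M)/(k/N), with a one-sided
hypergeometric p-value, optionally pooled over compounds as compound-gene
pairs and stratified by hit sign or gene essentiality; (2) pathway z-score
enrichment, z = (xbar - mu)/(sigma/sqrt(n)), treating the library CGI
distribution as the null; (3) generic over-representation analysis with gene
set size filters (5-200) and BH-adjusted hypergeometric p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection, ValidationError
from .scoring import bh_adjust

__all__ = [
    "EnrichmentRow",
    "fold_enrichment",
    "hypergeom_upper",
    "global_moa_enrichment",
    "pathway_zscore_enrichment",
    "ora_gene_sets",
]


@dataclass(frozen=True)
class EnrichmentRow:
    """One enrichment result: overlap counts, fold enrichment and p-value."""

    term: str
    n: int  # hits in term
    M: int  # total hits
    k: int  # library genes in term
    N: int  # library size
    fe: float
    p: float

    @property
    def log2_fe(self) -> float:
        with np.errstate(divide="ignore"):
            return float(np.log2(self.fe))


def hypergeom_upper(n: int, M: int, k: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= n).

    X counts successes among M draws without replacement from a population of
    N containing k successes.
    """
    if not (0 <= n <= min(M, k) and 0 <= M <= N and 0 <= k <= N):
        raise ValidationError(
            f"inconsistent hypergeometric arguments n={n}, M={M}, k={k}, N={N}"
        )
    return float(stats.hypergeom.sf(n - 1, N, k, M))


def fold_enrichment(hits: set, term_genes: set, library: set, term: str = "term") -> EnrichmentRow:
    """Fold enrichment of a gene set among hits, within one library."""
    if not hits:
        raise ValidationError("empty hit set")
    if not hits <= set(library):
        raise ValidationError("hits must be a subset of the library")
    k = len(set(term_genes) & set(library))
    if k == 0:
        raise ValidationError("term has no genes in the library")
    N = len(set(library))
    M = len(hits)
    n = len(set(hits) & set(term_genes))
    fe = (n / M) / (k / N)
    p = hypergeom_upper(n, M, k, N)
    return EnrichmentRow(term=term, n=n, M=M, k=k, N=N, fe=fe, p=p)


def _stratum(genes: set, essentiality: str, essential_set: set | None) -> set:
    if essentiality == "all":
        return genes
    if essential_set is None:
        raise ValidationError("essential_set required for essentiality stratification")
    if essentiality == "essential":
        return genes & essential_set
    if essentiality == "nonessential":
        return genes - essential_set
    raise ValidationError(f"unknown essentiality mode {essentiality!r}")


def global_moa_enrichment(
    hit_tables: dict[str, pd.DataFrame],
    moa_sets: dict[str, set],
    direction: str = "all",
    essentiality: str = "all",
    essential_set: set | None = None,
    term: str = "MoA",
) -> EnrichmentRow:
    """Pooled MoA enrichment across compounds, on compound-gene pairs.

    Each value of ``hit_tables`` is a per-compound table with columns ``gene``
    and ``hit`` (and optionally ``cgi``); its unique genes define that
    compound's library. Pairs are pooled: n = MoA hits summed over compounds,
    M = hits summed, k = MoA library genes summed, N = library sizes summed.
    ``direction`` restricts hits to "negative"/"positive" CGIs;
    ``essentiality`` restricts both hits and library to the
    "essential"/"nonessential" stratum.
    """
    if direction not in ("all", "negative", "positive"):
        raise ValidationError(f"unknown direction {direction!r}")
    n = M = k = N = 0
    for compound, table in hit_tables.items():
        if compound not in moa_sets:
            warnings.warn(f"compound {compound!r} has no MoA set; excluded")
            continue
        library = _stratum(set(table["gene"]), essentiality, essential_set)
        moa = set(moa_sets[compound]) & library
        sign = table.set_index("gene")["hit"]
        hit_genes = set(sign.index[sign != 0])
        if direction == "negative":
            hit_genes = set(sign.index[sign == -1])
        elif direction == "positive":
            hit_genes = set(sign.index[sign == 1])
        hit_genes &= library
        n += len(hit_genes & moa)
        M += len(hit_genes)
        k += len(moa)
        N += len(library)
    if M == 0 or k == 0:
        raise ValidationError("no pooled hits or no MoA genes in any library")
    fe = (n / M) / (k / N)
    return EnrichmentRow(term=term, n=n, M=M, k=k, N=N, fe=fe, p=hypergeom_upper(n, M, k, N))


def pathway_zscore_enrichment(
    cgi: pd.Series,
    pathways: GeneSetCollection,
    fdr_flag: float = 0.1,
) -> pd.DataFrame:
    """Pathway z-scores for one screen's per-gene CGI vector.

    z = (xbar - mu) / (sigma / sqrt(n)) with xbar the mean CGI of the
    pathway's library genes and mu, sigma the library-wide CGI mean and
    standard deviation; two-tailed normal p, BH adjusted across pathways.
    Pathways with no genes in the vector are dropped with a warning.
    """
    values = cgi.dropna()
    mu = float(values.mean())
    sigma = float(values.std(ddof=1))
    rows = []
    for name in pathways:
        members = sorted(set(pathways[name]) & set(values.index))
        if not members:
            warnings.warn(f"pathway {name!r} has no genes in the CGI table; dropped")
            continue
        n = len(members)
        xbar = float(values.loc[members].mean())
        z = (xbar - mu) / (sigma / np.sqrt(n))
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"pathway": name, "n": n, "xbar": xbar, "mu": mu, "sigma": sigma,
                     "z": z, "p": p})
    if not rows:
        raise ValidationError("no pathway overlaps the CGI table")
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["fdr"] < fdr_flag
    return out


def ora_gene_sets(
    hits: set,
    universe: set,
    sets: GeneSetCollection,
    min_size: int = 5,
    max_size: int = 200,
    p_cutoff: float = 0.05,
    q_cutoff: float = 0.2,
) -> pd.DataFrame:
    """Over-representation analysis with gene-set size filters.

    Sets whose intersection with the universe falls outside
    [min_size, max_size] are excluded before testing.
    """
    if not universe:
        raise ValidationError("empty universe")
    if not set(hits) <= set(universe):
        raise ValidationError("hits must be a subset of the universe")
    N, M = len(set(universe)), len(set(hits))
    rows = []
    for name in sets:
        members = set(sets[name]) & set(universe)
        k = len(members)
        if not min_size <= k <= max_size:
            continue
        n = len(set(hits) & members)
        fe = (n / M) / (k / N) if M else 0.0
        with np.errstate(divide="ignore"):
            rows.append({"term": name, "n": n, "M": M, "k": k, "N": N,
                         "fe": fe, "log2_fe": float(np.log2(fe)) if fe else -np.inf,
                         "p": hypergeom_upper(n, M, k, N)})
    if not rows:
        return pd.DataFrame(
            columns=["term", "n", "M", "k", "N", "fe", "log2_fe", "p", "fdr", "significant"]
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = (out["p"] <= p_cutoff) & (out["fdr"] <= q_cutoff)
    return out
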