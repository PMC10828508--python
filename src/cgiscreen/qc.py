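"""Screen quality-control metrics.

Three metrics characterize a screen: (1) Pearson correlation of LFC or CGI
vectors between every pair of technical replicates, (2) how well core
essential genes drop out relative to non-essential genes (AUC-ROC with
depletion ranking first), and (3) the within-vs-between context (WBC) score,
which measures how much more correlated a screen's replicates are with each
other than with replicates of unrelated screens. WBC is more sensitive than
raw replicate correlation when compound-specific effects are sparse.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ValidationError

__all__ = [
    "replicate_correlation",
    "essential_dropout_auc",
    "wbc_scores",
]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def replicate_correlation(values: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Pearson correlation for every unordered replicate pair, plus the mean.

    ``values`` has one row per guide (or gene) and one column per replicate.
    A pair involving a constant vector gets ``pcc = NaN`` and is flagged
    ``degenerate`` rather than silently skipped.
    """
    if values.shape[1] < 2:
        raise ValidationError("need >= 2 replicate columns")
    finite_rows = np.isfinite(values.to_numpy()).all(axis=1).sum()
    if finite_rows < 3:
        raise ValidationError("need >= 3 rows finite in every replicate")
    rows = []
    for a, b in combinations(values.columns, 2):
        r = _pearson(values[a].to_numpy(float), values[b].to_numpy(float))
        rows.append({"rep_a": a, "rep_b": b, "pcc": r, "degenerate": not np.isfinite(r)})
    pairs = pd.DataFrame(rows)
    mean = float(pairs.loc[~pairs["degenerate"], "pcc"].mean())
    return pairs, mean


def essential_dropout_auc(
    gene_lfc: pd.Series,
    essential: set,
    nonessential: set | None = None,
) -> float:
    """AUC-ROC for essential-gene dropout in one screen.

    Essential genes are the positive class and the ranking score is -LFC, so
    stronger depletion ranks first. Computed through the rank-sum
    (Mann-Whitney) identity with midranks for ties. ``nonessential`` defaults
    to the complement of ``essential`` within the table.
    """
    present = set(gene_lfc.index)
    pos = essential & present
    neg = (nonessential & present) if nonessential is not None else present - essential
    neg -= pos
    if len(pos) < 5 or len(neg) < 5:
        raise ValidationError(
            f"need >= 5 genes per class, got {len(pos)} essential / {len(neg)} other"
        )
    genes = sorted(pos) + sorted(neg)
    scores = -gene_lfc.loc[genes].to_numpy(dtype=float)
    if np.any(~np.isfinite(scores)):
        raise ValidationError("non-finite LFC among classified genes")
    ranks = rankdata(scores)
    n_pos, n_neg = len(pos), len(neg)
    rank_sum = ranks[:n_pos].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def wbc_scores(cgi_profiles: pd.DataFrame) -> pd.Series:
    """Within-vs-between context score per screen.

    ``cgi_profiles`` has genes as rows and a (screen, replicate) MultiIndex on
    columns. For screen s, with r_w the mean correlation among its replicate
    pairs and B the set of correlations between its replicates and those of
    every other screen, wbc(s) = (r_w - mean(B)) / sd(B).
    """
    if cgi_profiles.columns.nlevels != 2:
        raise ValidationError("columns must be a (screen, replicate) MultiIndex")
    screens = list(dict.fromkeys(cgi_profiles.columns.get_level_values(0)))
    if len(screens) < 2:
        raise ValidationError("need >= 2 screens for a between-context background")
    for s in screens:
        if cgi_profiles[s].shape[1] < 2:
            raise ValidationError(f"screen {s!r} has fewer than 2 replicates")
    corr = cgi_profiles.corr()
    out = {}
    for s in screens:
        cols = [c for c in cgi_profiles.columns if c[0] == s]
        within = [corr.loc[a, b] for a, b in combinations(cols, 2)]
        others = [c for c in cgi_profiles.columns if c[0] != s]
        between = np.array([corr.loc[a, b] for a in cols for b in others], dtype=float)
        r_w = float(np.mean(within))
        sd_b = float(np.std(between, ddof=1))
        out[s] = (r_w - float(np.mean(between))) / sd_b
    return pd.Series(out, name="wbc")
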