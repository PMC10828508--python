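"""Independent reference implementations used only to check the package.

Each oracle is deliberately naive (enumeration, brute force, direct
transliteration of the published formulas) and shares no code with the
implementation under test.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special, stats


def bh_bruteforce(p: np.ndarray) -> np.ndarray:
    """O(n^2) step-up: adj_i = min over j with p_(j) >= p_i of p_(j) * n / j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj_sorted = np.empty(n)
    for i in range(n):
        candidates = [sorted_p[j] * n / (j + 1) for j in range(i, n)]
        adj_sorted[i] = min(1.0, min(candidates))
    out = np.empty(n)
    out[order] = adj_sorted
    return out


def hypergeom_enum(n: int, M: int, k: int, N: int) -> float:
    """P(X >= n) by exhaustive summation of the hypergeometric pmf."""
    denom = math.comb(N, M)
    total = 0
    for x in range(n, min(M, k) + 1):
        if M - x <= N - k:
            total += math.comb(k, x) * math.comb(N - k, M - x)
    return total / denom


def auc_concordant_pairs(scores_pos, scores_neg) -> float:
    """AUC as the fraction of concordant (pos > neg) pairs, ties count half."""
    wins = 0.0
    for sp in scores_pos:
        for sn in scores_neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(scores_pos) * len(scores_neg))


def trigamma_inverse_bisect(x: float) -> float:
    """Invert trigamma by bisection (monotone decreasing on (0, inf))."""
    lo, hi = 1e-8, 1e8
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if special.polygamma(1, mid) > x:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def moderated_t_reference(means, s2, n_per_gene, d):
    """Direct transliteration of the empirical-Bayes moderated t formulas.

    Estimates (d0, s0^2) by matching the mean and variance of log s^2 to the
    log-F distribution (digamma/trigamma moments), shrinks each gene's
    variance, and returns (t, df_total, p, d0, s0_sq).
    """
    means = np.asarray(means, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, d / 2.0)
    if evar > 0:
        d0 = min(2.0 * trigamma_inverse_bisect(evar), 1e6)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = 1e6
        s0_sq = float(np.exp(emean))
    s_tilde_sq = (d0 * s0_sq + d * s2) / (d0 + d)
    t = means / np.sqrt(s_tilde_sq / n_per_gene)
    df_total = d0 + d
    p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    return t, df_total, p, d0, s0_sq
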