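"""Shared statistical machinery: Fisher tests, BH adjustment, rank tests.

scipy provides the single-table routines; the vectorised two-sided
Fisher test here exists because differential-methylation calling runs
one exact test per cytosine (10^5-10^6 tables), which is intractable
one scipy call at a time.  It uses the standard two-sided definition
(sum of all hypergeometric outcomes at most as probable as the observed
one, with the customary 1+1e-7 relative tolerance) and is tested
against ``scipy.stats.fisher_exact``.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats

_REL_TOL = 1.0 + 1e-7


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (empty-safe)."""
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    return stats.false_discovery_control(np.clip(p, 0.0, 1.0), method="bh")


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for one 2x2 table of counts."""
    return float(stats.fisher_exact(np.asarray(table, dtype=np.int64),
                                    alternative="two-sided")[1])


def fisher_exact_vec(a, b, c, d) -> np.ndarray:
    """Two-sided Fisher's exact p for tables [[a, b], [c, d]], vectorised.

    Conditions on the margins: X = a ~ Hypergeom(M = a+b+c+d,
    K = a+b, n = a+c).  For each table the two-sided p sums pmf(k) over
    all k in the support with pmf(k) <= pmf(a) * (1 + 1e-7).
    """
    a = np.atleast_1d(np.asarray(a, dtype=np.int64))
    b = np.atleast_1d(np.asarray(b, dtype=np.int64))
    c = np.atleast_1d(np.asarray(c, dtype=np.int64))
    d = np.atleast_1d(np.asarray(d, dtype=np.int64))
    M = a + b + c + d
    K = a + b          # row-1 margin ("tagged")
    n = a + c          # column-1 margin (draw size)
    lo = np.maximum(0, n + K - M)
    hi = np.minimum(K, n)
    width = hi - lo
    if len(width) == 0:
        return np.empty(0, dtype=np.float64)
    kmax = int(width.max())
    # grid of candidate outcomes per table (masked beyond each support)
    k = lo[:, None] + np.arange(kmax + 1)[None, :]
    valid = k <= hi[:, None]
    kc = np.where(valid, k, lo[:, None])
    pmf = stats.hypergeom.pmf(kc, M[:, None], K[:, None], n[:, None])
    pmf = np.where(valid, pmf, 0.0)
    p_obs = stats.hypergeom.pmf(a, M, K, n)
    take = pmf <= (p_obs * _REL_TOL)[:, None]
    out = np.clip(np.sum(np.where(take, pmf, 0.0), axis=1), 0.0, 1.0)
    out[M == 0] = 1.0  # degenerate empty table
    return out


def _midrank_u(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x against y (ties count half)."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mannwhitney_p(x, y, max_enumeration: int = 50_000) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact null by full enumeration of group assignments when the smaller
    group has at most 8 members and C(N, min(n1, n2)) stays below
    ``max_enumeration`` (ties handled via half-counts); otherwise the
    tie-corrected normal approximation with continuity correction.
    Two identical groups of constant values give p = 1.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("Mann-Whitney groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    small = min(n1, n2)
    if small <= 8 and math.comb(n1 + n2, small) <= max_enumeration:
        return _mw_exact(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return float(res.pvalue)


def _mw_exact(x: np.ndarray, y: np.ndarray) -> float:
    n1 = len(x)
    pooled = np.concatenate([x, y])
    n = len(pooled)
    mu = n1 * (n - n1) / 2.0
    u_obs = _midrank_u(x, y)
    d_obs = abs(u_obs - mu)
    hits = total = 0
    idx = np.arange(n)
    for comb in itertools.combinations(idx, n1):
        sel = np.zeros(n, dtype=bool)
        sel[list(comb)] = True
        u = _midrank_u(pooled[sel], pooled[~sel])
        total += 1
        if abs(u - mu) >= d_obs - 1e-12:
            hits += 1
    return hits / total


def group_summary(values: np.ndarray) -> dict:
    """Median and interquartile range of one group."""
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {"n": int(len(values)), "median": float(med),
            "q1": float(q1), "q3": float(q3)}
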