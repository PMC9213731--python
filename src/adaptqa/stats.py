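"""Small-sample exact nonparametric tests with midrank tie handling.

Cohort comparisons use the two-sided Wilcoxon signed-rank test (paired
plan parameters) and the two-sided Mann-Whitney U test (violators vs
non-violators).  Violator groups are small, so exact p-values matter:
both tests are computed exactly for small samples by dynamic programming
over the null distribution of the (doubled, hence integer) midrank sums —
Wilcoxon over all 2^n sign assignments, Mann-Whitney over all
C(n1+n2, n1) group assignments.  Above the exact-size cutoffs the scipy
normal approximations are used.

Conventions: zero differences are dropped (signed rank), ties get
midranks, and the two-sided p is ``min(1, 2 * min(P(T <= t), P(T >= t)))``
with inclusive tails.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = [
    "wilcoxon_signed_rank",
    "mann_whitney",
    "WILCOXON_EXACT_MAX_N",
    "MANN_WHITNEY_EXACT_MAX_TOTAL",
]

WILCOXON_EXACT_MAX_N = 25
MANN_WHITNEY_EXACT_MAX_TOTAL = 30


def _two_sided_p(counts: np.ndarray, stat2: int, total: float) -> float:
    """Two-sided p from an integer-support null distribution (inclusive tails)."""
    cdf = counts[: stat2 + 1].sum() / total
    sf = counts[stat2:].sum() / total
    return float(min(1.0, 2.0 * min(cdf, sf)))


def _signed_rank_counts(ranks2: np.ndarray) -> np.ndarray:
    """Counts of W+ (doubled scale) over all 2^n sign assignments."""
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(a, b=None) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired data (or differences).

    Pass paired samples ``a, b`` (tests ``b - a``) or a single array of
    differences.  Zero differences are dropped.  Returns a dict with the
    W+ statistic, p-value, effective n, and flags: ``insufficient`` when
    fewer than 5 nonzero pairs remain, ``exact`` when the DP enumeration
    was used (n <= 25) rather than the scipy normal approximation.
    """
    d = np.asarray(a, dtype=float) if b is None else np.asarray(b, dtype=float) - np.asarray(
        a, dtype=float
    )
    if b is not None and len(np.asarray(a)) != len(np.asarray(b)):
        raise ValueError("paired samples must have equal length")
    n_pairs = d.size
    d = d[d != 0.0]
    n = d.size
    out = {"n_pairs": n_pairs, "n_nonzero": n, "insufficient": n_pairs < 5}
    if n == 0:
        # all ties: no evidence against symmetry
        out.update(statistic=0.0, p=1.0, exact=True)
        return out
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= WILCOXON_EXACT_MAX_N:
        ranks2 = np.rint(2 * ranks).astype(int)
        counts = _signed_rank_counts(ranks2)
        w2 = int(round(2 * w_plus))
        p = _two_sided_p(counts, w2, 2.0**n)
        out.update(statistic=w_plus, p=p, exact=True)
    else:
        res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method="approx")
        out.update(statistic=w_plus, p=float(res.pvalue), exact=False)
    return out


def _ranksum_counts(ranks2: np.ndarray, n1: int) -> np.ndarray:
    """Counts of group-1 rank sums (doubled scale) over all subsets of size n1."""
    total = int(ranks2.sum())
    # dp[k, s] = number of k-subsets with doubled rank sum s
    dp = np.zeros((n1 + 1, total + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        for k in range(n1, 0, -1):
            shifted = np.zeros(total + 1)
            shifted[r:] = dp[k - 1, : total + 1 - r]
            dp[k] += shifted
    return dp[n1]


def mann_whitney(x, y) -> dict:
    """Two-sided Mann-Whitney U test between two independent samples.

    Exact by rank-sum enumeration (DP, midranks) for pooled sizes up to
    30; scipy's tie-corrected normal approximation above.  Returns the U
    statistic of the first sample, the p-value, group sizes, and flags
    ``insufficient`` (either group < 3) and ``exact``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    out = {"n1": n1, "n2": n2, "insufficient": min(n1, n2) < 3}
    if n1 == 0 or n2 == 0:
        out.update(statistic=float("nan"), p=float("nan"), exact=False)
        return out
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    out["statistic"] = u1
    if np.ptp(pooled) == 0.0:
        # all values identical: no separation whatsoever
        out.update(p=1.0, exact=True)
        return out
    if n1 + n2 <= MANN_WHITNEY_EXACT_MAX_TOTAL:
        ranks2 = np.rint(2 * ranks).astype(int)
        counts = _ranksum_counts(ranks2, n1)
        total = counts.sum()  # = C(n1+n2, n1)
        r1_2 = int(round(2 * r1))
        out.update(p=_two_sided_p(counts, r1_2, total), exact=True)
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        out.update(p=float(res.pvalue), exact=False)
    return out
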