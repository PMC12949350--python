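"""Rank-based and exact statistical primitives used by the fate pipeline.

The decision procedure leans on a small set of classical nonparametric tests:
the paired Wilcoxon signed-rank test (lateral gene vs vertically inherited
homolog, paired by RNA-seq sample), the Wilcoxon rank-sum test (lateral gene
vs donor ortholog, unpaired), the Kruskal-Wallis / Dunn post hoc combination
for the five-way expression categorisation, Benjamini-Hochberg FDR control
across genes, and the exact binomial test for category enrichment.

These are implemented here from their published formulas so that every
p-value entering a fate call has a single well-defined convention
(two-sided throughout, tie and zero handling as documented per function).
scipy/statsmodels equivalents are used as independent cross-checks in the
test suite.
"""

from __future__ import annotations

import math
from collections.abc import Sequence

import numpy as np
from scipy.stats import norm, rankdata, binom
from scipy.stats import kruskal as _scipy_kruskal

__all__ = [
    "bh_adjust",
    "exact_binomial_test",
    "dunn_test",
    "signed_rank_test",
    "rank_sum_test",
    "kruskal_wallis",
]


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sorted p-values p_(1) <= ... <= p_(m) are scaled to p_(i) * m / i and a
    cumulative minimum is taken from the largest rank down, so adjusted values
    are monotone in rank and capped at 1.  Input order is preserved.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def exact_binomial_test(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p-value.

    Sums Binomial(n, p0) probabilities of every outcome whose probability does
    not exceed that of the observed count.  A relative guard of 1 + 1e-7 on
    the comparison absorbs floating-point noise in the point masses (the same
    convention as R's binom.test).
    """
    k = int(k)
    n = int(n)
    if n < 0 or k < 0 or k > n:
        raise ValueError(f"invalid counts: k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"null proportion must be in (0, 1), got {p0}")
    pmf = binom.pmf(np.arange(n + 1), n, p0)
    threshold = pmf[k] * (1.0 + 1e-7)
    return float(min(1.0, pmf[pmf <= threshold].sum()))


def _tie_term(values: np.ndarray) -> float:
    """Sum of t^3 - t over groups of tied values."""
    _, counts = np.unique(values, return_counts=True)
    counts = counts[counts > 1].astype(float)
    return float(np.sum(counts**3 - counts))


def dunn_test(groups: Sequence[np.ndarray], pair: tuple[int, int]) -> tuple[float, float]:
    """Dunn's post hoc z test between two groups of a pooled ranking.

    All groups are ranked together (mid-ranks for ties); for groups i, j

        z = (rbar_i - rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))

    with the tie correction T = sum(t^3 - t) / (12 (N - 1)).  Returns the z
    statistic and the two-sided normal p-value.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    i, j = pair
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    if n_total < 3:
        raise ValueError("pooled sample size must be >= 3")
    ranks = rankdata(pooled)
    bounds = np.cumsum([0] + [a.size for a in arrays])
    mean_ranks = [ranks[bounds[g] : bounds[g + 1]].mean() for g in range(len(arrays))]
    tie = _tie_term(pooled) / (12.0 * (n_total - 1))
    var = (n_total * (n_total + 1) / 12.0 - tie) * (1.0 / arrays[i].size + 1.0 / arrays[j].size)
    if var <= 0:
        # all observations tied: no information, no difference
        return 0.0, 1.0
    z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(min(1.0, p))


def _signed_rank_exact_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-sided p for the signed-rank statistic over +/- assignments.

    Enumerates the null distribution of W+ = sum of ranks with positive sign
    by dynamic programming over the 2^n equiprobable sign vectors.  Only used
    with integer ranks (no ties).
    """
    total = int(ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks.astype(int):
        counts[r:] += counts[: total + 1 - r]
    counts /= counts.sum()
    w = int(round(w_plus))
    cdf = counts[: w + 1].sum()
    sf = counts[w:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def signed_rank_test(
    x: Sequence[float],
    y: Sequence[float] | None = None,
    exact_limit: int = 26,
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test, two-sided, Pratt zero handling.

    Differences d = x - y (or x directly) are ranked by absolute value with
    zeros included in the ranking but dropped from the statistic (Pratt).  The
    exact sign-permutation distribution is used when there are fewer than
    ``exact_limit`` pairs and no zeros or tied absolute differences; otherwise
    the normal approximation with Cureton's zero adjustment and the standard
    tie correction is applied (no continuity correction).

    Returns (W+, p).  All differences zero gives p = 1 (no evidence).
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        yv = np.asarray(y, dtype=float)
        if yv.shape != d.shape:
            raise ValueError("paired vectors must have equal length")
        d = d - yv
    if d.size < 2:
        raise ValueError("need at least two pairs")
    n = d.size
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    n_zero = int(np.sum(d == 0))
    if n_zero == n:
        return w_plus, 1.0

    nonzero_ranks = ranks[d != 0]
    has_ties = np.unique(nonzero_ranks).size != nonzero_ranks.size
    if n_zero == 0 and not has_ties and n < exact_limit:
        return w_plus, _signed_rank_exact_p(w_plus, ranks)

    mean = (n * (n + 1) - n_zero * (n_zero + 1)) / 4.0
    var = (n * (n + 1) * (2 * n + 1) - n_zero * (n_zero + 1) * (2 * n_zero + 1)) / 24.0
    var -= _tie_term(nonzero_ranks) / 48.0
    if var <= 0:
        return w_plus, 1.0
    z = (w_plus - mean) / math.sqrt(var)
    return w_plus, float(min(1.0, 2.0 * norm.sf(abs(z))))


def _rank_sum_exact_p(u: float, n1: int, n2: int) -> float:
    """Exact two-sided p for the Mann-Whitney U statistic (no ties).

    Enumerates the null distribution of the first sample's rank sum by a
    subset-sum count over n1-subsets of the pooled ranks 1..N, then shifts to
    the U scale.
    """
    n_total = n1 + n2
    max_sum = n_total * (n_total + 1) // 2
    # dp[k, s] = number of k-subsets of {1..N} with rank sum s
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for rank in range(1, n_total + 1):
        dp[1:, rank:] += dp[:-1, :-rank].copy()  # copy: each rank used once
    counts = dp[n1]
    counts = counts / counts.sum()
    u_int = int(round(u)) + n1 * (n1 + 1) // 2  # back to rank-sum scale
    cdf = counts[: u_int + 1].sum()
    sf = counts[u_int:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    exact_limit: int = 26,
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test, two-sided.

    Returns (U1, p) where U1 is the Mann-Whitney statistic of the first
    sample.  The exact distribution is used when both samples are smaller
    than ``exact_limit`` and there are no ties across the pooled data;
    otherwise the normal approximation with tie correction (no continuity
    correction).
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0

    has_ties = np.unique(pooled).size != pooled.size
    if not has_ties and n1 < exact_limit and n2 < exact_limit:
        return u1, _rank_sum_exact_p(u1, n1, n2)

    n_total = n1 + n2
    mean = n1 * n2 / 2.0
    tie = _tie_term(pooled)
    var = n1 * n2 / 12.0 * ((n_total + 1) - tie / (n_total * (n_total - 1)))
    if var <= 0:
        return u1, 1.0
    z = (u1 - mean) / math.sqrt(var)
    return u1, float(min(1.0, 2.0 * norm.sf(abs(z))))


def kruskal_wallis(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H test across groups (scipy), with the degenerate
    all-identical case mapped to (H=0, p=1) rather than an error."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = _scipy_kruskal(*arrays)
    return float(h), float(p)
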