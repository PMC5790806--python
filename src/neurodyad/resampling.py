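"""Nonparametric comparisons across social-distance categories and the
topology-preserving network permutation test.

Composite neural similarities are compared between one distance category
and all remaining dyads with a two-sample Kolmogorov-Smirnov test
(distribution-level) and a Wilcoxon rank-sum test (location-level; exact
null by enumeration for small samples, normal approximation with tie and
continuity corrections otherwise).

The permutation test keeps the social network's topology fixed and
shuffles which subject occupies which network position: a random bijection
of subjects onto nodes re-labels every dyad's social distance while the
dyadic similarity values stay attached to the subject pairs, giving a null
for the per-category mean composite similarity.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats

__all__ = [
    "GroupTestResult",
    "PermutationResult",
    "ks_group_vs_rest",
    "wilcoxon_group_vs_rest",
    "wilcoxon_pairwise",
    "rank_sum_test",
    "exact_rank_sum_p",
    "network_permutation_test",
]

EXACT_LIMIT = 400  # use exact enumeration when n1 * n2 <= this


@dataclasses.dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    p: float
    n_group: int
    n_rest: int
    test: str
    sidedness: str = "two_tailed"
    method: str = "asymptotic"


@dataclasses.dataclass(frozen=True)
class PermutationResult:
    categories: tuple[int, ...]
    observed: np.ndarray
    null_distribution: np.ndarray  # [n_perm x n_categories]
    p: np.ndarray
    n_perm: int
    seed: int
    sidedness: str = "two_tailed"


def _split(values, categories, k):
    values = np.asarray(values, dtype=float)
    categories = np.asarray(categories)
    grp = values[categories == k]
    rest = values[categories != k]
    if grp.size == 0 or rest.size == 0:
        raise ValueError(f"category {k} or its complement is empty")
    return grp, rest


def ks_group_vs_rest(values, categories, k) -> GroupTestResult:
    """Two-sample two-sided KS test of category-k dyads vs all other dyads."""
    grp, rest = _split(values, categories, k)
    res = stats.ks_2samp(grp, rest, alternative="two-sided", method="asymp")
    return GroupTestResult(
        statistic=float(res.statistic), p=float(res.pvalue),
        n_group=grp.size, n_rest=rest.size, test="ks",
    )


def exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided rank-sum p by dynamic programming over the ranks.

    Returns (W, p) where W is the sum of the pooled midranks of ``x``.
    The null distribution of W over all C(n1+n2, n1) equally likely group
    assignments is built by a subset-sum polynomial over doubled midranks
    (doubling makes tied midranks integral), so ties are handled exactly.
    Two-sided p = 2 * min(P(W <= w), P(W >= w)), capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w_obs = float(ranks[: x.size].sum())

    r2 = np.rint(2 * ranks).astype(np.int64)  # doubled midranks are integers
    n1 = x.size
    total = int(r2.sum())
    # dp[m, s] = number of m-subsets of the ranks with doubled sum s
    dp = np.zeros((n1 + 1, total + 1))
    dp[0, 0] = 1.0
    for r in r2:
        dp[1:, r:] += dp[:-1, : total + 1 - r]
    counts = dp[n1]
    n_total = counts.sum()  # C(n1+n2, n1)
    w2 = int(round(2 * w_obs))
    p_le = counts[: w2 + 1].sum() / n_total
    p_ge = counts[w2:].sum() / n_total
    return w_obs, float(min(1.0, 2.0 * min(p_le, p_ge)))


def _asymptotic_rank_sum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Normal approximation with tie correction and continuity correction."""
    pooled = np.concatenate([x, y])
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    mean = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return w, 1.0
    dev = w - mean
    z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var) if dev != 0 else 0.0
    return w, float(2.0 * stats.norm.sf(abs(z)))


def rank_sum_test(x, y) -> GroupTestResult:
    """Wilcoxon rank-sum test, W = rank sum of the first sample.

    Exact enumeration when n1*n2 <= 400, otherwise the tie- and
    continuity-corrected normal approximation.  All values tied across
    both samples yields p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if np.unique(np.concatenate([x, y])).size == 1:
        warnings.warn("all values tied across both groups; p = 1", stacklevel=2)
        w = x.size * (x.size + y.size + 1) / 2.0
        return GroupTestResult(w, 1.0, x.size, y.size, "wilcoxon", method="degenerate")
    if x.size * y.size <= EXACT_LIMIT:
        w, p = exact_rank_sum_p(x, y)
        method = "exact"
    else:
        w, p = _asymptotic_rank_sum_p(x, y)
        method = "asymptotic"
    return GroupTestResult(w, p, x.size, y.size, "wilcoxon", method=method)


def wilcoxon_group_vs_rest(values, categories, k) -> GroupTestResult:
    """Rank-sum test of category-k dyads against all remaining dyads."""
    grp, rest = _split(values, categories, k)
    return rank_sum_test(grp, rest)


def wilcoxon_pairwise(values, categories, k1, k2) -> GroupTestResult:
    """Rank-sum test between two specific distance categories."""
    values = np.asarray(values, dtype=float)
    categories = np.asarray(categories)
    a = values[categories == k1]
    b = values[categories == k2]
    if a.size == 0 or b.size == 0:
        raise ValueError("both categories must be nonempty")
    return rank_sum_test(a, b)


def network_permutation_test(
    composite,
    dyad_index: np.ndarray,
    categories,
    n_perm: int = 1000,
    seed: int = 0,
    sidedness: str = "two_tailed",
) -> PermutationResult:
    """Node-relabeling permutation test of per-category mean similarity.

    ``dyad_index`` holds integer subject indices (D x 2) and ``categories``
    each dyad's social-distance category as induced by the fixed network.
    Each permutation draws a uniform random bijection of subjects onto
    network positions and re-derives every dyad's category, leaving the
    similarity values (and the network topology) untouched.  Two-sided
    p-values are computed around the null mean with the add-one
    correction; ``sidedness="greater"``/``"less"`` give one-sided tails.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    composite = np.asarray(composite, dtype=float)
    pairs = np.asarray(dyad_index, dtype=int)
    categories = np.asarray(categories, dtype=int)
    d = composite.size
    if pairs.shape != (d, 2) or categories.size != d:
        raise ValueError("composite, dyad_index and categories must align")
    n = int(pairs.max()) + 1

    # category lookup by subject pair; permutations only re-index this
    catmat = np.zeros((n, n), dtype=int)
    catmat[pairs[:, 0], pairs[:, 1]] = categories
    catmat[pairs[:, 1], pairs[:, 0]] = categories

    cats = np.unique(categories)
    ncat = cats.size
    code = np.searchsorted(cats, categories)

    def category_means(codes: np.ndarray) -> np.ndarray:
        sums = np.bincount(codes, weights=composite, minlength=ncat)
        cnts = np.bincount(codes, minlength=ncat)
        with np.errstate(invalid="ignore"):
            return np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)

    observed = category_means(code)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, ncat))
    for b in range(n_perm):
        perm = rng.permutation(n)
        cat_b = catmat[perm[pairs[:, 0]], perm[pairs[:, 1]]]
        null[b] = category_means(np.searchsorted(cats, cat_b))

    null_mean = np.nanmean(null, axis=0)
    if sidedness == "two_tailed":
        exceed = np.nansum(
            np.abs(null - null_mean) >= np.abs(observed - null_mean) - 1e-12, axis=0
        )
    elif sidedness == "greater":
        exceed = np.nansum(null >= observed - 1e-12, axis=0)
    elif sidedness == "less":
        exceed = np.nansum(null <= observed + 1e-12, axis=0)
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    p = (1.0 + exceed) / (n_perm + 1.0)
    return PermutationResult(
        categories=tuple(int(c) for c in cats),
        observed=observed,
        null_distribution=null,
        p=p,
        n_perm=n_perm,
        seed=seed,
        sidedness=sidedness,
    )
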