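"""Self-implemented statistical primitives shared across the pipeline.

These are deliberately written out rather than delegated: the BH step-up,
the exact Mann-Whitney null and the empirical-Bayes machinery are the
analytical core of the pipeline, and each is checked against an
independent oracle in the test suite.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import special

from mirpanel.matrix import ConfigurationError


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} min(1, m * p_(j) / j) over the ordered p-values,
    mapped back to the input order.  Monotone: q >= p elementwise.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ConfigurationError("bh_adjust expects a 1-d vector")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ConfigurationError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two equally-shaped 2-d arrays.

    Row pairs where either side has zero variance yield NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ConfigurationError("shape mismatch in pearson_rows")
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / den
    r = np.where(den == 0, np.nan, r)
    return np.clip(r, -1.0, 1.0)


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r with two-tailed t-test p-values (df = n - 2)."""
    from scipy import stats as sps

    r = pearson_rows(x, y)
    n = x.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    return r, np.where(np.isnan(r), np.nan, np.clip(p, 0.0, 1.0))


@lru_cache(maxsize=128)
def _mannwhitney_sf_table(n: int, m: int) -> np.ndarray:
    """Exact null survival table of the Mann-Whitney U statistic.

    Entry u of the returned vector is P(U >= u) under the null that all
    C(n+m, n) orderings of n target and m reference values are equally
    likely.  Built by dynamic-programming convolution; assumes no ties.
    """
    # c(k, j, u): orderings of k targets and j references with U = u.
    # Recurrence on the largest pooled value: if it is a target it beats
    # all j references (c(k-1, j, u-j)); if a reference, c(k, j-1, u).
    max_u = n * m
    table = np.zeros((n + 1, max_u + 1), dtype=float)
    table[:, 0] = 1.0  # c(k, 0, 0) = 1 and c(0, j, 0) = 1
    for j in range(1, m + 1):
        for k in range(1, n + 1):
            # table[k-1] already holds c(k-1, j, .); table[k] holds c(k, j-1, .)
            if j <= max_u:
                table[k, j:] += table[k - 1, : max_u + 1 - j]
    counts = table[n]
    total = counts.sum()  # == C(n+m, n)
    sf = counts[::-1].cumsum()[::-1] / total
    return sf


def rank_sum_p_greater(target: np.ndarray, reference: np.ndarray) -> float:
    """One-sided (greater) Wilcoxon rank-sum p of target vs reference.

    Exact when the pooled values are tie-free and the table is tractable;
    midranks with a normal approximation (continuity-corrected, tie
    variance adjustment) otherwise.
    """
    target = np.asarray(target, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if target.size == 0:
        raise ConfigurationError("empty target spot set")
    if reference.size == 0:
        raise ConfigurationError("empty reference spot set")
    n, m = target.size, reference.size
    pooled = np.concatenate([target, reference])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and n * m <= 20000:
        ref_sorted = np.sort(reference)
        u = int(np.searchsorted(ref_sorted, target, side="left").sum())
        return float(_mannwhitney_sf_table(n, m)[u])
    return _rank_sum_normal(target, reference)


def _rank_sum_normal(target: np.ndarray, reference: np.ndarray) -> float:
    from scipy import stats as sps

    n, m = target.size, reference.size
    pooled = np.concatenate([target, reference])
    ranks = sps.rankdata(pooled)
    u = ranks[:n].sum() - n * (n + 1) / 2.0
    mu = n * m / 2.0
    nm = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (nm * (nm - 1))
    var = n * m / 12.0 * (nm + 1 - tie_term)
    if var == 0:
        return 1.0
    z = (u - mu - 0.5) / np.sqrt(var)
    return float(special.ndtr(-z))


def rank_sum_p_greater_batch(u_stats: np.ndarray, n: int, m: int) -> np.ndarray:
    """Exact one-sided p for a vector of tie-free U statistics with common
    group sizes -- the vectorized path used for detection calls."""
    sf = _mannwhitney_sf_table(n, m)
    u = np.asarray(u_stats, dtype=int)
    return sf[np.clip(u, 0, n * m)]


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    Standard monotone inversion used by the empirical-Bayes variance
    moment estimator; x -> 0+ maps to y -> +inf.
    """
    if x <= 0:
        return float("inf")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)
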