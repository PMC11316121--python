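"""Exact and approximate test statistics used by the pipeline.

Three primitives are implemented here rather than delegated:

* :func:`hypergeom_tail` — one-sided over-representation tail probability
  P(X >= k), computed in log space so that tiny p-values survive for large
  universes.
* :func:`mann_whitney_u` — two-sided Mann-Whitney U. Exact by complete
  enumeration of group labelings for small, tie-free samples; otherwise the
  normal approximation with midrank tie correction and continuity correction.
* :func:`shapiro_wilk` — the W statistic with Royston's weight and p-value
  approximations (valid for 3 <= n <= 5000).

scipy implements all three as well; the package keeps its own versions so
that the test suite can cross-check the two routes against each other and
against brute-force enumeration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln, ndtr, ndtri

from .models import ValidationError

__all__ = [
    "hypergeom_tail",
    "mann_whitney_u",
    "shapiro_wilk",
    "MannWhitneyResult",
    "ShapiroWilkResult",
]


# ---------------------------------------------------------------------------
# hypergeometric upper tail
# ---------------------------------------------------------------------------

def _log_comb(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K annotated, n drawn).

    This is the one-sided Fisher over-representation probability of seeing
    ``k`` or more annotated genes among ``n`` drawn from a universe of ``N``
    containing ``K`` annotated.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValidationError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    log_denom = _log_comb(N, n)
    hi = min(K, n)
    lo = max(k, n - (N - K))
    terms = [
        _log_comb(K, i) + _log_comb(N - K, n - i) - log_denom
        for i in range(lo, hi + 1)
    ]
    if not terms:
        return 0.0
    m = max(terms)
    p = math.exp(m) * sum(math.exp(t - m) for t in terms)
    return min(1.0, p)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    p_two_sided: float
    n_a: int
    n_b: int
    method: str  # "exact" | "normal_approx"


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _u_of_a(pooled_ranks: np.ndarray, idx_a: Sequence[int], n_a: int, n_b: int) -> float:
    r_a = float(pooled_ranks[list(idx_a)].sum())
    return r_a - n_a * (n_a + 1) / 2.0


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    exact_limit: int = 20,
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    ``U`` is reported as min(U_a, U_b) with midranks for ties. The null
    distribution is obtained by complete enumeration of all C(n_a+n_b, n_a)
    group labelings when the pooled sample is tie-free and no larger than
    ``exact_limit``; otherwise the normal approximation with tie and
    continuity corrections is used. The two-sided p is min(1, 2 * one-sided).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    u_a = _u_of_a(ranks, range(n_a), n_a, n_b)
    u_b = n_a * n_b - u_a
    u_min = min(u_a, u_b)

    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and n_a + n_b <= exact_limit:
        # exact: P(U_a <= u_min) over all labelings (U_a's null law is
        # symmetric, so the lower tail of U_a is the tail of min(U_a, U_b))
        total = 0
        hits = 0
        n = n_a + n_b
        tol = 1e-9
        for idx in combinations(range(n), n_a):
            u = _u_of_a(ranks, idx, n_a, n_b)
            total += 1
            if u <= u_min + tol:
                hits += 1
        p_one = hits / total
        return MannWhitneyResult(u_min, min(1.0, 2.0 * p_one), n_a, n_b, "exact")

    mu = n_a * n_b / 2.0
    n = n_a + n_b
    # tie correction on the variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        # all pooled values identical: no evidence either way
        return MannWhitneyResult(u_min, 1.0, n_a, n_b, "normal_approx")
    z = (u_min - mu + 0.5) / math.sqrt(var)  # continuity-corrected lower tail
    p_one = float(ndtr(z))
    return MannWhitneyResult(u_min, min(1.0, 2.0 * p_one), n_a, n_b, "normal_approx")


# ---------------------------------------------------------------------------
# Shapiro-Wilk (Royston's approximation)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapiroWilkResult:
    W: float
    p: float
    n: int


def _royston_weights(n: int) -> np.ndarray:
    m = ndtri((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    mm = float(m @ m)
    c = m / math.sqrt(mm)
    a = c.copy()
    u = 1.0 / math.sqrt(n)
    if n > 5:
        a_n = (
            -2.706056 * u**5
            + 4.434685 * u**4
            - 2.071190 * u**3
            - 0.147981 * u**2
            + 0.221157 * u
            + c[-1]
        )
        a_n1 = (
            -3.582633 * u**5
            + 5.682633 * u**4
            - 1.752461 * u**3
            - 0.293762 * u**2
            + 0.042981 * u
            + c[-2]
        )
        phi = (mm - 2 * m[-1] ** 2 - 2 * m[-2] ** 2) / (1 - 2 * a_n**2 - 2 * a_n1**2)
        a = m / math.sqrt(phi)
        a[-1] = a_n
        a[-2] = a_n1
        a[0] = -a_n
        a[1] = -a_n1
    elif n > 3:
        a_n = (
            -2.706056 * u**5
            + 4.434685 * u**4
            - 2.071190 * u**3
            - 0.147981 * u**2
            + 0.221157 * u
            + c[-1]
        )
        phi = (mm - 2 * m[-1] ** 2) / (1 - 2 * a_n**2)
        a = m / math.sqrt(phi)
        a[-1] = a_n
        a[0] = -a_n
    else:  # n == 3, exact weights
        a = np.array([-math.sqrt(0.5), 0.0, math.sqrt(0.5)])
    return a


def shapiro_wilk(sample: Sequence[float]) -> ShapiroWilkResult:
    """Shapiro-Wilk normality test for 3 <= n <= 5000.

    W is the squared correlation between the order statistics and Royston's
    approximately-optimal linear combination of normal scores; the p-value
    comes from Royston's W-to-normal transformation (arcsine law for n = 3,
    log-normal transforms otherwise), upper tail: small p means departure
    from normality.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    if n < 3 or n > 5000:
        raise ValidationError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {n}")
    if x[0] == x[-1]:
        raise ValidationError("Shapiro-Wilk is undefined for a constant sample")
    a = _royston_weights(n)
    xbar = x.mean()
    ssq = float(((x - xbar) ** 2).sum())
    w = float((a @ x) ** 2 / ssq)
    w = min(w, 1.0)

    if n == 3:
        p = (6.0 / math.pi) * (math.asin(math.sqrt(w)) - math.asin(math.sqrt(0.75)))
        p = min(1.0, max(0.0, p))
        return ShapiroWilkResult(w, p, n)
    if n <= 11:
        g = -2.273 + 0.459 * n
        mu = 0.5440 - 0.39978 * n + 0.025054 * n**2 - 0.0006714 * n**3
        sigma = math.exp(1.3822 - 0.77857 * n + 0.062767 * n**2 - 0.0020322 * n**3)
        if g - math.log(1.0 - w) <= 0:
            return ShapiroWilkResult(w, 0.0, n)
        wt = -math.log(g - math.log(1.0 - w))
    else:
        ln_n = math.log(n)
        mu = -1.5861 - 0.31082 * ln_n - 0.083751 * ln_n**2 + 0.0038915 * ln_n**3
        sigma = math.exp(-0.4803 - 0.082676 * ln_n + 0.0030302 * ln_n**2)
        wt = math.log(1.0 - w)
    z = (wt - mu) / sigma
    p = float(1.0 - ndtr(z))
    return ShapiroWilkResult(w, p, n)
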