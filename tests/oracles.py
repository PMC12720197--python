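"""Independent brute-force oracles used only by the tests.

These deliberately avoid the code paths (and the scipy routines) that the
implementation uses: the Clopper-Pearson oracle bisects exact binomial tail
sums built from ``math.comb``; the Fisher oracle enumerates every
margin-preserving table with exact integer hypergeometric numerators.
"""

from __future__ import annotations

import math


def binom_tail_upper(x: int, n: int, p: float) -> float:
    """P(X >= x) for X ~ Binomial(n, p), by direct summation."""
    return sum(math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(x, n + 1))


def binom_tail_lower(x: int, n: int, p: float) -> float:
    """P(X <= x) for X ~ Binomial(n, p), by direct summation."""
    return sum(math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(0, x + 1))


def _bisect(f, lo: float, hi: float, tol: float = 1e-12) -> float:
    flo = f(lo)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if hi - lo < tol:
            return mid
        if (f(mid) > 0) == (flo > 0):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def clopper_pearson_bisect(x: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """CP bounds found by bisection over cumulative binomial tails.

    Lower bound: the p at which P(X >= x | p) = alpha/2 (0 when x = 0);
    upper bound: the p at which P(X <= x | p) = alpha/2 (1 when x = n).
    """
    alpha = 1.0 - confidence
    low = 0.0 if x == 0 else _bisect(lambda p: binom_tail_upper(x, n, p) - alpha / 2, 0.0, 1.0)
    high = 1.0 if x == n else _bisect(lambda p: binom_tail_lower(x, n, p) - alpha / 2, 0.0, 1.0)
    return low, high


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration (probability-mass criterion).

    Numerators are exact integers C(r1, k) * C(r2, c1 - k); a table counts
    toward p when its numerator is <= the observed one within relative
    tolerance 1e-7 (ties included).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    num_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = 0
    for k in range(lo, hi + 1):
        num_k = math.comb(r1, k) * math.comb(r2, c1 - k)
        if num_k <= num_obs + num_obs * 1e-7:
            total += num_k
    return total / denom


def chi2_2x2_closed_form(a: int, b: int, c: int, d: int) -> float:
    """Uncorrected 2x2 chi-square statistic: n(ad - bc)^2 / (r1 r2 c1 c2)."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
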