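"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths they check: tails are summed
term-by-term from the probability mass recurrence (seeded by a single
log-space evaluation), and interval overlap is decided by all-pairs
comparison.
"""

from __future__ import annotations

import math


def poisson_upper_tail(k: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam) by ascending pmf summation."""
    if k <= 0:
        return 1.0
    log_term = k * math.log(lam) - lam - math.lgamma(k + 1)
    term = math.exp(log_term)
    total = 0.0
    i = k
    while True:
        total += term
        i += 1
        term *= lam / i
        if term < total * 1e-20 or term < 5e-324:
            break
    return min(total, 1.0)


def binom_upper_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p) by ascending pmf summation."""
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    log_term = (
        math.lgamma(n + 1)
        - math.lgamma(k + 1)
        - math.lgamma(n - k + 1)
        + k * math.log(p)
        + (n - k) * math.log(1.0 - p)
    )
    term = math.exp(log_term)
    total = 0.0
    odds = p / (1.0 - p)
    for i in range(k, n + 1):
        total += term
        if i < n:
            term *= (n - i) / (i + 1) * odds
        if term < total * 1e-20:
            break
    return min(total, 1.0)


def binom_lower_tail(k: int, n: int, p: float) -> float:
    """P(X <= k) for X ~ Binomial(n, p), via the mirrored upper tail."""
    return binom_upper_tail(n - k, n, 1.0 - p)


def poisson_difference_oracle(
    k_a: int,
    k_b: int,
    norm_a: float = 1.0,
    norm_b: float = 1.0,
    method: str = "conditional_binomial",
    p_floor: float = 1e-300,
    lambda_min: float = 1.0,
) -> float:
    """Reference p-value for the two-sample Poisson comparison."""
    rate_a, rate_b = k_a / norm_a, k_b / norm_b
    if method == "poisson_tail":
        if k_a == 0 and k_b == 0:
            return 1.0
        if rate_a >= rate_b:
            k_max, k_min, ratio = k_a, k_b, norm_a / norm_b
        else:
            k_max, k_min, ratio = k_b, k_a, norm_b / norm_a
        lam = max(k_min * ratio, lambda_min)
        p = poisson_upper_tail(k_max, lam)
    elif method == "conditional_binomial":
        n = k_a + k_b
        if n == 0:
            return 1.0
        pa = norm_a / (norm_a + norm_b)
        p = binom_upper_tail(k_a, n, pa) if rate_a >= rate_b else binom_lower_tail(k_a, n, pa)
    else:
        raise ValueError(method)
    return min(max(p, p_floor), 1.0)


def brute_force_overlap(intervals_a, intervals_b, min_overlap: int = 1):
    """All-pairs common/unique partition of two interval sets.

    Each interval is (chrom, start, end); returns (common_a, common_b)
    index sets.
    """

    def shares(x, y) -> bool:
        return x[0] == y[0] and min(x[2], y[2]) - max(x[1], y[1]) >= min_overlap

    common_a = {i for i, a in enumerate(intervals_a)
                if any(shares(a, b) for b in intervals_b)}
    common_b = {j for j, b in enumerate(intervals_b)
                if any(shares(b, a) for a in intervals_a)}
    return common_a, common_b


def pooled_t_test(x, y):
    """Textbook equal-variance two-sample t statistic and two-sided p."""
    import math as _m

    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    ssx = sum((v - mx) ** 2 for v in x)
    ssy = sum((v - my) ** 2 for v in y)
    df = nx + ny - 2
    sp2 = (ssx + ssy) / df
    se = _m.sqrt(sp2 * (1 / nx + 1 / ny))
    t = (mx - my) / se
    # two-sided p from the t CDF via the regularized incomplete beta
    from scipy.special import betainc

    p = betainc(df / 2.0, 0.5, df / (df + t * t))
    return t, float(p)
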