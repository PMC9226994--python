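"""Independent brute-force oracles used by the test suite.

Every function here is deliberately written from first principles (loops,
exact rational arithmetic) and shares no code with the package, so a test
comparing the two is a genuine dual-route check.
"""

from __future__ import annotations

import math
from fractions import Fraction


def quantile_linear(values, p: float) -> float:
    """Linear-interpolation quantile: order statistic k at prob (k-1)/(n-1)."""
    v = sorted(float(x) for x in values)
    n = len(v)
    h = (n - 1) * p
    lo = int(math.floor(h))
    frac = h - lo
    if lo + 1 >= n:
        return v[lo]
    return v[lo] + (v[lo + 1] - v[lo]) * frac


def cover_count(values, avg: float, half: float) -> int:
    c = 0
    for x in values:
        if avg - half <= x <= avg + half:
            c += 1
    return c


def zero_zone_scan(hc, sle, avg: float, sd: float, n_max: int) -> int:
    """Smallest n in 0..n_max maximizing the HC-minus-SLE cover difference."""
    best_n, best_diff = 0, -2.0
    for n in range(n_max + 1):
        half = n * sd / 10.0
        diff = cover_count(hc, avg, half) / len(hc) - cover_count(sle, avg, half) / len(sle)
        if diff > best_diff:
            best_n, best_diff = n, diff
    return best_n


def rank_direct(v: float, lower: float, upper: float, sd: float,
                band_steps: int = 10, floor: int = -3) -> int:
    """Rank by scanning expanding bands instead of closed-form arithmetic."""
    if lower <= v <= upper:
        return 0
    d = max(lower - v, v - upper)
    step = sd / 10.0
    k = 1
    while k * step < d - 1e-9 * step:
        k += 1
    band = (k - 1) // band_steps + 1
    return -min(band, -floor)


def auc_pairs(scores_sle, scores_hc) -> float:
    """AUC by explicit ordered-pair counting (lower score = more SLE-like)."""
    wins = 0.0
    for s in scores_sle:
        for h in scores_hc:
            if s < h:
                wins += 1.0
            elif s == h:
                wins += 0.5
    return wins / (len(scores_sle) * len(scores_hc))


def youden_max(scores_sle, scores_hc) -> float:
    """Maximum achievable Youden J over every real cutpoint.

    Positive call: score < threshold.  Only thresholds strictly between
    adjacent distinct scores (plus the two extremes) can change the
    confusion table, so scanning those is exhaustive.
    """
    u = sorted(set(list(scores_sle) + list(scores_hc)))
    cands = [u[0] - 1.0] + [(a + b) / 2.0 for a, b in zip(u, u[1:])] + [u[-1] + 1.0]
    best = -2.0
    for t in cands:
        sens = sum(1 for s in scores_sle if s < t) / len(scores_sle)
        spec = sum(1 for h in scores_hc if h >= t) / len(scores_hc)
        best = max(best, sens + spec - 1.0)
    return best


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full enumeration with exact rationals.

    Sums hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed table's
    (probability-mass criterion).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def pmf(k: int) -> Fraction:
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), math.comb(n, c1))

    p_obs = pmf(a)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = pmf(k)
        if pk <= p_obs:
            total += pk
    return float(total)


def spearman_midrank(x, y) -> float:
    """Spearman rho: Pearson correlation of midranks, from scratch."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            mid = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = mid
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den if den else float("nan")
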