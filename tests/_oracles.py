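"""Independent brute-force oracles used by the test suite.

Everything here is deliberately implemented from first principles (sorting,
exact rational arithmetic, exhaustive enumeration) and shares no code with
the package under test.
"""

from __future__ import annotations

import math
from fractions import Fraction


def sorted_median(values):
    xs = sorted(values)
    n = len(xs)
    mid = n // 2
    return xs[mid] if n % 2 else (xs[mid - 1] + xs[mid]) / 2


def mad_oracle(values, constant=1.4826):
    med = sorted_median(values)
    return constant * sorted_median([abs(x - med) for x in values])


def call_hits_oracle(values, k=2.0, constant=1.4826):
    """Direct-formula hit calling on a {gene: value} mapping.

    Returns ``(low set, high set)`` or ``None`` when the MAD is zero (the
    degenerate case where thresholds are undefined).
    """
    finite = {g: v for g, v in values.items() if math.isfinite(v)}
    med = sorted_median(list(finite.values()))
    mad = mad_oracle(list(finite.values()), constant)
    if mad == 0:
        return None
    low = {g for g, v in finite.items() if med - v > k * mad}
    high = {g for g, v in finite.items() if v - med > k * mad}
    return low, high


def quantile_oracle(values, q):
    """Linear-interpolation empirical quantile from the sorted sample."""
    xs = sorted(values)
    if len(xs) == 1:
        return xs[0]
    pos = q * (len(xs) - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, len(xs) - 1)
    frac = pos - lo
    return xs[lo] * (1 - frac) + xs[hi] * frac


def hypergeom_tail_oracle(k, n, K, N) -> Fraction:
    """P(X >= k) by exact rational summation over the support."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for j in range(k, min(n, K) + 1):
        if n - j <= N - K:
            acc += Fraction(math.comb(K, j) * math.comb(N - K, n - j), total)
    return acc


def fisher_two_sided_oracle(a, b, c, d) -> Fraction:
    """Two-sided Fisher exact p for [[a, b], [c, d]] by enumeration.

    Sums the probabilities of all tables with the same margins whose
    probability does not exceed the observed table's (the standard
    definition for the conditional exact test).
    """
    row1, col1, N = a + b, a + c, a + b + c + d
    total = math.comb(N, col1)

    def table_count(x):  # tables with first cell x
        if not (max(0, col1 - (N - row1)) <= x <= min(row1, col1)):
            return 0
        return math.comb(row1, x) * math.comb(N - row1, col1 - x)

    obs = table_count(a)
    acc = 0
    for x in range(0, min(row1, col1) + 1):
        cnt = table_count(x)
        if cnt and cnt <= obs:
            acc += cnt
    return Fraction(acc, total)


def count_objects_oracle(mask, min_area=None, max_area=None):
    """Connected components (8-connectivity) of a boolean grid by flood fill."""
    h, w = len(mask), len(mask[0])
    seen = [[False] * w for _ in range(h)]
    areas = []
    for i in range(h):
        for j in range(w):
            if mask[i][j] and not seen[i][j]:
                stack = [(i, j)]
                seen[i][j] = True
                area = 0
                while stack:
                    r, c = stack.pop()
                    area += 1
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and mask[rr][cc] and not seen[rr][cc]:
                                seen[rr][cc] = True
                                stack.append((rr, cc))
                areas.append(area)
    kept = [
        a
        for a in areas
        if (min_area is None or a >= min_area) and (max_area is None or a <= max_area)
    ]
    return len(kept)
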