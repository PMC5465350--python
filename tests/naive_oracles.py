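"""Independent reference implementations used as test oracles.

Deliberately naive: pure-Python double loops and exact integer arithmetic,
sharing no code with the package's vectorized implementations.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations


def naive_best_shift(a_features, a_center, b_features, b_center,
                     max_shift: int, align_window: int, center_exclusion: int):
    """Exhaustive double-loop shift search maximizing cosine similarity.

    Pair comparisons retain the alignment-interval positions outside the
    union of both sites' centre-exclusion windows, z-score each feature and
    concatenate.  Scan order 0, -1, +1, -2, +2, ... with strict improvement,
    encoding the smallest-|shift|, negative-first tie-break.
    """
    half = align_window // 2
    e = center_exclusion // 2

    def vector(features, center, shift, keep):
        lo = center + shift - half
        out = []
        for row in features:
            vals = [row[lo + p] for p in keep]
            m = sum(vals) / len(vals)
            sd = math.sqrt(sum((v - m) ** 2 for v in vals) / len(vals))
            out.extend([0.0] * len(vals) if sd == 0 else [(v - m) / sd for v in vals])
        return out

    order = [0]
    for k in range(1, max_shift + 1):
        order.extend([-k, k])
    best_s, best_sim = 0, -math.inf
    for s in order:
        ref_excl = set(range(half - e, half + e + 1))
        own_excl = set(range(half - s - e, half - s + e + 1))
        keep = [p for p in range(align_window) if p not in ref_excl and p not in own_excl]
        u = vector(a_features, a_center, 0, keep)
        v = vector(b_features, b_center, s, keep)
        nu = math.sqrt(sum(x * x for x in u))
        nv = math.sqrt(sum(x * x for x in v))
        sim = 0.0 if nu == 0 or nv == 0 else \
            sum(x * y for x, y in zip(u, v)) / (nu * nv)
        if sim > best_sim:
            best_s, best_sim = s, sim
    return best_s, best_sim


def exact_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact rational hypergeometric enumeration.

    Sums the probability of every table with the same margins whose
    probability does not exceed the observed table's.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    p_obs = Fraction(math.comb(r1, a) * math.comb(r2, c1 - a), denom)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_k = Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)
        if p_k <= p_obs:
            total += p_k
    return float(min(total, Fraction(1)))


def exact_mannwhitney_two_sided(xs, ys) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by full enumeration of group labellings.

    Returns (U of the first sample, p).  U counts pairs where x > y plus
    half the ties; the two-sided p is the permutation probability of a U at
    least as far from the null mean as observed.
    """
    xs, ys = list(xs), list(ys)
    pooled = xs + ys
    n_a, n_b = len(xs), len(ys)

    def u_stat(group_a_idx):
        group_a = [pooled[i] for i in group_a_idx]
        group_b = [pooled[i] for i in range(len(pooled)) if i not in group_a_idx]
        u = 0.0
        for x in group_a:
            for y in group_b:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u

    u_obs = 0.0
    for x in xs:
        for y in ys:
            u_obs += 1.0 if x > y else (0.5 if x == y else 0.0)
    mu = n_a * n_b / 2.0
    dev = abs(u_obs - mu) - 1e-12
    count = total = 0
    for idx in combinations(range(n_a + n_b), n_a):
        total += 1
        if abs(u_stat(set(idx)) - mu) >= dev:
            count += 1
    return u_obs, count / total
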