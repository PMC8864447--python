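"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive the procedures from their definitions with
different code paths (all-pairs scans, exhaustive path enumeration,
textbook formulas) so agreement is meaningful.
"""

from __future__ import annotations

import math


def merge_oracle(bins, merge_gap=5):
    """Exhaustive simulation of the iterative nearest-pair combination.

    Considers every pair (not just sorted-adjacent ones), picks the pair
    minimising (separation, left time, right time), combines it into the
    lower-median bin, and repeats until every separation exceeds the gap.
    """
    values = sorted(int(b) for b in bins)
    while len(values) > 1:
        best = None
        for i in range(len(values)):
            for j in range(i + 1, len(values)):
                d = abs(values[j] - values[i])
                key = (d, min(values[i], values[j]), max(values[i], values[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (d, _, _), i, j = best
        if d > merge_gap:
            break
        merged = (values[i] + values[j]) // 2
        values = [v for k, v in enumerate(values) if k not in (i, j)]
        values.append(merged)
        values.sort()
    return values


def enumerate_min_path_cost(weights):
    """Minimum total vertex weight over all simple top-to-bottom grid paths.

    ``weights[z][t]`` is the cost of entering vertex (z, t); moves go to
    any of the 8 grid neighbours without revisiting a vertex.  The cost
    of a path is the sum of the weights of every vertex on it, including
    the entry vertex in the first row (the start edge carries it) and
    excluding nothing (the goal edge is free).  Branch-and-bound depth
    first search; exact because all weights are positive.
    """
    z_n = len(weights)
    b_n = len(weights[0])
    best = [math.inf]
    visited = [[False] * b_n for _ in range(z_n)]

    def dfs(z, t, cost):
        if cost >= best[0]:
            return
        if z == z_n - 1:
            best[0] = cost
            return
        for dz in (-1, 0, 1):
            for dt in (-1, 0, 1):
                if dz == 0 and dt == 0:
                    continue
                nz, nt = z + dz, t + dt
                if 0 <= nz < z_n and 0 <= nt < b_n and not visited[nz][nt]:
                    visited[nz][nt] = True
                    dfs(nz, nt, cost + weights[nz][nt])
                    visited[nz][nt] = False

    for t0 in range(b_n):
        visited[0][t0] = True
        dfs(0, t0, weights[0][t0])
        visited[0][t0] = False
    return best[0]


def pooled_ttest_oracle(a, b):
    """One-tailed (greater) pooled-variance two-sample t from the textbook
    formula plus the t survival function."""
    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = tdist.sf(t, na + nb - 2)
    return t, p


def ks_statistic_oracle(a, b):
    """Two-sample KS D as the max absolute ECDF difference over the pooled
    sample points."""
    a = sorted(a)
    b = sorted(b)
    points = sorted(set(a) | set(b))
    d = 0.0
    for x in points:
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        d = max(d, abs(fa - fb))
    return d
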