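"""Independent brute-force oracles used to check the implementation.

These deliberately avoid every code path of the package: the root finder
here is a hand-written bisection on the conservation law, and the
hypergeometric tail is computed by exhaustive enumeration of draws.
"""

from itertools import combinations

import numpy as np


def conservation_excess(a, totals, ks, ab_total):
    y = a * np.asarray(ks, dtype=float)
    return a + float(np.sum(np.asarray(totals, dtype=float) * y / (1 + y))) - ab_total


def bisect_free_antibody(totals, ks, ab_total, iterations=200):
    """Plain bisection for the free-antibody root on [0, AB_t]."""
    lo, hi = 0.0, float(ab_total)
    if ab_total == 0 or all(t * k == 0 for t, k in zip(totals, ks)):
        return float(ab_total)
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        if conservation_excess(mid, totals, ks, ab_total) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def grid_bracket(totals, ks, ab_total, n=1_000_000):
    """Locate the sign change of the conservation law on a dense grid."""
    grid = np.linspace(0.0, ab_total, n)
    y = grid[:, None] * np.asarray(ks, dtype=float)[None, :]
    g = grid + (np.asarray(totals, dtype=float)[None, :] * y / (1 + y)).sum(
        axis=1) - ab_total
    idx = int(np.searchsorted(g > 0, True))
    return grid[max(idx - 1, 0)], grid[min(idx, n - 1)]


def hypergeom_upper_tail_enumerated(universe, n_a, n_b, observed):
    """P(X >= observed) by enumerating every size-n_b draw from the universe.

    Feasible only for small universes (C(universe, n_b) draws).
    """
    marked = set(range(n_a))
    hits = total = 0
    for draw in combinations(range(universe), n_b):
        total += 1
        if len(marked.intersection(draw)) >= observed:
            hits += 1
    return hits / total
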