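"""Independent oracles used by the unit and acceptance tests.

These are deliberately written with different machinery from the package:
exact big-integer hypergeometric enumeration (math.comb + Fraction) for the
Fisher test, and a literal double-argmin scan for mutual best hits.
"""

import math
from fractions import Fraction

#: Same "as extreme as observed" relative gate as the implementation, so
#: both sides classify exact pmf ties identically.
GATE = math.log1p(1e-7)


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration in exact arithmetic."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n or n == 0:
        return 1.0
    kmin, kmax = max(0, c1 - (n - r1)), min(r1, c1)
    numerators = {
        k: math.comb(r1, k) * math.comb(n - r1, c1 - k)
        for k in range(kmin, kmax + 1)
    }
    log_obs = math.log(numerators[a])
    total = sum(v for v in numerators.values() if math.log(v) <= log_obs + GATE)
    return float(Fraction(total, math.comb(n, c1)))


def brute_force_mutual_best(p_grid, both_grid=None):
    """Mutual-argmin pairs of a p-value grid, ties by larger both/low index.

    ``p_grid[i][j]`` is the p-value of medication i x metabolite j; returns
    the set of (i, j) pairs that are the best partner of both their row and
    their column under the (p, -both, column index / row index) order.
    """
    n_rows = len(p_grid)
    n_cols = len(p_grid[0])
    if both_grid is None:
        both_grid = [[0] * n_cols for _ in range(n_rows)]

    def row_key(i, j):
        return (p_grid[i][j], -both_grid[i][j], j)

    def col_key(i, j):
        return (p_grid[i][j], -both_grid[i][j], i)

    best_in_row = {
        i: min(range(n_cols), key=lambda j: row_key(i, j)) for i in range(n_rows)
    }
    best_in_col = {
        j: min(range(n_rows), key=lambda i: col_key(i, j)) for j in range(n_cols)
    }
    return {
        (i, j)
        for i, j in best_in_row.items()
        if best_in_col[j] == i
    }
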