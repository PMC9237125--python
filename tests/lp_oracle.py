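"""Brute-force LP oracle: exhaustive vertex enumeration.

Maximizes c.v subject to S v = 0 and l <= v <= u by enumerating every basic
feasible solution (n - rank(S) variables pinned at a bound, the rest solved
from the equality system).  Exponential, for toy networks only; written
without any LP machinery so it can serve as an independent check of the
solver path.
"""

from itertools import combinations, product

import numpy as np


def enumerate_lp_max(c, S, lower, upper, tol=1e-9):
    """Return (best objective, best vertex) or (None, None) if infeasible."""
    c = np.asarray(c, dtype=float)
    S = np.asarray(S, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    n = S.shape[1]
    r = np.linalg.matrix_rank(S) if S.size else 0
    n_fixed = n - r

    best_obj, best_v = None, None

    def consider(v):
        nonlocal best_obj, best_v
        if np.any(v < lower - 1e-7) or np.any(v > upper + 1e-7):
            return
        if S.size and np.max(np.abs(S @ v)) > 1e-6:
            return
        obj = float(c @ v)
        if best_obj is None or obj > best_obj:
            best_obj, best_v = obj, v.copy()

    if n_fixed == 0:
        sol, *_ = np.linalg.lstsq(S, np.zeros(S.shape[0]), rcond=None)
        consider(sol)
        return best_obj, best_v

    for fixed_idx in combinations(range(n), n_fixed):
        free_idx = [j for j in range(n) if j not in fixed_idx]
        S_free = S[:, free_idx] if S.size else np.zeros((0, len(free_idx)))
        for choice in product(*[(lower[j], upper[j]) for j in fixed_idx]):
            v = np.zeros(n)
            for j, val in zip(fixed_idx, choice):
                v[j] = val
            if free_idx:
                rhs = -S[:, list(fixed_idx)] @ np.array(choice) if S.size else None
                sol, residual, rank, _ = np.linalg.lstsq(S_free, rhs, rcond=None)
                v[free_idx] = sol
            consider(v)
    return best_obj, best_v
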