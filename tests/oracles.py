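"""Independent brute-force references used to validate the implementation.

These deliberately avoid the library code paths they check: posterior
marginals are computed by exhaustive enumeration over all slot paths, and
assignments by enumeration over all permutations.
"""

from itertools import permutations, product

import numpy as np


def enumerate_posterior(log_e: np.ndarray, log_trans: np.ndarray) -> np.ndarray:
    """Per-frame posterior marginals over slots for one identity by summing
    over every possible slot path (extended precision).

    ``log_e``: (T, N) log emissions; ``log_trans``: (T-1, N, N) with
    [t, i, j] = log p(slot i at t+1 | slot j at t).  Returns (T, N) log
    marginals normalized per frame.
    """
    n_frames, n_slots = log_e.shape
    probs = np.zeros((n_frames, n_slots), dtype=np.longdouble)
    for path in product(range(n_slots), repeat=n_frames):
        lp = np.longdouble(log_e[0, path[0]])
        for t in range(1, n_frames):
            lp += log_trans[t - 1, path[t], path[t - 1]] + log_e[t, path[t]]
        p = np.exp(lp)
        for t, i in enumerate(path):
            probs[t, i] += p
    probs /= probs.sum(axis=1, keepdims=True)
    return np.log(probs).astype(float)


def brute_force_assignment(cost: np.ndarray):
    """Minimum-total-cost bijection by enumeration over all permutations."""
    n = cost.shape[0]
    best_perm, best_total = None, np.inf
    for perm in permutations(range(n)):
        total = sum(cost[i, perm[i]] for i in range(n))
        if total < best_total:
            best_total, best_perm = total, perm
    return np.array(best_perm), float(best_total)


def brute_force_matching(cost: np.ndarray) -> float:
    """Minimum total cost of a maximum bipartite matching (rectangular),
    by enumeration."""
    n_rows, n_cols = cost.shape
    if n_rows <= n_cols:
        return min(
            sum(cost[i, c[i]] for i in range(n_rows))
            for c in permutations(range(n_cols), n_rows))
    return min(
        sum(cost[r[j], j] for j in range(n_cols))
        for r in permutations(range(n_rows), n_cols))
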