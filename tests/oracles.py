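"""Independent oracles shared across test modules."""

from itertools import combinations

import numpy as np


def brute_force_qp(y, D, T, max_support):
    """Global optimum of the nonnegative-rate QP by support enumeration.

    For every candidate support the equality-constrained stationary point is
    computed; supports whose stationary point leaves the nonnegative orthant
    are discarded.  The optimal support is among the enumerated ones whenever
    ``max_support`` is at least the solution's support size.
    """
    N = D.shape[1]
    best_obj, best_r = np.inf, np.zeros(N)
    for k in range(max_support + 1):
        for S in combinations(range(N), k):
            S = list(S)
            Dp = D[:, S]
            s, *_ = np.linalg.lstsq(Dp.T @ Dp, Dp.T @ y - T[S], rcond=None)
            if np.any(s < -1e-12):
                continue
            r = np.zeros(N)
            r[S] = np.maximum(s, 0.0)
            obj = np.sum((y - D @ r) ** 2) + 2.0 * T @ r
            if obj < best_obj:
                best_obj, best_r = obj, r
    return best_obj, best_r


def objective(r, y, D, T):
    return float(np.sum((y - D @ r) ** 2) + 2.0 * T @ r)
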