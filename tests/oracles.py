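"""Independent reference implementations for the path-extraction tests.

These deliberately use the most transparent formulations available — explicit
transition enumeration and exhaustive recursion — rather than the incremental
scan of the package kernel, so that agreement is a meaningful check.
"""

import numpy as np

NEG = -1.0e18


def bellman_best_score(con_same, con_change, allowed=None):
    """O(T*J^2) value recursion over all time-ordered paths; returns max score.

    A path visits one column per row; the column may decrease by at most one
    between consecutive rows.  Cell contributions are con_same when the column
    is unchanged and con_change otherwise.
    """
    T, J = con_same.shape
    if allowed is None:
        allowed = np.ones((T, J), dtype=bool)
    S = [con_same[0, j] if allowed[0, j] else NEG for j in range(J)]
    for n in range(1, T):
        S2 = [NEG] * J
        for j in range(J):
            if not allowed[n, j]:
                continue
            best = NEG
            for jp in range(0, min(j + 1, J - 1) + 1):
                if S[jp] <= NEG / 2:
                    continue
                c = con_same[n, j] if jp == j else con_change[n, j]
                if S[jp] + c > best:
                    best = S[jp] + c
            S2[j] = best
        S = S2
    return max(S)


def enumerate_best_path(con_same, con_change, tau_abs):
    """Exhaustive enumeration with the lexicographic tie-break.

    Maximises (score, -n_changes, -sum|tau|); feasible only on tiny lattices.
    Returns (path tuple, key triple).
    """
    T, J = con_same.shape
    best_key = None
    best_path = None
    stack = [((j,), con_same[0, j], 0, tau_abs[j]) for j in range(J)]
    while stack:
        path, score, changes, sabs = stack.pop()
        n = len(path)
        if n == T:
            key = (score, -changes, -sabs)
            if best_key is None or key > best_key:
                best_key = key
                best_path = path
            continue
        jp = path[-1]
        for j in range(max(jp - 1, 0), J):
            c = con_same[n, j] if j == jp else con_change[n, j]
            stack.append(
                (path + (j,), score + c, changes + (j != jp), sabs + tau_abs[j])
            )
    return best_path, best_key


def propagate_bounds(lo, hi, defined):
    """Quadratic-time slope −1 bound propagation (forward minima, backward maxima)."""
    T = len(lo)
    lo_out = np.array(lo, dtype=float)
    hi_out = np.array(hi, dtype=float)
    for n in range(T):
        if not defined[n]:
            continue
        for m in range(n):
            if defined[m]:
                lo_out[n] = max(lo_out[n], lo[m] - (n - m))
        for m in range(n + 1, T):
            if defined[m]:
                hi_out[n] = min(hi_out[n], hi[m] + (m - n))
    return lo_out, hi_out
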