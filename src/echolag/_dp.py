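"""Numba kernel for time-ordered optimal-path extraction on the (t, tau) lattice.

The path visits one delay cell per time step under the time-ordering
constraint that the delay may decrease by at most one lattice step per time
step (any upward jump is allowed).  The objective is lexicographic: maximise
the cumulative cell contribution, then prefer fewer delay changes, then the
smallest cumulative |tau|.  Contributions are supplied per cell twice — once
for arriving with unchanged delay and once for arriving after a delay change
(the latter already carrying any change penalty).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e18


@njit(cache=True, inline="always")
def _lex_gt(s1, c1, a1, s2, c2, a2):
    if s1 > s2:
        return True
    if s1 < s2:
        return False
    if c1 > c2:
        return True
    if c1 < c2:
        return False
    return a1 > a2


@njit(cache=True)
def best_path(con_same, con_change, allowed, tau_abs):
    """Return (path column indices, score, n_changes) of the lexicographic optimum.

    con_same, con_change : (T, J) float64 cell contributions
    allowed : (T, J) boolean mask (e.g. anchor constraints)
    tau_abs : (J,) |tau| per column, used as the final tie-break
    """
    T, J = con_same.shape
    S = np.empty(J)
    NC = np.empty(J)
    NA = np.empty(J)
    S2 = np.empty(J)
    NC2 = np.empty(J)
    NA2 = np.empty(J)
    bp = np.empty((T, J), np.int32)
    for j in range(J):
        if allowed[0, j]:
            S[j] = con_same[0, j]
            NC[j] = 0.0
            NA[j] = -tau_abs[j]
        else:
            S[j] = NEG
            NC[j] = 0.0
            NA[j] = 0.0
        bp[0, j] = -1

    for n in range(1, T):
        b1 = -1
        b2 = -1
        i_inc = 0
        for j in range(J):
            lim = j + 1
            if lim > J - 1:
                lim = J - 1
            while i_inc <= lim:
                if S[i_inc] > NEG * 0.5:
                    if b1 == -1 or _lex_gt(
                        S[i_inc], NC[i_inc], NA[i_inc], S[b1], NC[b1], NA[b1]
                    ):
                        b2 = b1
                        b1 = i_inc
                    elif b2 == -1 or _lex_gt(
                        S[i_inc], NC[i_inc], NA[i_inc], S[b2], NC[b2], NA[b2]
                    ):
                        b2 = i_inc
                i_inc += 1
            if not allowed[n, j]:
                S2[j] = NEG
                NC2[j] = 0.0
                NA2[j] = 0.0
                bp[n, j] = -1
                continue
            have = False
            bs = NEG
            bc = 0.0
            ba = 0.0
            bj = -1
            if S[j] > NEG * 0.5:  # stay at the same delay
                bs = S[j] + con_same[n, j]
                bc = NC[j]
                ba = NA[j] - tau_abs[j]
                bj = j
                have = True
            pred = b1
            if pred == j:
                pred = b2
            if pred != -1:  # arrive after a delay change
                cs = S[pred] + con_change[n, j]
                cc = NC[pred] - 1.0
                ca = NA[pred] - tau_abs[j]
                if (not have) or _lex_gt(cs, cc, ca, bs, bc, ba):
                    bs = cs
                    bc = cc
                    ba = ca
                    bj = pred
                    have = True
            if have:
                S2[j] = bs
                NC2[j] = bc
                NA2[j] = ba
                bp[n, j] = bj
            else:
                S2[j] = NEG
                NC2[j] = 0.0
                NA2[j] = 0.0
                bp[n, j] = -1
        S, S2 = S2, S
        NC, NC2 = NC2, NC
        NA, NA2 = NA2, NA

    best = 0
    for j in range(1, J):
        if _lex_gt(S[j], NC[j], NA[j], S[best], NC[best], NA[best]):
            best = j
    path = np.empty(T, np.int64)
    path[T - 1] = best
    for n in range(T - 1, 0, -1):
        path[n - 1] = bp[n, path[n]]
    return path, S[best], -NC[best]
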