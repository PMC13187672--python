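"""Exact LP oracle for the dip statistic at tiny n.

Minimizes sup|F_n - U| over unimodal CDFs U: convex increasing left of the
mode, concave increasing right, with at most one atom located at the mode.
Ties are collapsed to single knots so the convex/concave parts cannot fake
jumps through zero-width segments.
"""
import numpy as np
from scipy.optimize import linprog


def dip_lp(x):
    xs = np.sort(np.asarray(x, float))
    n = len(xs)
    if xs[0] == xs[-1]:
        return 0.0
    w, counts = np.unique(xs, return_counts=True)
    K = len(w)
    below = np.concatenate([[0], np.cumsum(counts)[:-1]]) / n  # F just left of knot
    at = np.cumsum(counts) / n  # F at knot

    def solve(mode_kind, m):
        split = mode_kind == "point"
        nv = K + (1 if split else 0) + 1
        d_idx = nv - 1

        def uvar(j, side):
            if not split:
                return j
            if j < m:
                return j
            if j == m:
                return m if side == "-" else m + 1
            return j + 1

        A_ub, b_ub = [], []

        def add(coef, rhs):
            row = [0.0] * nv
            for kk, v in coef.items():
                row[kk] += v
            A_ub.append(row)
            b_ub.append(rhs)

        for j in range(K):
            add({uvar(j, "+"): -1.0, d_idx: -1.0}, -at[j])  # u+ >= at - d
            add({uvar(j, "-"): 1.0, d_idx: -1.0}, below[j])  # u- <= below + d
        seq = []
        for j in range(K):
            seq.append(uvar(j, "-"))
            if split and j == m:
                seq.append(uvar(j, "+"))
        for a, b in zip(seq[:-1], seq[1:]):
            if a != b:
                add({a: 1.0, b: -1.0}, 0.0)
        for j in range(K - 2):
            dx1 = w[j + 1] - w[j]
            dx2 = w[j + 2] - w[j + 1]
            if (mode_kind == "segment" and j + 1 <= m) or (
                mode_kind == "point" and j + 2 <= m
            ):
                a0, a1, a2 = uvar(j, "-"), uvar(j + 1, "-"), uvar(j + 2, "-")
                add({a0: -1.0 / dx1, a1: 1.0 / dx1 + 1.0 / dx2, a2: -1.0 / dx2}, 0.0)
            if j >= m:
                a0, a1, a2 = uvar(j, "+"), uvar(j + 1, "+"), uvar(j + 2, "+")
                add({a0: 1.0 / dx1, a1: -1.0 / dx1 - 1.0 / dx2, a2: 1.0 / dx2}, 0.0)
        c = [0.0] * nv
        c[d_idx] = 1.0
        res = linprog(
            c, A_ub=A_ub, b_ub=b_ub, bounds=[(0.0, 1.0)] * nv, method="highs"
        )
        return res.fun if res.success else np.inf

    best = np.inf
    for m in range(K - 1):
        best = min(best, solve("segment", m))
    for m in range(K):
        best = min(best, solve("point", m))
    return best
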