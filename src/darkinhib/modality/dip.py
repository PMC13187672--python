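"""Hartigan & Hartigan dip statistic and a Monte-Carlo dip test.

The dip is the smallest sup-norm distance between the empirical CDF and the
class of unimodal CDFs. It is computed exactly with the classical
greatest-convex-minorant / least-concave-majorant cycling algorithm; the
Monte-Carlo p-value uses the uniform(0,1) null with an add-one correction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def dip_statistic(x) -> float:
    """Exact dip statistic of a one-dimensional sample.

    Invariant under strictly increasing affine transforms; bounded below by
    ``1/(2n)`` with equality at ``n = 2``. Raises for ``n < 2``; a sample of
    identical values has dip 0 by convention.
    """
    xs = np.sort(np.asarray(x, dtype=float))
    n = xs.size
    if n < 2:
        raise ValueError("dip statistic needs at least 2 values")
    if not np.all(np.isfinite(xs)):
        raise ValueError("dip statistic requires finite values")
    if xs[0] == xs[-1]:
        return 0.0

    # Predecessor pointers for the greatest convex minorant (GCM) of the
    # empirical CDF and successor pointers for the least concave majorant
    # (LCM), built once over the full range.
    mn = np.zeros(n, dtype=int)
    for j in range(1, n):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 0 or (xs[j] - xs[mnj]) * (mnj - mnmnj) < (
                xs[mnj] - xs[mnmnj]
            ) * (j - mnj):
                break
            mn[j] = mnmnj

    mj = np.zeros(n, dtype=int)
    mj[n - 1] = n - 1
    for k in range(n - 2, -1, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n - 1 or (xs[k] - xs[mjk]) * (mjk - mjmjk) < (
                xs[mjk] - xs[mjmjk]
            ) * (k - mjk):
                break
            mj[k] = mjmjk

    low, high = 0, n - 1
    dip = 0.0
    while True:
        # GCM change points from high down to low; LCM from low up to high.
        gcm = [high]
        while gcm[-1] > low:
            gcm.append(int(mn[gcm[-1]]))
        l_gcm = len(gcm)
        ig = l_gcm - 1
        lcm = [low]
        while lcm[-1] < high:
            lcm.append(int(mj[lcm[-1]]))
        l_lcm = len(lcm)
        ih = l_lcm - 1

        # Largest vertical separation between the two fitted curves
        # (measured in units of 1/n; halved at the very end).
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            ix = l_gcm - 2  # 0-based second element from the low end of gcm
            iv = 1  # 0-based second element of lcm
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (xs[lcmiv] - xs[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (xs[gcmix] - xs[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    lcmiv1 = lcm[iv - 1]
                    dx = (xs[gcmix] - xs[lcmiv1]) * (lcmiv - lcmiv1) / (
                        xs[lcmiv] - xs[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx > d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 0:
                    ix = 0
                if iv > l_lcm - 1:
                    iv = l_lcm - 1
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < dip:
            break

        # Maximal deviation of the empirical CDF below the GCM ...
        dl = 0.0
        if gcm[ig] != gcm[l_gcm - 1]:
            for j in range(ig, l_gcm - 1):
                temp = 1.0
                jb = gcm[j + 1]
                je = gcm[j]
                if je - jb > 1 and xs[je] != xs[jb]:
                    c = (je - jb) / (xs[je] - xs[jb])
                    for jr in range(jb, je + 1):
                        t = (jr - jb + 1) - (xs[jr] - xs[jb]) * c
                        if temp < t:
                            temp = t
                if dl < temp:
                    dl = temp
        # ... and above the LCM.
        du = 0.0
        if lcm[ih] != lcm[l_lcm - 1]:
            for j in range(ih, l_lcm - 1):
                temp = 1.0
                jb = lcm[j]
                je = lcm[j + 1]
                if je - jb > 1 and xs[je] != xs[jb]:
                    c = (je - jb) / (xs[je] - xs[jb])
                    for jr in range(jb + 1, je + 1):
                        t = (xs[jr] - xs[jb]) * c - (jr - jb - 1)
                        if temp < t:
                            temp = t
                if du < temp:
                    du = temp

        dipnew = max(dl, du)
        if dip < dipnew:
            dip = dipnew
        new_low, new_high = gcm[ig], lcm[ih]
        if new_low == low and new_high == high:
            break  # interval cannot shrink further; converged
        low, high = new_low, new_high

    # any sample with >= 2 distinct values has dip >= 1/(2n)
    return max(dip, 1.0) / (2.0 * n)


@dataclass(frozen=True)
class DipResult:
    dip: float
    p_value: float
    n: int
    n_null_draws: int
    seed: int

    @property
    def p_standard_error(self) -> float:
        """Binomial standard error of the Monte-Carlo p-value estimate."""
        p = self.p_value
        return float(np.sqrt(p * (1.0 - p) / self.n_null_draws))


def dip_test(x, n_null_draws: int = 999, seed: int = 0) -> DipResult:
    """Monte-Carlo dip test against the uniform(0,1) null.

    ``p = (b + 1)/(m + 1)`` where ``b`` counts null samples of the same size
    whose dip is at least the observed dip.
    """
    xs = np.asarray(x, dtype=float)
    n = xs.size
    if n < 4:
        raise ValueError("dip test needs at least 4 values")
    observed = dip_statistic(xs)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_null_draws):
        if dip_statistic(rng.random(n)) >= observed:
            exceed += 1
    p = (exceed + 1) / (n_null_draws + 1)
    return DipResult(dip=observed, p_value=p, n=n, n_null_draws=n_null_draws, seed=seed)
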