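"""Rank-based k-sample machinery: Kruskal-Wallis, Dunn post hoc with Holm
step-down adjustment, and compact letter displays.

All formulas use mid-ranks for ties and the classical tie corrections:

* Kruskal-Wallis: ``H = [12/(N(N+1))] * sum R_j^2/n_j - 3(N+1)``, divided by
  ``1 - sum(t^3 - t)/(N^3 - N)``; p from chi-square with k-1 df.
* Dunn: ``z_ij = (Rbar_i - Rbar_j) / sqrt([N(N+1)/12 - T/(12(N-1))] *
  (1/n_i + 1/n_j))`` with ``T = sum(t^3 - t)`` over tie groups; two-sided
  normal p-values.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps


class DegenerateDataError(ValueError):
    """All values identical (ranks carry no information)."""


def _midranks(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mid-ranks of ``values`` and the tie-group sizes."""
    ranks = sps.rankdata(values, method="average")
    _, counts = np.unique(values, return_counts=True)
    return ranks, counts


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Kruskal-Wallis H with tie correction; returns ``(H, df, p)``."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    if n_total < 3:
        raise ValueError("need at least 3 values in total")
    if np.ptp(pooled) == 0:
        raise DegenerateDataError("all values identical")
    ranks, tie_counts = _midranks(pooled)
    h = 0.0
    start = 0
    for a in arrays:
        r = ranks[start : start + a.size]
        h += r.sum() ** 2 / a.size
        start += a.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    correction = 1.0 - ((tie_counts**3 - tie_counts).sum()) / (n_total**3 - n_total)
    h /= correction
    df = len(arrays) - 1
    p = float(sps.chi2.sf(h, df))
    return float(h), df, p


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    z: float
    p_raw: float
    p_adjusted: float


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank_idx, idx in enumerate(order):
        running = max(running, (m - rank_idx) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]], adjust: str = "holm"
) -> list[PairwiseResult]:
    """Dunn's post-hoc z tests on joint mid-ranks for every pair of groups."""
    if adjust != "holm":
        raise ValueError("only Holm adjustment is supported")
    names = list(groups)
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    pooled = np.concatenate([arrays[k] for k in names])
    n_total = pooled.size
    if np.ptp(pooled) == 0:
        raise DegenerateDataError("all values identical")
    ranks, tie_counts = _midranks(pooled)
    mean_ranks: dict[str, float] = {}
    start = 0
    for k in names:
        size = arrays[k].size
        mean_ranks[k] = float(ranks[start : start + size].mean())
        start += size
    tie_sum = float((tie_counts**3 - tie_counts).sum())
    variance_core = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))

    pairs = list(combinations(names, 2))
    zs, ps = [], []
    for a, b in pairs:
        se = np.sqrt(variance_core * (1.0 / arrays[a].size + 1.0 / arrays[b].size))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        zs.append(float(z))
        ps.append(float(2.0 * sps.norm.sf(abs(z))))
    adjusted = holm_adjust(ps)
    return [
        PairwiseResult(pair=pair, z=z, p_raw=p, p_adjusted=pa)
        for pair, z, p, pa in zip(pairs, zs, ps, adjusted)
    ]


def compact_letter_display(
    group_names: Sequence[str],
    significant_pairs: set[tuple[str, str]],
) -> dict[str, str]:
    """Greedy insert-absorb letter codes.

    Two groups share at least one letter iff their pair is *not* in
    ``significant_pairs``. Letter count is not guaranteed minimal, but the
    encoding of the (non-)significance partition is exact and deterministic
    (groups processed in the given order, letters assigned alphabetically).
    """
    sig = {frozenset(p) for p in significant_pairs}

    def differs(a: str, b: str) -> bool:
        return frozenset((a, b)) in sig

    # letters as sets of mutually non-different groups
    letters: list[set[str]] = []
    for g in group_names:
        placed = False
        for members in letters:
            if all(not differs(g, m) for m in members):
                members.add(g)
                placed = True
        if not placed:
            letters.append({g})
    # absorb: drop letters fully contained in another
    keep: list[set[str]] = []
    for i, li in enumerate(letters):
        if any(li < lj or (li == lj and i > j) for j, lj in enumerate(letters) if i != j):
            continue
        keep.append(li)
    # verify every ns-pair shares a letter; add pair letters if greedy missed one
    for a, b in combinations(group_names, 2):
        if not differs(a, b) and not any(a in s and b in s for s in keep):
            keep.append({a, b})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, list[str]] = {g: [] for g in group_names}
    for idx, members in enumerate(keep):
        letter = alphabet[idx % len(alphabet)] * (idx // len(alphabet) + 1)
        for g in group_names:
            if g in members:
                out[g].append(letter)
    return {g: "".join(sorted(set(ls))) or "?" for g, ls in out.items()}
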