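"""Level classification, count tables and taxonomic group comparisons.

Levels use left-closed intervals on the upper category: with cutpoints
``(t1, t2, t3)``, low = (-inf, t1), moderate = [t1, t2), high = [t2, t3),
very_high = [t3, inf). A value exactly at a boundary therefore falls in the
higher category (44 -> high, 18 -> moderate with the published cutpoints).
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .stats import (
    PairwiseResult,
    compact_letter_display,
    dunn_posthoc,
    kruskal_wallis,
)
from .types import KNOWN_ORDER_CODES, Level, SpeciesSummary
from .modality.thresholds import ThresholdSet

_LEVEL_ORDER = [Level.LOW, Level.MODERATE, Level.HIGH, Level.VERY_HIGH]


def assign_level(percent: float, thresholds: ThresholdSet) -> Level:
    """Map a percent value to its categorical level (left-closed intervals)."""
    t1, t2, t3 = thresholds.cutpoints
    if percent < t1:
        return Level.LOW
    if percent < t2:
        return Level.MODERATE
    if percent < t3:
        return Level.HIGH
    return Level.VERY_HIGH


@dataclass(frozen=True)
class LevelAssignment:
    species: str
    percent: float
    level: Level
    thresholds_used: ThresholdSet


def assign_levels(
    summaries: Sequence[SpeciesSummary], thresholds: ThresholdSet
) -> list[LevelAssignment]:
    return [
        LevelAssignment(
            species=s.taxonomy.species,
            percent=s.mean_di_percent,
            level=assign_level(s.mean_di_percent, thresholds),
            thresholds_used=thresholds,
        )
        for s in summaries
    ]


def level_counts(
    summaries: Sequence[SpeciesSummary],
    by: Optional[str] = None,
    use_printed_labels: bool = True,
    thresholds: Optional[ThresholdSet] = None,
) -> pd.DataFrame:
    """Counts and proportions of species per level, optionally per group.

    ``by`` may be ``"order"`` or ``"tribe"``. With ``use_printed_labels`` the
    label printed in the source table is used; otherwise levels are assigned
    from ``thresholds``.
    """
    if not use_printed_labels and thresholds is None:
        raise ValueError("thresholds required when not using printed labels")
    rows = []
    for s in summaries:
        if use_printed_labels:
            if s.level_label is None:
                raise ValueError(f"no printed label for {s.taxonomy.species}")
            level = s.level_label
        else:
            level = assign_level(s.mean_di_percent, thresholds)
        rows.append(
            {
                "species": s.taxonomy.species,
                "order": s.taxonomy.order_code,
                "tribe": s.taxonomy.tribe,
                "level": level.value,
            }
        )
    df = pd.DataFrame(rows, columns=["species", "order", "tribe", "level"])
    level_values = [lv.value for lv in _LEVEL_ORDER]
    if df.empty:
        return pd.DataFrame(columns=["count", "proportion"], index=pd.Index(level_values, name="level")).iloc[0:0]
    if by is None:
        counts = df["level"].value_counts().reindex(level_values, fill_value=0)
        out = counts.to_frame("count")
        out.index.name = "level"
        out["proportion"] = out["count"] / out["count"].sum()
        return out
    if by not in ("order", "tribe"):
        raise ValueError("grouping must be 'order' or 'tribe'")
    table = (
        df.groupby([by, "level"]).size().unstack(fill_value=0).reindex(columns=level_values, fill_value=0)
    )
    table["total"] = table.sum(axis=1)
    return table


@dataclass(frozen=True)
class ConcordanceReport:
    n_total: int
    n_agree: int
    disagreements: tuple[tuple[str, float, str, str], ...]  # species, mean, printed, assigned

    @property
    def agreement_rate(self) -> float:
        return self.n_agree / self.n_total if self.n_total else float("nan")


def classification_concordance(
    summaries: Sequence[SpeciesSummary], thresholds: ThresholdSet
) -> ConcordanceReport:
    """Check printed level labels against re-assignment from printed means."""
    disagreements = []
    n = 0
    for s in summaries:
        if s.level_label is None:
            continue
        n += 1
        assigned = assign_level(s.mean_di_percent, thresholds)
        if assigned is not s.level_label:
            disagreements.append(
                (s.taxonomy.species, s.mean_di_percent, s.level_label.value, assigned.value)
            )
    return ConcordanceReport(
        n_total=n, n_agree=n - len(disagreements), disagreements=tuple(disagreements)
    )


@dataclass(frozen=True)
class GroupComparison:
    grouping: str
    group_sizes: dict[str, int]
    H: Optional[float]
    df: Optional[int]
    p_value: Optional[float]
    pairwise: tuple[PairwiseResult, ...]
    letters: dict[str, str]
    alpha: float
    min_group_n: int
    dropped_groups: tuple[str, ...] = ()
    note: str = ""

    @property
    def insufficient(self) -> bool:
        return self.H is None


def _order_rank(order_code: str) -> int:
    codes = list(KNOWN_ORDER_CODES)
    return codes.index(order_code) if order_code in codes else len(codes)


def compare_groups(
    values: Sequence[float],
    group_labels: Sequence[str],
    grouping: str = "tribe",
    min_group_n: int = 5,
    alpha: float = 0.05,
    order_codes: Optional[Sequence[str]] = None,
) -> GroupComparison:
    """Kruskal-Wallis + Dunn-Holm + compact letters for one taxonomic grouping.

    Groups with fewer than ``min_group_n`` data points are dropped before
    testing. Groups are ordered by phylogenetic order code (when supplied)
    then by name, so letter displays are deterministic.
    """
    vals = np.asarray(values, dtype=float)
    labels = list(group_labels)
    if len(labels) != vals.size:
        raise ValueError("values and group_labels must align")
    counts = Counter(labels)
    kept = {g for g, c in counts.items() if c >= min_group_n and g is not None}
    dropped = tuple(sorted(set(counts) - kept, key=str))

    if order_codes is not None:
        first_order = {}
        for lab, oc in zip(labels, order_codes):
            first_order.setdefault(lab, oc)
        kept_sorted = sorted(kept, key=lambda g: (_order_rank(first_order.get(g, "")), str(g)))
    else:
        kept_sorted = sorted(kept, key=str)

    sizes = {g: counts[g] for g in kept_sorted}
    if len(kept_sorted) < 2:
        return GroupComparison(
            grouping=grouping, group_sizes=sizes, H=None, df=None, p_value=None,
            pairwise=(), letters={}, alpha=alpha, min_group_n=min_group_n,
            dropped_groups=dropped,
            note=f"fewer than 2 groups with >= {min_group_n} data points",
        )
    groups = {g: vals[[i for i, lab in enumerate(labels) if lab == g]] for g in kept_sorted}
    h, df, p = kruskal_wallis([groups[g] for g in kept_sorted])
    pairwise = tuple(dunn_posthoc(groups, adjust="holm"))
    significant = {pr.pair for pr in pairwise if pr.p_adjusted < alpha}
    letters = compact_letter_display(kept_sorted, significant)
    return GroupComparison(
        grouping=grouping, group_sizes=sizes, H=h, df=df, p_value=p,
        pairwise=pairwise, letters=letters, alpha=alpha, min_group_n=min_group_n,
        dropped_groups=dropped,
    )
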