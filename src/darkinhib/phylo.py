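"""Mapping species-level dark-inhibition results onto a phylogeny.

Genus-level annotations (unweighted mean of species means, classified with
the category thresholds), coverage statistics against the known number of
flowering-plant orders, and export of an iTOL-compatible colour dataset for
tree visualisation.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import dendropy

from .classify import assign_level
from .modality.thresholds import PAPER_DEFAULT, ThresholdSet
from .types import Level, SpeciesSummary, normalize_species_name

#: Fixed palette: one colour per level plus grey for "no data".
LEVEL_COLORS: dict[Level, str] = {
    Level.LOW: "#2c7bb6",
    Level.MODERATE: "#abd9e9",
    Level.HIGH: "#fdae61",
    Level.VERY_HIGH: "#d7191c",
}
NO_DATA_COLOR = "#bdbdbd"


class TreeError(ValueError):
    pass


def read_tree(path: Union[str, Path]) -> dendropy.Tree:
    """Parse a Newick tree and normalise tip labels (underscores to spaces).

    Raises :class:`TreeError` on malformed input or duplicate tip names.
    """
    path = Path(path)
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as e:  # dendropy raises several parse error types
        raise TreeError(f"malformed Newick in {path}: {e}") from e
    seen = set()
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None:
            continue
        name = normalize_species_name(leaf.taxon.label)
        leaf.taxon.label = name
        if name in seen:
            raise TreeError(f"duplicate tip name after normalization: {name!r}")
        seen.add(name)
    return tree


@dataclass(frozen=True)
class GenusAnnotation:
    genus: str
    mean_di_percent: float
    level: Level
    n_species_with_data: int

    @property
    def color(self) -> str:
        return LEVEL_COLORS[self.level]


def genus_annotations(
    summaries: Sequence[SpeciesSummary],
    thresholds: ThresholdSet = PAPER_DEFAULT,
) -> list[GenusAnnotation]:
    """Aggregate species means to genus level and classify the genus mean.

    The genus value is the unweighted mean of its species means (not pooled
    data points); genera with a single studied species are still annotated.
    """
    by_genus: dict[str, list[float]] = defaultdict(list)
    for s in summaries:
        by_genus[s.taxonomy.genus].append(s.mean_di_percent)
    out = []
    for genus in sorted(by_genus):
        vals = by_genus[genus]
        mean = sum(vals) / len(vals)
        out.append(
            GenusAnnotation(
                genus=genus,
                mean_di_percent=mean,
                level=assign_level(mean, thresholds),
                n_species_with_data=len(vals),
            )
        )
    return out


@dataclass(frozen=True)
class CoverageReport:
    n_species: int
    n_genera: int
    n_orders_covered: int
    reference_order_count: int

    @property
    def order_fraction(self) -> float:
        return self.n_orders_covered / self.reference_order_count


#: Number of flowering-plant orders in current classifications.
ANGIOSPERM_ORDER_COUNT = 64


def coverage_summary(
    summaries: Sequence[SpeciesSummary],
    reference_order_count: int = ANGIOSPERM_ORDER_COUNT,
) -> CoverageReport:
    """How much of the angiosperm phylogeny has dark-inhibition data."""
    orders = {s.taxonomy.order_code for s in summaries}
    genera = {s.taxonomy.genus for s in summaries}
    if reference_order_count < len(orders):
        raise ValueError("reference order count below covered count")
    return CoverageReport(
        n_species=len({s.taxonomy.species for s in summaries}),
        n_genera=len(genera),
        n_orders_covered=len(orders),
        reference_order_count=reference_order_count,
    )


ITOL_HEADER = """DATASET_COLORSTRIP
SEPARATOR TAB
DATASET_LABEL\tdark inhibition level
COLOR\t#d7191c
DATA
"""


@dataclass
class ItolExport:
    path: Path
    n_records: int
    unmatched: list[str]


def export_itol_annotation(
    tree: dendropy.Tree,
    annotations: Sequence[GenusAnnotation],
    path: Union[str, Path],
) -> ItolExport:
    """Write an iTOL colour-strip dataset file for genus-level annotations.

    A genus matches a tree tip whose label equals a species binomial of that
    genus (genus = first name token). Annotations without any matching tip
    are listed in the returned report (and in a sidecar ``.unmatched.txt``
    file); zero matches is an error suggesting a name-normalisation check.
    """
    path = Path(path)
    tips_by_genus: dict[str, list[str]] = defaultdict(list)
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None:
            continue
        label = leaf.taxon.label
        tips_by_genus[label.split()[0]].append(label)

    records = []
    unmatched = []
    for ann in annotations:
        tips = tips_by_genus.get(ann.genus)
        if not tips:
            unmatched.append(ann.genus)
            continue
        for tip in tips:
            records.append((tip, ann.color, ann.level.value))
    if not records:
        raise TreeError(
            "no annotation matched any tree tip; check name normalization "
            "(underscores vs spaces, genus capitalization)"
        )
    lines = [ITOL_HEADER]
    for tip, color, label in records:
        lines.append(f"{tip.replace(' ', '_')}\t{color}\t{label}\n")
    path.write_text("".join(lines), encoding="utf-8")
    sidecar = path.with_suffix(path.suffix + ".unmatched.txt")
    sidecar.write_text("\n".join(unmatched) + ("\n" if unmatched else ""), encoding="utf-8")
    return ItolExport(path=path, n_records=len(records), unmatched=unmatched)


def parse_itol_annotation(path: Union[str, Path]) -> list[tuple[str, str, str]]:
    """Read back (tip, color, label) records from an iTOL dataset file."""
    out = []
    in_data = False
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.strip() == "DATA":
            in_data = True
            continue
        if in_data and line.strip():
            tip, color, label = line.split("\t")
            out.append((normalize_species_name(tip), color, label))
    return out
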