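"""Reading, writing and validating observation- and summary-level tables.

The canonical on-disk format is tab-separated UTF-8 text with a documented
header; comma-separated input is accepted via ``dialect="csv"``. Rows that
violate type invariants are collected into a rejection report rather than
silently dropped, so ingestion is auditable.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .types import (
    KNOWN_ORDER_CODES,
    TRIBE_NA,
    ActivityObservation,
    AssayMethod,
    Dataset,
    Level,
    PathwayFlags,
    SpeciesSummary,
    Taxonomy,
    ValidationReport,
    dataset_to_dict,
    normalize_species_name,
)

#: Mandatory columns of an observation table.
OBS_REQUIRED_COLUMNS = (
    "source_id",
    "order_code",
    "species",
    "light_activity",
    "dark_activity",
    "method",
)

#: Optional observation columns and their parsers.
OBS_OPTIONAL_COLUMNS = (
    "tribe",
    "genotype",
    "growth_stage",
    "activity_unit",
    "dark_treatment_light_level",
    "assay_pH",
    "assay_temperature_C",
    "edta_mM",
    "mgcl2_in_extraction",
    "digitized",
)


class SchemaError(ValueError):
    """A required column is missing or the file is structurally unusable."""


@dataclass
class Rejection:
    row: int
    reason: str


@dataclass
class IngestResult:
    dataset: Dataset
    rejections: list[Rejection] = field(default_factory=list)


def _sep_for(dialect: str) -> str:
    if dialect in ("tsv", "tab", "\t"):
        return "\t"
    if dialect in ("csv", ","):
        return ","
    raise ValueError(f"unknown dialect {dialect!r}")


def _opt_float(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    return float(v)


def _opt_bool(v) -> Optional[bool]:
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    if isinstance(v, bool):
        return v
    return str(v).strip().lower() in ("1", "true", "yes")


def read_observations(path: Union[str, Path], dialect: str = "tsv") -> IngestResult:
    """Read an observation-level table into a :class:`Dataset`.

    Every well-formed row becomes an :class:`ActivityObservation`; rows that
    violate invariants (non-numeric or non-positive light activity, negative
    dark activity, unknown method code) are reported as rejections.

    Raises
    ------
    SchemaError
        If a mandatory column is missing (the error names the column).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(dialect), dtype=str, encoding="utf-8")
    for col in OBS_REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column: {col!r}")

    observations: list[ActivityObservation] = []
    rejections: list[Rejection] = []
    for i, row in df.iterrows():
        rownum = int(i) + 2  # 1-based, counting the header line
        try:
            light = float(row["light_activity"])
            dark = float(row["dark_activity"])
            if not (math.isfinite(light) and math.isfinite(dark)):
                raise ValueError
        except (TypeError, ValueError):
            rejections.append(Rejection(rownum, "non-numeric activity value"))
            continue
        try:
            method = AssayMethod(str(row["method"]).strip())
        except ValueError:
            rejections.append(
                Rejection(rownum, f"unknown method {row['method']!r}")
            )
            continue
        tax = Taxonomy(
            order_code=str(row["order_code"]).strip(),
            species=normalize_species_name(str(row["species"])),
            tribe=(str(row["tribe"]).strip() if "tribe" in df.columns and pd.notna(row.get("tribe")) else None),
        )
        try:
            obs = ActivityObservation(
                source_id=str(row["source_id"]).strip(),
                taxonomy=tax,
                light_activity=light,
                dark_activity=dark,
                method=method,
                activity_unit=str(row.get("activity_unit", "arbitrary") or "arbitrary"),
                genotype=(str(row["genotype"]) if "genotype" in df.columns and pd.notna(row.get("genotype")) else None),
                growth_stage=(str(row["growth_stage"]) if "growth_stage" in df.columns and pd.notna(row.get("growth_stage")) else None),
                dark_treatment_light_level=_opt_float(row.get("dark_treatment_light_level")),
                assay_pH=_opt_float(row.get("assay_pH")),
                assay_temperature_C=_opt_float(row.get("assay_temperature_C")),
                edta_mM=_opt_float(row.get("edta_mM")),
                mgcl2_in_extraction=_opt_bool(row.get("mgcl2_in_extraction")),
                digitized=bool(_opt_bool(row.get("digitized")) or False),
            )
        except ValueError as e:
            rejections.append(Rejection(rownum, str(e)))
            continue
        observations.append(obs)

    ds = Dataset(observations=observations, provenance=str(path))
    return IngestResult(dataset=ds, rejections=rejections)


def write_observations(ds: Dataset, path: Union[str, Path], dialect: str = "tsv") -> None:
    """Write observations to the canonical tabular format (round-trip safe)."""
    rows = []
    for o in ds.observations:
        rows.append(
            {
                "source_id": o.source_id,
                "order_code": o.taxonomy.order_code,
                "tribe": o.taxonomy.tribe,
                "species": o.taxonomy.species,
                "genotype": o.genotype,
                "growth_stage": o.growth_stage,
                "light_activity": o.light_activity,
                "dark_activity": o.dark_activity,
                "activity_unit": o.activity_unit,
                "method": o.method.value,
                "dark_treatment_light_level": o.dark_treatment_light_level,
                "assay_pH": o.assay_pH,
                "assay_temperature_C": o.assay_temperature_C,
                "edta_mM": o.edta_mM,
                "mgcl2_in_extraction": o.mgcl2_in_extraction,
                "digitized": o.digitized,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(dialect), index=False, encoding="utf-8")


_LEVEL_FROM_TEXT = {lvl.value: lvl for lvl in Level}


def load_table1_fixture() -> Dataset:
    """Load the packaged species-summary table (157 flowering-plant species).

    The fixture preserves the printed species means, standard deviations,
    level labels and pathway flags; printed labels are provenance and are
    kept separate from any re-derived classification.
    """
    with resources.files("darkinhib.data").joinpath("table1.tsv").open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, sep="\t")
    summaries = []
    for _, row in df.iterrows():
        tribe = row["tribe"] if pd.notna(row["tribe"]) else TRIBE_NA
        sd = float(row["sd_di_percent"]) if pd.notna(row["sd_di_percent"]) else None
        summaries.append(
            SpeciesSummary(
                taxonomy=Taxonomy(
                    order_code=row["order_code"],
                    order_name=KNOWN_ORDER_CODES.get(row["order_code"]),
                    tribe=tribe,
                    species=normalize_species_name(row["species"]),
                ),
                pathway=PathwayFlags(
                    is_C4=bool(row["is_C4"]),
                    is_C2=bool(row["is_C2"]),
                    is_CAM=bool(row["is_CAM"]),
                ),
                mean_di_percent=float(row["mean_di_percent"]),
                sd_di_percent=sd,
                # the table prints an SD only for species with >= 2 values
                n_datapoints=None,
                level_label=_LEVEL_FROM_TEXT[row["level_label"]],
            )
        )
    return Dataset(
        summaries=summaries,
        provenance="packaged species-summary fixture (published literature compilation)",
    )


def validate_dataset(ds: Dataset) -> ValidationReport:
    """Report invariant violations: duplicates, unknown codes, out-of-range means."""
    report = ValidationReport()
    seen: set[str] = set()
    for i, s in enumerate(ds.summaries):
        name = s.taxonomy.species
        if name in seen:
            report.add("duplicate_species", f"duplicate species summary: {name}", row=i)
        seen.add(name)
        if s.taxonomy.order_code not in KNOWN_ORDER_CODES:
            report.add(
                "unknown_order_code",
                f"unknown order code {s.taxonomy.order_code!r} for {name}",
                row=i,
            )
        if not (-100.0 <= s.mean_di_percent <= 100.0):
            report.add(
                "mean_out_of_range",
                f"mean {s.mean_di_percent} outside [-100, 100] for {name}",
                row=i,
            )
        if s.taxonomy.genus != name.split()[0]:
            report.add("genus_mismatch", f"genus/species mismatch for {name}", row=i)
    for i, o in enumerate(ds.observations):
        if o.taxonomy.order_code not in KNOWN_ORDER_CODES:
            report.add(
                "unknown_order_code",
                f"unknown order code {o.taxonomy.order_code!r} in observation {i}",
                row=i,
            )
    return report


def dataset_to_json(ds: Dataset, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(dataset_to_dict(ds), indent=2), encoding="utf-8")
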