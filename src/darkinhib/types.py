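"""Core domain types for the dark-inhibition meta-analysis.

Dark inhibition is the depression of Rubisco total activity in dark-adapted
relative to light-adapted leaves, expressed as ``1 - dark/light`` (unitless)
or as a percentage. The literature reports it per genotype (observations);
the analysis summarises it per species and classifies species into four
categorical levels (low / moderate / high / very high).
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field, asdict
from typing import Optional

#: Order codes used in the species summary table (three-letter abbreviations
#: of the 14 flowering-plant orders with published dark-inhibition data).
KNOWN_ORDER_CODES: dict[str, str] = {
    "Nym": "Nymphales",
    "Ali": "Alismatales",
    "Asp": "Asparagales",
    "Poa": "Poales",
    "Ast": "Asterales",
    "Sol": "Solanales",
    "Car": "Caryophyllales",
    "Sax": "Saxifragales",
    "Myr": "Myrtales",
    "Cuc": "Cucurbitales",
    "Ros": "Rosales",
    "Fab": "Fabales",
    "Mal": "Malpighiales",
    "Bra": "Brassicales",
}

#: Sentinel used for a tribe that the source table explicitly marks as not
#: available (distinct from an empty/unparsed field).
TRIBE_NA = "N/A"


class AssayMethod(enum.Enum):
    """Experimental method used to determine Rubisco total activity."""

    RADIOLABEL_CO2 = "radiolabel_CO2"
    COUPLED_3PGA_NADH = "coupled_3PGA_NADH"
    RADIOLABEL_CA1P = "radiolabel_CA1P"


class Level(enum.Enum):
    """Categorical dark-inhibition level."""

    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"
    VERY_HIGH = "very_high"

    @property
    def rank(self) -> int:
        return _LEVEL_RANK[self]


_LEVEL_RANK = {Level.LOW: 0, Level.MODERATE: 1, Level.HIGH: 2, Level.VERY_HIGH: 3}


def normalize_species_name(name: str) -> str:
    """Trim, collapse internal whitespace and capitalize the genus token.

    Hybrid designations (e.g. ``"Arachnis x Ascocentrum x Vanda"``) are kept
    verbatim apart from whitespace normalisation; the genus is always the
    first token.
    """
    tokens = name.replace("_", " ").split()
    if not tokens:
        return ""
    tokens[0] = tokens[0][:1].upper() + tokens[0][1:]
    return " ".join(tokens)


@dataclass(frozen=True)
class Taxonomy:
    order_code: str
    species: str
    order_name: Optional[str] = None
    family: Optional[str] = None
    tribe: Optional[str] = None  # TRIBE_NA when explicitly unavailable

    @property
    def genus(self) -> str:
        return self.species.split()[0] if self.species else ""


@dataclass(frozen=True)
class PathwayFlags:
    """Photosynthetic-pathway flags; independent (a species may carry several)."""

    is_C4: bool = False
    is_C2: bool = False
    is_CAM: bool = False


@dataclass(frozen=True)
class ActivityObservation:
    """One genotype-level light/dark total-activity pair with provenance."""

    source_id: str
    taxonomy: Taxonomy
    light_activity: float
    dark_activity: float
    method: AssayMethod
    activity_unit: str = "arbitrary"
    genotype: Optional[str] = None
    growth_stage: Optional[str] = None
    dark_treatment_light_level: Optional[float] = None
    assay_pH: Optional[float] = None
    assay_temperature_C: Optional[float] = None
    edta_mM: Optional[float] = None
    mgcl2_in_extraction: Optional[bool] = None
    digitized: bool = False

    def __post_init__(self) -> None:
        if not (self.light_activity > 0):
            raise ValueError(
                f"light_activity must be > 0, got {self.light_activity!r}"
            )
        if self.dark_activity < 0:
            raise ValueError(
                f"dark_activity must be >= 0, got {self.dark_activity!r}"
            )


@dataclass(frozen=True)
class SpeciesSummary:
    """Per-species mean dark inhibition with taxonomy and pathway flags.

    ``level_label`` carries a label as printed in the source table; it is
    provenance and is never overwritten by re-classification.
    """

    taxonomy: Taxonomy
    mean_di_percent: float
    pathway: PathwayFlags = field(default_factory=PathwayFlags)
    sd_di_percent: Optional[float] = None
    n_datapoints: Optional[int] = None
    level_label: Optional[Level] = None

    def __post_init__(self) -> None:
        if self.sd_di_percent is not None and self.sd_di_percent < 0:
            raise ValueError("sd_di_percent must be non-negative")
        if (
            self.sd_di_percent is not None
            and self.n_datapoints is not None
            and self.n_datapoints < 2
        ):
            raise ValueError("sd requires n_datapoints >= 2")


@dataclass
class Dataset:
    """Container coupling observation- and summary-level records."""

    observations: list[ActivityObservation] = field(default_factory=list)
    summaries: list[SpeciesSummary] = field(default_factory=list)
    provenance: str = ""

    def species_means(self) -> list[float]:
        return [s.mean_di_percent for s in self.summaries]


@dataclass(frozen=True)
class Finding:
    """One validation finding (reported, never raised)."""

    kind: str
    message: str
    row: Optional[int] = None


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def add(self, kind: str, message: str, row: Optional[int] = None) -> None:
        self.findings.append(Finding(kind=kind, message=message, row=row))

    def __len__(self) -> int:
        return len(self.findings)


@dataclass(frozen=True)
class DarkInhibition:
    """The dark-inhibition statistic: ``ratio = 1 - dark/light``.

    ``percent`` is exactly ``100 * ratio``. The ratio may be negative when
    dark activity exceeds light activity (daytime-inhibitor artifacts) and is
    bounded above by 1 (complete inhibition).
    """

    ratio: float

    @property
    def percent(self) -> float:
        return 100.0 * self.ratio


def dataset_to_dict(ds: Dataset) -> dict:
    """JSON-ready dict form of a Dataset (enums as their string values)."""

    def conv(o):
        d = asdict(o)

        def walk(x):
            if isinstance(x, dict):
                return {k: walk(v) for k, v in x.items()}
            if isinstance(x, enum.Enum):
                return x.value
            return x

        return walk(d)

    return {
        "provenance": ds.provenance,
        "observations": [conv(o) for o in ds.observations],
        "summaries": [conv(s) for s in ds.summaries],
    }
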