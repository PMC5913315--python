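"""Domain types for insular conservation-assessment records.

The unit of analysis is one assessed species carrying a Red List status,
one or more insular region labels, and zero or more coded threat entries.
Threat codes follow the hierarchical IUCN threat classification scheme
(version 3.2 style, dot-separated integers such as ``"8.1.2"``) and are
aggregated into 11 major threat classes by a configurable longest-prefix
mapping (:class:`ThreatClassScheme`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum


class Timing(str, Enum):
    """When a threat operates on the population."""

    PAST = "past"
    ONGOING = "ongoing"
    FUTURE = "future"
    UNKNOWN = "unknown"


class Scope(str, Enum):
    """Fraction of the total population a threat affects."""

    WHOLE_GT90 = "whole_gt90"
    MAJORITY_50_90 = "majority_50_90"
    MINORITY_LT50 = "minority_lt50"
    UNKNOWN = "unknown"


class Severity(str, Enum):
    """Rate of decline a threat causes."""

    VERY_RAPID_DECLINES = "very_rapid_declines"
    RAPID_DECLINES = "rapid_declines"
    SLOW_SIGNIFICANT_DECLINES = "slow_significant_declines"
    CAUSING_FLUCTUATIONS = "causing_fluctuations"
    NEGLIGIBLE_DECLINES = "negligible_declines"
    NO_DECLINE = "no_decline"
    UNKNOWN = "unknown"


class Taxon(str, Enum):
    AMPHIBIANS = "amphibians"
    ARTHROPODS = "arthropods"
    BIRDS = "birds"
    FRESHWATER_FISH = "freshwater_fish"
    GASTROPODS = "gastropods"
    MAMMALS = "mammals"
    PLANTS = "plants"
    REPTILES = "reptiles"


class Status(str, Enum):
    """Red List category; EX/EW form the extinct partition, CR/EN/VU the
    threatened one."""

    EX = "EX"
    EW = "EW"
    CR = "CR"
    EN = "EN"
    VU = "VU"


EXTINCT_STATUSES = frozenset({Status.EX, Status.EW})
THREATENED_STATUSES = frozenset({Status.CR, Status.EN, Status.VU})

#: The 15 most documented insular regions (each with >50 assessed species).
DEFAULT_REGIONS: tuple[str, ...] = (
    "Africa Atlantic",
    "Asian Coast",
    "East Indies",
    "Indo-Burma",
    "Japan",
    "Madagascar",
    "Mediterranean Basin",
    "New Caledonia",
    "New Zealand",
    "North America Pacific",
    "Papua New Guinea",
    "Philippines",
    "Polynesia and Micronesia",
    "South America Pacific",
    "West Indies",
)

_CODE_RE = re.compile(r"^\d+(\.\d+)*$")


class ValidationError(ValueError):
    """Raised when a record, code, or configuration violates the data model."""


def validate_threat_code(code: str) -> str:
    """Check that *code* is a dot-separated integer path with a level-1
    component in 1..12; return it unchanged."""
    if not isinstance(code, str) or not _CODE_RE.match(code):
        raise ValidationError(f"malformed threat code: {code!r}")
    level1 = int(code.split(".", 1)[0])
    if not 1 <= level1 <= 12:
        raise ValidationError(f"threat code level-1 component out of range 1..12: {code!r}")
    return code


@dataclass(frozen=True)
class ThreatEntry:
    """A single coded threat with its timing/scope/severity qualifiers."""

    code: str
    timing: Timing = Timing.UNKNOWN
    scope: Scope = Scope.UNKNOWN
    severity: Severity = Severity.UNKNOWN

    def __post_init__(self) -> None:
        validate_threat_code(self.code)
        # coerce plain strings so constructors accept either form
        object.__setattr__(self, "timing", Timing(self.timing))
        object.__setattr__(self, "scope", Scope(self.scope))
        object.__setattr__(self, "severity", Severity(self.severity))


@dataclass
class SpeciesRecord:
    """One assessed species: taxon, status, insular regions, raw threats.

    ``threats`` may be empty, meaning no identified cause of decline; such
    species are retained on load but excluded from networks and statistics.
    """

    species_id: str
    name: str
    taxon: Taxon
    status: Status
    regions: frozenset[str]
    threats: list[ThreatEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.taxon = Taxon(self.taxon)
        self.status = Status(self.status)
        self.regions = frozenset(self.regions)
        if not self.regions:
            raise ValidationError(f"species {self.species_id!r}: regions must be non-empty")

    @property
    def is_extinct(self) -> bool:
        return self.status in EXTINCT_STATUSES

    @property
    def is_threatened(self) -> bool:
        return self.status in THREATENED_STATUSES


@dataclass(frozen=True)
class SchemeEntry:
    prefix: str
    class_id: int
    class_name: str


class ThreatClassScheme:
    """Longest-prefix mapping from hierarchical threat codes to the 11
    aggregated threat classes.

    A prefix matches a code when the prefix's dot-separated components are
    an initial segment of the code's components (so prefix ``"1"`` matches
    ``"1.2"`` but not ``"11.1"``). Among matching entries the longest wins;
    codes matching no entry are excluded from all analyses.
    """

    N_CLASSES = 11

    def __init__(self, entries: list[SchemeEntry]):
        if len({e.prefix for e in entries}) != len(entries):
            raise ValidationError("scheme has duplicate prefixes")
        class_ids = {e.class_id for e in entries}
        if class_ids != set(range(1, self.N_CLASSES + 1)):
            raise ValidationError(
                f"scheme must cover exactly class ids 1..{self.N_CLASSES}, got {sorted(class_ids)}"
            )
        names: dict[int, str] = {}
        for e in entries:
            validate_threat_code(e.prefix)
            if names.setdefault(e.class_id, e.class_name) != e.class_name:
                raise ValidationError(f"class id {e.class_id} has conflicting names")
        self.entries: tuple[SchemeEntry, ...] = tuple(entries)
        self._names = names

    def class_name(self, class_id: int) -> str:
        return self._names[class_id]

    @property
    def class_ids(self) -> tuple[int, ...]:
        return tuple(range(1, self.N_CLASSES + 1))

    @property
    def class_names(self) -> dict[int, str]:
        return dict(self._names)

    def map_code(self, code: str) -> int | None:
        """Class id of the longest matching prefix, or None when unmapped."""
        parts = validate_threat_code(code).split(".")
        best: SchemeEntry | None = None
        best_len = -1
        for e in self.entries:
            p = e.prefix.split(".")
            if len(p) <= len(parts) and parts[: len(p)] == p and len(p) > best_len:
                best, best_len = e, len(p)
        return best.class_id if best is not None else None

    def representative_code(self, class_id: int) -> str:
        """A canonical code guaranteed to map to *class_id* (its shortest
        prefix, extended by one level)."""
        prefixes = sorted(
            (e.prefix for e in self.entries if e.class_id == class_id),
            key=lambda p: p.count("."),
        )
        if not prefixes:
            raise ValidationError(f"unknown class id {class_id}")
        return prefixes[0] + ".1"


def map_threat_code(code: str, scheme: ThreatClassScheme) -> int | None:
    """Map one hierarchical threat code to its aggregated class id."""
    return scheme.map_code(code)


def threat_profile(record: SpeciesRecord, scheme: ThreatClassScheme) -> frozenset[int]:
    """The distinct set of mapped threat-class ids over a species' threats.

    Duplicate codes (or distinct codes under one class) collapse; codes with
    no scheme prefix are dropped.
    """
    out = set()
    for t in record.threats:
        cid = scheme.map_code(t.code)
        if cid is not None:
            out.add(cid)
    return frozenset(out)
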