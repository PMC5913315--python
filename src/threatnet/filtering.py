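"""Record filters applied before network construction.

Three screens: the status partition (extinct = EX+EW vs threatened =
CR+EN+VU), region eligibility (keep regions with strictly more than 50
distinct assessed species), and the harsh-impact screen (keep species with
at least one threat whose scope is whole/majority AND whose severity is a
very rapid / rapid / slow-significant decline, both on the same entry).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .model import (
    EXTINCT_STATUSES,
    Scope,
    Severity,
    SpeciesRecord,
    THREATENED_STATUSES,
    ThreatEntry,
    Timing,
)

HARSH_SCOPES = frozenset({Scope.WHOLE_GT90, Scope.MAJORITY_50_90})
HARSH_SEVERITIES = frozenset(
    {Severity.VERY_RAPID_DECLINES, Severity.RAPID_DECLINES, Severity.SLOW_SIGNIFICANT_DECLINES}
)
#: Timings kept when the optional current-threat restriction is enabled.
CURRENT_TIMINGS = frozenset({Timing.ONGOING, Timing.FUTURE, Timing.UNKNOWN})


@dataclass
class FilterReport:
    """Audit record for one filter application."""

    rule: str
    input_count: int
    output_count: int
    per_region_counts: dict[str, int] = field(default_factory=dict)

    def as_row(self) -> dict:
        return {"rule": self.rule, "input_count": self.input_count, "output_count": self.output_count}


def partition_by_status(
    records: list[SpeciesRecord],
) -> tuple[list[SpeciesRecord], list[SpeciesRecord]]:
    """Split records into the (extinct, threatened) partitions.

    Extinct covers EX and EW; threatened covers CR, EN, and VU. Input order
    is preserved within each partition.
    """
    extinct = [r for r in records if r.status in EXTINCT_STATUSES]
    threatened = [r for r in records if r.status in THREATENED_STATUSES]
    return extinct, threatened


def region_species_counts(records: list[SpeciesRecord]) -> Counter:
    """Distinct assessed species per region (a species in k regions counts
    once in each of the k tallies)."""
    counts: Counter = Counter()
    for r in records:
        counts.update(r.regions)
    return counts


def eligible_regions(records: list[SpeciesRecord], min_assessed: int = 50) -> set[str]:
    """Regions whose distinct-species count strictly exceeds *min_assessed*."""
    if min_assessed < 0:
        raise ValueError("min_assessed must be >= 0")
    return {region for region, n in region_species_counts(records).items() if n > min_assessed}


def restrict_to_regions(
    records: list[SpeciesRecord], regions: set[str]
) -> tuple[list[SpeciesRecord], FilterReport]:
    """Drop region labels outside *regions*; drop species left with none."""
    kept: list[SpeciesRecord] = []
    for r in records:
        inside = r.regions & regions
        if inside:
            if inside != r.regions:
                r = SpeciesRecord(r.species_id, r.name, r.taxon, r.status, inside, list(r.threats))
            kept.append(r)
    report = FilterReport(
        rule=f"restrict_to_regions(n={len(regions)})",
        input_count=len(records),
        output_count=len(kept),
        per_region_counts=dict(region_species_counts(kept)),
    )
    return kept, report


def _qualifies(entry: ThreatEntry) -> bool:
    # scope and severity must both qualify on the SAME entry
    return entry.scope in HARSH_SCOPES and entry.severity in HARSH_SEVERITIES


def filter_harsh_impact(
    records: list[SpeciesRecord], retain_all_threats: bool = True
) -> list[SpeciesRecord]:
    """Keep species significantly and harshly impacted by at least one threat.

    A species qualifies when it has >= 1 threat entry with scope in
    {whole >90%, majority 50-90%} and severity in {very rapid, rapid,
    slow significant declines}; ``unknown`` never qualifies. With
    ``retain_all_threats=False`` only the qualifying entries are kept inside
    each retained species. Idempotent; output is an order-preserving
    sub-list of the input.
    """
    out: list[SpeciesRecord] = []
    for r in records:
        qualifying = [t for t in r.threats if _qualifies(t)]
        if not qualifying:
            continue
        if retain_all_threats:
            out.append(r)
        else:
            out.append(
                SpeciesRecord(r.species_id, r.name, r.taxon, r.status, r.regions, qualifying)
            )
    return out


def filter_current_timing(records: list[SpeciesRecord]) -> list[SpeciesRecord]:
    """Optional screen: drop threat entries whose timing is ``past``; drop
    species left with no entries. Off by default in the pipeline."""
    out = []
    for r in records:
        kept = [t for t in r.threats if t.timing in CURRENT_TIMINGS]
        if kept:
            out.append(SpeciesRecord(r.species_id, r.name, r.taxon, r.status, r.regions, kept))
    return out
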