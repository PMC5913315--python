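"""Readers and writers for assessment tables and configuration.

The canonical table dialect is one CSV row per species-threat pair
(columns ``species_id,name,taxon,status,regions,threat_code,timing,scope,
severity``; regions pipe-delimited within the cell; an empty ``threat_code``
means the species has no identified cause of decline). An equivalent JSON
layout nests the threat entries per species. Rows sharing a ``species_id``
are merged into one record with accumulated threats.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .model import (
    Scope,
    Severity,
    SchemeEntry,
    SpeciesRecord,
    ThreatClassScheme,
    ThreatEntry,
    Timing,
    ValidationError,
)

REQUIRED_COLUMNS = (
    "species_id",
    "name",
    "taxon",
    "status",
    "regions",
    "threat_code",
    "timing",
    "scope",
    "severity",
)

#: Explicit alias table for qualifier tokens as they appear in common
#: Red List exports. Only tokens listed here are coerced; any other
#: unrecognized token is an error (silent coercion hides dialect drift).
DEFAULT_QUALIFIER_ALIASES: dict[str, str] = {
    "": "unknown",
    "unknown": "unknown",
    "whole (>90%)": "whole_gt90",
    "majority (50-90%)": "majority_50_90",
    "minority (<50%)": "minority_lt50",
    "very rapid declines": "very_rapid_declines",
    "rapid declines": "rapid_declines",
    "slow, significant declines": "slow_significant_declines",
    "causing/could cause fluctuations": "causing_fluctuations",
    "negligible declines": "negligible_declines",
    "no decline": "no_decline",
}


class FormatError(ValueError):
    """Raised when an input file does not conform to the expected layout."""


def _coerce_enum(enum_cls, token, row: int, column: str, aliases: dict[str, str]):
    raw = "" if token is None or (isinstance(token, float) and pd.isna(token)) else str(token).strip()
    key = aliases.get(raw.lower(), raw)
    try:
        return enum_cls(key)
    except ValueError:
        raise ValidationError(
            f"row {row}: unrecognized {column} token {raw!r} "
            f"(not an enum value and not in the alias table)"
        ) from None


def load_species_table(
    path: str | Path,
    format: str | None = None,
    aliases: dict[str, str] | None = None,
) -> list[SpeciesRecord]:
    """Load assessment records from CSV or JSON.

    Parameters
    ----------
    path
        Input file. The format is inferred from the suffix unless given.
    format
        ``"csv"`` or ``"json"``.
    aliases
        Qualifier alias table; defaults to :data:`DEFAULT_QUALIFIER_ALIASES`.

    Returns
    -------
    list of SpeciesRecord
        One validated record per distinct ``species_id``, threats accumulated
        across rows in input order.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "json":
        return _load_json(path)
    if format != "csv":
        raise FormatError(f"unknown format {format!r}")
    aliases = DEFAULT_QUALIFIER_ALIASES if aliases is None else aliases

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    records: dict[str, SpeciesRecord] = {}
    for row_idx, row in enumerate(df.itertuples(index=False)):
        sid = str(row.species_id).strip()
        if not sid:
            raise ValidationError(f"row {row_idx}: empty species_id")
        taxon = _coerce_enum_field(row.taxon, "taxon", row_idx)
        status = _coerce_enum_field(row.status, "status", row_idx)
        regions = frozenset(r.strip() for r in str(row.regions).split("|") if r.strip())
        threats: list[ThreatEntry] = []
        code = str(row.threat_code).strip()
        if code:
            threats.append(
                ThreatEntry(
                    code=code,
                    timing=_coerce_enum(Timing, row.timing, row_idx, "timing", aliases),
                    scope=_coerce_enum(Scope, row.scope, row_idx, "scope", aliases),
                    severity=_coerce_enum(Severity, row.severity, row_idx, "severity", aliases),
                )
            )
        if sid in records:
            prev = records[sid]
            if prev.taxon != taxon or prev.status != status:
                raise ValidationError(
                    f"row {row_idx}: species {sid!r} re-declared with conflicting "
                    f"taxon/status ({prev.taxon.value}/{prev.status.value} vs "
                    f"{taxon.value}/{status.value})"
                )
            prev.regions = prev.regions | regions
            prev.threats.extend(threats)
        else:
            records[sid] = SpeciesRecord(
                species_id=sid,
                name=str(row.name).strip(),
                taxon=taxon,
                status=status,
                regions=regions,
                threats=threats,
            )
    return list(records.values())


def _coerce_enum_field(token, column: str, row: int):
    from .model import Status, Taxon

    cls = Taxon if column == "taxon" else Status
    try:
        return cls(str(token).strip())
    except ValueError:
        raise ValidationError(f"row {row}: unknown {column} token {token!r}") from None


def _load_json(path: Path) -> list[SpeciesRecord]:
    data = json.loads(Path(path).read_text())
    if not isinstance(data, list):
        raise FormatError(f"{path}: JSON root must be a list of species objects")
    records = []
    for i, obj in enumerate(data):
        for key in ("species_id", "taxon", "status", "regions"):
            if key not in obj:
                raise FormatError(f"{path}: species object {i} missing key {key!r}")
        threats = [
            ThreatEntry(
                code=t["code"],
                timing=t.get("timing", "unknown"),
                scope=t.get("scope", "unknown"),
                severity=t.get("severity", "unknown"),
            )
            for t in obj.get("threats", [])
        ]
        records.append(
            SpeciesRecord(
                species_id=str(obj["species_id"]),
                name=str(obj.get("name", "")),
                taxon=obj["taxon"],
                status=obj["status"],
                regions=frozenset(obj["regions"]),
                threats=threats,
            )
        )
    ids = [r.species_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate species_id in JSON input")
    return records


def write_species_table(records: list[SpeciesRecord], path: str | Path, format: str | None = None) -> None:
    """Write records in the canonical dialect (inverse of :func:`load_species_table`)."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "json":
        payload = [
            {
                "species_id": r.species_id,
                "name": r.name,
                "taxon": r.taxon.value,
                "status": r.status.value,
                "regions": sorted(r.regions),
                "threats": [
                    {
                        "code": t.code,
                        "timing": t.timing.value,
                        "scope": t.scope.value,
                        "severity": t.severity.value,
                    }
                    for t in r.threats
                ],
            }
            for r in records
        ]
        path.write_text(json.dumps(payload, indent=1) + "\n")
        return
    if format != "csv":
        raise FormatError(f"unknown format {format!r}")
    rows = []
    for r in records:
        regions = "|".join(sorted(r.regions))
        if r.threats:
            for t in r.threats:
                rows.append(
                    (r.species_id, r.name, r.taxon.value, r.status.value, regions,
                     t.code, t.timing.value, t.scope.value, t.severity.value)
                )
        else:
            rows.append((r.species_id, r.name, r.taxon.value, r.status.value, regions,
                         "", "unknown", "unknown", "unknown"))
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, index=False)


def load_scheme(path: str | Path) -> ThreatClassScheme:
    """Load a threat-class scheme from a YAML/JSON list of
    ``{prefix, class_id, class_name}`` entries."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, list):
        raise FormatError(f"{path}: scheme must be a list of entries")
    entries = [
        SchemeEntry(prefix=str(e["prefix"]), class_id=int(e["class_id"]), class_name=str(e["class_name"]))
        for e in raw
    ]
    return ThreatClassScheme(entries)


def default_scheme() -> ThreatClassScheme:
    """The shipped 11-class scheme (editable; see ``config/default_scheme.yaml``)."""
    ref = resources.files("threatnet") / "config" / "default_scheme.yaml"
    entries = [
        SchemeEntry(prefix=str(e["prefix"]), class_id=int(e["class_id"]), class_name=str(e["class_name"]))
        for e in yaml.safe_load(ref.read_text())
    ]
    return ThreatClassScheme(entries)


def default_region_coords() -> dict[str, tuple[float, float]]:
    """Region -> (lat, lon) centroid table shipped with the package."""
    ref = resources.files("threatnet") / "config" / "regions.yaml"
    return {e["region"]: (float(e["lat"]), float(e["lon"])) for e in yaml.safe_load(ref.read_text())}
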