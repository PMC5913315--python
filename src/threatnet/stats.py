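"""Summary statistics over species-threat networks.

Covers the descriptive quantities of the analysis: per-class link counts
and shares, threats-per-species mean +/- sample standard deviation, the
single-threat vs threat-association decomposition over species, the top-N
threat combinations, and per-group (taxon / region / status) breakdowns.
Percentages are carried as 0-100 reals at full precision; rounding to the
one-decimal presentation happens only in the reporting layer.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import SpeciesRecord, ThreatClassScheme, threat_profile
from .networks import BipartiteNetwork, NetworkKind


@dataclass
class NetworkSummary:
    """Descriptive summary of an unweighted species-threat network.

    ``sd_threats_per_species`` is the sample (n-1) standard deviation of the
    per-species profile sizes; mean and sd are None when undefined (0 or 1
    entity) rather than silent NaN.
    """

    n_entity_nodes: int
    n_threat_nodes: int
    n_edges: int
    per_threat_links: dict[int, int]
    per_threat_share: dict[int, float]
    mean_threats_per_species: float | None
    sd_threats_per_species: float | None

    @property
    def n_nodes(self) -> int:
        return self.n_entity_nodes + self.n_threat_nodes


@dataclass
class AssociationTally:
    """Species counts per distinct threat-class combination.

    Keys of ``combos`` are strictly sorted, duplicate-free class-id tuples;
    size-1 combinations are "single threats", size >= 2 are "threat
    associations". Shares are species-denominated (percent of species with
    at least one mapped threat) and sum to 100.
    """

    combos: dict[tuple[int, ...], int] = field(default_factory=dict)

    @property
    def n_species(self) -> int:
        return sum(self.combos.values())

    @property
    def n_single_combos(self) -> int:
        return sum(1 for k in self.combos if len(k) == 1)

    @property
    def n_association_combos(self) -> int:
        return sum(1 for k in self.combos if len(k) >= 2)

    @property
    def single_share(self) -> float | None:
        n = self.n_species
        if n == 0:
            return None
        return 100.0 * sum(v for k, v in self.combos.items() if len(k) == 1) / n

    @property
    def association_share(self) -> float | None:
        n = self.n_species
        if n == 0:
            return None
        return 100.0 * sum(v for k, v in self.combos.items() if len(k) >= 2) / n


def summarize_network(net: BipartiteNetwork) -> NetworkSummary:
    """Summarize an unweighted species-threat network.

    Shares are 100 x links / n_edges per class; the mean obeys
    mean x n_entity_nodes = n_edges exactly before rounding.
    """
    if net.kind is not NetworkKind.SPECIES_UNWEIGHTED:
        raise ValueError("summarize_network expects a species_unweighted network")
    links = net.threat_links()
    n_edges = net.n_edges
    shares = {c: (100.0 * v / n_edges if n_edges else 0.0) for c, v in links.items()}
    degrees = Counter(e for (e, _c) in net.edges)
    sizes = np.array([degrees[e] for e in net.entity_nodes], dtype=float)
    n = len(net.entity_nodes)
    mean = float(sizes.mean()) if n > 0 else None
    sd = float(sizes.std(ddof=1)) if n > 1 else None
    return NetworkSummary(
        n_entity_nodes=n,
        n_threat_nodes=len(net.threat_nodes),
        n_edges=n_edges,
        per_threat_links=links,
        per_threat_share=shares,
        mean_threats_per_species=mean,
        sd_threats_per_species=sd,
    )


def association_tally(records: list[SpeciesRecord], scheme: ThreatClassScheme) -> AssociationTally:
    """Group species by their exact threat profile.

    Species with an empty profile (no mapped threat) are excluded, so combo
    counts sum to the number of analyzable species.
    """
    combos: Counter = Counter()
    for r in records:
        profile = threat_profile(r, scheme)
        if profile:
            combos[tuple(sorted(profile))] += 1
    return AssociationTally(combos=dict(combos))


def top_combinations(
    tally: AssociationTally, n: int = 10
) -> list[tuple[tuple[int, ...], int, float]]:
    """Top-N combinations as (combo, count, percent-of-species) rows.

    Sorted by count descending; ties broken by smaller combination first,
    then lexicographic class-id order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    total = tally.n_species
    ordered = sorted(tally.combos.items(), key=lambda kv: (-kv[1], len(kv[0]), kv[0]))
    return [(combo, count, 100.0 * count / total) for combo, count in ordered[:n]]


def _group_keys(record: SpeciesRecord, group_by: str) -> list[str]:
    if group_by == "taxon":
        return [record.taxon.value]
    if group_by == "status":
        return [record.status.value]
    if group_by == "region":
        return sorted(record.regions)
    raise ValueError(f"group_by must be taxon, region, or status; got {group_by!r}")


def group_breakdown(
    records: list[SpeciesRecord],
    scheme: ThreatClassScheme,
    group_by: str,
) -> dict[str, tuple[NetworkSummary, AssociationTally]]:
    """Per-group network summary + association tally.

    A multi-region species appears in every one of its regions' rows, so
    region rows are not additive to the global summary; taxon and status
    rows partition the species set and are.
    """
    from .networks import build_species_threat_network

    groups: dict[str, list[SpeciesRecord]] = {}
    for r in records:
        for g in _group_keys(r, group_by):
            groups.setdefault(g, []).append(r)
    out = {}
    for g in sorted(groups):
        members = groups[g]
        net = build_species_threat_network(members, scheme)
        out[g] = (summarize_network(net), association_tally(members, scheme))
    return out


def breakdown_table(
    breakdown: dict[str, tuple[NetworkSummary, AssociationTally]],
    scheme: ThreatClassScheme,
) -> pd.DataFrame:
    """Flatten a group breakdown into one row per group."""
    rows = []
    for g, (summary, tally) in breakdown.items():
        row = {
            "group": g,
            "n_species": summary.n_entity_nodes,
            "n_edges": summary.n_edges,
            "n_threat_classes_linked": sum(1 for v in summary.per_threat_links.values() if v > 0),
            "mean_threats_per_species": summary.mean_threats_per_species,
            "sd_threats_per_species": summary.sd_threats_per_species,
            "single_share": tally.single_share,
            "association_share": tally.association_share,
        }
        for c in scheme.class_ids:
            name = scheme.class_name(c)
            row[f"links_{name}"] = summary.per_threat_links[c]
            row[f"share_{name}"] = summary.per_threat_share[c]
        rows.append(row)
    return pd.DataFrame(rows)


def summary_as_dict(summary: NetworkSummary, scheme: ThreatClassScheme) -> dict:
    """JSON-friendly view of a summary (full precision)."""
    return {
        "n_entity_nodes": summary.n_entity_nodes,
        "n_threat_nodes": summary.n_threat_nodes,
        "n_nodes": summary.n_nodes,
        "n_edges": summary.n_edges,
        "mean_threats_per_species": summary.mean_threats_per_species,
        "sd_threats_per_species": summary.sd_threats_per_species,
        "per_threat_links": {scheme.class_name(c): v for c, v in summary.per_threat_links.items()},
        "per_threat_share": {scheme.class_name(c): v for c, v in summary.per_threat_share.items()},
    }
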