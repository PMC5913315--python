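"""Bipartite species/taxa/region - threat networks.

Three network kinds are built from assessment records:

* ``species_unweighted`` - one node per species with a non-empty threat
  profile, one unit edge per (species, threat class);
* ``taxa_weighted`` - one node per taxon, edge weight = number of distinct
  species of that taxon whose profile contains the class;
* ``region_weighted`` - likewise per insular region; a species occurring in
  k regions contributes to all k region weights.

All 11 threat-class nodes are always present regardless of degree, so a
species network over n species has n + 11 nodes. Entity nodes are kept in
sorted order so exports are byte-stable across runs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import networkx as nx
import pandas as pd

from .model import SpeciesRecord, ThreatClassScheme, threat_profile


class NetworkKind(str, Enum):
    SPECIES_UNWEIGHTED = "species_unweighted"
    TAXA_WEIGHTED = "taxa_weighted"
    REGION_WEIGHTED = "region_weighted"


@dataclass
class BipartiteNetwork:
    """Two-part graph between entities (species, taxa, or regions) and the
    11 threat classes; edges carry positive integer weights (all 1 for the
    species kind)."""

    kind: NetworkKind
    entity_nodes: tuple[str, ...]
    threat_nodes: tuple[int, ...]
    edges: dict[tuple[str, int], int]
    entity_attrs: dict[str, dict] | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.entity_nodes) + len(self.threat_nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def entity_degree(self, entity: str) -> int:
        return sum(1 for (e, _c) in self.edges if e == entity)

    def threat_links(self) -> dict[int, int]:
        """Unweighted link count per threat class (degree of the class node)."""
        counts = Counter(c for (_e, c) in self.edges)
        return {c: counts.get(c, 0) for c in self.threat_nodes}

    def threat_weights(self) -> dict[int, int]:
        """Summed edge weight per threat class."""
        out = {c: 0 for c in self.threat_nodes}
        for (_e, c), w in self.edges.items():
            out[c] += w
        return out

    def to_networkx(self, scheme: ThreatClassScheme | None = None) -> nx.Graph:
        g = nx.Graph()
        for c in self.threat_nodes:
            name = scheme.class_name(c) if scheme else str(c)
            g.add_node(f"threat:{c}", part="threat", bipartite=1, label=name, kind=self.kind.value)
        for e in self.entity_nodes:
            attrs = (self.entity_attrs or {}).get(e, {})
            g.add_node(e, part="entity", bipartite=0, kind=self.kind.value, **attrs)
        for (e, c), w in sorted(self.edges.items()):
            g.add_edge(e, f"threat:{c}", weight=int(w))
        return g


def build_species_threat_network(
    records: list[SpeciesRecord], scheme: ThreatClassScheme
) -> BipartiteNetwork:
    """Unweighted species-threat network.

    Species with no mapped threat are excluded, so every entity node has
    degree >= 1; node count = (#species with >=1 mapped threat) + 11 and
    edge count = sum of per-species profile sizes.
    """
    edges: dict[tuple[str, int], int] = {}
    entities = []
    attrs: dict[str, dict] = {}
    for r in sorted(records, key=lambda r: r.species_id):
        profile = threat_profile(r, scheme)
        if not profile:
            continue
        entities.append(r.species_id)
        attrs[r.species_id] = {"status": r.status.value, "taxon": r.taxon.value}
        for c in sorted(profile):
            edges[(r.species_id, c)] = 1
    return BipartiteNetwork(
        kind=NetworkKind.SPECIES_UNWEIGHTED,
        entity_nodes=tuple(entities),
        threat_nodes=scheme.class_ids,
        edges=edges,
        entity_attrs=attrs,
    )


def build_group_threat_network(
    records: list[SpeciesRecord],
    scheme: ThreatClassScheme,
    group_by: str,
    region_coords: dict[str, tuple[float, float]] | None = None,
) -> BipartiteNetwork:
    """Weighted taxa- or region-threat network.

    Edge weight = number of distinct species in the group whose profile
    contains the class (a species never contributes more than 1 to any
    single group-class weight; a multi-region species contributes to each
    of its regions).
    """
    if group_by not in ("taxon", "region"):
        raise ValueError(f"group_by must be 'taxon' or 'region', got {group_by!r}")
    weights: Counter = Counter()
    for r in records:
        profile = threat_profile(r, scheme)
        if not profile:
            continue
        groups = [r.taxon.value] if group_by == "taxon" else sorted(r.regions)
        for g in groups:
            for c in profile:
                weights[(g, c)] += 1
    entities = tuple(sorted({g for (g, _c) in weights}))
    attrs: dict[str, dict] = {}
    kind = NetworkKind.TAXA_WEIGHTED if group_by == "taxon" else NetworkKind.REGION_WEIGHTED
    if kind is NetworkKind.REGION_WEIGHTED and region_coords:
        for g in entities:
            if g in region_coords:
                lat, lon = region_coords[g]
                attrs[g] = {"lat": lat, "lon": lon}
    return BipartiteNetwork(
        kind=kind,
        entity_nodes=entities,
        threat_nodes=scheme.class_ids,
        edges={k: int(v) for k, v in sorted(weights.items())},
        entity_attrs=attrs,
    )


def export_network(
    net: BipartiteNetwork,
    path: str | Path,
    format: str,
    scheme: ThreatClassScheme | None = None,
) -> None:
    """Write a network as GEXF, GraphML, or a CSV edge list.

    GEXF/GraphML carry node attributes ``part`` (entity/threat), ``kind``,
    per-entity attributes (species status/taxon, region lat/lon), and edge
    weights. The edge-list CSV has header ``entity,threat_class,weight``.
    """
    path = Path(path)
    if format == "edgelist_csv":
        rows = [(e, c, w) for (e, c), w in sorted(net.edges.items())]
        pd.DataFrame(rows, columns=["entity", "threat_class", "weight"]).to_csv(path, index=False)
    elif format == "gexf":
        nx.write_gexf(net.to_networkx(scheme), path)
    elif format == "graphml":
        nx.write_graphml(net.to_networkx(scheme), path)
    else:
        raise ValueError(f"unknown export format {format!r}")


def read_edgelist_csv(path: str | Path) -> dict[tuple[str, int], int]:
    """Read back an exported edge-list CSV (round-trip helper)."""
    df = pd.read_csv(path, dtype={"entity": str, "threat_class": int, "weight": int})
    return {(row.entity, int(row.threat_class)): int(row.weight) for row in df.itertuples(index=False)}


def collapse_species_by_group(
    species_net: BipartiteNetwork,
    records: list[SpeciesRecord],
    group_by: str = "taxon",
) -> dict[tuple[str, int], int]:
    """Independent collapse of a species network into group-class weights
    (used to cross-check :func:`build_group_threat_network`)."""
    by_id = {r.species_id: r for r in records}
    weights: Counter = Counter()
    for (sid, c) in species_net.edges:
        r = by_id[sid]
        groups = [r.taxon.value] if group_by == "taxon" else sorted(r.regions)
        for g in groups:
            weights[(g, c)] += 1
    return {k: int(v) for k, v in weights.items()}
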