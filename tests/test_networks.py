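"""Bipartite network construction and export."""

import networkx as nx
import pytest

from threatnet import (
    build_group_threat_network,
    build_species_threat_network,
    export_network,
    threat_profile,
)
from threatnet.io import default_region_coords
from threatnet.networks import collapse_species_by_group, read_edgelist_csv
from threatnet.synthetic import SyntheticConfig, simulate_dataset

from conftest import make_species


class TestSpeciesNetwork:
    def test_single_species_single_class(self, scheme):
        net = build_species_threat_network([make_species("s", ["8.1"])], scheme)
        assert net.n_nodes == 12
        assert net.n_edges == 1

    def test_hand_built_three_species(self, scheme):
        records = [
            make_species("s1", ["8.1"]),
            make_species("s2", ["8.1", "5.1"]),
            make_species("s3", ["2.1"]),
        ]
        net = build_species_threat_network(records, scheme)
        assert net.n_nodes == 14
        assert net.n_edges == 4
        assert net.threat_links()[scheme.map_code("8.1")] == 2

    def test_unmapped_only_species_excluded(self, scheme, toy_records):
        net = build_species_threat_network(toy_records, scheme)
        assert "s4" not in net.entity_nodes  # only threat is geological (unmapped)
        assert net.n_nodes == 3 + 11

    def test_all_eleven_threat_nodes_always_present(self, scheme):
        net = build_species_threat_network([make_species("s", ["8.1"])], scheme)
        assert net.threat_nodes == tuple(range(1, 12))

    def test_edge_count_is_sum_of_profile_sizes(self, scheme):
        cfg = SyntheticConfig(seed=5, n_species=200)
        records = simulate_dataset(cfg, scheme)
        net = build_species_threat_network(records, scheme)
        assert net.n_edges == sum(len(threat_profile(r, scheme)) for r in records)

    def test_bipartite_and_degree_conservation(self, scheme):
        records = simulate_dataset(SyntheticConfig(seed=9, n_species=150), scheme)
        net = build_species_threat_network(records, scheme)
        g = net.to_networkx(scheme)
        parts = nx.get_node_attributes(g, "part")
        assert all(parts[u] != parts[v] for u, v in g.edges)
        entity_deg = sum(net.entity_degree(e) for e in net.entity_nodes)
        assert entity_deg == sum(net.threat_links().values()) == net.n_edges


class TestGroupNetworks:
    def test_taxa_weights_count_distinct_species(self, scheme):
        records = [
            make_species("s1", ["8.1"], taxon="birds"),
            make_species("s2", ["8.1", "5.1"], taxon="birds"),
        ]
        net = build_group_threat_network(records, scheme, "taxon")
        inv, exploit = scheme.map_code("8.1"), scheme.map_code("5.1")
        assert net.edges[("birds", inv)] == 2
        assert net.edges[("birds", exploit)] == 1

    def test_multi_region_species_weights_both_regions(self, scheme):
        records = [make_species("s1", ["8.1"], regions=("A", "B"))]
        net = build_group_threat_network(records, scheme, "region")
        inv = scheme.map_code("8.1")
        assert net.edges[("A", inv)] == 1 and net.edges[("B", inv)] == 1

    def test_empty_records(self, scheme):
        net = build_group_threat_network([], scheme, "taxon")
        assert net.n_nodes == 11 and net.n_edges == 0

    def test_group_weight_sum_equals_profile_sizes(self, scheme):
        records = simulate_dataset(SyntheticConfig(seed=3, n_species=120), scheme)
        net = build_group_threat_network(records, scheme, "taxon")
        by_taxon = {}
        for r in records:
            by_taxon.setdefault(r.taxon.value, []).append(r)
        for taxon, members in by_taxon.items():
            total = sum(w for (g, _c), w in net.edges.items() if g == taxon)
            assert total == sum(len(threat_profile(r, scheme)) for r in members)

    def test_taxa_network_equals_species_network_collapse(self, scheme):
        records = simulate_dataset(SyntheticConfig(seed=11, n_species=300), scheme)
        species_net = build_species_threat_network(records, scheme)
        taxa_net = build_group_threat_network(records, scheme, "taxon")
        assert taxa_net.edges == collapse_species_by_group(species_net, records, "taxon")

    def test_invalid_group_by(self, scheme):
        with pytest.raises(ValueError):
            build_group_threat_network([], scheme, "kingdom")


class TestExport:
    def test_edgelist_round_trip(self, scheme, tmp_path, toy_records):
        net = build_species_threat_network(toy_records, scheme)
        p = tmp_path / "edges.csv"
        export_network(net, p, "edgelist_csv", scheme)
        assert read_edgelist_csv(p) == net.edges

    def test_gexf_parses_and_carries_attributes(self, scheme, tmp_path, toy_records):
        net = build_species_threat_network(toy_records, scheme)
        p = tmp_path / "net.gexf"
        export_network(net, p, "gexf", scheme)
        g = nx.read_gexf(p)
        assert g.number_of_nodes() == net.n_nodes
        assert g.nodes["s1"]["part"] == "entity"
        assert g.nodes["s1"]["status"] == "EX"
        assert g.nodes["threat:8"]["part"] == "threat"

    def test_graphml_round_trip_edges(self, scheme, tmp_path, toy_records):
        net = build_species_threat_network(toy_records, scheme)
        p = tmp_path / "net.graphml"
        export_network(net, p, "graphml", scheme)
        g = nx.read_graphml(p)
        assert g.number_of_edges() == net.n_edges

    def test_region_export_carries_coordinates(self, scheme, tmp_path):
        coords = default_region_coords()
        records = [
            make_species(f"s{i}", ["8.1"], regions=(region,))
            for i, region in enumerate(coords)
        ]
        net = build_group_threat_network(records, scheme, "region", coords)
        p = tmp_path / "regions.gexf"
        export_network(net, p, "gexf", scheme)
        g = nx.read_gexf(p)
        for region, (lat, lon) in coords.items():
            assert g.nodes[region]["lat"] == pytest.approx(lat)
            assert g.nodes[region]["lon"] == pytest.approx(lon)

    def test_unknown_format(self, scheme, toy_records, tmp_path):
        net = build_species_threat_network(toy_records, scheme)
        with pytest.raises(ValueError):
            export_network(net, tmp_path / "x", "dot", scheme)
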