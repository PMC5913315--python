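#!/usr/bin/env python
"""Build and export the six bipartite networks.

From the table written by 01_simulate.py: applies the region-eligibility
screen (>50 assessed species), partitions by status, and builds the
species- (unweighted), taxa-, and region-level (weighted) networks for
each partition, exported as GEXF and CSV edge lists under results/.
"""

from pathlib import Path

from threatnet import (
    build_group_threat_network,
    build_species_threat_network,
    default_scheme,
    eligible_regions,
    export_network,
    load_species_table,
    partition_by_status,
)
from threatnet.filtering import restrict_to_regions
from threatnet.io import default_region_coords

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    scheme = default_scheme()
    records = load_species_table(RESULTS / "records.csv")
    regions = eligible_regions(records)
    records, report = restrict_to_regions(records, regions)
    print(f"region eligibility (>50 species): {len(regions)} regions kept, "
          f"{report.output_count}/{report.input_count} species retained")
    coords = default_region_coords()
    for name, part in zip(("extinct", "threatened"), partition_by_status(records)):
        nets = {
            "species": build_species_threat_network(part, scheme),
            "taxa": build_group_threat_network(part, scheme, "taxon"),
            "regions": build_group_threat_network(part, scheme, "region", coords),
        }
        for label, net in nets.items():
            export_network(net, RESULTS / f"{name}_{label}.gexf", "gexf", scheme)
            export_network(net, RESULTS / f"{name}_{label}_edges.csv", "edgelist_csv", scheme)
            print(f"  {name}/{label}: {net.n_nodes} nodes, {net.n_edges} edges")


if __name__ == "__main__":
    main()
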