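#!/usr/bin/env python
"""Global-scale statistics for both partitions.

Reports, per partition: node/edge counts, per-class link shares, mean +/-
sample-sd threats per species, the single-threat vs threat-association
decomposition over species, and the top-10 combinations. Writes
results/03_global_report.json and prints the headline numbers.
"""

import json
from pathlib import Path

from threatnet import (
    association_tally,
    build_species_threat_network,
    default_scheme,
    eligible_regions,
    load_species_table,
    partition_by_status,
    summarize_network,
    top_combinations,
)
from threatnet.filtering import restrict_to_regions
from threatnet.stats import summary_as_dict

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    scheme = default_scheme()
    records = load_species_table(RESULTS / "records.csv")
    records, _ = restrict_to_regions(records, eligible_regions(records))
    report = {}
    for name, part in zip(("extinct", "threatened"), partition_by_status(records)):
        summary = summarize_network(build_species_threat_network(part, scheme))
        tally = association_tally(part, scheme)
        top = top_combinations(tally, 10)
        report[name] = {
            "summary": summary_as_dict(summary, scheme),
            "single_share": tally.single_share,
            "association_share": tally.association_share,
            "n_single_combos": tally.n_single_combos,
            "n_association_combos": tally.n_association_combos,
            "top_combinations": [
                {"classes": [scheme.class_name(c) for c in combo], "count": n, "share": share}
                for combo, n, share in top
            ],
        }
        shares = summary.per_threat_share
        leader = max(shares, key=shares.get)
        print(f"{name}: {summary.n_entity_nodes} species, {summary.n_edges} links; "
              f"mean threats/species {summary.mean_threats_per_species:.1f} "
              f"± {summary.sd_threats_per_species:.1f}; "
              f"top threat {scheme.class_name(leader)} ({shares[leader]:.1f}% of links); "
              f"alone {tally.single_share:.1f}% / in association {tally.association_share:.1f}%")
    (RESULTS / "03_global_report.json").write_text(json.dumps(report, indent=1) + "\n")


if __name__ == "__main__":
    main()
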