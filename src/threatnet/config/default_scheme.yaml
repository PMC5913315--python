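# Default mapping from hierarchical threat-code prefixes (IUCN threat
# classification scheme v3.2 level-1 categories) to the 11 aggregated
# threat classes used throughout the analysis. Longest prefix wins.
#
# Level-1 category 10 (geological events) is deliberately unmapped: codes
# under it fall outside the 11 classes and are excluded from all analyses.
# Replace this file (or pass your own) to use a different aggregation.
- {prefix: "1", class_id: 1, class_name: urbanization}
- {prefix: "2", class_id: 2, class_name: cultivation}
- {prefix: "3", class_id: 3, class_name: energy_and_mining}
- {prefix: "4", class_id: 4, class_name: transportation}
- {prefix: "5", class_id: 5, class_name: wildlife_exploitation}
- {prefix: "6", class_id: 6, class_name: human_disturbance}
- {prefix: "7", class_id: 7, class_name: habitat_modifications}
- {prefix: "8", class_id: 8, class_name: biological_invasions}
- {prefix: "9", class_id: 9, class_name: pollution}
- {prefix: "11", class_id: 10, class_name: climate_change}
- {prefix: "12", class_id: 11, class_name: other}
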