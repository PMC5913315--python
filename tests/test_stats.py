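"""Network summaries, association tallies, top combinations, breakdowns."""

from itertools import combinations

import numpy as np
import pytest

from threatnet import (
    association_tally,
    build_species_threat_network,
    group_breakdown,
    summarize_network,
    threat_profile,
    top_combinations,
)
from threatnet.stats import AssociationTally, breakdown_table
from threatnet.synthetic import SyntheticConfig, simulate_dataset

from conftest import make_species


class TestSummarizeNetwork:
    def test_profile_sizes_1_2_1(self, scheme):
        records = [
            make_species("s1", ["8.1"]),
            make_species("s2", ["8.1", "5.1"]),
            make_species("s3", ["2.1"]),
        ]
        s = summarize_network(build_species_threat_network(records, scheme))
        assert s.n_edges == 4
        assert s.mean_threats_per_species == pytest.approx(4 / 3)
        assert s.sd_threats_per_species == pytest.approx(np.std([1, 2, 1], ddof=1))

    def test_single_species_sd_undefined(self, scheme):
        s = summarize_network(build_species_threat_network([make_species("s", ["8.1"])], scheme))
        assert s.mean_threats_per_species == 1.0
        assert s.sd_threats_per_species is None

    def test_empty_network_flags_undefined(self, scheme):
        s = summarize_network(build_species_threat_network([], scheme))
        assert s.n_edges == 0
        assert s.mean_threats_per_species is None and s.sd_threats_per_species is None

    def test_shares_sum_to_100(self, scheme):
        records = simulate_dataset(SyntheticConfig(seed=2, n_species=400), scheme)
        s = summarize_network(build_species_threat_network(records, scheme))
        assert sum(s.per_threat_share.values()) == pytest.approx(100.0, abs=0.1)

    def test_mean_edge_identity(self, scheme):
        records = simulate_dataset(SyntheticConfig(seed=7, n_species=250), scheme)
        s = summarize_network(build_species_threat_network(records, scheme))
        assert s.mean_threats_per_species * s.n_entity_nodes == pytest.approx(s.n_edges)

    def test_rejects_weighted_network(self, scheme):
        from threatnet import build_group_threat_network
        net = build_group_threat_network([make_species("s", ["8.1"])], scheme, "taxon")
        with pytest.raises(ValueError):
            summarize_network(net)


def brute_force_tally(records, scheme):
    """Exhaustive count over every non-empty subset of the 11 classes."""
    profiles = [threat_profile(r, scheme) for r in records]
    out = {}
    for size in range(1, 12):
        for subset in combinations(range(1, 12), size):
            n = sum(1 for p in profiles if p == frozenset(subset))
            if n:
                out[subset] = n
    return out


class TestAssociationTally:
    def test_hand_enumerated_profiles(self, scheme):
        records = [
            make_species("s1", ["8.1"]),
            make_species("s2", ["8.1"]),
            make_species("s3", ["8.1", "5.1"]),
            make_species("s4", ["2.1"]),
        ]
        t = association_tally(records, scheme)
        inv, exploit, cult = (scheme.map_code(c) for c in ("8.1", "5.1", "2.1"))
        assert t.combos == {(inv,): 2, tuple(sorted((inv, exploit))): 1, (cult,): 1}
        assert t.single_share == pytest.approx(75.0)
        assert t.association_share == pytest.approx(25.0)

    def test_identical_singleton_profiles(self, scheme):
        records = [make_species(f"s{i}", ["8.1"]) for i in range(5)]
        t = association_tally(records, scheme)
        assert len(t.combos) == 1 and t.single_share == 100.0

    def test_unmapped_species_excluded_from_denominator(self, scheme, toy_records):
        t = association_tally(toy_records, scheme)
        assert t.n_species == 3  # s4 has no mapped class

    def test_empty_shares_are_none(self, scheme):
        t = association_tally([], scheme)
        assert t.single_share is None and t.association_share is None

    def test_matches_bruteforce_subset_oracle(self, scheme):
        records = simulate_dataset(SyntheticConfig(seed=13, n_species=300), scheme)
        t = association_tally(records, scheme)
        assert t.combos == brute_force_tally(records, scheme)
        assert t.single_share + t.association_share == pytest.approx(100.0)


class TestTopCombinations:
    def test_tie_break_smaller_combo_first(self):
        t = AssociationTally(combos={(1,): 5, (2,): 5, (1, 2): 5})
        assert [c for c, _n, _s in top_combinations(t, 3)] == [(1,), (2,), (1, 2)]

    def test_truncation_to_available(self):
        t = AssociationTally(combos={(1,): 3, (2, 3): 1})
        assert len(top_combinations(t, 10)) == 2

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(17)
        combos = {}
        while len(combos) < 20:
            size = int(rng.integers(1, 5))
            key = tuple(sorted(rng.choice(np.arange(1, 12), size=size, replace=False).tolist()))
            combos.setdefault(key, int(rng.integers(1, 1000)))
        t = AssociationTally(combos=combos)
        top = top_combinations(t, 20)
        counts = [n for _c, n, _s in top]
        assert counts == sorted(combos.values(), reverse=True)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            top_combinations(AssociationTally(combos={(1,): 1}), 0)


class TestGroupBreakdown:
    def test_single_group_reproduces_global(self, scheme):
        records = [make_species(f"s{i}", ["8.1", "5.1"][: 1 + i % 2]) for i in range(6)]
        bd = group_breakdown(records, scheme, "taxon")
        assert set(bd) == {"birds"}
        summary, tally = bd["birds"]
        global_summary = summarize_network(build_species_threat_network(records, scheme))
        assert summary == global_summary
        assert tally.combos == association_tally(records, scheme).combos

    def test_disjoint_regions_are_additive(self, scheme):
        records = [make_species(f"a{i}", ["8.1"], regions=("A",)) for i in range(3)] + \
                  [make_species(f"b{i}", ["2.1", "5.1"], regions=("B",)) for i in range(2)]
        bd = group_breakdown(records, scheme, "region")
        total_edges = sum(s.n_edges for s, _t in bd.values())
        assert total_edges == summarize_network(build_species_threat_network(records, scheme)).n_edges

    def test_two_taxa_shares_hand_computed(self, scheme):
        records = [
            make_species("s1", ["8.1"], taxon="birds"),
            make_species("s2", ["8.1", "5.1"], taxon="birds"),
            make_species("s3", ["2.1"], taxon="plants"),
        ]
        bd = group_breakdown(records, scheme, "taxon")
        birds, _ = bd["birds"]
        assert birds.per_threat_share[scheme.map_code("8.1")] == pytest.approx(100 * 2 / 3)
        assert birds.per_threat_share[scheme.map_code("5.1")] == pytest.approx(100 / 3)
        plants, _ = bd["plants"]
        assert plants.per_threat_share[scheme.map_code("2.1")] == pytest.approx(100.0)

    def test_status_rows_and_table_shape(self, scheme):
        records = simulate_dataset(SyntheticConfig(seed=21, n_species=200), scheme)
        bd = group_breakdown(records, scheme, "status")
        table = breakdown_table(bd, scheme)
        assert set(table["group"]) <= {"EX", "EW", "CR", "EN", "VU"}
        for _, row in table.iterrows():
            share_cols = [c for c in table.columns if c.startswith("share_")]
            assert row[share_cols].sum() == pytest.approx(100.0, abs=0.1)
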