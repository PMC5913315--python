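import pytest

from threatnet import SpeciesRecord, ThreatEntry, default_scheme


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


def make_species(sid, classes_or_codes, status="EN", taxon="birds", regions=("Madagascar",),
                 scope="unknown", severity="unknown", timing="ongoing"):
    """Build a species record from threat codes (strings) or class-style
    level-1 codes (ints are turned into '<n>.1')."""
    threats = [
        ThreatEntry(code=c if isinstance(c, str) else f"{c}.1",
                    scope=scope, severity=severity, timing=timing)
        for c in classes_or_codes
    ]
    return SpeciesRecord(
        species_id=sid, name=sid, taxon=taxon, status=status,
        regions=frozenset(regions), threats=threats,
    )


@pytest.fixture
def toy_records():
    """Four species with hand-checkable profiles under the default scheme:
    profiles {invasions}, {invasions, exploitation}, {cultivation}, {} (no
    mapped threat: code 10.x is deliberately unmapped)."""
    return [
        make_species("s1", ["8.1", "8.2"], status="EX"),
        make_species("s2", ["8.1.2", "5.1"], status="CR", taxon="mammals"),
        make_species("s3", ["2.1"], status="VU", taxon="plants", regions=("West Indies",)),
        make_species("s4", ["10.1"], status="EN", taxon="reptiles"),
    ]
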