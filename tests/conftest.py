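import pytest

from ssdesign import synthetic_data as syn


@pytest.fixture(scope="session")
def helix30():
    """Plain 30-residue ideal alpha helix."""
    return syn.make_structure(syn.FixtureSpec(motif="helix", length=30))


@pytest.fixture(scope="session")
def planted_helix():
    """Helix with residues 8 and 22 hinged to an ideal 3.85 Å Cβ–Cβ contact."""
    return syn.make_structure(
        syn.FixtureSpec(motif="helix", length=30, planted_pairs=[(8, 22, 3.85)]))


@pytest.fixture(scope="session")
def bridged_helix():
    """Helix carrying a planted native disulfide C8-C22 (Sγ–Sγ = 2.05 Å)."""
    return syn.make_structure(
        syn.FixtureSpec(motif="helix", length=30,
                        planted_pairs=[(8, 22, 3.85)], native_bridges=[(8, 22)]))


@pytest.fixture(scope="session")
def dumbbell40():
    """Two helical domains joined by an extended linker, ideal pair at (12, 32)."""
    return syn.make_structure(
        syn.FixtureSpec(motif="dumbbell", length=40, planted_pairs=[(12, 32, 3.85)]))
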