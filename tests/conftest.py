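"""Shared fixtures: synthetic receptor and planted poses (no downloads)."""

import pytest

from peplib.fingerprints import GeometricCriteria
from peplib.fixtures import make_poses_with_planted_interactions, make_toy_receptor

# one plant of every interaction type, each at a site that realizes it exclusively
ALL_TYPE_PLANTS = [
    [("hbond_acceptor_from_ligand", "A:THR250")],
    [("hbond_donor_to_ligand", "A:ILE253")],
    [("hydrophobic", "A:MET252")],
    [("pi_pi", "A:HIS435")],
    [("cation_pi", "A:TYR436")],
    [("salt_bridge", "A:GLU430")],
    [("salt_bridge", "A:LYS340")],
    [("cation_pi", "A:LYS340")],
    [("hbond_acceptor_from_ligand", "A:ASN434")],
    [("hbond_donor_to_ligand", "A:ASN434")],
    [("pi_pi", "A:HIS435"), ("hydrophobic", "A:MET252"),
     ("salt_bridge", "A:GLU430")],
    [],
]


@pytest.fixture(scope="session")
def receptor(tmp_path_factory):
    path = tmp_path_factory.mktemp("receptor") / "toy_receptor.pdb"
    return make_toy_receptor(path)


@pytest.fixture(scope="session")
def planted_poses(receptor):
    poses, truth = make_poses_with_planted_interactions(
        receptor, ALL_TYPE_PLANTS
    )
    return poses, truth


@pytest.fixture
def criteria():
    return GeometricCriteria()
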