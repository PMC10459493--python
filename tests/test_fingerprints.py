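"""Interaction detection vs an independent all-pairs geometric oracle,
receptor reading, fingerprint invariances and frequency tables."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Geometry import Point3D

from peplib.fingerprints import (
    GeometricCriteria,
    InteractionFingerprinter,
    ReceptorAtom,
    StructureAtoms,
    _receptor_typing,
    _ring_geometry,
    detect_interactions,
    read_receptor,
    residue_interaction_frequency,
    type_ligand,
)
from peplib.fixtures import make_poses_with_planted_interactions, make_toy_receptor


def oracle_bits(receptor, pose, criteria):
    """Plain nested-loop re-derivation of interaction bits.

    Shares only the atom-typing tables with the implementation; every
    geometric test is recomputed here with explicit formulas and no spatial
    indexing, pruning or vectorization.
    """
    lig = type_ligand(pose)

    def dist(a, b):
        return float(np.sqrt(((a - b) ** 2).sum()))

    def angle(a, b, c):
        v1, v2 = a - b, c - b
        cosv = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        return float(np.degrees(np.arccos(max(-1.0, min(1.0, cosv)))))

    bits = set()
    for key, atoms in receptor.residues().items():
        donors, acceptors, apolar, rings, positive, negative = _receptor_typing(
            atoms
        )
        for don in donors:
            for ai in lig.acceptors:
                if dist(don.coord, lig.coords[ai]) <= criteria.hbond_max_dist:
                    bits.add((key, "hbond_donor_to_ligand"))
        for acc in acceptors:
            for di, h_idx in lig.donors:
                if dist(lig.coords[di], acc.coord) > criteria.hbond_max_dist:
                    continue
                if h_idx and not any(
                    angle(lig.coords[di], lig.coords[h], acc.coord)
                    >= criteria.hbond_min_angle for h in h_idx
                ):
                    continue
                bits.add((key, "hbond_acceptor_from_ligand"))
        for apo in apolar:
            for ci in lig.apolar:
                if dist(apo.coord, lig.coords[ci]) <= criteria.hydrophobic_max_dist:
                    bits.add((key, "hydrophobic"))
        for ring in rings:
            centroid, normal = _ring_geometry(ring)
            for lring in lig.rings:
                lcent, lnorm = _ring_geometry(lig.coords[lring])
                if dist(centroid, lcent) > criteria.pipi_max_centroid_dist:
                    continue
                ang = float(np.degrees(np.arccos(
                    min(1.0, abs(float(np.dot(normal, lnorm)))))))
                lo, hi = criteria.pipi_tshape_angle_range
                if ang <= criteria.pipi_max_parallel_angle or lo <= ang <= hi:
                    bits.add((key, "pi_pi"))
            for ci in lig.cations:
                if dist(centroid, lig.coords[ci]) <= criteria.cation_pi_max_dist:
                    bits.add((key, "cation_pi"))
        for pos in positive:
            for lring in lig.rings:
                lcent, _n = _ring_geometry(lig.coords[lring])
                if dist(pos.coord, lcent) <= criteria.cation_pi_max_dist:
                    bits.add((key, "cation_pi"))
            for ai in lig.anions:
                if dist(pos.coord, lig.coords[ai]) <= criteria.salt_bridge_max_dist:
                    bits.add((key, "salt_bridge"))
        for neg in negative:
            for ci in lig.cations:
                if dist(neg.coord, lig.coords[ci]) <= criteria.salt_bridge_max_dist:
                    bits.add((key, "salt_bridge"))
    return bits


class TestReadReceptor:
    def test_chain_selection(self, tmp_path):
        rec = make_toy_receptor(tmp_path / "r.pdb")
        only_a = read_receptor(tmp_path / "r.pdb", chains=["A"])
        assert all(a.chain == "A" for a in only_a.atoms)
        assert len(only_a) < len(rec)

    def test_absent_chain_lists_available(self, tmp_path):
        make_toy_receptor(tmp_path / "r.pdb")
        with pytest.raises(ValueError, match="available"):
            read_receptor(tmp_path / "r.pdb", chains=["Z"])

    def test_author_numbering_preserved(self, receptor):
        keys = receptor.residue_keys()
        assert "A:THR250" in keys
        assert "A:HIS435" in keys
        assert "B:GLY900" in keys


class TestDetection:
    def test_constructed_hbond_inside_cutoffs(self, receptor, criteria):
        poses, _ = make_poses_with_planted_interactions(
            receptor, [[("hbond_acceptor_from_ligand", "A:THR250")]]
        )
        fp = detect_interactions(receptor, poses[0], criteria)
        assert fp.bits == {("A:THR250", "hbond_acceptor_from_ligand")}

    def test_same_pair_outside_cutoff_is_silent(self, receptor, criteria):
        poses, _ = make_poses_with_planted_interactions(
            receptor, [[("hbond_acceptor_from_ligand", "A:THR250")]]
        )
        pose = Chem.Mol(poses[0])
        conf = pose.GetConformer()
        for i in range(pose.GetNumAtoms()):
            p = conf.GetAtomPosition(i)
            conf.SetAtomPosition(i, Point3D(p.x, p.y, p.z + 2.5))  # N-O 5.4 A
        fp = detect_interactions(receptor, pose, criteria)
        assert ("A:THR250", "hbond_acceptor_from_ligand") not in fp.bits

    def test_parallel_rings_stack(self, receptor, criteria):
        poses, _ = make_poses_with_planted_interactions(
            receptor, [[("pi_pi", "A:HIS435")]]
        )
        fp = detect_interactions(receptor, poses[0], criteria)
        assert fp.bits == {("A:HIS435", "pi_pi")}

    def test_planted_truth_recovered_exactly(self, receptor, planted_poses,
                                             criteria):
        poses, truth = planted_poses
        for pose in poses:
            expected = {
                (row.residue, row.interaction_type)
                for row in truth[truth.pose_id == pose.GetProp("_Name")]
                .itertuples()
            }
            fp = detect_interactions(receptor, pose, criteria)
            assert fp.bits == expected, pose.GetProp("_Name")

    def test_matches_all_pairs_oracle(self, receptor, planted_poses, criteria):
        poses, _ = planted_poses
        for pose in poses:
            fp = detect_interactions(receptor, pose, criteria)
            assert fp.bits == oracle_bits(receptor, pose, criteria)

    def test_far_pose_rejected(self, receptor, criteria):
        mol = Chem.RWMol()
        mol.AddAtom(Chem.Atom("C"))
        conf = Chem.Conformer(1)
        conf.SetAtomPosition(0, Point3D(500.0, 500.0, 500.0))
        m = mol.GetMol()
        Chem.SanitizeMol(m)
        m.AddConformer(conf)
        with pytest.raises(ValueError, match="not a docked pose"):
            detect_interactions(receptor, m, criteria)


class TestInvariances:
    @staticmethod
    def _transform(coords, rot, shift):
        return coords @ rot.T + shift

    def test_rigid_body_invariance(self, receptor, planted_poses, criteria):
        poses, _ = planted_poses
        rng = np.random.default_rng(17)
        # random proper rotation via QR
        q, _r = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = rng.normal(scale=30.0, size=3)
        moved_atoms = [
            ReceptorAtom(name=a.name, element=a.element, resname=a.resname,
                         resseq=a.resseq, chain=a.chain,
                         coord=self._transform(a.coord, q, shift))
            for a in receptor.atoms
        ]
        moved_receptor = StructureAtoms(moved_atoms)
        for pose in poses[:6]:
            moved = Chem.Mol(pose)
            conf = moved.GetConformer()
            new = self._transform(conf.GetPositions(), q, shift)
            for i, xyz in enumerate(new):
                conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
            before = detect_interactions(receptor, pose, criteria).bits
            after = detect_interactions(moved_receptor, moved, criteria).bits
            assert before == after

    def test_tightening_cutoffs_never_adds(self, receptor, planted_poses):
        poses, _ = planted_poses
        loose = GeometricCriteria()
        tight = GeometricCriteria(
            hbond_max_dist=3.0, hydrophobic_max_dist=4.0,
            pipi_max_centroid_dist=4.5, cation_pi_max_dist=5.0,
            salt_bridge_max_dist=3.5,
        )
        for pose in poses:
            assert detect_interactions(receptor, pose, tight).bits <= \
                detect_interactions(receptor, pose, loose).bits

    def test_atom_order_invariance(self, receptor, criteria):
        poses, _ = make_poses_with_planted_interactions(
            receptor, [[("salt_bridge", "A:GLU430"),
                        ("hydrophobic", "A:LEU314")]]
        )
        pose = poses[0]
        order = list(range(pose.GetNumAtoms()))[::-1]
        renumbered = Chem.RenumberAtoms(pose, order)
        assert detect_interactions(receptor, renumbered, criteria).bits == \
            detect_interactions(receptor, pose, criteria).bits


class TestFingerprinterEstimator:
    def test_universe_frozen_across_poses(self, receptor, planted_poses):
        poses, _ = planted_poses
        fper = InteractionFingerprinter(receptor=receptor).fit(poses)
        fps = fper.transform(poses)
        dims = {len(fp.space) for fp in fps}
        assert len(dims) == 1
        matrix = fper.to_matrix(fps)
        assert matrix.shape == (len(poses), len(fps[0].space))
        # far-away decoy chain must not enter the contact universe
        assert not any(k.startswith("B:") for k in fper.residues_)

    def test_transform_before_fit_raises(self, receptor):
        with pytest.raises(ValueError):
            InteractionFingerprinter(receptor=receptor).transform([])


class TestResidueInteractionFrequency:
    def test_identical_fingerprints_give_zero_or_one(self, receptor,
                                                     planted_poses, criteria):
        poses, _ = planted_poses
        fp = detect_interactions(receptor, poses[3], criteria)
        table = residue_interaction_frequency([fp] * 10)
        values = set(np.unique(table.values))
        assert values <= {0.0, 1.0}

    def test_manual_tally_on_four_fingerprints(self, receptor, criteria):
        plants = [
            [("pi_pi", "A:HIS435")],
            [("pi_pi", "A:HIS435")],
            [("pi_pi", "A:HIS435"), ("hydrophobic", "A:MET252")],
            [("salt_bridge", "A:GLU430")],
        ]
        poses, _ = make_poses_with_planted_interactions(receptor, plants)
        fper = InteractionFingerprinter(receptor=receptor).fit(poses)
        fps = fper.transform(poses)
        table = residue_interaction_frequency(fps)
        assert table.loc["A:HIS435", "pi_pi"] == pytest.approx(3 / 4)
        assert table.loc["A:MET252", "hydrophobic"] == pytest.approx(1 / 4)
        assert table.loc["A:GLU430", "salt_bridge"] == pytest.approx(1 / 4)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            residue_interaction_frequency([])
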