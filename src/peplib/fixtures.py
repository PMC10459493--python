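"""Self-contained synthetic fixtures: toy receptor, planted poses, scored SD.

Everything here exists so that every pipeline stage can run and be tested
without downloads or a docking engine.  The toy receptor is a handful of
spatially isolated residue fragments (minimal atom sets, one interaction
capability each where possible) author-numbered to mimic Fc-region labels
(THR250, MET252, ILE253, GLU430, ASN434, HIS435, ...).  Poses are placed
analytically so that exactly the requested interactions satisfy the default
geometric criteria and no others; scored SD files draw per-run scores from a
seeded normal noise model around planted true values.  Nothing here has
realistic protein geometry or energetics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

from .fingerprints import (
    GeometricCriteria,
    StructureAtoms,
    _receptor_typing,
    _ring_geometry,
    read_receptor,
)

_Z = np.array([0.0, 0.0, 1.0])

# default residue layout: (resname, resseq, chain, {atom name: offset}) placed
# on a 14 A grid so sites on different residues can never cross-talk under the
# default cutoffs (max 6 A).
_PENTAGON = {
    name: 1.16 * np.array([np.cos(a), np.sin(a), 0.0])
    for name, a in zip(
        ("CG", "ND1", "CE1", "NE2", "CD2"),
        np.deg2rad(90 + 72 * np.arange(5)),
    )
}
_HEXAGON = {
    name: 1.39 * np.array([np.cos(a), np.sin(a), 0.0])
    for name, a in zip(
        ("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),
        np.deg2rad(90 + 60 * np.arange(6)),
    )
}

DEFAULT_RECEPTOR_LAYOUT: list[tuple[str, int, str, dict[str, np.ndarray]]] = [
    ("THR", 250, "A", {"CA": np.zeros(3), "C": np.array([1.5, 0, 0]),
                       "O": np.array([1.5, 1.23, 0.0])}),
    ("LEU", 251, "A", {"CA": np.zeros(3), "C": np.array([1.5, 0, 0]),
                       "O": np.array([1.5, 1.23, 0.0]),
                       "CB": np.array([-1.0, -1.0, 0.0]),
                       "CG": np.array([-2.3, -1.6, 0.0]),
                       "CD1": np.array([-3.5, -0.8, 0.0])}),
    ("MET", 252, "A", {"CB": np.zeros(3), "CG": np.array([1.5, 0, 0]),
                       "CE": np.array([3.0, 0.8, 0.0])}),
    ("ILE", 253, "A", {"N": np.zeros(3), "CA": np.array([1.45, 0, 0])}),
    ("LEU", 314, "A", {"CB": np.zeros(3), "CG": np.array([1.5, 0.3, 0]),
                       "CD1": np.array([2.8, -0.5, 0.0])}),
    ("LYS", 340, "A", {"CE": np.zeros(3), "NZ": np.array([1.45, 0, 0])}),
    ("GLU", 430, "A", {"CA": np.zeros(3), "C": np.array([1.5, 0, 0]),
                       "O": np.array([1.5, 1.23, 0.0]),
                       "CD": np.array([-4.0, 0, 0]),
                       "OE1": np.array([-5.0, 0.8, 0.0]),
                       "OE2": np.array([-4.3, -1.2, 0.0])}),
    ("ASN", 434, "A", {"CG": np.zeros(3), "OD1": np.array([0, 1.23, 0.0]),
                       "ND2": np.array([1.9, -1.4, 0.0])}),
    ("HIS", 435, "A", dict(_PENTAGON)),
    ("TYR", 436, "A", {**_HEXAGON, "OH": 2.75 * np.array(
        [np.cos(np.deg2rad(270)), np.sin(np.deg2rad(270)), 0.0])}),
]

_GRID = 14.0


def _default_centers(n: int) -> list[np.ndarray]:
    cols = 4
    return [np.array([(i % cols) * _GRID, (i // cols) * _GRID, 0.0])
            for i in range(n)]


@dataclass
class FixtureSpec:
    """Bundle of fixture-generation parameters; same spec + seed => same bytes."""

    seed: int = 42
    alphabet: str = "ACDGKSTW"
    length: int = 2
    noise_sd: float = 0.5
    runs: int = 5


def make_toy_receptor(
    path: str | Path,
    residues: list[tuple[str, int, str, dict[str, np.ndarray]]] | None = None,
    include_decoy_chain: bool = True,
    min_atom_separation: float = 1.0,
) -> StructureAtoms:
    """Write a small synthetic receptor PDB and return it re-read.

    The default layout spreads ten residue fragments on a 14 Angstrom grid:
    backbone-carbonyl acceptors (THR250, LEU251, GLU430), a backbone-amine
    donor (ILE253), apolar carbons (MET252, LEU251, LEU314), side-chain
    donor/acceptor amide (ASN434), charged groups (GLU430 carboxylate, LYS340
    ammonium) and aromatic rings (HIS435, TYR436).  ``include_decoy_chain``
    adds a far-away chain B glycine for chain-selection tests.  Raises when
    two atoms come closer than ``min_atom_separation``.
    """
    if residues is None:
        centers = _default_centers(len(DEFAULT_RECEPTOR_LAYOUT))
        residues = [
            (resname, resseq, chain,
             {name: center + off for name, off in atoms.items()})
            for (resname, resseq, chain, atoms), center
            in zip(DEFAULT_RECEPTOR_LAYOUT, centers)
        ]
    if include_decoy_chain:
        residues = residues + [
            ("GLY", 900, "B", {"CA": np.array([70.0, 70.0, 0.0])})
        ]
    coords = np.array([c for *_rest, atoms in residues for c in atoms.values()])
    if len(coords) > 1:
        diffs = coords[:, None, :] - coords[None, :, :]
        dmat = np.sqrt((diffs ** 2).sum(-1))
        np.fill_diagonal(dmat, np.inf)
        if dmat.min() < min_atom_separation:
            raise ValueError(
                f"overlapping atoms in receptor spec: min distance "
                f"{dmat.min():.2f} A < {min_atom_separation} A"
            )
    lines = []
    serial = 1
    for resname, resseq, chain, atoms in residues:
        for name, xyz in atoms.items():
            element = name[0]
            namef = name if len(name) >= 4 else f" {name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {namef}{'':1s}{resname:>3s} {chain}"
                f"{resseq:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
    return read_receptor(path)


# ---------------------------------------------------------------------------
# planted poses

_A = Chem.Atom  # noqa: N816  (alias for brevity in fragment builders)


def _add_fragment(mol: Chem.RWMol, coords: list[np.ndarray], kind: str,
                  site: np.ndarray, normal: np.ndarray) -> None:
    """Append one interaction fragment to ``mol``/``coords`` at ``site``."""

    def add_atom(symbol: str, pos: np.ndarray, charge: int = 0,
                 no_implicit: bool = False, aromatic: bool = False) -> int:
        atom = Chem.Atom(symbol)
        atom.SetFormalCharge(charge)
        atom.SetNoImplicit(no_implicit)
        atom.SetIsAromatic(aromatic)
        idx = mol.AddAtom(atom)
        coords.append(np.asarray(pos, dtype=float))
        return idx

    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    # an arbitrary in-plane frame orthogonal to n
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, n)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, ref)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)

    if kind == "ligand_donor":  # methylamine N-H aimed at a receptor acceptor
        ni = add_atom("N", site + 2.9 * n)
        hi = add_atom("H", site + 1.9 * n)
        ci = add_atom("C", site + 2.9 * n + 1.2 * u + 0.8 * n)
        mol.AddBond(ni, hi, Chem.BondType.SINGLE)
        mol.AddBond(ni, ci, Chem.BondType.SINGLE)
    elif kind == "ligand_acceptor":  # formaldehyde O aimed at a receptor donor
        oi = add_atom("O", site + 2.9 * n)
        ci = add_atom("C", site + 2.9 * n + 0.8 * u + 0.93 * n)
        mol.AddBond(ci, oi, Chem.BondType.DOUBLE)
    elif kind == "apolar_carbon":  # methane
        add_atom("C", site + 3.8 * n)
    elif kind == "benzene":
        center = site + 5.0 * n
        idxs = [
            add_atom("C", center + 1.39 * (np.cos(a) * u + np.sin(a) * v),
                     aromatic=True)
            for a in np.deg2rad(60.0 * np.arange(6))
        ]
        for i in range(6):
            bond = mol.AddBond(idxs[i], idxs[(i + 1) % 6],
                               Chem.BondType.AROMATIC)
            mol.GetBondWithIdx(bond - 1).SetIsAromatic(True)
    elif kind == "benzene_close":  # for cation-pi from a receptor cation
        center = site + 4.5 * n
        idxs = [
            add_atom("C", center + 1.39 * (np.cos(a) * u + np.sin(a) * v),
                     aromatic=True)
            for a in np.deg2rad(60.0 * np.arange(6))
        ]
        for i in range(6):
            bond = mol.AddBond(idxs[i], idxs[(i + 1) % 6],
                               Chem.BondType.AROMATIC)
            mol.GetBondWithIdx(bond - 1).SetIsAromatic(True)
    elif kind == "quaternary_cation":  # bare N+ (no H: neither donor nor acceptor)
        add_atom("N", site + 4.5 * n, charge=1, no_implicit=True)
    elif kind == "cation_close":  # N+ at salt-bridge range
        add_atom("N", site + 3.8 * n, charge=1, no_implicit=True)
    elif kind == "carboxylate":  # formate anion at salt-bridge range
        o1 = add_atom("O", site + 3.8 * n, charge=-1)
        ci = add_atom("C", site + 3.8 * n + 1.0 * u + 0.75 * n)
        o2 = add_atom("O", site + 3.8 * n + 1.6 * u + 1.85 * n)
        mol.AddBond(ci, o1, Chem.BondType.SINGLE)
        mol.AddBond(ci, o2, Chem.BondType.DOUBLE)
    else:  # pragma: no cover
        raise ValueError(f"unknown fragment kind {kind!r}")


def _resolve_site(receptor: StructureAtoms, residue_key: str, itype: str
                  ) -> tuple[np.ndarray, np.ndarray, str]:
    """Pick the site coordinate, approach normal and fragment kind for a plant.

    Raises ``ValueError`` for infeasible plants (residue lacks the required
    group, or no geometry can realize the type exclusively).
    """
    residues = receptor.residues()
    if residue_key not in residues:
        raise ValueError(f"residue {residue_key} not in receptor")
    atoms = residues[residue_key]
    donors, acceptors, apolar, rings, positive, negative = _receptor_typing(atoms)
    backbone_acceptors = [a for a in acceptors if a.name in ("O", "OXT")]
    sidechain_o = [a for a in acceptors if a.name in ("OD1", "OE1")]
    if itype == "hbond_acceptor_from_ligand":
        pool = backbone_acceptors or sidechain_o
        if not pool:
            raise ValueError(
                f"infeasible plant: {residue_key} has no exclusive acceptor site"
            )
        return pool[0].coord, _Z, "ligand_donor"
    if itype == "hbond_donor_to_ligand":
        pool = [d for d in donors if d.name in ("N", "ND2", "NZ", "NE1")]
        if not pool:
            raise ValueError(
                f"infeasible plant: {residue_key} has no exclusive donor site"
            )
        return pool[0].coord, _Z, "ligand_acceptor"
    if itype == "hydrophobic":
        if not apolar:
            raise ValueError(f"infeasible plant: {residue_key} has no apolar carbon")
        return apolar[-1].coord, _Z, "apolar_carbon"
    if itype == "pi_pi":
        if not rings:
            raise ValueError(f"infeasible plant: {residue_key} has no aromatic ring")
        centroid, normal = _ring_geometry(rings[0])
        return centroid, normal, "benzene"
    if itype == "cation_pi":
        if rings:
            centroid, normal = _ring_geometry(rings[0])
            return centroid, normal, "quaternary_cation"
        if positive:
            return positive[0].coord, _Z, "benzene_close"
        raise ValueError(
            f"infeasible plant: {residue_key} has neither ring nor cation"
        )
    if itype == "salt_bridge":
        if negative:
            return negative[0].coord, _Z, "cation_close"
        if positive:
            return positive[0].coord, _Z, "carboxylate"
        raise ValueError(f"infeasible plant: {residue_key} has no charged group")
    raise ValueError(f"unknown interaction type {itype!r}")


def make_poses_with_planted_interactions(
    receptor: StructureAtoms,
    plants: list[list[tuple[str, str]]],
    path: str | Path | None = None,
    pose_ids: list[str] | None = None,
) -> tuple[list[Chem.Mol], pd.DataFrame]:
    """Build one pose per plant list; each plant is ``(interaction_type, residue_key)``.

    Every pose satisfies exactly its planted interactions under the default
    :class:`GeometricCriteria` and no others (sites are spatially isolated in
    the default toy receptor).  Returns the poses and a ground-truth table
    with columns (pose_id, residue, interaction_type); writes an SD file when
    ``path`` is given.  An empty plant list yields a single far-carbon probe
    pose with an empty fingerprint.
    """
    poses: list[Chem.Mol] = []
    truth_rows = []
    if pose_ids is None:
        pose_ids = [f"pose{i:03d}" for i in range(len(plants))]
    for pose_id, plant in zip(pose_ids, plants):
        mol = Chem.RWMol()
        coords: list[np.ndarray] = []
        if not plant:
            # inert probe within detection range of the receptor, no contacts
            probe = receptor.coords.mean(axis=0) + np.array([0.0, 0.0, 10.0])
            atom = Chem.Atom("C")
            mol.AddAtom(atom)
            coords.append(probe)
        for itype, residue_key in plant:
            site, normal, kind = _resolve_site(receptor, residue_key, itype)
            _add_fragment(mol, coords, kind, site, normal)
            truth_rows.append(
                {"pose_id": pose_id, "residue": residue_key,
                 "interaction_type": itype}
            )
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i, xyz in enumerate(coords):
            conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
        m = mol.GetMol()
        Chem.SanitizeMol(m)
        m.AddConformer(conf)
        m.SetProp("_Name", pose_id)
        poses.append(m)
    truth = pd.DataFrame(truth_rows,
                         columns=["pose_id", "residue", "interaction_type"])
    if path is not None:
        writer = Chem.SDWriter(str(path))
        for pose in poses:
            writer.write(pose)
        writer.close()
    return poses, truth


def make_scored_sd(
    path: str | Path,
    true_scores: dict[str, float],
    runs: int = 5,
    noise_sd: float = 0.5,
    seed: int = 0,
    inter_offset: float = -1.0,
) -> pd.DataFrame:
    """Write a multi-run scored SD file around planted true scores.

    Each peptide id gets ``runs`` records with ``SCORE`` drawn from
    ``normal(true, noise_sd)`` (seeded, hence byte-reproducible) and
    ``SCORE.INTER = SCORE + inter_offset``.  Returns the table of emitted
    scores.  With ``noise_sd=0`` ranks equal the planted order exactly.
    """
    rng = np.random.default_rng(seed)
    dummy = Chem.MolFromSmiles("CC")
    AllChem.Compute2DCoords(dummy)
    rows = []
    writer = Chem.SDWriter(str(path))
    for pid in sorted(true_scores):
        for run in range(1, runs + 1):
            score = float(true_scores[pid] + rng.normal(0.0, noise_sd)
                          if noise_sd > 0 else true_scores[pid])
            mol = Chem.Mol(dummy)
            mol.SetProp("_Name", pid)
            mol.SetProp("SCORE", f"{score:.4f}")
            mol.SetProp("SCORE.INTER", f"{score + inter_offset:.4f}")
            mol.SetProp("RUN", str(run))
            writer.write(mol)
            rows.append({"peptide_id": pid, "run": run, "score": score,
                         "inter_score": score + inter_offset})
    writer.close()
    return pd.DataFrame(rows)
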