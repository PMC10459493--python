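"""Receptor-ligand interaction detection and per-residue fingerprints.

Interactions between a receptor structure (PDB) and a docked ligand pose are
detected with explicit geometric criteria — published standard cutoffs, made
configurable — and assembled into a fixed-dimension fingerprint over
(receptor residue x interaction type).  Six types are distinguished:

* ``hbond_donor_to_ligand``   — receptor donor N/O to a ligand acceptor;
* ``hbond_acceptor_from_ligand`` — ligand donor (with H) to a receptor acceptor;
* ``hydrophobic``             — apolar carbon-carbon contact;
* ``pi_pi``                   — aromatic ring stacking (parallel or T-shaped);
* ``cation_pi``               — charged group to aromatic ring centroid;
* ``salt_bridge``             — opposite formal charges within cutoff.

Receptor atoms are typed from residue/atom-name tables (donor and acceptor
heavy atoms, apolar carbons, aromatic rings, charged side-chain groups);
ligand atoms are typed from the RDKit connection table.  When donor hydrogens
are present the D-H...A angle is required on top of the heavy-atom distance;
without hydrogens (the usual case for crystallographic receptors) the
heavy-atom distance criterion alone applies.  Residue numbering follows the
source PDB verbatim, so labels like THR250 or HIS435 match the literature.
"""

from __future__ import annotations

import json
import warnings
from collections.abc import Iterable, Sequence
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, TransformerMixin

INTERACTION_TYPES = (
    "hbond_donor_to_ligand",
    "hbond_acceptor_from_ligand",
    "hydrophobic",
    "pi_pi",
    "cation_pi",
    "salt_bridge",
)


@dataclass
class GeometricCriteria:
    """Geometric cutoffs for interaction detection (distances in Angstrom).

    Defaults are standard literature values; the original study's proprietary
    fingerprint definitions are not published, so every cutoff is explicit and
    configurable, and the values used are recorded alongside every output.
    """

    hbond_max_dist: float = 3.5
    hbond_min_angle: float = 120.0  # degrees, D-H...A, applied when H present
    hydrophobic_max_dist: float = 4.5
    pipi_max_centroid_dist: float = 5.5
    pipi_max_parallel_angle: float = 30.0
    pipi_tshape_angle_range: tuple[float, float] = (60.0, 90.0)
    cation_pi_max_dist: float = 6.0
    salt_bridge_max_dist: float = 4.0

    def __post_init__(self):
        for name in ("hbond_max_dist", "hydrophobic_max_dist",
                     "pipi_max_centroid_dist", "cation_pi_max_dist",
                     "salt_bridge_max_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


# ---------------------------------------------------------------------------
# receptor atom typing tables (PDB v3 atom names)

_BACKBONE_DONOR = "N"      # except proline
_BACKBONE_ACCEPTORS = ("O", "OXT")

_SIDECHAIN_DONORS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "TRP": ("NE1",),
    "HIS": ("ND1", "NE2"),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
}

_SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
}

# carbons whose bonded neighbours are only C, H or S
_APOLAR_CARBONS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "CYS": ("CB",),
    "THR": ("CG2",),
    "VAL": ("CB", "CG1", "CG2"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "MET": ("CB", "CG", "CE"),
    "PRO": ("CB", "CG"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2"),
    "HIS": ("CB",),
    "LYS": ("CB", "CG", "CD"),
    "ARG": ("CB", "CG"),
    "ASP": ("CB",),
    "GLU": ("CB", "CG"),
    "ASN": ("CB",),
    "GLN": ("CB", "CG"),
}

_AROMATIC_RINGS: dict[str, tuple[tuple[str, ...], ...]] = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TRP": (
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
    ),
    "HIS": (("CG", "ND1", "CE1", "NE2", "CD2"),),
}

# side-chain charged-group heavy atoms at physiological pH
_POSITIVE_ATOMS: dict[str, tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2", "CZ"),
}
_NEGATIVE_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}


@dataclass
class ReceptorAtom:
    name: str
    element: str
    resname: str
    resseq: int
    chain: str
    coord: np.ndarray
    serial: int = 0

    @property
    def residue_key(self) -> str:
        return f"{self.chain}:{self.resname}{self.resseq}"


class StructureAtoms:
    """A flat, typed view of receptor atoms with author numbering preserved."""

    def __init__(self, atoms: Sequence[ReceptorAtom], source: str = ""):
        if not atoms:
            raise ValueError("structure has no atoms")
        self.atoms = list(atoms)
        self.source = source
        self.coords = np.array([a.coord for a in self.atoms], dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in structure")

    def __len__(self) -> int:
        return len(self.atoms)

    def residue_keys(self) -> list[str]:
        """Residue keys in order of first appearance."""
        seen: list[str] = []
        for atom in self.atoms:
            key = atom.residue_key
            if not seen or seen[-1] != key:
                if key not in seen:
                    seen.append(key)
        return seen

    def residues(self) -> dict[str, list[ReceptorAtom]]:
        grouped: dict[str, list[ReceptorAtom]] = {}
        for atom in self.atoms:
            grouped.setdefault(atom.residue_key, []).append(atom)
        return grouped


def read_receptor(path: str | Path, chains: Sequence[str] | None = None) -> StructureAtoms:
    """Read a PDB receptor, keeping only ``chains`` (all when None).

    Author residue numbering is preserved verbatim; alternate locations are
    resolved to the highest-occupancy conformer; waters and other hetero
    records are skipped.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("receptor", str(path))
    model = next(structure.get_models())
    available = [c.id for c in model]
    if chains is not None:
        missing = [c for c in chains if c not in available]
        if missing:
            raise ValueError(
                f"chain(s) {missing} not in structure; available: {available}"
            )
    atoms: list[ReceptorAtom] = []
    for chain in model:
        if chains is not None and chain.id not in chains:
            continue
        for residue in chain:
            hetflag, resseq, _icode = residue.id
            if hetflag.strip():
                continue  # waters / heteroatoms
            for atom in residue:
                if atom.is_disordered():
                    atom = max(atom.disordered_get_list(),
                               key=lambda a: a.get_occupancy() or 0.0)
                atoms.append(
                    ReceptorAtom(
                        name=atom.get_name(),
                        element=(atom.element or "").strip().upper(),
                        resname=residue.get_resname().strip(),
                        resseq=int(resseq),
                        chain=chain.id,
                        coord=np.asarray(atom.get_coord(), dtype=float),
                        serial=atom.get_serial_number() or 0,
                    )
                )
    return StructureAtoms(atoms, source=str(path))


# ---------------------------------------------------------------------------
# ligand typing


@dataclass
class LigandTypes:
    """Typed atom indices / groups of a ligand pose."""

    coords: np.ndarray
    donors: list[tuple[int, list[int]]]  # heavy donor idx, attached H indices
    acceptors: list[int]
    apolar: list[int]
    rings: list[list[int]]  # aromatic rings (atom indices)
    cations: list[int]
    anions: list[int]


def type_ligand(mol: Chem.Mol) -> LigandTypes:
    """Type a ligand pose from its RDKit connection table.

    Donors: N/O/S with at least one hydrogen (explicit H coordinates are used
    for the angle criterion when available).  Acceptors: O, and N that is
    neither positively charged nor an amide/aromatic-NH nitrogen.  Apolar
    carbons: only C/H/S neighbours.  Rings: fully aromatic SSSR rings.
    Charged groups: atoms with non-zero formal charge.
    """
    if mol.GetNumConformers() == 0:
        raise ValueError("ligand pose has no 3D coordinates")
    coords = mol.GetConformer().GetPositions()
    donors: list[tuple[int, list[int]]] = []
    acceptors: list[int] = []
    apolar: list[int] = []
    cations: list[int] = []
    anions: list[int] = []
    for atom in mol.GetAtoms():
        idx = atom.GetIdx()
        sym = atom.GetSymbol()
        charge = atom.GetFormalCharge()
        if charge > 0:
            cations.append(idx)
        elif charge < 0:
            anions.append(idx)
        if sym == "H":
            continue
        neighbors = list(atom.GetNeighbors())
        if sym in ("N", "O", "S") and atom.GetTotalNumHs(includeNeighbors=True) > 0:
            h_idx = [n.GetIdx() for n in neighbors if n.GetSymbol() == "H"]
            donors.append((idx, h_idx))
        if sym == "O":
            acceptors.append(idx)
        elif sym == "N" and charge <= 0:
            amide = any(
                n.GetSymbol() == "C"
                and any(b.GetBondTypeAsDouble() == 2.0
                        and b.GetOtherAtom(n).GetSymbol() == "O"
                        for b in n.GetBonds())
                for n in neighbors
            )
            if not amide and not atom.GetIsAromatic():
                acceptors.append(idx)
        elif sym == "C":
            if all(n.GetSymbol() in ("C", "H", "S") for n in neighbors):
                apolar.append(idx)
    rings = []
    ring_info = mol.GetRingInfo()
    for ring in ring_info.AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            rings.append(list(ring))
    return LigandTypes(
        coords=coords, donors=donors, acceptors=acceptors, apolar=apolar,
        rings=rings, cations=cations, anions=anions,
    )


# ---------------------------------------------------------------------------
# fingerprints


class FingerprintSpace:
    """Frozen ordered universe of (residue key x interaction type) columns."""

    def __init__(self, residue_keys: Sequence[str]):
        self.residue_keys = list(residue_keys)
        self.columns = [
            (res, t) for res in self.residue_keys for t in INTERACTION_TYPES
        ]
        self._index = {col: i for i, col in enumerate(self.columns)}

    def __len__(self) -> int:
        return len(self.columns)

    def index(self, residue_key: str, itype: str) -> int:
        return self._index[(residue_key, itype)]

    def column_labels(self) -> list[str]:
        return [f"{res}:{t}" for res, t in self.columns]


class InteractionFingerprint:
    """Per-residue, per-type interaction counts (and presence bits)."""

    def __init__(self, space: FingerprintSpace,
                 counts: dict[tuple[str, str], int] | None = None,
                 ligand_id: str = ""):
        self.space = space
        self.ligand_id = ligand_id
        self.counts = {k: int(v) for k, v in (counts or {}).items() if v}

    def count_vector(self) -> np.ndarray:
        vec = np.zeros(len(self.space), dtype=np.int64)
        for key, v in self.counts.items():
            vec[self.space.index(*key)] = v
        return vec

    def bit_vector(self) -> np.ndarray:
        return (self.count_vector() > 0).astype(np.int8)

    @property
    def bits(self) -> set[tuple[str, str]]:
        return set(self.counts)

    def __repr__(self) -> str:  # pragma: no cover
        return f"InteractionFingerprint({self.ligand_id!r}, {sorted(self.counts)})"


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _ring_geometry(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of a ring given its atom coordinates."""
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _u, _s, vh = np.linalg.svd(centered)
    return centroid, vh[2]


def _receptor_typing(residue_atoms: list[ReceptorAtom]):
    """Classify one residue's atoms into donor/acceptor/apolar/ring/charge sets."""
    resname = residue_atoms[0].resname
    by_name = {a.name: a for a in residue_atoms}
    donors = []
    if resname != "PRO" and _BACKBONE_DONOR in by_name:
        donors.append(by_name[_BACKBONE_DONOR])
    donors += [by_name[n] for n in _SIDECHAIN_DONORS.get(resname, ()) if n in by_name]
    acceptors = [by_name[n] for n in _BACKBONE_ACCEPTORS if n in by_name]
    acceptors += [by_name[n] for n in _SIDECHAIN_ACCEPTORS.get(resname, ())
                  if n in by_name]
    apolar = [by_name[n] for n in _APOLAR_CARBONS.get(resname, ()) if n in by_name]
    rings = []
    for ring_names in _AROMATIC_RINGS.get(resname, ()):
        if all(n in by_name for n in ring_names):
            rings.append(np.array([by_name[n].coord for n in ring_names]))
    positive = [by_name[n] for n in _POSITIVE_ATOMS.get(resname, ()) if n in by_name]
    negative = [by_name[n] for n in _NEGATIVE_ATOMS.get(resname, ()) if n in by_name]
    return donors, acceptors, apolar, rings, positive, negative


def detect_interactions(
    receptor: StructureAtoms,
    pose: Chem.Mol,
    criteria: GeometricCriteria | None = None,
    space: FingerprintSpace | None = None,
    max_pose_distance: float = 15.0,
) -> InteractionFingerprint:
    """Detect all interactions between ``receptor`` and one ligand ``pose``.

    Evaluation is exhaustive over atom pairs within the cutoffs (a k-d tree
    prunes the receptor-side search; the result is identical to an all-pairs
    scan).  Returns an :class:`InteractionFingerprint` over ``space`` (by
    default, all receptor residues).  Raises when no pose atom lies within
    ``max_pose_distance`` of the receptor.
    """
    criteria = criteria or GeometricCriteria()
    lig = type_ligand(pose)
    tree = cKDTree(receptor.coords)
    dmin = min(tree.query(lig.coords[i])[0] for i in range(len(lig.coords)))
    if dmin > max_pose_distance:
        raise ValueError(
            f"pose is {dmin:.1f} A from the receptor "
            f"(limit {max_pose_distance} A); not a docked pose"
        )
    if space is None:
        space = FingerprintSpace(receptor.residue_keys())
    counts: dict[tuple[str, str], int] = {}

    def hit(residue_key: str, itype: str) -> None:
        if residue_key in space.residue_keys:
            counts[(residue_key, itype)] = counts.get((residue_key, itype), 0) + 1

    ligand_id = pose.GetProp("_Name") if pose.HasProp("_Name") else ""

    for residue_key, residue_atoms in receptor.residues().items():
        donors, acceptors, apolar, rings, positive, negative = _receptor_typing(
            residue_atoms
        )
        # receptor donor -> ligand acceptor (heavy-atom rule; receptor H rarely present)
        for don in donors:
            for ai in lig.acceptors:
                if np.linalg.norm(don.coord - lig.coords[ai]) <= criteria.hbond_max_dist:
                    hit(residue_key, "hbond_donor_to_ligand")
        # ligand donor -> receptor acceptor, with D-H...A angle when H explicit
        for acc in acceptors:
            for di, h_idx in lig.donors:
                if np.linalg.norm(lig.coords[di] - acc.coord) > criteria.hbond_max_dist:
                    continue
                if h_idx:
                    ok = any(
                        _angle(lig.coords[di], lig.coords[h], acc.coord)
                        >= criteria.hbond_min_angle
                        for h in h_idx
                    )
                else:
                    ok = True
                if ok:
                    hit(residue_key, "hbond_acceptor_from_ligand")
        for apo in apolar:
            for ci in lig.apolar:
                if (np.linalg.norm(apo.coord - lig.coords[ci])
                        <= criteria.hydrophobic_max_dist):
                    hit(residue_key, "hydrophobic")
        for ring_coords in rings:
            centroid, normal = _ring_geometry(ring_coords)
            for lring in lig.rings:
                lcent, lnorm = _ring_geometry(lig.coords[lring])
                if np.linalg.norm(centroid - lcent) > criteria.pipi_max_centroid_dist:
                    continue
                angle = np.degrees(
                    np.arccos(np.clip(abs(np.dot(normal, lnorm)), -1.0, 1.0))
                )
                lo, hi = criteria.pipi_tshape_angle_range
                if angle <= criteria.pipi_max_parallel_angle or lo <= angle <= hi:
                    hit(residue_key, "pi_pi")
            for ci in lig.cations:
                if np.linalg.norm(centroid - lig.coords[ci]) <= criteria.cation_pi_max_dist:
                    hit(residue_key, "cation_pi")
        # receptor cation vs ligand aromatic ring
        for pos in positive:
            for lring in lig.rings:
                lcent, _ = _ring_geometry(lig.coords[lring])
                if np.linalg.norm(pos.coord - lcent) <= criteria.cation_pi_max_dist:
                    hit(residue_key, "cation_pi")
        for pos in positive:
            for ai in lig.anions:
                if (np.linalg.norm(pos.coord - lig.coords[ai])
                        <= criteria.salt_bridge_max_dist):
                    hit(residue_key, "salt_bridge")
        for neg in negative:
            for ci in lig.cations:
                if (np.linalg.norm(neg.coord - lig.coords[ci])
                        <= criteria.salt_bridge_max_dist):
                    hit(residue_key, "salt_bridge")
    return InteractionFingerprint(space, counts, ligand_id=ligand_id)


class InteractionFingerprinter(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: docked poses -> interaction-bit matrix.

    ``fit`` freezes the residue universe — all receptor residues with any atom
    within ``contact_radius`` of any pose atom across the fitted pose set — so
    that every transformed fingerprint shares one column space.

    Parameters
    ----------
    receptor:
        :class:`StructureAtoms` for the receptor.
    criteria:
        :class:`GeometricCriteria`; defaults are standard literature cutoffs.
    contact_radius:
        Universe-freezing radius in Angstrom (default 8).
    """

    def __init__(self, receptor: StructureAtoms | None = None,
                 criteria: GeometricCriteria | None = None,
                 contact_radius: float = 8.0):
        self.receptor = receptor
        self.criteria = criteria
        self.contact_radius = contact_radius

    def fit(self, X: Iterable[Chem.Mol], y=None) -> "InteractionFingerprinter":
        if self.receptor is None:
            raise ValueError("receptor is required")
        tree = cKDTree(self.receptor.coords)
        near: set[int] = set()
        for pose in X:
            coords = pose.GetConformer().GetPositions()
            for idx_list in tree.query_ball_point(coords, self.contact_radius):
                near.update(idx_list)
        keys_in_order = self.receptor.residue_keys()
        touched = {self.receptor.atoms[i].residue_key for i in near}
        self.residues_ = [k for k in keys_in_order if k in touched]
        if not self.residues_:
            warnings.warn("no receptor residue within contact radius of any pose",
                          stacklevel=2)
        self.space_ = FingerprintSpace(self.residues_)
        self.criteria_ = self.criteria or GeometricCriteria()
        return self

    def transform(self, X: Iterable[Chem.Mol]) -> list[InteractionFingerprint]:
        if not hasattr(self, "space_"):
            raise ValueError("fit must be called before transform")
        return [
            detect_interactions(self.receptor, pose, criteria=self.criteria_,
                                space=self.space_)
            for pose in X
        ]

    def to_matrix(self, fingerprints: Sequence[InteractionFingerprint]) -> pd.DataFrame:
        """Bit matrix: rows = ligands, columns = residue:type."""
        data = np.stack([fp.bit_vector() for fp in fingerprints])
        return pd.DataFrame(
            data,
            index=[fp.ligand_id for fp in fingerprints],
            columns=self.space_.column_labels(),
        )


def residue_interaction_frequency(
    fingerprints: Sequence[InteractionFingerprint],
) -> pd.DataFrame:
    """Fraction of ligands showing each residue x type interaction.

    Rows are receptor residues, columns the six interaction types; values in
    [0, 1].  All fingerprints must share one space.
    """
    if not fingerprints:
        raise ValueError("empty fingerprint list")
    space = fingerprints[0].space
    if any(fp.space is not space and fp.space.columns != space.columns
           for fp in fingerprints):
        raise ValueError("fingerprints do not share one space")
    bits = np.stack([fp.bit_vector() for fp in fingerprints])
    frac = bits.mean(axis=0)
    table = pd.DataFrame(
        frac.reshape(len(space.residue_keys), len(INTERACTION_TYPES)),
        index=space.residue_keys,
        columns=list(INTERACTION_TYPES),
    )
    return table
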