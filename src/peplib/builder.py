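"""Peptide sequence -> molecule conversion, ionization and 3D embedding.

Sequences are built as all-L free peptides (free N-terminal amine, free
C-terminal carboxylic acid).  Ionization applies the dominant-microstate rules
at pH 7.4: N-terminus and Lys/Arg side chains protonated (+1), C-terminus and
Asp/Glu side chains deprotonated (-1), His/Cys/Tyr/Ser/Thr left neutral.
Conformers are generated with RDKit's ETKDG distance-geometry embedding
followed by an MMFF94 relaxation; the rotamer-library side-chain optimization
used by the original docking study is deliberately not reproduced.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .errors import EmbeddingError, ParseError
from .library import validate_sequence

# dominant-microstate ionization rules at physiological pH, as SMARTS
_CARBOXYLIC_ACID = Chem.MolFromSmarts("[CX3](=O)[OX2H1]")
_PRIMARY_AMINE = Chem.MolFromSmarts("[NX3H2;!$(NC=[O,N,S])][CX4]")
# N-terminal proline: the only secondary non-amide amine in canonical peptides
_SECONDARY_AMINE = Chem.MolFromSmarts("[NX3H1;R;!$(NC=[O,N,S])][CX4]")
_GUANIDINE_NH = Chem.MolFromSmarts("[NX3][CX3](=[NX2H1])[NX3]")


@dataclass
class PeptideMolecule:
    """A peptide sequence with neutral and (optionally) ionized connection tables."""

    sequence: str
    mol: Chem.Mol
    smiles_neutral: str
    mol_ionized: Chem.Mol | None = None
    smiles_ionized: str | None = None
    ph: float | None = None

    @property
    def formula(self) -> str:
        return Chem.rdMolDescriptors.CalcMolFormula(self.mol)

    @property
    def net_formal_charge(self) -> int:
        if self.mol_ionized is None:
            return Chem.GetFormalCharge(self.mol)
        return Chem.GetFormalCharge(self.mol_ionized)


def sequence_to_molecule(sequence: str) -> PeptideMolecule:
    """Build the neutral free-acid/free-amine all-L peptide for ``sequence``."""
    validate_sequence(sequence)
    mol = Chem.MolFromSequence(sequence)
    if mol is None:  # pragma: no cover - validate_sequence screens all bad input
        raise ValueError(f"could not build a molecule from sequence {sequence!r}")
    mol.SetProp("_Name", sequence)
    return PeptideMolecule(
        sequence=sequence, mol=mol, smiles_neutral=Chem.MolToSmiles(mol)
    )


def ionize(peptide: PeptideMolecule, ph: float = 7.4) -> PeptideMolecule:
    """Apply rule-based ionization at ``ph`` and return an updated record.

    Rules (dominant microstates near physiological pH): every carboxylic acid
    (C-terminus, Asp, Glu) is deprotonated; every non-amide primary amine
    (N-terminus, Lys) is protonated; Arg guanidine is protonated on the imine
    nitrogen.  His (pKa ~6), Cys, Tyr, Ser and Thr stay neutral.  The rules are
    pH-independent within ~5-9; ``ph`` outside [0, 14] is rejected.
    """
    if not 0.0 <= ph <= 14.0:
        raise ValueError(f"pH must be within [0, 14], got {ph}")
    mol = Chem.RWMol(peptide.mol)
    for (_c, _o_dbl, o_h) in mol.GetSubstructMatches(_CARBOXYLIC_ACID):
        atom = mol.GetAtomWithIdx(o_h)
        atom.SetFormalCharge(-1)
        atom.SetNumExplicitHs(0)
        atom.SetNoImplicit(True)
    for (n, _c) in mol.GetSubstructMatches(_PRIMARY_AMINE):
        atom = mol.GetAtomWithIdx(n)
        atom.SetFormalCharge(+1)
        atom.SetNumExplicitHs(3)
        atom.SetNoImplicit(True)
    for (n, _c) in mol.GetSubstructMatches(_SECONDARY_AMINE):
        atom = mol.GetAtomWithIdx(n)
        atom.SetFormalCharge(+1)
        atom.SetNumExplicitHs(2)
        atom.SetNoImplicit(True)
    for (_n1, _c, n_imine, _n2) in mol.GetSubstructMatches(_GUANIDINE_NH):
        atom = mol.GetAtomWithIdx(n_imine)
        atom.SetFormalCharge(+1)
        atom.SetNumExplicitHs(2)
        atom.SetNoImplicit(True)
    ionized = mol.GetMol()
    Chem.SanitizeMol(ionized)
    ionized.SetProp("_Name", peptide.sequence)
    return PeptideMolecule(
        sequence=peptide.sequence,
        mol=peptide.mol,
        smiles_neutral=peptide.smiles_neutral,
        mol_ionized=ionized,
        smiles_ionized=Chem.MolToSmiles(ionized),
        ph=ph,
    )


def embed_conformer(
    peptide: PeptideMolecule | Chem.Mol,
    seed: int = 1,
    ionized: bool = False,
    max_retries: int = 5,
    optimize: bool = True,
) -> Chem.Mol:
    """Embed one low-energy 3D conformer; identical seed -> identical coordinates.

    Returns a new molecule with explicit hydrogens and a single conformer
    (coordinates in Angstrom).  The embedding method is recorded in the
    ``embed_method`` property.  Raises :class:`EmbeddingError` when distance
    geometry fails for ``max_retries`` consecutive seed offsets.
    """
    if isinstance(peptide, PeptideMolecule):
        source = peptide.mol_ionized if ionized and peptide.mol_ionized else peptide.mol
    else:
        source = peptide
    mol = Chem.AddHs(Chem.Mol(source))
    last = -1
    for attempt in range(max_retries):
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed) + attempt
        params.useRandomCoords = attempt > 1
        last = AllChem.EmbedMolecule(mol, params)
        if last == 0:
            break
    if last != 0:
        raise EmbeddingError(
            f"ETKDG embedding failed after {max_retries} attempts "
            f"(seed {seed}, last status {last})"
        )
    if optimize:
        AllChem.MMFFOptimizeMolecule(mol, maxIters=500)
    mol.SetProp("embed_method", "ETKDGv3+MMFF94" if optimize else "ETKDGv3")
    return mol


def check_conformer(mol: Chem.Mol, min_dist: float = 0.7,
                    bond_range: tuple[float, float] = (0.8, 2.0)) -> None:
    """Validate conformer invariants: no atom clash, covalent bond lengths sane."""
    conf = mol.GetConformer()
    coords = conf.GetPositions()
    diffs = coords[:, None, :] - coords[None, :, :]
    dmat = np.sqrt((diffs ** 2).sum(-1))
    np.fill_diagonal(dmat, np.inf)
    if dmat.min() < min_dist:
        raise ValueError(f"atoms closer than {min_dist} A: min {dmat.min():.3f}")
    for bond in mol.GetBonds():
        d = dmat[bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()]
        if not bond_range[0] <= d <= bond_range[1]:
            raise ValueError(
                f"bond {bond.GetBeginAtomIdx()}-{bond.GetEndAtomIdx()} length "
                f"{d:.3f} A outside {bond_range}"
            )


def write_sdf(mols: Iterable[Chem.Mol], path: str | Path) -> int:
    """Write molecules to a V2000 SD file, preserving all tag fields. Returns count."""
    writer = Chem.SDWriter(str(path))
    writer.SetForceV3000(False)
    n = 0
    for mol in mols:
        if mol.GetNumConformers() == 0:
            AllChem.Compute2DCoords(mol)
        writer.write(mol)
        n += 1
    writer.close()
    return n


def read_sdf(path: str | Path, sanitize: bool = True) -> list[Chem.Mol]:
    """Read a V2000 SD file; raises :class:`ParseError` naming the bad record."""
    supplier = Chem.SDMolSupplier(str(path), sanitize=sanitize, removeHs=False)
    mols: list[Chem.Mol] = []
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ParseError("malformed SD block", record_index=i)
        mols.append(mol)
    return mols
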