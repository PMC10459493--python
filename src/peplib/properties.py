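"""Sequence- and molecule-level peptide descriptors and library summaries.

Descriptors mirror the ones used to characterize the combinatorial library:

* net charge at a given pH via the Henderson-Hasselbalch equation over the
  termini and ionizable side chains (D, E, C, Y acidic; H, K, R basic), with
  the pKa table shipped as versioned data and swappable;
* molecular weight as the sum of standard average residue masses plus one
  water (delegated to Biopython);
* Eisenberg hydrophobicity as the arithmetic mean of the normalized consensus
  scale over residues;
* Wildman-Crippen logP on the neutral form (partition coefficients are defined
  for neutral species);
* rotatable bonds under the strict rotor definition: non-ring single bonds
  between non-terminal heavy atoms, excluding amide (and amidine/guanidinium)
  C-N bonds — the definition under which a complete tetrapeptide library
  averages ~14.3 rotors;
* TPSA, H-bond donor/acceptor counts, ring count and heavy-atom count.

``library_mean_additive`` exploits the fact that every descriptor above is
exactly additive in per-position residue contributions, so complete-library
means are computable from 20 x length single-substitution evaluations instead
of ``20**length`` molecules.  The shortcut is validated against brute force in
the test suite.
"""

from __future__ import annotations

import csv
import math
from collections.abc import Callable, Iterable, Iterator
from dataclasses import dataclass, fields
from importlib import resources

import numpy as np
import pandas as pd
from Bio.SeqUtils import molecular_weight as _bio_mw
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski
from rdkit.Chem.rdMolDescriptors import CalcNumRotatableBonds, NumRotatableBondsOptions
from sklearn.base import BaseEstimator, TransformerMixin

from .builder import PeptideMolecule, sequence_to_molecule
from .library import CANONICAL_ALPHABET, validate_sequence

WATER_MASS = 18.0153  # average molecular weight of H2O, g/mol


def _load_table(filename: str) -> pd.DataFrame:
    with resources.files("peplib.data").joinpath(filename).open() as handle:
        return pd.read_csv(handle, comment="#")


def load_pka_table(name: str = "lehninger") -> dict[str, tuple[str, float]]:
    """Load a named pKa table as ``{group: (kind, pKa)}``.

    ``group`` is ``"nterm"``, ``"cterm"`` or a one-letter side-chain code;
    ``kind`` is ``"acidic"`` or ``"basic"``.
    """
    df = _load_table(f"pka_{name}.csv")
    table = {row.group: (row.kind, float(row.pka)) for row in df.itertuples()}
    for group, (kind, pka) in table.items():
        if not 0.0 < pka < 14.0:
            raise ValueError(f"pKa for {group} out of (0, 14): {pka}")
        if kind not in ("acidic", "basic"):
            raise ValueError(f"unknown group kind {kind!r} for {group}")
    return table


def load_eisenberg_scale() -> dict[str, float]:
    """Load the Eisenberg normalized consensus hydrophobicity scale (20 values)."""
    df = _load_table("eisenberg_consensus.csv")
    scale = {row.residue: float(row.hydrophobicity) for row in df.itertuples()}
    if sorted(scale) != sorted(CANONICAL_ALPHABET):
        raise ValueError("Eisenberg scale must cover exactly the 20 canonical residues")
    if abs(sum(scale.values()) / 20.0) > 0.005:
        raise ValueError("Eisenberg consensus scale must have zero mean")
    return scale


_DEFAULT_PKA = load_pka_table()
_DEFAULT_SCALE = load_eisenberg_scale()


def net_charge(
    sequence: str,
    ph: float = 7.0,
    table: dict[str, tuple[str, float]] | None = None,
) -> float:
    """Henderson-Hasselbalch net charge of the free peptide at ``ph``.

    Sum over the N-terminus, C-terminus and every ionizable side chain of
    ``+1/(1+10**(pH-pKa))`` for basic groups and ``-1/(1+10**(pKa-pH))`` for
    acidic groups.
    """
    validate_sequence(sequence)
    if not 0.0 <= ph <= 14.0:
        raise ValueError(f"pH must be within [0, 14], got {ph}")
    table = table if table is not None else _DEFAULT_PKA
    groups = ["nterm", "cterm"] + [ch for ch in sequence if ch in table]
    charge = 0.0
    for group in groups:
        kind, pka = table[group]
        if kind == "basic":
            charge += 1.0 / (1.0 + 10.0 ** (ph - pka))
        else:
            charge -= 1.0 / (1.0 + 10.0 ** (pka - ph))
    return charge


def peptide_molecular_weight(sequence: str) -> float:
    """Average molecular weight (g/mol): sum of residue masses plus one water."""
    validate_sequence(sequence)
    return float(_bio_mw(sequence, seq_type="protein"))


def eisenberg_hydrophobicity(
    sequence: str, scale: dict[str, float] | None = None
) -> float:
    """Mean Eisenberg consensus hydrophobicity over residues."""
    validate_sequence(sequence)
    scale = scale if scale is not None else _DEFAULT_SCALE
    return sum(scale[ch] for ch in sequence) / len(sequence)


def _as_mol(molecule: PeptideMolecule | Chem.Mol | str) -> Chem.Mol:
    if isinstance(molecule, PeptideMolecule):
        return molecule.mol
    if isinstance(molecule, str):
        return sequence_to_molecule(molecule).mol
    return molecule


def crippen_logp(molecule: PeptideMolecule | Chem.Mol | str) -> float:
    """Wildman-Crippen atom-contribution logP of the neutral form."""
    return float(Crippen.MolLogP(_as_mol(molecule)))


def rotatable_bonds(molecule: PeptideMolecule | Chem.Mol | str) -> int:
    """Strict rotatable-bond count (amide/amidine C-N and terminal bonds excluded)."""
    return int(
        CalcNumRotatableBonds(_as_mol(molecule), NumRotatableBondsOptions.Strict)
    )


@dataclass
class PropertyRecord:
    """One peptide's descriptor panel."""

    id: str
    sequence: str
    net_charge: float
    molecular_weight: float
    crippen_logp: float
    eisenberg_hydrophobicity: float
    rotatable_bonds: int
    tpsa: float
    hbd: int
    hba: int
    rings: int
    heavy_atoms: int


NUMERIC_DESCRIPTORS = [f.name for f in fields(PropertyRecord)][2:]


def descriptor_panel(
    molecule: PeptideMolecule | str,
    ph: float = 7.0,
    pka_table: dict[str, tuple[str, float]] | None = None,
    scale: dict[str, float] | None = None,
) -> PropertyRecord:
    """Compute the full descriptor panel for one peptide (neutral form)."""
    if isinstance(molecule, str):
        molecule = sequence_to_molecule(molecule)
    seq, mol = molecule.sequence, molecule.mol
    return PropertyRecord(
        id=seq,
        sequence=seq,
        net_charge=net_charge(seq, ph=ph, table=pka_table),
        molecular_weight=peptide_molecular_weight(seq),
        crippen_logp=crippen_logp(mol),
        eisenberg_hydrophobicity=eisenberg_hydrophobicity(seq, scale=scale),
        rotatable_bonds=rotatable_bonds(mol),
        tpsa=float(Descriptors.TPSA(mol)),
        hbd=int(Lipinski.NumHDonors(mol)),
        hba=int(Lipinski.NumHAcceptors(mol)),
        rings=int(Descriptors.RingCount(mol)),
        heavy_atoms=int(mol.GetNumHeavyAtoms()),
    )


class PeptideDescriptors(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer mapping peptide sequences to a descriptor table.

    ``transform`` accepts an iterable of sequences and returns a
    :class:`pandas.DataFrame` with one row per peptide and the
    :class:`PropertyRecord` columns.  Stateless: ``fit`` only validates
    parameters.

    Parameters
    ----------
    ph:
        pH for the Henderson-Hasselbalch net charge (descriptor profiling uses
        pH 7 by convention; ionization for docking uses 7.4).
    pka_table:
        Name of a shipped pKa table (``"lehninger"``).
    """

    def __init__(self, ph: float = 7.0, pka_table: str = "lehninger"):
        self.ph = ph
        self.pka_table = pka_table

    def fit(self, X: Iterable[str], y=None) -> "PeptideDescriptors":
        if not 0.0 <= self.ph <= 14.0:
            raise ValueError(f"pH must be within [0, 14], got {self.ph}")
        self.pka_table_ = load_pka_table(self.pka_table)
        self.scale_ = load_eisenberg_scale()
        return self

    def transform(self, X: Iterable[str]) -> pd.DataFrame:
        if not hasattr(self, "pka_table_"):
            self.fit(X)
        records = [
            descriptor_panel(seq, ph=self.ph, pka_table=self.pka_table_,
                             scale=self.scale_)
            for seq in X
        ]
        return pd.DataFrame([vars(r) for r in records])


def iter_descriptor_records(
    sequences: Iterable[str], ph: float = 7.0
) -> Iterator[PropertyRecord]:
    """Stream descriptor panels over a sequence iterable (constant memory)."""
    for seq in sequences:
        yield descriptor_panel(seq, ph=ph)


def write_property_csv(records: Iterable[PropertyRecord], path) -> int:
    """Stream PropertyRecords to CSV; returns the number of rows."""
    names = [f.name for f in fields(PropertyRecord)]
    n = 0
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(names)
        for rec in records:
            writer.writerow([getattr(rec, name) for name in names])
            n += 1
    return n


# ---------------------------------------------------------------------------
# library-level summaries


DEFAULT_BIN_EDGES: dict[str, np.ndarray] = {
    "net_charge": np.linspace(-4.5, 4.5, 37),
    "molecular_weight": np.linspace(200.0, 800.0, 61),
    "crippen_logp": np.linspace(-8.0, 4.0, 49),
    "eisenberg_hydrophobicity": np.linspace(-2.6, 1.6, 43),
    "rotatable_bonds": np.arange(2.5, 25.5, 1.0),
    "tpsa": np.linspace(100.0, 500.0, 41),
    "hbd": np.arange(-0.5, 20.5, 1.0),
    "hba": np.arange(-0.5, 20.5, 1.0),
    "rings": np.arange(-0.5, 9.5, 1.0),
    "heavy_atoms": np.arange(15.5, 65.5, 1.0),
}


class _Welford:
    """One-pass streaming mean and (sample) standard deviation."""

    def __init__(self):
        self.n = 0
        self.mean = 0.0
        self.m2 = 0.0

    def add(self, x: float) -> None:
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        self.m2 += delta * (x - self.mean)

    @property
    def sd(self) -> float:
        return math.sqrt(self.m2 / (self.n - 1)) if self.n > 1 else 0.0


def library_profile(
    records: Iterable[PropertyRecord],
    bin_edges: dict[str, np.ndarray] | None = None,
) -> dict:
    """One-pass streaming summary (mean, sd, histogram) per descriptor.

    Bin edges are configurable and recorded in the output.  Values outside the
    configured range are clipped into the edge bins so counts always sum to n.
    """
    edges = dict(DEFAULT_BIN_EDGES)
    if bin_edges:
        edges.update({k: np.asarray(v, dtype=float) for k, v in bin_edges.items()})
    stats = {name: _Welford() for name in NUMERIC_DESCRIPTORS}
    counts = {name: np.zeros(len(edges[name]) - 1, dtype=np.int64)
              for name in NUMERIC_DESCRIPTORS}
    n = 0
    for rec in records:
        n += 1
        for name in NUMERIC_DESCRIPTORS:
            x = float(getattr(rec, name))
            stats[name].add(x)
            e = edges[name]
            idx = int(np.clip(np.searchsorted(e, x, side="right") - 1, 0, len(e) - 2))
            counts[name][idx] += 1
    if n == 0:
        raise ValueError("empty record stream")
    return {
        "n": n,
        "descriptors": {
            name: {
                "mean": stats[name].mean,
                "sd": stats[name].sd,
                "bin_edges": edges[name].tolist(),
                "counts": counts[name].tolist(),
            }
            for name in NUMERIC_DESCRIPTORS
        },
    }


def library_mean_additive(
    descriptor: Callable[[str], float],
    alphabet: str = CANONICAL_ALPHABET,
    length: int = 4,
    base_letter: str = "G",
) -> float:
    """Exact complete-library mean of a positionally additive descriptor.

    For a descriptor ``d`` satisfying ``d(s) = c0 + sum_p c_p(s_p)`` the mean
    over the complete combinatorial library equals the base value plus the mean
    single-substitution shift at each position — ``1 + length*|alphabet|``
    evaluations instead of ``|alphabet|**length``.  All descriptors in this
    module are additive in this sense (validated against brute force in tests).
    """
    base_seq = base_letter * length
    base = descriptor(base_seq)
    total = base
    for p in range(length):
        shift = 0.0
        for letter in alphabet:
            s = base_seq[:p] + letter + base_seq[p + 1:]
            shift += descriptor(s) - base
        total += shift / len(alphabet)
    return total
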