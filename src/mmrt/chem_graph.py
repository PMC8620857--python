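"""Heavy-atom molecular graphs featurized for retention-time modeling.

A molecule is represented as a graph whose nodes are the heavy (non-hydrogen)
atoms and whose edges are the covalent bonds between them.  Each atom carries a
fixed-length feature vector (element one-hot, degree, valence, formal charge,
radical electrons, hybridization, aromaticity) and each bond a short feature
vector (bond-type one-hot, conjugation, ring membership).  Hydrogens never
appear as nodes; they influence the representation only through the valence and
degree blocks.

The "ghost atom" operation zeroes a single atom's feature vector while leaving
the connectivity untouched.  Running the model on the ghosted graph and
subtracting from the unghosted prediction yields that atom's contribution to
the predicted retention time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from rdkit import Chem

__all__ = [
    "MoleculeGraph",
    "FEATURE_LAYOUT_VERSION",
    "ATOM_FEATURE_DIM",
    "BOND_FEATURE_DIM",
    "parse_smiles",
    "ghost_atom",
    "SmilesParseError",
    "MultiFragmentError",
]

# Bump whenever the block layout below changes; serialized models store it and
# refuse to run on graphs featurized differently.
FEATURE_LAYOUT_VERSION = "mmrt-feat-1"

_ELEMENTS = ["C", "N", "O", "P", "S", "F", "Cl", "Br", "I"]  # + "other" slot
_DEGREES = list(range(6))  # 0..5
_VALENCES = list(range(7))  # 0..6
_HYBRIDIZATIONS = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
]  # + "other" slot
_BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]

ATOM_FEATURE_DIM = (len(_ELEMENTS) + 1) + len(_DEGREES) + len(_VALENCES) + 1 + 1 + (len(_HYBRIDIZATIONS) + 1) + 1
BOND_FEATURE_DIM = len(_BOND_TYPES) + 2


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


class MultiFragmentError(ValueError):
    """Raised for multi-fragment (e.g. salt) SMILES unless salts are stripped."""


@dataclass(frozen=True, eq=False)
class MoleculeGraph:
    """Featurized heavy-atom connectivity graph.

    Attributes
    ----------
    atom_features : (n_atoms, ATOM_FEATURE_DIM) float array
    bonds : list of (i, j) with i < j, 0-based atom indices
    bond_features : (n_bonds, BOND_FEATURE_DIM) float array
    smiles_canonical : canonical SMILES (stereochemistry retained for
        bookkeeping; the feature vectors themselves are achiral)
    ring_bond : boolean array, True where the bond lies in a ring
    mol : the underlying RDKit molecule; its atom indices coincide with the
        graph's atom indices (used for substructure work downstream)
    """

    atom_features: np.ndarray
    bonds: tuple[tuple[int, int], ...]
    bond_features: np.ndarray
    smiles_canonical: str
    ring_bond: np.ndarray
    mol: Chem.Mol
    name: str | None = None

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def neighbors(self, i: int) -> list[tuple[int, int]]:
        """(neighbor index, bond index) pairs for atom ``i``."""
        out = []
        for b, (a, c) in enumerate(self.bonds):
            if a == i:
                out.append((c, b))
            elif c == i:
                out.append((a, b))
        return out


def _one_hot(value, choices, other: bool) -> list[float]:
    vec = [0.0] * (len(choices) + (1 if other else 0))
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        if other:
            vec[-1] = 1.0
        else:
            # clip into range: degree/valence beyond vocabulary maps to the top bin
            vec[-1] = 1.0
    return vec


def _atom_vector(atom: Chem.Atom) -> list[float]:
    v: list[float] = []
    v += _one_hot(atom.GetSymbol(), _ELEMENTS, other=True)
    v += _one_hot(atom.GetDegree(), _DEGREES, other=False)
    v += _one_hot(atom.GetTotalValence(), _VALENCES, other=False)
    v.append(float(np.clip(atom.GetFormalCharge(), -2, 2)))
    v.append(float(atom.GetNumRadicalElectrons()))
    v += _one_hot(atom.GetHybridization(), _HYBRIDIZATIONS, other=True)
    v.append(1.0 if atom.GetIsAromatic() else 0.0)
    return v


def _bond_vector(bond: Chem.Bond) -> list[float]:
    v = _one_hot(bond.GetBondType(), _BOND_TYPES, other=False)
    v.append(1.0 if bond.GetIsConjugated() else 0.0)
    v.append(1.0 if bond.IsInRing() else 0.0)
    return v


def parse_smiles(smiles: str, name: str | None = None, strip_salts: bool = False) -> MoleculeGraph:
    """Parse a SMILES string into a featurized heavy-atom graph.

    Parameters
    ----------
    smiles : SMILES string describing a single covalent unit.
    strip_salts : if True, multi-fragment inputs keep only the largest
        fragment (by heavy-atom count); otherwise they are rejected.

    Raises
    ------
    SmilesParseError : invalid SMILES.
    MultiFragmentError : multi-fragment SMILES with ``strip_salts=False``.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"could not parse SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) > 1:
        if not strip_salts:
            raise MultiFragmentError(
                f"SMILES {smiles!r} contains {len(frags)} fragments; "
                "pass strip_salts=True (--strip-salts) to keep the largest"
            )
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    if mol.GetNumHeavyAtoms() == 0:
        raise SmilesParseError(f"SMILES {smiles!r} has no heavy atoms")

    atom_features = np.array([_atom_vector(a) for a in mol.GetAtoms()], dtype=np.float64)
    bonds: list[tuple[int, int]] = []
    bond_rows: list[list[float]] = []
    ring_flags: list[bool] = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i > j:
            i, j = j, i
        bonds.append((i, j))
        bond_rows.append(_bond_vector(bond))
        ring_flags.append(bond.IsInRing())
    order = np.argsort([i * mol.GetNumAtoms() + j for i, j in bonds]) if bonds else []
    bonds = [bonds[k] for k in order]
    bond_features = (
        np.array([bond_rows[k] for k in order], dtype=np.float64)
        if bonds
        else np.zeros((0, BOND_FEATURE_DIM))
    )
    ring_bond = np.array([ring_flags[k] for k in order], dtype=bool) if bonds else np.zeros(0, dtype=bool)

    return MoleculeGraph(
        atom_features=atom_features,
        bonds=tuple(bonds),
        bond_features=bond_features,
        smiles_canonical=Chem.MolToSmiles(mol),
        ring_bond=ring_bond,
        mol=mol,
        name=name,
    )


def ghost_atom(graph: MoleculeGraph, i: int) -> MoleculeGraph:
    """Return a copy of ``graph`` with atom ``i``'s feature vector zeroed.

    Bonds and all other atoms are untouched; the ghost atom keeps its place in
    the connectivity but has no properties of its own.
    """
    if not 0 <= i < graph.n_atoms:
        raise IndexError(f"atom index {i} out of range for {graph.n_atoms}-atom graph")
    feats = graph.atom_features.copy()
    feats[i, :] = 0.0
    return replace(graph, atom_features=feats)
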