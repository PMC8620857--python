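"""Descriptor-based reference models the graph network is compared against.

Classical QSRR practice regresses retention time on a short vector of
hand-picked molecular descriptors.  The descriptor set here is a stand-in
assembled from the obvious composition features (the original study's exact
hand-picked list is not published in its main text): atom counts by element
class, ring and aromatic counts, hydrogen-bond donors/acceptors, net formal
charge, and counts of the five functional groups that dominate mixed-mode
retention.
"""

from __future__ import annotations

import warnings

import numpy as np
from rdkit.Chem import Lipinski
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression, Ridge

from .chem_graph import MoleculeGraph
from .groups import GROUP_SMARTS, count_groups

__all__ = ["DESCRIPTOR_NAMES", "compute_descriptors", "fit_baseline", "predict_baseline"]

DESCRIPTOR_NAMES: tuple[str, ...] = (
    "n_heavy_atoms",
    "n_nitrogen",
    "n_oxygen",
    "n_phosphorus",
    "n_sulfur",
    "n_halogen",
    "n_rings",
    "n_aromatic_atoms",
    "n_hbd",
    "n_hba",
    "formal_charge_sum",
    *(f"n_{g}" for g in GROUP_SMARTS),
)

_HALOGENS = {"F", "Cl", "Br", "I"}


def compute_descriptors(graph: MoleculeGraph) -> np.ndarray:
    """Descriptor vector for one molecule, deterministic per canonical SMILES."""
    mol = graph.mol
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    groups = count_groups(mol)
    values = [
        mol.GetNumHeavyAtoms(),
        symbols.count("N"),
        symbols.count("O"),
        symbols.count("P"),
        symbols.count("S"),
        sum(1 for s in symbols if s in _HALOGENS),
        mol.GetRingInfo().NumRings(),
        sum(1 for a in mol.GetAtoms() if a.GetIsAromatic()),
        Lipinski.NumHDonors(mol),
        Lipinski.NumHAcceptors(mol),
        sum(a.GetFormalCharge() for a in mol.GetAtoms()),
        *(groups[g] for g in GROUP_SMARTS),
    ]
    return np.array(values, dtype=float)


def fit_baseline(kind: str, train: list[tuple[MoleculeGraph, float]], seed: int = 0):
    """Fit a descriptor baseline: ``kind`` is "linear" (ordinary least
    squares, ridge fallback if the design matrix is singular) or
    "random_forest" (200 trees, seeded)."""
    if len(train) < 2:
        raise ValueError("need at least 2 training rows")
    X = np.vstack([compute_descriptors(g) for g, _ in train])
    y = np.array([rt for _, rt in train], dtype=float)
    if kind == "linear":
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X]))
        if rank < X.shape[1] + 1:
            warnings.warn("singular design matrix; falling back to ridge regression")
            model = Ridge(alpha=1e-6)
        else:
            model = LinearRegression()
    elif kind == "random_forest":
        model = RandomForestRegressor(n_estimators=200, random_state=seed)
    else:
        raise ValueError(f"unknown baseline kind {kind!r}")
    model.fit(X, y)
    return model


def predict_baseline(model, graphs: list[MoleculeGraph]) -> np.ndarray:
    X = np.vstack([compute_descriptors(g) for g in graphs])
    return model.predict(X)
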