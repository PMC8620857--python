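"""Ghost-atom attribution: what does the trained model think each atom and
functional group contributes to retention time?

The effect of atom *i* is the drop in predicted retention time when that
atom's feature vector is zeroed: ``eps_i = E_T - E_T(i ghosted)``.  A positive
effect means the atom increases retention.  Fragment-level effects sum
``eps_i`` over the atoms of each connected acyclic subgraph of up to five
heavy atoms, then aggregate occurrences of the same canonical fragment across
a dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .chem_graph import MoleculeGraph, ghost_atom
from .groups import GROUP_SMARTS, match_group_atoms
from .mpnn import RTModel, forward

__all__ = [
    "AtomEffect",
    "SubgraphEffect",
    "atom_effects",
    "enumerate_subgraphs",
    "dataset_subgraph_effects",
    "functional_group_effects",
    "render_atom_colormap",
]


@dataclass(frozen=True)
class AtomEffect:
    molecule: str
    atom_index: int
    effect_min: float  # eps_i, minutes


@dataclass(frozen=True)
class SubgraphEffect:
    fragment_smiles: str
    n_occurrences: int
    mean_effect_min: float
    sd_effect_min: float
    total_effects: tuple[float, ...]  # sum of eps_i per occurrence


def atom_effects(model: RTModel, graph: MoleculeGraph) -> list[AtomEffect]:
    """One effect per atom, each from a fresh pair of forward passes."""
    base = forward(model, graph)
    name = graph.name or graph.smiles_canonical
    return [
        AtomEffect(name, i, base - forward(model, ghost_atom(graph, i)))
        for i in range(graph.n_atoms)
    ]


def enumerate_subgraphs(
    graph: MoleculeGraph,
    max_atoms: int = 5,
    ring_rule: str = "exclude-ring-bonds",
) -> list[tuple[frozenset[int], str]]:
    """All connected subgraphs with <= ``max_atoms`` atoms and no ring bonds.

    A subgraph is a set of atom indices; its bonds are all bonds of the
    molecule between those atoms (edge-induced).  Under the default ring rule
    any subgraph containing an in-ring bond is excluded, so within an aromatic
    ring only the single atoms survive.  ``ring_rule="exclude-complete-rings"``
    relaxes this to drop only subgraphs whose induced bonds themselves close a
    cycle.  Uniqueness within the molecule is by atom-index set; the canonical
    fragment SMILES is the cross-dataset grouping key.
    """
    if ring_rule not in ("exclude-ring-bonds", "exclude-complete-rings"):
        raise ValueError(f"unknown ring_rule {ring_rule!r}")
    n = graph.n_atoms
    if ring_rule == "exclude-ring-bonds":
        usable = [b for b, _ in enumerate(graph.bonds) if not graph.ring_bond[b]]
    else:
        usable = list(range(graph.n_bonds))
    adj: list[set[int]] = [set() for _ in range(n)]
    for b in usable:
        i, j = graph.bonds[b]
        adj[i].add(j)
        adj[j].add(i)

    subsets: set[frozenset[int]] = {frozenset([i]) for i in range(n)}
    frontier = list(subsets)
    while frontier:
        nxt = []
        for subset in frontier:
            if len(subset) == max_atoms:
                continue
            reachable = set().union(*(adj[i] for i in subset)) - subset
            for j in reachable:
                grown = subset | {j}
                if grown not in subsets:
                    subsets.add(grown)
                    nxt.append(grown)
        frontier = nxt

    out: list[tuple[frozenset[int], str]] = []
    for subset in subsets:
        induced = [
            b
            for b, (i, j) in enumerate(graph.bonds)
            if i in subset and j in subset
        ]
        if ring_rule == "exclude-ring-bonds" and any(graph.ring_bond[b] for b in induced):
            continue
        if ring_rule == "exclude-complete-rings" and len(induced) >= len(subset):
            continue  # edges >= nodes in a connected subgraph implies a cycle
        out.append((subset, _fragment_key(graph, subset, induced)))
    out.sort(key=lambda t: (len(t[0]), sorted(t[0])))
    return out


def _fragment_key(graph: MoleculeGraph, subset: frozenset[int], induced_bonds: list[int]) -> str:
    rd_bonds = [
        graph.mol.GetBondBetweenAtoms(*graph.bonds[b]).GetIdx() for b in induced_bonds
    ]
    return Chem.MolFragmentToSmiles(
        graph.mol,
        atomsToUse=sorted(subset),
        bondsToUse=rd_bonds or None,
        canonical=True,
        isomericSmiles=False,
    )


def dataset_subgraph_effects(
    model: RTModel,
    dataset: list[MoleculeGraph],
    max_atoms: int = 5,
    min_count: int = 30,
    ring_rule: str = "exclude-ring-bonds",
) -> list[SubgraphEffect]:
    """Fragment effects over a dataset, ranked by mean effect.

    Atom effects are computed once per molecule; every subgraph occurrence is
    assigned the sum of its atoms' effects; occurrences sharing a canonical
    fragment SMILES are pooled (per occurrence, not per molecule).  Fragments
    seen fewer than ``min_count`` times are dropped.  The returned list is
    sorted by mean effect, most positive first.
    """
    pools: dict[str, list[float]] = {}
    for graph in dataset:
        eps = np.array([e.effect_min for e in atom_effects(model, graph)])
        for subset, key in enumerate_subgraphs(graph, max_atoms, ring_rule):
            pools.setdefault(key, []).append(float(eps[sorted(subset)].sum()))
    out = [
        SubgraphEffect(
            fragment_smiles=key,
            n_occurrences=len(vals),
            mean_effect_min=float(np.mean(vals)),
            sd_effect_min=float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            total_effects=tuple(vals),
        )
        for key, vals in pools.items()
        if len(vals) >= min_count
    ]
    out.sort(key=lambda s: -s.mean_effect_min)
    return out


def functional_group_effects(
    model: RTModel, dataset: list[MoleculeGraph]
) -> dict[str, tuple[float, int]]:
    """Mean summed atom effect per functional group occurrence.

    For each group in :data:`mmrt.groups.GROUP_SMARTS`, every substructure
    occurrence contributes the sum of eps_i over its matched atoms; the value
    reported is (mean over occurrences, occurrence count).  Groups never seen
    are omitted.
    """
    pools: dict[str, list[float]] = {name: [] for name in GROUP_SMARTS}
    for graph in dataset:
        eps = np.array([e.effect_min for e in atom_effects(model, graph)])
        for name in GROUP_SMARTS:
            for atoms in match_group_atoms(graph.mol, name):
                pools[name].append(float(eps[sorted(atoms)].sum()))
    return {
        name: (float(np.mean(vals)), len(vals))
        for name, vals in pools.items()
        if vals
    }


def render_atom_colormap(
    graph: MoleculeGraph,
    effects: list[AtomEffect],
    path,
    cmap: str = "bwr",
) -> None:
    """Write a 2D depiction with atoms colored by effect (red = increases RT,
    blue = decreases) and a color bar in minutes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from rdkit.Chem.Draw import rdMolDraw2D

    eps = np.zeros(graph.n_atoms)
    for e in effects:
        eps[e.atom_index] = e.effect_min
    vmax = max(float(np.abs(eps).max()), 1e-9)
    colormap = plt.get_cmap(cmap)
    colors = {
        i: tuple(colormap(0.5 + eps[i] / (2 * vmax))[:3]) for i in range(graph.n_atoms)
    }

    drawer = rdMolDraw2D.MolDraw2DCairo(500, 420)
    mol = Chem.Mol(graph.mol)
    rdMolDraw2D.PrepareAndDrawMolecule(
        drawer,
        mol,
        highlightAtoms=list(range(graph.n_atoms)),
        highlightAtomColors=colors,
        highlightBonds=[],
    )
    drawer.FinishDrawing()
    png = drawer.GetDrawingText()

    import io as _io

    fig, (ax, cax) = plt.subplots(
        1, 2, figsize=(6, 4.2), gridspec_kw={"width_ratios": [12, 1]}
    )
    ax.imshow(plt.imread(_io.BytesIO(png)))
    ax.axis("off")
    sm = plt.cm.ScalarMappable(
        cmap=colormap, norm=matplotlib.colors.Normalize(vmin=-vmax, vmax=vmax)
    )
    fig.colorbar(sm, cax=cax, label="atom effect on RT (min)")
    if graph.name:
        ax.set_title(graph.name)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
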