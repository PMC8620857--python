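"""Synthetic molecule / feature-table / calibration generators.

Real mixed-mode retention times come from a proprietary standards library, so
the package generates its own test universe: random branched alkane scaffolds
(3-10 carbons) decorated with the five functional groups that dominate
mixed-mode retention, with ground-truth retention time linear in the group
counts:

    rt_true = beta0 + sum_g count_g * effect_g,     rt_obs = rt_true + N(0, sigma)

The default effect sizes mirror the magnitudes the attribution workflow is
expected to find on real data: phosphate +15 min and carboxylic acid +4 min
(strong retainers on the anion-exchange-like phase), amide -7 min, amine
-3 min (invented; only the negative sign is documented for amines), hydroxyl
+0.5 min.  Because the truth is exactly additive in group counts, a model
trained on these data has a recoverable answer, and attribution should read
the effects back off the trained network.

The generator emulates composition-driven retention only: no conformational
or intramolecular-hydrogen-bond effects, no isomer-resolving structure
dependence beyond group placement, no chromatographic drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from .annotate import ADDUCTS, theoretical_mz
from .chem_graph import MoleculeGraph, parse_smiles
from .groups import count_groups
from .qc_metrics import CalibrationSeries

__all__ = [
    "SyntheticSpec",
    "DEFAULT_GROUP_EFFECTS",
    "generate_molecules",
    "generate_feature_table",
    "generate_calibration",
    "OracleRTModel",
]

DEFAULT_GROUP_EFFECTS: dict[str, float] = {
    "phosphate": 15.0,
    "carboxylic_acid": 4.0,
    "amide": -7.0,
    "amine": -3.0,
    "hydroxyl": 0.5,
}

# branch SMILES appended to a scaffold carbon, one free valence each
_GROUP_SMILES = {
    "phosphate": "OP(=O)(O)O",
    "carboxylic_acid": "C(=O)O",
    "amide": "C(N)=O",
    "amine": "N",
    "hydroxyl": "O",
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth model and sampling plan for synthetic molecules."""

    group_effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GROUP_EFFECTS))
    intercept_min: float = 8.0
    noise_sd_min: float = 0.5
    n_molecules: int = 300
    min_carbons: int = 3
    max_carbons: int = 10
    max_groups: int = 4
    seed: int = 0
    interaction_pairs: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        if self.noise_sd_min < 0:
            raise ValueError("noise sd must be >= 0")
        if self.n_molecules < 1:
            raise ValueError("need n_molecules >= 1")


def _random_scaffold(rng: np.random.Generator, n_carbons: int) -> list[list[int]]:
    """Random tree over carbons, as child lists per node (node 0 is root)."""
    children: list[list[int]] = [[] for _ in range(n_carbons)]
    degree = [0] * n_carbons
    for i in range(1, n_carbons):
        candidates = [j for j in range(i) if degree[j] < 4]
        parent = int(rng.choice(candidates))
        children[parent].append(i)
        degree[parent] += 1
        degree[i] += 1
    return children


def _place_groups(
    rng: np.random.Generator,
    n_carbons: int,
    children: list[list[int]],
    groups: list[str],
) -> dict[int, list[str]] | None:
    degree = [len(ch) for ch in children]
    for i, ch in enumerate(children):
        for c in ch:
            degree[c] += 1
    free = [4 - d for d in degree]
    placement: dict[int, list[str]] = {}
    for g in groups:
        open_slots = [i for i in range(n_carbons) if free[i] > 0]
        if not open_slots:
            return None
        site = int(rng.choice(open_slots))
        placement.setdefault(site, []).append(g)
        free[site] -= 1
    return placement


def _assemble_smiles(children: list[list[int]], placement: dict[int, list[str]]) -> str:
    def emit(node: int) -> str:
        s = "C"
        for g in placement.get(node, []):
            s += f"({_GROUP_SMILES[g]})"
        for c in children[node]:
            s += f"({emit(c)})"
        return s

    return emit(0)


def generate_molecules(spec: SyntheticSpec = SyntheticSpec()) -> pd.DataFrame:
    """Generate the synthetic molecule table.

    Columns: ``name, smiles, rt_min`` (observed RT) plus the hidden truth
    columns ``rt_true`` and ``n_<group>``.  Deterministic under
    ``spec.seed``; every SMILES round-trips through :func:`parse_smiles`.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    group_names = list(spec.group_effects)
    for k in range(spec.n_molecules):
        for _attempt in range(50):
            n_c = int(rng.integers(spec.min_carbons, spec.max_carbons + 1))
            children = _random_scaffold(rng, n_c)
            n_groups = int(rng.integers(1, spec.max_groups + 1))
            groups = [group_names[i] for i in rng.integers(0, len(group_names), n_groups)]
            placement = _place_groups(rng, n_c, children, groups)
            if placement is None:
                continue
            smiles = _assemble_smiles(children, placement)
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                continue
            counted = count_groups(mol)
            wanted = {g: groups.count(g) for g in group_names}
            if any(counted.get(g, 0) != wanted[g] for g in group_names):
                continue  # decoration produced an unintended pattern overlap
            break
        else:
            raise RuntimeError("could not assemble a valid molecule in 50 attempts")
        rt_true = spec.intercept_min + sum(
            wanted[g] * spec.group_effects[g] for g in group_names
        )
        for (g1, g2), beta in spec.interaction_pairs.items():
            rt_true += beta * wanted.get(g1, 0) * wanted.get(g2, 0)
        rt_obs = rt_true + rng.normal(0.0, spec.noise_sd_min)
        rows.append(
            {
                "name": f"syn{k:04d}",
                "smiles": Chem.MolToSmiles(mol),
                "rt_min": rt_obs,
                "rt_true": rt_true,
                **{f"n_{g}": wanted[g] for g in group_names},
            }
        )
    return pd.DataFrame(rows)


class OracleRTModel:
    """Oracle predictor that returns each molecule's generated retention time.

    Stands in for a trained model in end-to-end annotation tests: it predicts
    by lookup on canonical SMILES, so the true candidate's retention-time
    delta is exactly zero.
    """

    def __init__(self, table: pd.DataFrame, rt_column: str = "rt_min"):
        self._rt = {
            Chem.MolToSmiles(Chem.MolFromSmiles(s)): float(rt)
            for s, rt in zip(table["smiles"], table[rt_column])
        }

    def predict(self, graph: MoleculeGraph) -> float:
        return self._rt[graph.smiles_canonical]

    def predict_many(self, graphs) -> np.ndarray:
        return np.array([self.predict(g) for g in graphs])


def _positional_isomer(
    rng: np.random.Generator,
    smiles: str,
    children: list[list[int]],
    n_carbons: int,
    groups: list[str],
) -> str | None:
    """A different molecule with the same molecular formula (same scaffold
    size, same group multiset, different placement)."""
    for _ in range(30):
        alt_children = _random_scaffold(rng, n_carbons)
        placement = _place_groups(rng, n_carbons, alt_children, groups)
        if placement is None:
            continue
        cand = _assemble_smiles(alt_children, placement)
        mol = Chem.MolFromSmiles(cand)
        if mol is None:
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical != smiles:
            return canonical
    return None


def generate_feature_table(
    n_features: int = 20,
    n_true_hits: int = 10,
    seed: int = 0,
    spec: SyntheticSpec = SyntheticSpec(),
    n_decoys: int = 2,
    ppm_jitter: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emulated untargeted feature table plus matching candidate database.

    Each of the ``n_true_hits`` features is the [M-H]- ion of one database
    molecule, with m/z perturbed by less than 2 ppm and RT equal to that
    molecule's generated RT; the database also carries ``n_decoys`` isomers
    per hit (same formula, different structure and RT).  The remaining
    features are designed to fail the p-value / fold-change / intensity
    filter, so the filtering step keeps exactly the true hits.
    """
    if n_true_hits > n_features:
        raise ValueError("n_true_hits cannot exceed n_features")
    rng = np.random.default_rng(seed)

    mol_spec = SyntheticSpec(**{**spec.__dict__, "seed": seed + 1, "n_molecules": n_true_hits})
    # re-generate with structural bookkeeping for isomer construction
    mols = generate_molecules(mol_spec)
    group_names = list(mol_spec.group_effects)

    db_rows, feat_rows = [], []
    for k, row in mols.iterrows():
        mol = Chem.MolFromSmiles(row.smiles)
        formula = rdMolDescriptors.CalcMolFormula(mol)
        groups = [g for g in group_names for _ in range(int(row[f"n_{g}"]))]
        n_carbons = sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "C") - groups.count(
            "carboxylic_acid"
        ) - groups.count("amide")
        db_rows.append(
            {
                "name": f"true{k:03d}",
                "formula": formula,
                "smiles": row.smiles,
                "rt_min": row.rt_min,
                "is_true": 1,
            }
        )
        for d in range(n_decoys):
            children = _random_scaffold(rng, n_carbons)
            iso = _positional_isomer(rng, row.smiles, children, n_carbons, groups)
            if iso is None:
                continue
            db_rows.append(
                {
                    "name": f"decoy{k:03d}_{d}",
                    "formula": formula,
                    "smiles": iso,
                    "rt_min": row.rt_true + rng.normal(0.0, max(spec.noise_sd_min, 0.25)),
                    "is_true": 0,
                }
            )
        mz = theoretical_mz(formula, ADDUCTS["[M-H]-"])
        mz *= 1.0 + rng.uniform(-ppm_jitter, ppm_jitter) * 1e-6
        feat_rows.append(
            {
                "mz": mz,
                "rt_min": row.rt_min,
                "intensity": 10 ** rng.uniform(6.5, 8.0),
                "p_value": 10 ** rng.uniform(-5, np.log10(0.009)),
                "fold_change": rng.uniform(2.5, 8.0),
                "true_name": f"true{k:03d}",
            }
        )
    for j in range(n_features - n_true_hits):
        fail_mode = j % 3  # 0: dim, 1: insignificant, 2: small fold change
        feat_rows.append(
            {
                "mz": rng.uniform(65.0, 975.0),
                "rt_min": rng.uniform(1.0, 55.0),
                "intensity": 10 ** rng.uniform(4, 5.9) if fail_mode == 0 else 10 ** rng.uniform(6.5, 8.0),
                "p_value": rng.uniform(0.02, 0.5) if fail_mode == 1 else 10 ** rng.uniform(-5, -3),
                "fold_change": rng.uniform(0.5, 1.9) if fail_mode == 2 else rng.uniform(2.5, 8.0),
                "true_name": "",
            }
        )
    return pd.DataFrame(feat_rows), pd.DataFrame(db_rows)


def generate_calibration(
    n_levels: int = 13,
    start_pmole: float = 0.0254,
    fold_step: float = 3.0,
    slope: float = 5.0e4,
    noise_floor: float = 1.0e4,
    rel_noise: float = 0.02,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[list[CalibrationSeries], np.ndarray, float]:
    """Standard-curve replicates in 3-fold amount increments.

    Returns (series per replicate, S:N matrix (levels, replicates), analytic
    LLOD = smallest level with noiseless S:N >= 3).
    """
    if n_levels < 3:
        raise ValueError("need at least 3 levels")
    rng = np.random.default_rng(seed)
    amounts = start_pmole * fold_step ** np.arange(n_levels)
    series = []
    sn = np.zeros((n_levels, n_replicates))
    for r in range(n_replicates):
        noise = rng.normal(0.0, rel_noise, size=n_levels)
        responses = slope * amounts * (1.0 + noise)
        series.append(
            CalibrationSeries(tuple(amounts), tuple(responses), replicate=r)
        )
        sn[:, r] = responses / noise_floor
    analytic = amounts[slope * amounts / noise_floor >= 3.0]
    analytic_llod = float(analytic[0]) if analytic.size else float("inf")
    return series, sn, analytic_llod
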