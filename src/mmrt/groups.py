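"""Functional-group substructure patterns shared across the package.

The five groups below are the ones whose influence on mixed-mode retention the
attribution workflow is asked to rank: phosphate and carboxylic acid (strong
retainers on an anion-exchange-like phase), amide and amine (eluting early),
and hydroxyl (weakly retaining).  Patterns are deliberately conservative:
the hydroxyl pattern excludes acid and phosphate -OH so the groups do not
overlap, and the amine pattern excludes amide nitrogens.
"""

from __future__ import annotations

from rdkit import Chem

__all__ = ["GROUP_SMARTS", "group_patterns", "count_groups", "match_group_atoms"]

GROUP_SMARTS: dict[str, str] = {
    "phosphate": "[OX2]P(=O)([OX2])[OX2]",
    "carboxylic_acid": "[CX3](=O)[OX2H1]",
    "amide": "[NX3][CX3]=[OX1]",
    "amine": "[NX3;H2,H1;!$(N[CX3]=[OX1])]",
    "hydroxyl": "[OX2H;!$([OX2H][CX3]=[OX1]);!$([OX2H]P)]",
}

_COMPILED: dict[str, Chem.Mol] = {}


def group_patterns() -> dict[str, Chem.Mol]:
    if not _COMPILED:
        for name, smarts in GROUP_SMARTS.items():
            _COMPILED[name] = Chem.MolFromSmarts(smarts)
    return _COMPILED


def match_group_atoms(mol: Chem.Mol, group: str) -> list[frozenset[int]]:
    """Atom-index sets of each distinct occurrence of ``group`` in ``mol``."""
    pattern = group_patterns()[group]
    seen: set[frozenset[int]] = set()
    out: list[frozenset[int]] = []
    for match in mol.GetSubstructMatches(pattern):
        key = frozenset(match)
        if key not in seen:
            seen.add(key)
            out.append(key)
    return out


def count_groups(mol: Chem.Mol) -> dict[str, int]:
    return {name: len(match_group_atoms(mol, name)) for name in GROUP_SMARTS}
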