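"""Untargeted-feature annotation: filter, mass-match, rank by predicted RT.

The workflow mirrors how a retention-time model earns its keep in an
untargeted LC-MS study: differential features are filtered on significance,
fold change and intensity; surviving features are matched against a candidate
metabolite database by adduct-corrected ppm mass error (negative mode,
[M-H]- and [M+Cl]- by default, 3 ppm tolerance); and the tied-by-mass
candidates are ranked by how close their predicted retention time falls to
the observed one — rank 1 is the putative identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from pyteomics import mass as _pyteomics_mass

from .chem_graph import parse_smiles

__all__ = [
    "Feature",
    "AdductSpec",
    "CandidateMatch",
    "ADDUCTS",
    "DEFAULT_SCAN_RANGE",
    "filter_features",
    "ppm_error",
    "theoretical_mz",
    "monoisotopic_mass",
    "match_and_rank",
]

logger = logging.getLogger(__name__)

DEFAULT_SCAN_RANGE = (65.0, 975.0)  # m/z window of the acquisition method


@dataclass(frozen=True)
class AdductSpec:
    """Single-charge negative-mode adduct: observed m/z = neutral
    monoisotopic mass + mass_shift.  The electron mass is folded into the
    shift constants."""

    name: str
    mass_shift: float


ADDUCTS: dict[str, AdductSpec] = {
    "[M-H]-": AdductSpec("[M-H]-", -1.007276),
    "[M+Cl]-": AdductSpec("[M+Cl]-", +34.968853),
}


@dataclass(frozen=True)
class Feature:
    """One aligned untargeted LC-MS feature."""

    mz: float
    rt_min: float
    intensity: float
    p_value: float
    fold_change: float

    def in_scan_range(self, scan_range: tuple[float, float] = DEFAULT_SCAN_RANGE) -> bool:
        return scan_range[0] <= self.mz <= scan_range[1]


@dataclass(frozen=True)
class CandidateMatch:
    name: str
    formula: str
    smiles: str
    adduct: str
    theoretical_mz: float
    ppm_error: float
    predicted_rt_min: float
    rt_delta_min: float
    rank: int = 0


def filter_features(
    features: list[Feature],
    p_max: float = 0.01,
    fc_min: float = 2.0,
    intensity_min: float = 1.0e6,
) -> list[Feature]:
    """Keep features with p < p_max, fold change > fc_min and intensity >
    intensity_min (all strict), preserving input order.

    Fold change is assumed already direction-folded upstream (values >= 1
    regardless of direction); sort the result by ``p_value`` to reproduce a
    smallest-p-first worklist.
    """
    return [
        f
        for f in features
        if f.p_value < p_max and f.fold_change > fc_min and f.intensity > intensity_min
    ]


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """(observed - theoretical) / theoretical * 1e6."""
    if observed_mz <= 0 or theoretical_mz <= 0:
        raise ValueError("m/z values must be positive")
    return (observed_mz - theoretical_mz) / theoretical_mz * 1.0e6


def monoisotopic_mass(formula: str) -> float:
    """Neutral monoisotopic mass from a molecular formula (standard isotope
    masses; CHNOPS + halogens and anything else pyteomics knows)."""
    try:
        return float(_pyteomics_mass.calculate_mass(formula=formula))
    except Exception as exc:
        raise ValueError(f"cannot compute monoisotopic mass for formula {formula!r}: {exc}") from exc


def theoretical_mz(formula_or_mass: str | float, adduct: AdductSpec) -> float:
    """Expected m/z of ``adduct`` for a neutral molecule given its formula or
    its explicit monoisotopic mass."""
    if isinstance(formula_or_mass, str):
        neutral = monoisotopic_mass(formula_or_mass)
    else:
        neutral = float(formula_or_mass)
    return neutral + adduct.mass_shift


def match_and_rank(
    feature: Feature,
    db: pd.DataFrame,
    model,
    ppm_tol: float = 3.0,
    adducts: tuple[AdductSpec, ...] = (ADDUCTS["[M-H]-"], ADDUCTS["[M+Cl]-"]),
) -> list[CandidateMatch]:
    """Match one feature against a candidate database and rank by RT.

    ``db`` needs columns ``name, smiles`` and either ``formula`` or
    ``monoisotopic_mass``.  For every adduct, candidates within ``ppm_tol``
    of the observed m/z are retained and scored with the model's predicted
    retention time; ranking is ascending |predicted - observed| RT, ties
    broken by |ppm error| then name.  Candidates whose SMILES fail to parse
    are skipped with a warning.
    """
    matches: list[CandidateMatch] = []
    predictions: dict[str, float | None] = {}
    for row in db.itertuples():
        if "monoisotopic_mass" in db.columns and pd.notna(getattr(row, "monoisotopic_mass", None)):
            neutral = float(row.monoisotopic_mass)
        else:
            neutral = monoisotopic_mass(row.formula)
        for adduct in adducts:
            th = neutral + adduct.mass_shift
            err = ppm_error(feature.mz, th)
            if abs(err) > ppm_tol:
                continue
            if row.smiles not in predictions:
                try:
                    graph = parse_smiles(row.smiles)
                    predictions[row.smiles] = float(model.predict(graph))
                except Exception as exc:  # noqa: BLE001 - bad DB rows are non-fatal
                    logger.warning("skipping candidate %s: %s", row.name, exc)
                    predictions[row.smiles] = None
            pred = predictions[row.smiles]
            if pred is None:
                continue
            matches.append(
                CandidateMatch(
                    name=str(row.name),
                    formula=str(getattr(row, "formula", "")),
                    smiles=row.smiles,
                    adduct=adduct.name,
                    theoretical_mz=th,
                    ppm_error=err,
                    predicted_rt_min=pred,
                    rt_delta_min=abs(pred - feature.rt_min),
                )
            )
    matches.sort(key=lambda m: (m.rt_delta_min, abs(m.ppm_error), m.name))
    return [
        CandidateMatch(**{**m.__dict__, "rank": i + 1}) for i, m in enumerate(matches)
    ]
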