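"""CSV readers/writers and the evaluation report.

All retention times are minutes and all m/z values Thomson; the column names
(`rt_min`, `mz`) enforce the units at the file boundary.  Schema problems are
collected per row and reported together with 1-based line numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotate import Feature
from .chem_graph import MoleculeGraph, parse_smiles
from .mpnn import fraction_within, rmse

__all__ = [
    "SchemaError",
    "read_molecule_csv",
    "read_feature_csv",
    "read_candidate_csv",
    "MoleculeRecord",
    "evaluate_report",
]


class SchemaError(ValueError):
    """Input file does not match the expected schema."""


@dataclass(frozen=True)
class MoleculeRecord:
    name: str
    smiles: str
    rt_min: float | None
    graph: MoleculeGraph
    subset: str | None = None


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")


def _numeric(df: pd.DataFrame, columns: list[str], path) -> pd.DataFrame:
    out = df.copy()
    problems = []
    for col in columns:
        converted = pd.to_numeric(out[col], errors="coerce")
        bad = out.index[converted.isna() & out[col].notna()]
        problems += [f"line {i + 2}: non-numeric {col}={out.loc[i, col]!r}" for i in bad]
        out[col] = converted
    if problems:
        raise SchemaError(f"{path}: " + "; ".join(problems))
    return out


def read_molecule_csv(
    path, require_rt: bool = True, strip_salts: bool = False, strict: bool = True
) -> list[MoleculeRecord]:
    """Read `name,smiles,rt_min` (rt_min optional when ``require_rt`` is
    False; an optional `subset` column tags rows for the evaluation report).

    In strict mode a SMILES that fails to parse aborts with its line number;
    otherwise offending rows are dropped.
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["name", "smiles"] + (["rt_min"] if require_rt else []), path)
    if "rt_min" in df.columns:
        df = _numeric(df, ["rt_min"], path)
    records = []
    errors = []
    for i, row in df.iterrows():
        try:
            graph = parse_smiles(str(row.smiles), name=str(row["name"]), strip_salts=strip_salts)
        except Exception as exc:  # noqa: BLE001
            errors.append(f"line {i + 2}: {exc}")
            continue
        rt = row.get("rt_min")
        if require_rt and (rt is None or not np.isfinite(float(rt))):
            errors.append(f"line {i + 2}: missing or non-finite rt_min")
            continue
        records.append(
            MoleculeRecord(
                name=str(row["name"]),
                smiles=str(row.smiles),
                rt_min=float(rt) if rt is not None and pd.notna(rt) else None,
                graph=graph,
                subset=str(row.subset) if "subset" in df.columns and pd.notna(row.subset) else None,
            )
        )
    if errors and strict:
        raise SchemaError(f"{path}: " + "; ".join(errors))
    return records


def read_feature_csv(path) -> list[Feature]:
    """Read `mz,rt_min,intensity,p_value,fold_change`."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["mz", "rt_min", "intensity", "p_value", "fold_change"], path)
    df = _numeric(df, ["mz", "rt_min", "intensity", "p_value", "fold_change"], path)
    return [
        Feature(
            mz=row.mz,
            rt_min=row.rt_min,
            intensity=row.intensity,
            p_value=row.p_value,
            fold_change=row.fold_change,
        )
        for row in df.itertuples()
    ]


def read_candidate_csv(path) -> pd.DataFrame:
    """Read `name,formula,smiles[,monoisotopic_mass]`."""
    df = pd.read_csv(path, dtype={"name": str, "formula": str, "smiles": str})
    _require_columns(df, ["name", "smiles"], path)
    if "formula" not in df.columns and "monoisotopic_mass" not in df.columns:
        raise SchemaError(f"{path}: need a formula or monoisotopic_mass column")
    if "monoisotopic_mass" in df.columns:
        df = _numeric(df, ["monoisotopic_mass"], path)
    return df


def evaluate_report(
    model,
    dataset: list[MoleculeRecord],
    subsets: dict[str, list[str]] | None = None,
    tolerance_min: float = 2.0,
) -> pd.DataFrame:
    """Per-subset performance table: n, RMSE, n and fraction within the RT
    tolerance; always includes an `overall` row.

    ``subsets`` maps a subset name to member molecule names; members not in
    the dataset are skipped with a warning column in mind (reported n counts
    what was actually evaluated).
    """
    import warnings

    by_name = {rec.name: rec for rec in dataset}
    preds = {rec.name: float(model.predict(rec.graph)) for rec in dataset}

    def row(name: str, members: list[str]) -> dict:
        known = [m for m in members if m in by_name]
        for m in members:
            if m not in by_name:
                warnings.warn(f"subset {name!r}: unknown molecule {m!r} skipped")
        p = [preds[m] for m in known]
        o = [by_name[m].rt_min for m in known]
        return {
            "subset": name,
            "n": len(known),
            "rmse_min": rmse(p, o) if known else float("nan"),
            "n_within_tol": int(sum(abs(a - b) < tolerance_min for a, b in zip(p, o))),
            "fraction_within_tol": fraction_within(p, o, tolerance_min) if known else float("nan"),
        }

    rows = [row("overall", [r.name for r in dataset])]
    tagged: dict[str, list[str]] = {}
    for rec in dataset:
        if rec.subset:
            tagged.setdefault(rec.subset, []).append(rec.name)
    for name, members in {**tagged, **(subsets or {})}.items():
        rows.append(row(name, members))
    return pd.DataFrame(rows)
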