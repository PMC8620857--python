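"""Feature filtering, ppm mass matching and RT-based candidate ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mmrt.annotate import (
    ADDUCTS,
    Feature,
    filter_features,
    match_and_rank,
    monoisotopic_mass,
    ppm_error,
    theoretical_mz,
)


def make_feature(mz=100.0, rt=10.0, intensity=2e6, p=0.005, fc=3.0):
    return Feature(mz=mz, rt_min=rt, intensity=intensity, p_value=p, fold_change=fc)


class ConstantModel:
    def __init__(self, value=10.0):
        self.value = value

    def predict(self, graph):
        return self.value


class LookupModel:
    """Predicts by canonical SMILES lookup."""

    def __init__(self, table):
        from rdkit import Chem

        self.table = {Chem.CanonSmiles(k): v for k, v in table.items()}

    def predict(self, graph):
        return self.table[graph.smiles_canonical]


# -- filtering ----------------------------------------------------------------

def test_filter_keeps_qualifying_row():
    assert filter_features([make_feature()]) == [make_feature()]


@pytest.mark.parametrize(
    "kwargs",
    [
        {"p": 0.01},  # boundary p is excluded (strict <)
        {"fc": 2.0},  # boundary fold change excluded (strict >)
        {"intensity": 1e6},  # boundary intensity excluded (strict >)
        {"p": 0.5},
        {"fc": 1.2},
        {"intensity": 1e3},
    ],
)
def test_filter_strict_boundaries(kwargs):
    assert filter_features([make_feature(**kwargs)]) == []


def test_filter_five_row_table_sorted_by_p():
    rows = [
        make_feature(p=0.5),
        make_feature(p=0.004, mz=110.0),
        make_feature(fc=1.0),
        make_feature(p=0.001, mz=120.0),
        make_feature(intensity=10.0),
    ]
    kept = filter_features(rows)
    assert [f.mz for f in kept] == [110.0, 120.0]  # stable input order
    assert [f.mz for f in sorted(kept, key=lambda f: f.p_value)] == [120.0, 110.0]


# -- ppm and theoretical m/z --------------------------------------------------

def test_ppm_error_examples():
    assert ppm_error(100.0001, 100.0) == pytest.approx(1.0)
    assert ppm_error(55.5, 55.5) == 0.0
    assert ppm_error(188.0567, 188.0564) == pytest.approx(1.595, abs=1e-3)
    with pytest.raises(ValueError):
        ppm_error(-1.0, 100.0)


@given(st.floats(50.0, 1000.0), st.floats(-4.9, 4.9))
@settings(max_examples=50, deadline=None)
def test_ppm_error_antisymmetric_for_close_masses(mass, ppm):
    other = mass * (1 + ppm * 1e-6)
    assert ppm_error(mass, other) == pytest.approx(-ppm_error(other, mass), abs=1e-4)


def test_theoretical_mz_glucose():
    mz = theoretical_mz("C6H12O6", ADDUCTS["[M-H]-"])
    assert mz == pytest.approx(179.056112, abs=1e-4)


def test_theoretical_mz_explicit_mass_passthrough():
    from mmrt.annotate import AdductSpec

    assert theoretical_mz(100.0, AdductSpec("none", 0.0)) == 100.0


def test_theoretical_mz_matches_observed_acetylglutamate():
    # the [M-H]- ion of C7H11NO5 sits within 2 ppm of an m/z of 188.0567
    th = theoretical_mz("C7H11NO5", ADDUCTS["[M-H]-"])
    assert abs(ppm_error(188.0567, th)) < 2.0


def test_unknown_element_raises():
    with pytest.raises(ValueError, match="formula"):
        monoisotopic_mass("C2Xx3")


# -- matching and ranking -----------------------------------------------------

def test_empty_db_gives_empty_matches():
    db = pd.DataFrame(columns=["name", "formula", "smiles"])
    assert match_and_rank(make_feature(), db, ConstantModel()) == []


def test_isomers_ranked_by_rt_proximity():
    db = pd.DataFrame(
        {
            "name": ["iso10", "iso20", "iso30"],
            "formula": ["C6H12O6"] * 3,
            "smiles": [
                "OCC(O)C(O)C(O)C(O)C=O",
                "OCC1OC(O)C(O)C(O)C1O",
                "OCC1(O)OCC(O)C(O)C1O",
            ],
        }
    )
    model = LookupModel(
        {
            "OCC(O)C(O)C(O)C(O)C=O": 10.0,
            "OCC1OC(O)C(O)C(O)C1O": 20.0,
            "OCC1(O)OCC(O)C(O)C1O": 30.0,
        }
    )
    feature = make_feature(mz=theoretical_mz("C6H12O6", ADDUCTS["[M-H]-"]), rt=19.0)
    matches = match_and_rank(feature, db, model)
    assert [m.name for m in matches] == ["iso20", "iso10", "iso30"]
    assert [m.rank for m in matches] == [1, 2, 3]
    assert all(m.adduct == "[M-H]-" for m in matches)


def test_chloride_adduct_only_match_is_labeled():
    # observed m/z equals the [M+Cl]- ion of threonate; [M-H]- misses by far
    db = pd.DataFrame(
        {"name": ["threonate"], "formula": ["C4H8O5"], "smiles": ["OCC(O)C(O)C(=O)O"]}
    )
    mz = theoretical_mz("C4H8O5", ADDUCTS["[M+Cl]-"])
    matches = match_and_rank(make_feature(mz=mz, rt=23.0), db, ConstantModel(23.0))
    assert len(matches) == 1
    assert matches[0].adduct == "[M+Cl]-"
    assert matches[0].rank == 1


def test_unparseable_candidate_skipped_not_fatal(caplog):
    db = pd.DataFrame(
        {
            "name": ["bad", "good"],
            "formula": ["C6H12O6", "C6H12O6"],
            "smiles": ["C1CC", "OCC1OC(O)C(O)C(O)C1O"],
        }
    )
    feature = make_feature(mz=theoretical_mz("C6H12O6", ADDUCTS["[M-H]-"]))
    matches = match_and_rank(feature, db, ConstantModel())
    assert [m.name for m in matches] == ["good"]


def test_monoisotopic_mass_column_takes_precedence():
    db = pd.DataFrame({"name": ["x"], "smiles": ["CCO"], "monoisotopic_mass": [100.0]})
    matches = match_and_rank(make_feature(mz=100.0 - 1.007276), db, ConstantModel())
    assert len(matches) == 1


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None)
def test_rank1_minimizes_rt_delta_and_tol_monotonic(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 8))
    smiles = ["CCO", "CCC", "CCN", "CCCO", "CC(C)O", "CCCC", "CCCN", "CCOC"][:n]
    mass = 150.0
    db = pd.DataFrame(
        {
            "name": [f"c{i}" for i in range(n)],
            "smiles": smiles,
            "monoisotopic_mass": mass * (1 + rng.uniform(-4, 4, n) * 1e-6),
        }
    )
    model = LookupModel({s: float(rng.uniform(0, 50)) for s in smiles})
    feature = make_feature(mz=mass - 1.007276, rt=float(rng.uniform(0, 50)))
    wide = match_and_rank(feature, db, model, ppm_tol=3.0, adducts=(ADDUCTS["[M-H]-"],))
    narrow = match_and_rank(feature, db, model, ppm_tol=1.0, adducts=(ADDUCTS["[M-H]-"],))
    if wide:
        assert wide[0].rt_delta_min == min(m.rt_delta_min for m in wide)
    assert {m.name for m in narrow} <= {m.name for m in wide}
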