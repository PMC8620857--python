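"""MPNN regressor: forward pass, training, splitting, metrics, persistence."""

import dataclasses
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mmrt import (
    MPNNConfig,
    cross_validate,
    forward,
    fraction_within,
    load_model,
    parse_smiles,
    rmse,
    save_model,
    split_dataset,
    train,
)
from mmrt.chem_graph import ghost_atom
from mmrt.mpnn import FeatureLayoutError, RTModel, _init_params

SMILES = ["CCO", "CCC", "CCN", "CCCO", "CC(C)O", "CCCC", "CCCN", "CCOC"]


def random_model(hidden_dim=32, seed=0) -> RTModel:
    cfg = MPNNConfig(hidden_dim=hidden_dim, seed=seed)
    return RTModel(config=cfg, params=_init_params(cfg, np.random.default_rng(seed)))


def reindex(graph, perm):
    """Isomorphic copy of a graph under an atom permutation."""
    inv = np.argsort(perm)
    pairs = [(min(inv[i], inv[j]), max(inv[i], inv[j])) for i, j in graph.bonds]
    order = np.argsort([i * graph.n_atoms + j for i, j in pairs])
    return dataclasses.replace(
        graph,
        atom_features=graph.atom_features[perm],
        bonds=tuple(pairs[k] for k in order),
        bond_features=graph.bond_features[order],
        ring_bond=graph.ring_bond[order],
    )


def test_zero_head_predicts_constant():
    model = random_model()
    model.params["head_W2"].data[:] = 0.0
    model.params["head_b2"].data[:] = 0.25
    model.target_mean, model.target_sd = 10.0, 4.0
    preds = {forward(model, parse_smiles(s)) for s in SMILES}
    assert preds == {10.0 + 4.0 * 0.25}


def test_forward_invariant_to_atom_reindexing():
    model = random_model()
    rng = np.random.default_rng(0)
    for s in SMILES:
        g = parse_smiles(s)
        base = forward(model, g)
        for _ in range(3):
            perm = rng.permutation(g.n_atoms)
            assert forward(model, reindex(g, perm)) == pytest.approx(base, abs=1e-5)


def test_forward_rejects_feature_layout_mismatch():
    model = random_model()
    g = parse_smiles("CCO")
    bad = dataclasses.replace(g, atom_features=g.atom_features[:, :-2])
    with pytest.raises(FeatureLayoutError):
        forward(model, bad)


def test_ghosted_graph_still_predicts_finite():
    model = random_model()
    g = parse_smiles("CCO")
    assert np.isfinite(forward(model, ghost_atom(g, 1)))


# -- training -----------------------------------------------------------------

def test_train_constant_dataset_predicts_constant():
    dataset = [(parse_smiles(s), 7.5) for s in SMILES[:6]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = train(dataset, MPNNConfig(hidden_dim=32, epochs=50, batch_size=8, seed=3))
    for g, _ in dataset:
        assert forward(model, g) == pytest.approx(7.5, abs=0.1)


def test_train_separates_two_rt_groups():
    graphs = [parse_smiles(s) for s in SMILES]
    dataset = [(g, 5.0) for g in graphs[:4]] + [(g, 40.0) for g in graphs[4:]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = train(dataset, MPNNConfig(hidden_dim=32, epochs=60, batch_size=8, seed=4))
    low = [forward(model, g) for g in graphs[:4]]
    high = [forward(model, g) for g in graphs[4:]]
    assert max(low) < min(high)


def test_training_reduces_training_error():
    graphs = [parse_smiles(s) for s in SMILES]
    rts = [5.0, 8.0, 3.0, 12.0, 9.0, 15.0, 4.0, 11.0]
    dataset = list(zip(graphs, rts))
    errs = []
    for epochs in (1, 40):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = train(dataset, MPNNConfig(hidden_dim=32, epochs=epochs, batch_size=8, seed=5))
        errs.append(rmse([forward(model, g) for g in graphs], rts))
    assert errs[1] <= errs[0]


def test_train_is_deterministic():
    dataset = [(parse_smiles(s), rt) for s, rt in zip(SMILES[:4], [5.0, 8.0, 3.0, 12.0])]
    cfg = MPNNConfig(hidden_dim=32, epochs=3, batch_size=4, seed=9)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m1, m2 = train(dataset, cfg), train(dataset, cfg)
    for k in m1.params:
        np.testing.assert_array_equal(m1.params[k].data, m2.params[k].data)


def test_train_rejects_nonfinite_rt():
    dataset = [(parse_smiles("CCO"), np.nan), (parse_smiles("CCC"), 5.0)]
    with pytest.raises(ValueError, match="non-finite"):
        train(dataset, MPNNConfig(hidden_dim=32, epochs=1))


def test_train_warns_when_smaller_than_batch():
    dataset = [(parse_smiles(s), rt) for s, rt in zip(SMILES[:3], [5.0, 8.0, 3.0])]
    with pytest.warns(UserWarning, match="smaller than batch"):
        train(dataset, MPNNConfig(hidden_dim=32, epochs=1, batch_size=64))


# -- splitting ----------------------------------------------------------------

def test_split_398_gives_318_80():
    sp = split_dataset(398, 0.8, seed=0)
    assert len(sp.train) == 318 and len(sp.test) == 80


def test_split_half_up_rounding():
    sp = split_dataset(5, 0.5, seed=1)
    assert len(sp.train) == 3 and len(sp.test) == 2


def test_split_deterministic_and_disjoint():
    a = split_dataset(10, 0.8, seed=5)
    b = split_dataset(10, 0.8, seed=5)
    assert a.train == b.train and a.test == b.test
    assert set(a.train) | set(a.test) == set(range(10))
    assert not set(a.train) & set(a.test)


def test_split_validates_inputs():
    with pytest.raises(ValueError):
        split_dataset(1, 0.8, seed=0)
    with pytest.raises(ValueError):
        split_dataset(10, 1.0, seed=0)


# -- metrics ------------------------------------------------------------------

def test_rmse_hand_values():
    assert rmse([1, 2, 3], [1, 2, 3]) == 0.0
    assert rmse([0, 0], [3, 4]) == pytest.approx(np.sqrt(12.5))
    with pytest.raises(ValueError):
        rmse([1, 2], [1])


def test_fraction_within_strict_inequality():
    assert fraction_within([1, 3, 9], [1, 1, 1], 2.0) == pytest.approx(1 / 3)
    assert fraction_within([1, 3, 9], [1, 1, 1], np.inf) == 1.0
    assert fraction_within([1, 3, 9], [1, 1, 1], 0.0) == pytest.approx(1 / 3)


@given(
    st.lists(st.floats(-100, 100), min_size=1, max_size=30),
    st.integers(0, 2**31 - 1),
)
@settings(max_examples=50, deadline=None)
def test_metrics_match_bruteforce(values, seed):
    rng = np.random.default_rng(seed)
    other = rng.uniform(-100, 100, size=len(values)).tolist()
    brute_rmse = (sum((a - b) ** 2 for a, b in zip(values, other)) / len(values)) ** 0.5
    assert rmse(values, other) == pytest.approx(brute_rmse, abs=1e-12)
    assert rmse(values, other) == pytest.approx(rmse(other, values))
    tol = 2.0
    brute_frac = sum(abs(a - b) < tol for a, b in zip(values, other)) / len(values)
    assert fraction_within(values, other, tol) == pytest.approx(brute_frac, abs=1e-12)


# -- cross-validation ---------------------------------------------------------

def test_cross_validate_constant_dataset_near_zero():
    dataset = [(parse_smiles(s), 7.5) for s in SMILES]
    cfg = MPNNConfig(hidden_dim=32, epochs=30, batch_size=8, seed=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mean, sd, folds = cross_validate(dataset, k=2, config=cfg, seeds=[1, 2])
    assert mean < 0.1
    assert len(folds) == 2


def test_cross_validate_deterministic():
    dataset = [(parse_smiles(s), rt) for s, rt in zip(SMILES, [5, 8, 3, 12, 9, 15, 4, 11])]
    cfg = MPNNConfig(hidden_dim=32, epochs=2, batch_size=8, seed=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r1 = cross_validate(dataset, k=2, config=cfg, seeds=[3, 4])
        r2 = cross_validate(dataset, k=2, config=cfg, seeds=[3, 4])
    assert r1 == r2


# -- persistence --------------------------------------------------------------

def test_save_load_roundtrip(tiny_model, tmp_path):
    path = tmp_path / "model.npz"
    save_model(tiny_model, path)
    reloaded = load_model(path)
    for s in SMILES:
        g = parse_smiles(s)
        assert forward(reloaded, g) == pytest.approx(forward(tiny_model, g), abs=1e-6)


def test_load_rejects_tampered_version(tiny_model, tmp_path):
    import json

    path = tmp_path / "model.npz"
    save_model(tiny_model, path)
    with np.load(path) as archive:
        arrays = {k: archive[k] for k in archive.files}
    meta = json.loads(bytes(arrays["_meta"]).decode())
    meta["feature_layout"] = "something-else"
    arrays["_meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)
    with pytest.raises(FeatureLayoutError):
        load_model(path)


def test_load_rejects_corrupt_file(tmp_path):
    path = tmp_path / "junk.npz"
    path.write_bytes(b"not a model")
    with pytest.raises(ValueError):
        load_model(path)
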