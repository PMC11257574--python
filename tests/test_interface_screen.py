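"""Contact extraction, confidence filtering, ranking and the consensus screen."""

import numpy as np
import pytest

from oracles import brute_force_contacts
from sepexo.interface_screen import (
    build_interface_set,
    evaluate_pair,
    extract_contacts,
    filter_by_plddt,
    rank_models,
    screen_all_pairs,
    screen_report,
)
from sepexo.model_io import Atom, Chain, Residue, StructureModel
from sepexo.synthetic_data import make_pair_model


def _single_atom_pair_model(distance: float, plddt_a=90.0, plddt_b=90.0):
    return StructureModel(
        model_id="pair1",
        chains=[
            Chain("A", [Residue(1, "ALA", [Atom("CA", "C", 0, 0, 0)], plddt_a)]),
            Chain("B", [Residue(1, "ALA", [Atom("CA", "C", distance, 0, 0)], plddt_b)]),
        ],
    )


def test_separated_chains_have_no_contacts():
    model, _ = make_pair_model(6, 6, 0, seed=0)
    assert extract_contacts(model, ("A", "B")) == []


@pytest.mark.parametrize("seed", range(8))
def test_planted_contacts_match_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    na, nb = (int(v) for v in rng.integers(4, 30, size=2))
    k = int(rng.integers(0, min(na, nb) + 1))
    model, truth = make_pair_model(na, nb, k, seed=seed)
    contacts = extract_contacts(model, ("A", "B"))
    assert len(contacts) == k
    oracle = brute_force_contacts(model, ("A", "B"), 4.0)
    got = {(c.res_a_index, c.res_b_index): c.min_distance for c in contacts}
    assert set(got) == set(oracle)
    for key in got:
        assert got[key] == pytest.approx(oracle[key], abs=1e-6)
    planted = {(c["res_a"], c["res_b"]): c["distance"] for c in truth.planted_contacts}
    assert set(got) == set(planted)


def test_exact_cutoff_distance_is_inclusive():
    model = _single_atom_pair_model(4.0)
    contacts = extract_contacts(model, ("A", "B"), cutoff_angstrom=4.0)
    assert len(contacts) == 1
    assert contacts[0].min_distance == pytest.approx(4.0, abs=1e-12)
    assert extract_contacts(model, ("A", "B"), cutoff_angstrom=3.999999) == []


def test_contact_symmetry_between_chain_orders():
    model, _ = make_pair_model(15, 12, 5, seed=3)
    ab = {(c.res_a_index, c.res_b_index): c.min_distance
          for c in extract_contacts(model, ("A", "B"))}
    ba = {(c.res_b_index, c.res_a_index): c.min_distance
          for c in extract_contacts(model, ("B", "A"))}
    assert set(ab) == set(ba)
    for key in ab:
        assert ab[key] == pytest.approx(ba[key], abs=1e-6)


def test_contact_set_monotone_in_cutoff():
    rng = np.random.default_rng(42)
    for _ in range(100):
        model, _ = make_pair_model(
            8, 8, int(rng.integers(0, 9)), seed=int(rng.integers(2**31))
        )
        sets = [
            {(c.res_a_index, c.res_b_index)
             for c in extract_contacts(model, ("A", "B"), cutoff)}
            for cutoff in (3.5, 4.0, 5.0)
        ]
        assert sets[0] <= sets[1] <= sets[2]


def test_extract_contacts_input_validation():
    model, _ = make_pair_model(4, 4, 1, seed=0)
    with pytest.raises(KeyError):
        extract_contacts(model, ("A", "Q"))
    with pytest.raises(ValueError, match="positive"):
        extract_contacts(model, ("A", "B"), cutoff_angstrom=-1.0)


# ------------------------------------------------------------------ filtering

def test_plddt_filter_boundary_semantics():
    """49.99 on one partner drops the contact; exactly 50.0 keeps it."""
    kept = filter_by_plddt(
        extract_contacts(_single_atom_pair_model(3.0, plddt_a=50.0), ("A", "B")),
        _single_atom_pair_model(3.0, plddt_a=50.0),
    )
    assert len(kept) == 1
    dropped_model = _single_atom_pair_model(3.0, plddt_a=49.99)
    dropped = filter_by_plddt(
        extract_contacts(dropped_model, ("A", "B")), dropped_model
    )
    assert dropped == []


def test_full_confidence_filter_is_identity():
    model, _ = make_pair_model(10, 10, 6, plddt_a=100.0, plddt_b=100.0, seed=2)
    contacts = extract_contacts(model, ("A", "B"))
    assert filter_by_plddt(contacts, model) == contacts


@pytest.mark.parametrize("scope", ["both", "either"])
def test_filter_matches_independent_residue_scan(scope):
    rng = np.random.default_rng(9)
    pl_a = [float(v) for v in rng.uniform(20, 100, 12)]
    pl_b = [float(v) for v in rng.uniform(20, 100, 12)]
    model, _ = make_pair_model(12, 12, 8, plddt_a=pl_a, plddt_b=pl_b, seed=9)
    contacts = extract_contacts(model, ("A", "B"))
    kept = filter_by_plddt(contacts, model, min_plddt=50, scope=scope)
    op = (lambda a, b: a >= 50 and b >= 50) if scope == "both" else (
        lambda a, b: a >= 50 or b >= 50)
    expected = [
        c for c in contacts
        if op(pl_a[c.res_a_index - 1], pl_b[c.res_b_index - 1])
    ]
    assert kept == expected
    assert len(kept) <= len(contacts)  # contraction
    stricter = filter_by_plddt(contacts, model, min_plddt=70, scope=scope)
    assert set((c.res_a_index, c.res_b_index) for c in stricter) <= set(
        (c.res_a_index, c.res_b_index) for c in kept
    )


def test_filter_rejects_contact_with_missing_residue():
    model, _ = make_pair_model(4, 4, 1, seed=1)
    contacts = extract_contacts(model, ("A", "B"))
    small, _ = make_pair_model(1, 1, 0, seed=1)
    with pytest.raises(KeyError):
        filter_by_plddt(contacts, small)


# -------------------------------------------------------------------- ranking

def test_rank_models_descending_and_permutation_invariant():
    models = [
        make_pair_model(4, 4, 0, plddt_a=v, plddt_b=v, seed=i, model_id=f"m{i}")[0]
        for i, v in enumerate([90, 80, 70, 60, 50])
    ]
    ranked = rank_models(models)
    assert [m.model_id for m in ranked] == ["m0", "m1", "m2", "m3", "m4"]
    assert [m.rank for m in ranked] == [1, 2, 3, 4, 5]
    rng = np.random.default_rng(0)
    shuffled = [models[i] for i in rng.permutation(5)]
    assert [m.model_id for m in rank_models(shuffled)] == [m.model_id for m in ranked]


def test_rank_models_breaks_ties_by_id():
    a = make_pair_model(4, 4, 0, plddt_a=70, plddt_b=70, seed=0, model_id="zeta")[0]
    b = make_pair_model(4, 4, 0, plddt_a=70, plddt_b=70, seed=1, model_id="alpha")[0]
    assert [m.model_id for m in rank_models([a, b])] == ["alpha", "zeta"]
    with pytest.raises(ValueError):
        rank_models([])


# ------------------------------------------------------------------ consensus

def _iset(n_contacts, plddt, order_tag, seed=0):
    model, _ = make_pair_model(
        10, 10, n_contacts, plddt_a=plddt, plddt_b=plddt, seed=seed
    )
    model.rank = 1
    return build_interface_set(model, ("A", "B"), order_tag, ("P", "Q"))


def test_one_sided_interface_is_not_consensus():
    result = evaluate_pair(_iset(10, 90.0, "P:Q"), _iset(0, 90.0, "Q:P"))
    assert result.consensus is False
    assert result.score == 0.0


def test_bidirectional_interface_is_consensus_with_min_score():
    result = evaluate_pair(_iset(3, 88.0, "P:Q"), _iset(5, 72.0, "Q:P"))
    assert result.consensus is True
    assert result.score == pytest.approx(72.0)


def test_consensus_symmetric_in_order_tags():
    a, b = _iset(3, 88.0, "P:Q"), _iset(5, 72.0, "Q:P")
    r1, r2 = evaluate_pair(a, b), evaluate_pair(b, a)
    assert r1.consensus == r2.consensus and r1.score == r2.score


def test_evaluate_pair_rejects_mismatched_labels():
    other = _iset(3, 88.0, "P:R")
    other.pair_label = ("P", "R")
    with pytest.raises(ValueError, match="mismatched"):
        evaluate_pair(_iset(3, 88.0, "P:Q"), other)


def test_interface_mean_plddt_matches_independent_mean():
    pl_a = [60.0 + i for i in range(10)]
    pl_b = [80.0 + i for i in range(10)]
    model, truth = make_pair_model(10, 10, 4, plddt_a=pl_a, plddt_b=pl_b, seed=4)
    model.rank = 1
    iset = build_interface_set(model, ("A", "B"), "P:Q", ("P", "Q"))
    vals = []
    for c in truth.planted_contacts:
        vals.append(pl_a[c["res_a"] - 1])
        vals.append(pl_b[c["res_b"] - 1])
    assert iset.interface_mean_plddt == pytest.approx(np.mean(vals))


# ---------------------------------------------------------------- full screen

def _grid(consensus_pairs, one_sided_pairs, subunits_a, subunits_b, seed=0):
    rng = np.random.default_rng(seed)
    table = {}
    for a in subunits_a:
        for b in subunits_b:
            for order in ((a, b), (b, a)):
                n = 0
                if (a, b) in consensus_pairs:
                    n = 5
                elif (a, b) in one_sided_pairs and order == (a, b):
                    n = 5
                model, _ = make_pair_model(
                    10, 10, n, seed=int(rng.integers(2**31)),
                    model_id=f"{order[0]}_{order[1]}",
                )
                table[order] = [model]
    return table


def test_screen_recovers_planted_consensus_pairs_ranked_first():
    septins = [f"S{i}" for i in range(1, 5)]
    exocyst = [f"E{i}" for i in range(1, 9)]
    planted = {("S1", "E2"), ("S2", "E5"), ("S3", "E1"), ("S4", "E8"),
               ("S1", "E7"), ("S2", "E3")}
    decoys = {("S3", "E4"), ("S4", "E6"), ("S1", "E1")}
    table = _grid(planted, decoys, septins, exocyst, seed=77)
    results = screen_all_pairs(table)
    found = {r.pair_label for r in results if r.consensus}
    assert found == {tuple(sorted(p)) for p in planted}
    assert all(r.consensus for r in results[:6])
    assert all(not r.consensus for r in results[6:])
    df = screen_report(results)
    assert len(df) == 64 and df.consensus.sum() == 12  # two rows per pair


def test_screen_all_empty_interfaces_yields_no_consensus():
    table = _grid(set(), set(), ["S1", "S2"], ["E1"], seed=1)
    results = screen_all_pairs(table)
    assert all(not r.consensus for r in results)


def test_screen_idempotent_under_duplicated_orders():
    table = _grid({("S1", "E1")}, set(), ["S1"], ["E1"], seed=5)
    once = screen_all_pairs(dict(table))
    again = screen_all_pairs(dict(table))
    assert screen_report(once).equals(screen_report(again))


def test_screen_missing_order_warns_and_continues():
    table = _grid({("S1", "E1")}, set(), ["S1"], ["E1"], seed=2)
    del table[("E1", "S1")]
    with pytest.warns(UserWarning, match="one input order"):
        results = screen_all_pairs(table)
    assert len(results) == 1 and not results[0].evaluable
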