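"""Fragment network: reference geometry, pair classification semantics,
graph construction and the Gi/Ge split."""

import numpy as np
import pytest

from fragnet.fixtures import FixtureSpec, make_chain_ligand, make_pocket_shell
from fragnet.fragments import deduplicate_fragments, fragment_ligand
from fragnet.graph import (
    CLASH_THRESHOLD,
    DistortionParams,
    FragmentGraph,
    build_graph,
    evaluate_pair,
    reference_geometry,
    split_graph,
)

from conftest import CC_SP3_REF, SP3_BEND, sp3_stub_pair


# ---------------------------------------------------------------------------
# reference geometry
# ---------------------------------------------------------------------------


def test_reference_geometry_pinned_values():
    length, bends = reference_geometry("C", "sp3", "C", "sp3", 1)
    assert length == pytest.approx(1.53)
    assert bends == (109.5, 109.5)
    _len, bends = reference_geometry("C", "sp", "C", "sp", 3)
    assert bends == (180.0, 180.0)
    double, _ = reference_geometry("C", "sp2", "C", "sp2", 2)
    single, _ = reference_geometry("C", "sp3", "C", "sp3", 1)
    assert double < single


def test_reference_geometry_is_symmetric_and_errors_on_unknown():
    a = reference_geometry("C", "sp2", "N", "sp3", 1)[0]
    b = reference_geometry("N", "sp3", "C", "sp2", 1)[0]
    assert a == b
    with pytest.raises(KeyError, match="Xx"):
        reference_geometry("Xx", "sp3", "C", "sp3", 1)


# ---------------------------------------------------------------------------
# pair classification
# ---------------------------------------------------------------------------


def test_ideal_junction_gives_zero_distortion_candidate():
    a, b = sp3_stub_pair()
    verdict = evaluate_pair(a, b, DistortionParams(0, 0, 0, 0))
    assert verdict.kind == "inclusion"
    (cand,) = verdict.candidates
    assert cand.bond_order == 1
    assert cand.measured_distance == pytest.approx(CC_SP3_REF)
    assert all(c.deviation == pytest.approx(0.0, abs=1e-9) for c in cand.angle_checks)
    names = {c.name for c in cand.angle_checks}
    assert names == {"bend_a", "bend_b", "torsion"}


def test_subcovalent_contact_is_exclusion_at_any_tolerance():
    a, b = sp3_stub_pair(distance=0.5)
    for params in (DistortionParams(0, 0, 0, 0), DistortionParams(45, 45, 45, 45)):
        v = evaluate_pair(a, b, params)
        assert v.kind == "exclusion"
        assert v.reason == "steric_clash"


def test_distance_window_boundary_arithmetic():
    a, b = sp3_stub_pair(distance=CC_SP3_REF * 1.12)
    assert evaluate_pair(a, b, DistortionParams(45, 45, 45, 10)).kind == "none"
    assert evaluate_pair(a, b, DistortionParams(45, 45, 45, 15)).kind == "inclusion"


def test_angle_deviation_straddles_tolerance():
    a, b = sp3_stub_pair(bend_a=SP3_BEND + 12.0)
    assert evaluate_pair(a, b, DistortionParams(45, 45, 10, 45)).kind == "none"
    assert evaluate_pair(a, b, DistortionParams(45, 45, 15, 45)).kind == "inclusion"


def test_unrealistic_angle_is_exclusion_independent_of_tolerance():
    a, b = sp3_stub_pair(bend_a=SP3_BEND + 60.0)  # beyond the 45 deg ceiling
    for params in (DistortionParams(0, 0, 0, 0), DistortionParams(45, 45, 45, 45)):
        v = evaluate_pair(a, b, params)
        assert v.kind == "exclusion"
        assert v.reason == "unrealistic_angle"


def test_far_fragments_have_no_relation():
    a, b = sp3_stub_pair(distance=6.0)
    assert evaluate_pair(a, b, DistortionParams(45, 45, 45, 45)).kind == "none"


def test_evaluate_pair_is_symmetric():
    a, b = sp3_stub_pair(bend_b=SP3_BEND + 5.0, torsion=290.0)
    va = evaluate_pair(a, b, DistortionParams(10, 10, 10, 10))
    vb = evaluate_pair(b, a, DistortionParams(10, 10, 10, 10))
    assert va.kind == vb.kind == "inclusion"
    ca, cb = va.candidates[0], vb.candidates[0]
    assert (ca.atom_a, ca.atom_b) == (cb.atom_b, cb.atom_a)
    assert ca.measured_distance == pytest.approx(cb.measured_distance)
    devs_a = {c.name: c.deviation for c in ca.angle_checks}
    devs_b = {c.name: c.deviation for c in cb.angle_checks}
    assert devs_a["bend_a"] == pytest.approx(devs_b["bend_b"])
    assert devs_a["torsion"] == pytest.approx(devs_b["torsion"])


def test_torsion_measured_against_nearest_staggered_minimum():
    a, b = sp3_stub_pair(torsion=300.0 + 20.0)
    v = evaluate_pair(a, b, DistortionParams(25, 45, 45, 45))
    assert v.kind == "inclusion"
    torsion = next(c for c in v.candidates[0].angle_checks if c.name == "torsion")
    assert torsion.deviation == pytest.approx(20.0, abs=1e-6)
    assert evaluate_pair(a, b, DistortionParams(15, 45, 45, 45)).kind == "none"


def test_inclusion_monotone_in_each_distortion_component():
    a, b = sp3_stub_pair(
        distance=CC_SP3_REF * 1.08, bend_a=SP3_BEND + 8.0, torsion=300.0 + 8.0
    )
    base = DistortionParams(15, 15, 15, 15)
    assert evaluate_pair(a, b, base).kind == "inclusion"
    sweep = (0, 5, 10, 15, 30, 45)
    for component in ("torsion_deg", "oop_deg", "dihedral_deg", "distance_pct"):
        included = []
        for value in sweep:
            params = DistortionParams(**{**base.__dict__, component: value})
            included.append(evaluate_pair(a, b, params).kind == "inclusion")
        # once included, stays included as the component grows
        assert included == sorted(included)


# ---------------------------------------------------------------------------
# graph construction and split
# ---------------------------------------------------------------------------


def _fixture_graph(seed=11, n=4, pocket=False, params=DistortionParams(0, 0, 0, 0)):
    spec = FixtureSpec(n_fragments=n, seed=seed)
    lig, _t, _a = make_chain_ligand(spec)
    frags = deduplicate_fragments(fragment_ligand(lig, {"scaffold_tree"}))
    pockets = [make_pocket_shell(lig, 2.0)] if pocket else []
    return frags, build_graph(frags, pockets, params)


def test_build_graph_matches_all_pairs_evaluation():
    frags, g = _fixture_graph()
    expected_incl, expected_excl = set(), set()
    for i in range(len(frags)):
        for j in range(i + 1, len(frags)):
            v = evaluate_pair(frags[i], frags[j], DistortionParams(0, 0, 0, 0))
            key = tuple(sorted((frags[i].fragment_id, frags[j].fragment_id)))
            if v.kind == "inclusion":
                expected_incl.add(key)
            elif v.kind == "exclusion":
                expected_excl.add(key)
    assert set(g.inclusion_edges) == expected_incl
    assert g.exclusion_edges == expected_excl
    assert all(g.nodes[f.fragment_id]["mw"] == pytest.approx(f.mw) for f in frags)


def test_ideal_fixture_recovers_ground_truth_adjacency_at_zero_tolerance():
    spec = FixtureSpec(n_fragments=5, seed=2)
    lig, truth, adjacency = make_chain_ligand(spec)
    g = build_graph(truth, [], DistortionParams(0, 0, 0, 0))
    expected = {
        tuple(sorted((truth[i].fragment_id, truth[j].fragment_id)))
        for i, j in adjacency
    }
    assert set(g.inclusion_edges) == expected
    assert not g.exclusion_edges


def test_empty_fragment_list_gives_empty_graph():
    g = build_graph([], [], DistortionParams())
    assert not g.nodes and not g.inclusion_edges and not g.exclusion_edges


def test_split_graph_gates_on_compatibility():
    frags, g = _fixture_graph(pocket=True)
    gi, ge = split_graph(g, "shell")
    assert set(gi.nodes) == {
        k for k, targets in g.compatibility.items() if "shell" in targets
    }
    assert set(gi.nodes) == set(ge.nodes)
    assert not ge.inclusion_edges and not gi.exclusion_edges
    with pytest.raises(KeyError, match="unknown target"):
        split_graph(g, "nonsense")


def test_split_graph_partition_matches_brute_force_filter(rng):
    g = FragmentGraph()
    ids = [f"f{k}" for k in range(12)]
    compat = {}
    for k, fid in enumerate(ids):
        g.add_node(fid, 100.0 + k, (2,))
        compat[fid] = rng.random() < 0.6
        if compat[fid]:
            g.compatibility[fid].add("T")
    pairs = [(i, j) for i in range(12) for j in range(i + 1, 12)]
    for i, j in pairs:
        r = rng.random()
        if r < 0.3:
            g.inclusion_edges[(ids[i], ids[j])] = ()
        elif r < 0.5:
            g.exclusion_edges.add((ids[i], ids[j]))
    gi, ge = split_graph(g, "T")
    keep = {fid for fid in ids if compat[fid]}
    assert set(gi.nodes) == keep
    assert set(gi.inclusion_edges) == {
        (u, v) for u, v in g.inclusion_edges if u in keep and v in keep
    }
    assert ge.exclusion_edges == {
        (u, v) for u, v in g.exclusion_edges if u in keep and v in keep
    }


def test_no_pair_is_both_inclusion_and_exclusion():
    g = FragmentGraph()
    g.add_node("a", 1.0, (1,))
    g.add_node("b", 1.0, (1,))
    g.add_inclusion("a", "b", ())
    with pytest.raises(ValueError):
        g.add_exclusion("a", "b")


def test_distortion_params_validation():
    with pytest.raises(ValueError):
        DistortionParams(torsion_deg=50)
    with pytest.raises(ValueError):
        DistortionParams(distance_pct=-1)


def test_graph_json_roundtrip(tmp_path):
    _frags, g = _fixture_graph(pocket=True)
    g.to_json(tmp_path / "g.json")
    back = FragmentGraph.from_json(tmp_path / "g.json")
    assert set(back.nodes) == set(g.nodes)
    assert set(back.inclusion_edges) == set(g.inclusion_edges)
    assert back.exclusion_edges == g.exclusion_edges
    assert {k: set(v) for k, v in back.compatibility.items()} == {
        k: set(v) for k, v in g.compatibility.items()
    }
    for key in g.inclusion_edges:
        assert back.inclusion_edges[key] == g.inclusion_edges[key]
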