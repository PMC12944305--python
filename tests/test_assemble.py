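"""Growth enumeration, 3D assembly, conformation dedup and pose agreement."""

import numpy as np
import pytest
from rdkit import Chem

from fragnet.assemble import (
    AssembledMolecule,
    AssemblyPath,
    H_MASS,
    assemble,
    deduplicate_molecules,
    enumerate_paths,
    pose_consistency,
)
from fragnet.fixtures import FixtureSpec, make_chain_ligand, round_trip
from fragnet.fragments import deduplicate_fragments, fragment_ligand
from fragnet.graph import DistortionParams, FragmentGraph, LinkCandidate, build_graph, split_graph

from conftest import benzene_fragment, translate_fragment


# ---------------------------------------------------------------------------
# abstract-graph enumeration
# ---------------------------------------------------------------------------


def _abstract_graph(edges, exclusions, mws, fv=8):
    """Gi/Ge over string node ids with one trivial candidate per edge."""
    gi, ge = FragmentGraph(), FragmentGraph()
    for node, mw in mws.items():
        gi.add_node(node, mw, (fv,))
        ge.add_node(node, mw, (fv,))
    for u, v in edges:
        gi.add_inclusion(u, v, [LinkCandidate(0, 0, 1, 1.5, 1.53)])
    for u, v in exclusions:
        ge.add_exclusion(u, v)
    return gi, ge


def _oracle_paths(nodes, edges, exclusions, mws, seed, cap):
    """Independent recursive simple-path enumerator with pairwise Ge checks."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    exc = {frozenset(p) for p in exclusions}
    out = []

    def rec(path, mw):
        if len(path) >= 2:
            out.append(tuple(path))
        if mw >= cap:
            return
        for nxt in sorted(adj[path[-1]]):
            if nxt in path:
                continue
            if any(frozenset((nxt, p)) in exc for p in path):
                continue
            rec(path + [nxt], mw + mws[nxt] - 2 * H_MASS)

    rec([seed], mws[seed])
    return sorted(out)


def test_isolated_seed_yields_no_paths():
    gi, ge = _abstract_graph([], [], {"s": 100.0, "x": 100.0})
    assert enumerate_paths(gi, ge, "s") == []


def test_exclusion_vetoes_nonadjacent_pair():
    mws = {"A": 100.0, "B": 100.0, "C": 100.0}
    gi, ge = _abstract_graph([("A", "B"), ("B", "C")], [("A", "C")], mws)
    paths = enumerate_paths(gi, ge, "A")
    assert [p.fragment_ids for p in paths] == [("A", "B")]


def test_enumeration_matches_dfs_oracle_on_random_graphs(rng):
    for trial in range(100):
        n = int(rng.integers(2, 9))
        nodes = [f"f{k}" for k in range(n)]
        mws = {node: float(rng.uniform(60, 220)) for node in nodes}
        edges, exclusions = [], []
        for i in range(n):
            for j in range(i + 1, n):
                r = rng.random()
                if r < 0.35:
                    edges.append((nodes[i], nodes[j]))
                elif r < 0.5:
                    exclusions.append((nodes[i], nodes[j]))
        cap = float(rng.uniform(200, 700))
        gi, ge = _abstract_graph(edges, exclusions, mws)
        seed = nodes[int(rng.integers(0, n))]
        got = sorted(p.fragment_ids for p in enumerate_paths(gi, ge, seed, mw_cap=cap))
        assert got == _oracle_paths(nodes, edges, exclusions, mws, seed, cap)


def test_mw_cap_emits_intermediate_paths_and_stops():
    mws = {"A": 300.0, "B": 300.0, "C": 300.0}
    gi, ge = _abstract_graph([("A", "B"), ("B", "C")], [], mws)
    # A+B = 597.98 < 650 so the chain may extend; A+B+C exceeds it but is
    # still emitted (the cap stops further growth, not the emission)
    paths = [p.fragment_ids for p in enumerate_paths(gi, ge, "A", mw_cap=650.0)]
    assert paths == [("A", "B"), ("A", "B", "C")]
    paths = [p.fragment_ids for p in enumerate_paths(gi, ge, "A", mw_cap=550.0)]
    assert paths == [("A", "B")]


def test_growth_atom_restriction_and_validation():
    mws = {"A": 100.0, "B": 100.0}
    gi, ge = _abstract_graph([("A", "B")], [], mws)
    # the only candidate uses seed atom 0; restricting to atom 0 keeps it
    assert enumerate_paths(gi, ge, "A", growth_atoms={0})
    with pytest.raises(ValueError, match="free-valence"):
        enumerate_paths(gi, ge, "A", growth_atoms={5})
    with pytest.raises(ValueError, match="seed"):
        enumerate_paths(gi, ge, "missing")


def test_valence_bookkeeping_limits_junctions_per_atom():
    # middle node with a single free valence cannot host two junctions
    gi, ge = _abstract_graph(
        [("A", "B"), ("B", "C")], [], {"A": 100.0, "B": 100.0, "C": 100.0}, fv=1
    )
    paths = [p.fragment_ids for p in enumerate_paths(gi, ge, "A")]
    assert ("A", "B") in paths and ("A", "B", "C") not in paths


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def _biphenyl_pair():
    a = benzene_fragment(name="L", free_atom=0)
    b = translate_fragment(
        benzene_fragment(name="R", free_atom=3), (2 * 1.39 + 1.48, 0.0, 0.0)
    )
    return a, b


def test_assemble_biphenyl_preserves_coordinates():
    a, b = _biphenyl_pair()
    link = LinkCandidate(0, 3, 1, 1.48, 1.48)
    path = AssemblyPath((a.fragment_id, b.fragment_id), (link,), a.mw + b.mw - 2 * H_MASS)
    built = assemble(path, {a.fragment_id: a, b.fragment_id: b})
    assert built.canonical_form == "c1ccc(-c2ccccc2)cc1"
    merged = np.asarray(built.mol.GetConformer().GetPositions())
    assert np.allclose(merged[:6], a.coords)
    assert np.allclose(merged[6:], b.coords)
    assert built.atom_provenance == (a.fragment_id,) * 6 + (b.fragment_id,) * 6
    from rdkit.Chem import Descriptors

    assert Descriptors.MolWt(built.mol) == pytest.approx(path.cumulative_mw, abs=1e-6)


def test_assemble_valence_overflow_is_reported():
    a, b = _biphenyl_pair()
    link = LinkCandidate(0, 3, 2, 1.48, 1.48)  # double bond to an aromatic CH
    path = AssemblyPath((a.fragment_id, b.fragment_id), (link,), 0.0)
    with pytest.raises(ValueError, match="valence"):
        assemble(path, {a.fragment_id: a, b.fragment_id: b})


def test_reconstruction_from_every_seed_on_ideal_fixture():
    report = round_trip(FixtureSpec(n_fragments=4, seed=9), DistortionParams(0, 0, 0, 0))
    assert report.full_recovery
    assert report.n_seeds == 4


def test_reconstruction_prefixes_survive_planted_exclusion():
    spec = FixtureSpec(n_fragments=3, seed=1, planted_exclusions=((0, 2),))
    report = round_trip(spec, DistortionParams(0, 0, 0, 0))
    assert report.n_recovered == 0  # full chain blocked by the Ge veto
    assert report.n_paths_total > 0  # prefix paths still emitted


# ---------------------------------------------------------------------------
# molecule dedup and pose consistency
# ---------------------------------------------------------------------------


def _built_benzene_pair(shift):
    a, b = _biphenyl_pair()
    a2 = translate_fragment(a, shift)
    b2 = translate_fragment(b, shift)
    link = LinkCandidate(0, 3, 1, 1.48, 1.48)
    out = []
    for fa, fb in ((a, b), (a2, b2)):
        path = AssemblyPath((fa.fragment_id, fb.fragment_id), (link,), fa.mw + fb.mw - 2 * H_MASS)
        out.append(assemble(path, {fa.fragment_id: fa, fb.fragment_id: fb}))
    return out


def test_molecule_dedup_keeps_distinct_conformations():
    near = _built_benzene_pair((0.3, 0.0, 0.0))
    assert len(deduplicate_molecules(near, 1.0)) == 1
    far = _built_benzene_pair((1.5, 0.0, 0.0))
    assert len(deduplicate_molecules(far, 1.0)) == 2


def test_molecule_dedup_matches_greedy_oracle(rng):
    from fragnet.fragments import _inplace_rmsd_mols

    mols = []
    for k in range(12):
        shift = rng.uniform(-2, 2, size=3)
        mols.append(_built_benzene_pair(shift)[1])
    survivors = deduplicate_molecules(mols, 1.0)
    kept = []
    for m in mols:
        if all(
            m.canonical_form != o.canonical_form
            or _inplace_rmsd_mols(m.mol, o.mol) >= 1.0
            for o in kept
        ):
            kept.append(m)
    assert [s.name for s in survivors] == [k.name for k in kept]
    assert [s.name for s in deduplicate_molecules(survivors, 1.0)] == [
        s.name for s in survivors
    ]


def test_pose_consistency_translation_and_formula(rng):
    built = _built_benzene_pair((0, 0, 0))[0]
    assert pose_consistency(built, Chem.Mol(built.mol)) == pytest.approx(0.0, abs=1e-12)
    shifted = Chem.Mol(built.mol)
    conf = shifted.GetConformer()
    from rdkit.Geometry import Point3D

    for i in range(shifted.GetNumAtoms()):
        p = conf.GetAtomPosition(i)
        conf.SetAtomPosition(i, Point3D(p.x, p.y, p.z + 3.0))
    assert pose_consistency(built, shifted) == pytest.approx(3.0, abs=1e-9)
    with pytest.raises(ValueError, match="structure"):
        pose_consistency(built, Chem.MolFromSmiles("CCO"))


def test_provenance_completeness_and_mw_additivity():
    spec = FixtureSpec(n_fragments=5, seed=4)
    lig, _t, _a = make_chain_ligand(spec)
    frags = deduplicate_fragments(fragment_ligand(lig, {"scaffold_tree"}))
    g = build_graph(frags, [], DistortionParams(0, 0, 0, 0))
    gi, ge = split_graph(g, None)
    store = {f.fragment_id: f for f in frags}
    seed = sorted(store)[0]
    from rdkit.Chem import Descriptors

    for path in enumerate_paths(gi, ge, seed):
        built = assemble(path, store)
        assert len(built.atom_provenance) == built.mol.GetNumAtoms()
        assert set(built.atom_provenance) == set(path.fragment_ids)
        expected = sum(store[i].mw for i in path.fragment_ids) - sum(
            2 * c.bond_order * H_MASS for c in path.chosen_links
        )
        assert path.cumulative_mw == pytest.approx(expected)
        assert Descriptors.MolWt(built.mol) == pytest.approx(expected, abs=1e-6)
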