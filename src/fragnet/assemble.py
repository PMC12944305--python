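"""Growing molecules from a seed through the inclusion graph.

Starting at a seed fragment, every simple path through Gi whose fragments
are pairwise free of exclusion relations (checked against Ge for *all*
pairs, not just consecutive ones) is enumerated, up to a molecular-weight
cap.  Each path is then materialized as a single 3D molecule: one covalent
bond per junction, coordinates untouched, no minimization - the fragments
already sit where the crystal structures put them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem

from .fragments import Fragment3D, _inplace_rmsd_mols
from .graph import FragmentGraph, LinkCandidate

__all__ = [
    "AssemblyPath",
    "AssembledMolecule",
    "enumerate_paths",
    "assemble",
    "deduplicate_molecules",
    "pose_consistency",
    "MW_CAP",
    "MOLECULE_DEDUP_RMSD",
    "POSE_RMSD_GATE",
    "H_MASS",
]

MW_CAP = 650.0  # Da, growth stops once the cumulative weight reaches this
MOLECULE_DEDUP_RMSD = 1.0  # angstrom, duplicate-conformation threshold
POSE_RMSD_GATE = 2.5  # angstrom, generated-vs-docked pose agreement gate
H_MASS = 1.008


@dataclass(frozen=True)
class AssemblyPath:
    """An ordered fragment chain (or tree) rooted at the seed.

    ``chosen_links[k]`` joins ``fragment_ids[k+1]`` to its parent fragment;
    for a linear path the parent is simply the previous fragment.  Branched
    assemblies record explicit ``parents`` (index into ``fragment_ids``).
    """

    fragment_ids: tuple[str, ...]
    chosen_links: tuple[LinkCandidate, ...]  # oriented parent -> child
    cumulative_mw: float
    parents: tuple[int, ...] = ()

    def __post_init__(self):
        if len(self.chosen_links) != len(self.fragment_ids) - 1:
            raise ValueError("need exactly one link per added fragment")
        if self.parents and len(self.parents) != len(self.chosen_links):
            raise ValueError("need one parent index per link")

    @property
    def parent_indices(self) -> tuple[int, ...]:
        return self.parents or tuple(range(len(self.fragment_ids) - 1))

    @property
    def is_linear(self) -> bool:
        return self.parent_indices == tuple(range(len(self.fragment_ids) - 1))


@dataclass
class AssembledMolecule:
    """A built 3D molecule with per-atom fragment provenance."""

    mol: Chem.Mol
    atom_provenance: tuple[str, ...]  # source fragment id per atom
    path: AssemblyPath
    descriptors: object | None = None

    @property
    def canonical_form(self) -> str:
        return Chem.MolToSmiles(self.mol)

    @property
    def name(self) -> str:
        return "+".join(self.path.fragment_ids)


def _path_mw(mws: list[float], orders: list[int]) -> float:
    return sum(mws) - sum(2 * o * H_MASS for o in orders)


def enumerate_paths(
    gi: FragmentGraph,
    ge: FragmentGraph,
    seed: str,
    growth_atoms=None,
    mw_cap: float = MW_CAP,
    allow_branching: bool = False,
) -> list[AssemblyPath]:
    """All valid simple growth paths from the seed.

    A path extends from its last fragment to an inclusion neighbor while
    its cumulative weight is still below ``mw_cap``; every intermediate
    path (length >= 2 fragments) is emitted, so the enumeration is anytime.
    The new fragment must not share an exclusion relation with *any*
    fragment already in the path.  ``growth_atoms`` restricts the seed-side
    atom of links attached to the seed.  Free valences are tracked along
    the path; at each junction the deterministically first feasible
    candidate (sorted by atom indices, then bond order) is chosen.

    With ``allow_branching=True`` the enumeration covers connected subtrees
    of Gi rooted at the seed instead of linear chains; a multi-valent
    interior seed can then grow in several directions at once, which the
    reconstruction protocol needs when the seed is an interior fragment of
    the original ligand.  Each distinct tree is emitted once.
    """
    if mw_cap <= 0:
        raise ValueError("mw_cap must be positive")
    if seed not in gi.nodes:
        raise ValueError(f"seed {seed!r} is not a node of Gi")
    seed_fv = gi.nodes[seed]["free_valence"]
    if growth_atoms is not None:
        growth_atoms = frozenset(int(i) for i in growth_atoms)
        bad = [i for i in growth_atoms if i >= len(seed_fv) or seed_fv[i] <= 0]
        if bad:
            raise ValueError(f"growth atoms {bad} are not free-valence atoms of the seed")

    results: list[AssemblyPath] = []
    seen_trees: set = set()

    def remaining(consumed, node, atom):
        return gi.nodes[node]["free_valence"][atom] - consumed.get((node, atom), 0)

    def tree_key(path, parents, links):
        return frozenset(
            (path[parents[k]], path[k + 1], links[k].atom_a, links[k].atom_b, links[k].bond_order)
            for k in range(len(links))
        )

    def extend(path, parents, links, mw, consumed):
        if allow_branching and len(path) >= 2:
            key = tree_key(path, parents, links)
            if key in seen_trees:
                return  # same tree reached by a different addition order
            seen_trees.add(key)
        if len(path) >= 2:
            results.append(
                AssemblyPath(tuple(path), tuple(links), mw, parents=tuple(parents))
            )
        if mw >= mw_cap:
            return
        anchors = range(len(path)) if allow_branching else (len(path) - 1,)
        for anchor_idx in anchors:
            anchor = path[anchor_idx]
            for nxt in gi.inclusion_neighbors(anchor):
                if nxt in path:
                    continue
                if any(ge.excluded(nxt, p) for p in path):
                    continue
                chosen = None
                for cand in gi.candidates(anchor, nxt):
                    if (
                        anchor == seed
                        and growth_atoms is not None
                        and cand.atom_a not in growth_atoms
                    ):
                        continue
                    if remaining(consumed, anchor, cand.atom_a) < cand.bond_order:
                        continue
                    if remaining(consumed, nxt, cand.atom_b) < cand.bond_order:
                        continue
                    chosen = cand
                    break
                if chosen is None:
                    continue
                consumed2 = dict(consumed)
                consumed2[(anchor, chosen.atom_a)] = (
                    consumed2.get((anchor, chosen.atom_a), 0) + chosen.bond_order
                )
                consumed2[(nxt, chosen.atom_b)] = (
                    consumed2.get((nxt, chosen.atom_b), 0) + chosen.bond_order
                )
                new_mw = mw + gi.nodes[nxt]["mw"] - 2 * chosen.bond_order * H_MASS
                extend(
                    path + [nxt],
                    parents + [anchor_idx],
                    links + [chosen],
                    new_mw,
                    consumed2,
                )

    extend([seed], [], [], gi.nodes[seed]["mw"], {})
    results.sort(key=lambda p: (len(p.fragment_ids), p.fragment_ids, p.parent_indices))
    return results


def assemble(path: AssemblyPath, fragments: dict[str, Fragment3D]) -> AssembledMolecule:
    """Materialize a path as one molecule, creating the recorded junction bonds.

    Coordinates are inherited untouched; hydrogens displaced by the new
    bonds disappear implicitly; aromaticity is re-perceived on the merged
    structure.  A valence overflow (two junctions consuming the same last
    open slot) raises with the offending atom named.
    """
    frags = [fragments[i] for i in path.fragment_ids]
    combo = frags[0].mol
    offsets = [0]
    provenance = [path.fragment_ids[0]] * frags[0].mol.GetNumAtoms()
    for frag, fid in zip(frags[1:], path.fragment_ids[1:]):
        offsets.append(combo.GetNumAtoms())
        combo = Chem.CombineMols(combo, frag.mol)
        provenance.extend([fid] * frag.mol.GetNumAtoms())

    order_map = {
        1: Chem.BondType.SINGLE,
        2: Chem.BondType.DOUBLE,
        3: Chem.BondType.TRIPLE,
    }
    rw = Chem.RWMol(combo)
    for k, link in enumerate(path.chosen_links):
        ia = offsets[path.parent_indices[k]] + link.atom_a
        ib = offsets[k + 1] + link.atom_b
        rw.AddBond(ia, ib, order_map[link.bond_order])
    mol = rw.GetMol()
    from rdkit.Chem import rdchem

    try:
        Chem.SanitizeMol(mol)
    except (rdchem.AtomValenceException, rdchem.KekulizeException) as exc:
        raise ValueError(f"valence overflow while assembling {path.fragment_ids}: {exc}") from exc
    return AssembledMolecule(mol=mol, atom_provenance=tuple(provenance), path=path)


def deduplicate_molecules(
    mols: list[AssembledMolecule], rmsd_cut: float = MOLECULE_DEDUP_RMSD
) -> list[AssembledMolecule]:
    """Drop repeated builds of the same molecule in (nearly) the same pose.

    Molecules are grouped by canonical form; within a group the greedy
    keep-first scan removes any member whose symmetry-aware in-frame RMSD
    to an already-kept member is below ``rmsd_cut``.  Distinct
    conformations of the same molecule all survive.
    """
    if rmsd_cut <= 0:
        raise ValueError("rmsd_cut must be positive")
    kept_by_form: dict[str, list[AssembledMolecule]] = {}
    survivors = []
    for am in mols:
        group = kept_by_form.setdefault(am.canonical_form, [])
        if any(_inplace_rmsd_mols(am.mol, other.mol) < rmsd_cut for other in group):
            continue
        group.append(am)
        survivors.append(am)
    return survivors


def pose_consistency(mol: AssembledMolecule, docked_pose: Chem.Mol) -> float:
    """Symmetry-aware in-frame RMSD between a built molecule and an
    externally docked pose of the same structure.  Callers gate at 2.5 A."""
    pose = Chem.RemoveHs(docked_pose)
    if Chem.MolToSmiles(pose) != mol.canonical_form:
        raise ValueError("docked pose does not match the molecule's structure")
    return _inplace_rmsd_mols(mol.mol, pose)
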