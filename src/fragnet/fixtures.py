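"""Synthetic in-frame test systems with known answer keys.

Chain ligands of six-membered C/N aromatic rings joined by single bonds
stand in for aligned co-crystallized ligands: every fragmentation rule-set
cuts exactly the inter-ring bonds, so fragmentation, graph construction,
growth and reconstruction can all be checked against a constructed ground
truth.  Rings are regular hexagons and junctions sit at exact reference
geometry (bond length from the pinned table, 120-degree bends, coplanar
rings), so at zero distortion tolerance the recovered inclusion edges must
equal the ground-truth adjacency.  Jittered fixtures rigidly perturb each
ring at its entry atom, distorting only junction geometry.

These fixtures emulate aligned-frame fragment geometry, not kinase
pharmacophores: passing tests demonstrate the bookkeeping and geometry
rules, not binding-site realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

from .assemble import assemble, enumerate_paths
from .fragments import Fragment3D, Provenance, deduplicate_fragments, fragment_ligand
from .graph import DistortionParams, build_graph, reference_geometry, split_graph
from .pocket import PocketModel

__all__ = [
    "FixtureSpec",
    "make_chain_ligand",
    "make_pocket_shell",
    "round_trip",
    "RoundTripReport",
]

RING_SIDE = 1.39  # aromatic C-C/C-N ring bond length (regular hexagon side)

# 6-ring aromatic templates; positions 0 and 3 (the junction vertices) stay carbon
_RING_TEMPLATES = (
    ("benzene", ("C", "C", "C", "C", "C", "C")),
    ("pyridine", ("C", "N", "C", "C", "C", "C")),
    ("pyrazine", ("C", "N", "C", "C", "N", "C")),
    ("pyrimidine", ("C", "N", "C", "C", "C", "N")),
)


@dataclass(frozen=True)
class FixtureSpec:
    n_fragments: int = 3
    geometry: str = "ideal"  # "ideal" | "jittered"
    sigma_angstrom: float = 0.0
    sigma_deg: float = 0.0
    seed: int = 0
    pocket_shell: bool = False
    planted_exclusions: tuple = ()  # pairs of ring indices

    def __post_init__(self):
        if self.n_fragments < 2:
            raise ValueError("n_fragments must be >= 2")
        if self.geometry not in ("ideal", "jittered"):
            raise ValueError("geometry must be 'ideal' or 'jittered'")
        if self.sigma_angstrom < 0 or self.sigma_deg < 0:
            raise ValueError("jitter sigmas must be non-negative")


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    x, y, z = axis
    return np.array(
        [
            [c + x * x * (1 - c), x * y * (1 - c) - z * s, x * z * (1 - c) + y * s],
            [y * x * (1 - c) + z * s, c + y * y * (1 - c), y * z * (1 - c) - x * s],
            [z * x * (1 - c) - y * s, z * y * (1 - c) + x * s, c + z * z * (1 - c)],
        ]
    )


def _hexagon(center_x: float) -> np.ndarray:
    """Regular hexagon in the z=0 plane; vertex 0 points -x, vertex 3 +x."""
    angles = np.radians(180.0 + 60.0 * np.arange(6))
    return np.column_stack(
        [center_x + RING_SIDE * np.cos(angles), RING_SIDE * np.sin(angles), np.zeros(6)]
    )


def _build_aromatic_mol(elements, coords, ring_bonds, junction_bonds):
    rw = Chem.RWMol()
    for el in elements:
        rw.AddAtom(Chem.Atom(el))
    for i, j, order in ring_bonds:
        rw.AddBond(i, j, Chem.BondType.DOUBLE if order == 2 else Chem.BondType.SINGLE)
    for i, j in junction_bonds:
        rw.AddBond(i, j, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, (x, y, z) in enumerate(coords):
        conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
    mol.AddConformer(conf)
    Chem.SanitizeMol(mol)
    return mol


def make_chain_ligand(spec: FixtureSpec):
    """Build a linear multi-ring aromatic ligand with a known answer key.

    Returns ``(ligand, fragments, adjacency)`` where ``fragments`` is the
    ground-truth per-ring :class:`Fragment3D` list (free valence 1 at each
    junction atom) and ``adjacency`` the ground-truth ring-index pairs.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_fragments
    junction_len, _ = reference_geometry("C", "aromatic", "C", "aromatic", 1)
    spacing = 2 * RING_SIDE + junction_len

    template_idx = rng.integers(0, len(_RING_TEMPLATES), size=n)
    ring_elements = [_RING_TEMPLATES[i][1] for i in template_idx]
    ring_coords = [_hexagon(k * spacing) for k in range(n)]

    if spec.geometry == "jittered":
        for k in range(1, n):
            pivot = ring_coords[k][0].copy()  # entry junction atom
            axis = rng.normal(size=3)
            angle = rng.normal(0.0, spec.sigma_deg)
            rot = _rotation_matrix(axis, angle)
            ring_coords[k] = (ring_coords[k] - pivot) @ rot.T + pivot
            shift = rng.normal(0.0, spec.sigma_angstrom)
            ring_coords[k] = ring_coords[k] + np.array([shift, 0.0, 0.0])

    # assemble the full ligand
    elements, coords, ring_bonds, junction_bonds = [], [], [], []
    for k in range(n):
        base = 6 * k
        elements.extend(ring_elements[k])
        coords.extend(ring_coords[k])
        for m in range(6):
            order = 2 if m % 2 == 0 else 1  # alternating Kekule pattern
            ring_bonds.append((base + m, base + (m + 1) % 6, order))
        if k < n - 1:
            junction_bonds.append((base + 3, base + 6))
    ligand = _build_aromatic_mol(elements, coords, ring_bonds, junction_bonds)
    ligand.SetProp("_Name", f"fixture-{spec.seed}-{n}")

    # ground-truth fragments: one ring each, free valence at junction vertices
    fragments = []
    for k in range(n):
        ring_mol = _build_aromatic_mol(
            ring_elements[k],
            ring_coords[k],
            [(m, (m + 1) % 6, 2 if m % 2 == 0 else 1) for m in range(6)],
            [],
        )
        fv = [0] * 6
        if k > 0:
            fv[0] = 1
        if k < n - 1:
            fv[3] = 1
        prov = Provenance(ligand_id=ligand.GetProp("_Name"), method="answer_key")
        fragments.append(Fragment3D(ring_mol, tuple(fv), prov, fragment_id=f"ring{k:02d}"))
    adjacency = [(k, k + 1) for k in range(n - 1)]
    return ligand, fragments, adjacency


def make_pocket_shell(
    ligand: Chem.Mol,
    shell_distance,
    anchor_atoms=None,
    target_id: str = "shell",
) -> PocketModel:
    """Pseudo-atom pocket at controlled distances from chosen ligand atoms.

    A pseudo-atom is placed ``shell_distance`` straight above (+z) each
    anchor atom, so the nearest fragment-pocket distance is the shell
    distance by construction.  ``shell_distance`` may be a scalar or a
    mapping anchor-atom -> distance.  Default anchors are the off-junction
    ring vertices (index 1 of every ring) of chain-ligand fixtures, which
    keeps each pseudo-atom more than 3.5 angstrom from every other ring.
    """
    coords = np.asarray(ligand.GetConformer().GetPositions(), dtype=float)
    if anchor_atoms is None:
        anchor_atoms = list(range(1, ligand.GetNumAtoms(), 6))
    if isinstance(shell_distance, dict):
        anchors = {int(k): float(v) for k, v in shell_distance.items()}
    else:
        anchors = {int(a): float(shell_distance) for a in anchor_atoms}
    pts = [coords[a] + np.array([0.0, 0.0, h]) for a, h in sorted(anchors.items())]
    return PocketModel(
        target_id=target_id,
        elements=("C",) * len(pts),
        coords=np.asarray(pts),
        residues=tuple(f"PSD{a}" for a in sorted(anchors)),
        chains=("X",) * len(pts),
    )


@dataclass
class RoundTripReport:
    ligand_form: str
    n_seeds: int
    recovered_from: dict
    n_paths_total: int

    @property
    def n_recovered(self) -> int:
        return sum(bool(v) for v in self.recovered_from.values())

    @property
    def recovery_rate(self) -> float:
        return self.n_recovered / self.n_seeds if self.n_seeds else 0.0

    @property
    def full_recovery(self) -> bool:
        return self.n_seeds > 0 and self.n_recovered == self.n_seeds


def round_trip(
    spec: FixtureSpec,
    params: DistortionParams,
    methods=("brics", "recap", "scaffold_tree"),
    mw_cap: float = 650.0,
) -> RoundTripReport:
    """Fragment a fixture ligand, rebuild from every fragment as seed, and
    report whether the original canonical form was recovered.

    Planted exclusions (by ring index, ordered along the chain) are forced
    into the exclusion graph, overriding any inclusion verdict.
    """
    ligand, _truth, _adj = make_chain_ligand(spec)
    target_form = Chem.MolToSmiles(Chem.RemoveHs(ligand))

    frags = deduplicate_fragments(fragment_ligand(ligand, methods))
    pockets = []
    if spec.pocket_shell:
        pockets.append(make_pocket_shell(ligand, 2.0))
    graph = build_graph(frags, pockets, params)

    # order fragments along the chain to resolve planted ring-index pairs
    by_x = sorted(frags, key=lambda f: float(np.mean(f.coords[:, 0])))
    for i, j in spec.planted_exclusions:
        u, v = by_x[i].fragment_id, by_x[j].fragment_id
        graph.inclusion_edges.pop(graph._key(u, v), None)
        graph.add_exclusion(u, v)

    gi, ge = split_graph(graph, "shell" if spec.pocket_shell else None)
    store = {f.fragment_id: f for f in frags}

    recovered, n_paths = {}, 0
    for f in sorted(frags, key=lambda f: f.fragment_id):
        if f.fragment_id not in gi.nodes:
            recovered[f.fragment_id] = False
            continue
        paths = enumerate_paths(gi, ge, f.fragment_id, mw_cap=mw_cap, allow_branching=True)
        n_paths += len(paths)
        hit = False
        for path in paths:
            if assemble(path, store).canonical_form == target_form:
                hit = True
                break
        recovered[f.fragment_id] = hit
    return RoundTripReport(
        ligand_form=target_form,
        n_seeds=len(frags),
        recovered_from=recovered,
        n_paths_total=n_paths,
    )
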