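"""Shared builders: controlled-geometry fragment stubs and tiny systems."""

from __future__ import annotations

import math

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

from fragnet.fragments import Fragment3D, Provenance

SP3_BEND = 109.5  # pinned ideal tetrahedral bend (degrees)
CC_SP3_REF = 1.53  # pinned reference C(sp3)-C(sp3) single-bond length


def mol_from_atoms(elements, coords, bonds):
    """Explicit molecule builder: elements, (n,3) coords, (i, j, order) bonds."""
    rw = Chem.RWMol()
    for el in elements:
        rw.AddAtom(Chem.Atom(el))
    order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
    for i, j, order in bonds:
        rw.AddBond(int(i), int(j), order_map[order])
    mol = rw.GetMol()
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, Point3D(*[float(v) for v in xyz]))
    mol.AddConformer(conf)
    Chem.SanitizeMol(mol)
    return mol


def sp3_stub(origin, neighbor, name="stub"):
    """Ethane-like C-C fragment: atom 0 has one free valence, atom 1 is its
    only heavy neighbor (controls bend/torsion geometry)."""
    mol = mol_from_atoms(["C", "C"], [origin, neighbor], [(0, 1, 1)])
    return Fragment3D(mol, (1, 0), Provenance(name))


def sp3_stub_pair(
    distance=CC_SP3_REF,
    bend_a=SP3_BEND,
    bend_b=SP3_BEND,
    torsion=300.0,
):
    """Two sp3 stubs whose nascent-bond geometry is set exactly.

    Fragment A sits at the origin with its neighbor in the xy plane at
    ``bend_a`` degrees from the +x bond direction; fragment B sits at
    ``(distance, 0, 0)`` with its neighbor at ``bend_b`` degrees from -x,
    rolled about the bond axis so that the n(A)-A-B-n(B) dihedral equals
    ``torsion`` degrees.
    """
    a_ang = math.radians(bend_a)
    n_a = CC_SP3_REF * np.array([math.cos(a_ang), math.sin(a_ang), 0.0])
    frag_a = sp3_stub((0.0, 0.0, 0.0), n_a, "A")

    b_ang = math.radians(bend_b)
    # torsion measured from n(A) (at +y side, dihedral reference 0 deg)
    phi = math.radians(torsion)
    direction = np.array(
        [
            -math.cos(b_ang),
            math.sin(b_ang) * math.cos(phi),
            math.sin(b_ang) * math.sin(phi),
        ]
    )
    origin_b = np.array([distance, 0.0, 0.0])
    frag_b = sp3_stub(origin_b, origin_b + CC_SP3_REF * direction, "B")
    return frag_a, frag_b


def benzene_fragment(translate=(0.0, 0.0, 0.0), free_atom=0, name="benzene", rotate_deg=0.0):
    """Planar regular benzene with one free-valence atom, optionally rotated
    about its ring axis and rigidly translated."""
    angles = np.radians(np.arange(6) * 60.0 + rotate_deg)
    coords = np.column_stack(
        [1.39 * np.cos(angles), 1.39 * np.sin(angles), np.zeros(6)]
    ) + np.asarray(translate, dtype=float)
    bonds = [(m, (m + 1) % 6, 2 if m % 2 == 0 else 1) for m in range(6)]
    mol = mol_from_atoms(["C"] * 6, coords, bonds)
    fv = [0] * 6
    fv[free_atom] = 1
    return Fragment3D(mol, tuple(fv), Provenance(name))


def translate_fragment(frag: Fragment3D, shift) -> Fragment3D:
    mol = Chem.Mol(frag.mol)
    conf = mol.GetConformer()
    for i in range(mol.GetNumAtoms()):
        p = conf.GetAtomPosition(i)
        s = np.asarray(shift, dtype=float)
        conf.SetAtomPosition(i, Point3D(p.x + s[0], p.y + s[1], p.z + s[2]))
    return Fragment3D(mol, frag.free_valence, frag.provenance)


def transform_fragment(frag: Fragment3D, rotation: np.ndarray, shift) -> Fragment3D:
    mol = Chem.Mol(frag.mol)
    conf = mol.GetConformer()
    coords = frag.coords @ rotation.T + np.asarray(shift, dtype=float)
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, Point3D(*[float(v) for v in xyz]))
    return Fragment3D(mol, frag.free_valence, frag.provenance)


def embedded_mol(smiles: str, seed: int = 7) -> Chem.Mol:
    """A 3D-embedded heavy-atom molecule for tests that need coordinates."""
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    if AllChem.EmbedMolecule(mol, randomSeed=seed) != 0:
        raise RuntimeError(f"embedding failed for {smiles}")
    return Chem.RemoveHs(mol)


def random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
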