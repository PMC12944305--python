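"""Binding-site model and fragment-protein compatibility.

A pocket is simply the set of protein heavy atoms near an anchor (a point
or a reference ligand), all in the common aligned frame.  A fragment is
compatible with the pocket when it neither clashes with the protein
(closest approach below ``clash_floor``) nor floats away from it (no atom
within ``contact_ceiling`` of the protein).  The 1.4-3.5 angstrom window is
read as clash floor / contact ceiling: requiring *every* fragment-protein
distance to fall inside the window would reject essentially any fragment,
which cannot be the intent of avoiding "steric hindrance" while staying
near the site.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

from .fragments import Fragment3D

__all__ = ["PocketModel", "extract_pocket", "check_compatibility"]

DEFAULT_CLASH_FLOOR = 1.4
DEFAULT_CONTACT_CEILING = 3.5


@dataclass
class PocketModel:
    """Protein heavy atoms surrounding the binding site."""

    target_id: str
    elements: tuple[str, ...]
    coords: np.ndarray  # (n, 3) angstrom
    residues: tuple[str, ...] = ()
    chains: tuple[str, ...] = ()
    clash_floor: float = DEFAULT_CLASH_FLOOR
    contact_ceiling: float = DEFAULT_CONTACT_CEILING

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.coords.shape[0] == 0:
            raise ValueError("pocket_atoms must be non-empty")
        if not (0 < self.clash_floor < self.contact_ceiling):
            raise ValueError("need 0 < clash_floor < contact_ceiling")
        n = self.coords.shape[0]
        if len(self.elements) != n:
            raise ValueError("elements length must match coords")
        if not self.residues:
            self.residues = ("",) * n
        if not self.chains:
            self.chains = ("",) * n

    # -- persistence ---------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "target_id": self.target_id,
            "elements": list(self.elements),
            "coords": np.round(self.coords, 6).tolist(),
            "residues": list(self.residues),
            "chains": list(self.chains),
            "clash_floor": self.clash_floor,
            "contact_ceiling": self.contact_ceiling,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PocketModel":
        d = json.loads(Path(path).read_text())
        return cls(
            target_id=d["target_id"],
            elements=tuple(d["elements"]),
            coords=np.asarray(d["coords"], dtype=float),
            residues=tuple(d["residues"]),
            chains=tuple(d["chains"]),
            clash_floor=d["clash_floor"],
            contact_ceiling=d["contact_ceiling"],
        )


def _anchor_points(anchor) -> np.ndarray:
    if isinstance(anchor, Fragment3D):
        return anchor.coords
    if hasattr(anchor, "GetConformer"):  # an RDKit molecule
        return np.asarray(anchor.GetConformer().GetPositions(), dtype=float)
    pts = np.asarray(anchor, dtype=float)
    return pts.reshape(-1, 3)


def extract_pocket(
    structure,
    anchor,
    radius: float = 10.0,
    target_id: str = "",
    clash_floor: float = DEFAULT_CLASH_FLOOR,
    contact_ceiling: float = DEFAULT_CONTACT_CEILING,
) -> PocketModel:
    """Select protein heavy atoms within ``radius`` of the anchor.

    ``structure`` is a PDB file path or a parsed Bio.PDB structure, assumed
    pre-aligned to the same frame as the fragments.  An empty selection
    signals misaligned inputs and raises.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if isinstance(structure, (str, Path)):
        parser = PDBParser(QUIET=True)
        structure = parser.get_structure(target_id or Path(structure).stem, str(structure))
    pts = _anchor_points(anchor)

    elements, coords, residues, chains = [], [], [], []
    for atom in structure.get_atoms():
        element = (atom.element or "").strip() or atom.get_name()[:1]
        if element.upper() == "H":
            continue
        residue = atom.get_parent()
        if residue.id[0] != " ":  # skip HETATM (waters, ions, ligands)
            continue
        pos = atom.get_coord().astype(float)
        if np.min(np.linalg.norm(pts - pos, axis=1)) <= radius:
            elements.append(element)
            coords.append(pos)
            residues.append(f"{residue.get_resname()}{residue.id[1]}")
            chains.append(residue.get_parent().id)
    if not coords:
        raise ValueError(
            "no protein atom within radius of the anchor; "
            "inputs are probably not in the same aligned frame"
        )
    return PocketModel(
        target_id=target_id or structure.id,
        elements=tuple(elements),
        coords=np.asarray(coords),
        residues=tuple(residues),
        chains=tuple(chains),
        clash_floor=clash_floor,
        contact_ceiling=contact_ceiling,
    )


def check_compatibility(frag: Fragment3D, pocket: PocketModel) -> bool:
    """True iff the fragment sits in the site without steric clash.

    (i) no fragment heavy atom closer than ``clash_floor`` to any pocket
    atom, and (ii) at least one fragment heavy atom within
    ``contact_ceiling`` of some pocket atom.
    """
    fc = frag.coords
    diffs = fc[:, None, :] - pocket.coords[None, :, :]
    dists = np.sqrt(np.sum(diffs * diffs, axis=2))
    dmin = float(dists.min())
    return dmin >= pocket.clash_floor and dmin <= pocket.contact_ceiling
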