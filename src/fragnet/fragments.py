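"""3D fragment library construction.

Ligands co-crystallized in a common binding-site frame are cut into
fragments by rule-based bond cleavage while *preserving every atom's 3D
coordinates*.  A fragment is a chemical group in a particular 3D
orientation: the same 2D structure in two different orientations is two
different library entries.  Atoms that lost a bond to cleavage carry a
free-valence count, i.e. how many covalent links they may later accept.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
from rdkit import Chem
from rdkit.Chem import BRICS, Descriptors

__all__ = [
    "Provenance",
    "Fragment3D",
    "FragmentFilterVerdict",
    "fragment_ligand",
    "filter_fragment",
    "deduplicate_fragments",
    "compute_inplace_rmsd",
    "hybridization_tag",
    "FRAGMENT_MW_CAP",
    "FRAGMENT_DEDUP_RMSD",
]

FRAGMENT_MW_CAP = 300.0  # Da; heavier fragments are dropped from the library
FRAGMENT_DEDUP_RMSD = 0.25  # angstrom; in-frame duplicate threshold

_HYB_MAP = {
    Chem.HybridizationType.SP: "sp",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
}


def hybridization_tag(atom: Chem.Atom) -> str:
    """Coarse hybridization label used for geometry lookups.

    Aromatic atoms are their own class; anything exotic (hypervalent S,
    etc.) is treated as sp3.
    """
    if atom.GetIsAromatic():
        return "aromatic"
    return _HYB_MAP.get(atom.GetHybridization(), "sp3")


def _load_json(name: str) -> dict:
    with resources.files("fragnet.data").joinpath(name).open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class Provenance:
    """Where a fragment came from: source ligand, structure, chain, rule-set."""

    ligand_id: str
    structure_id: str = ""
    chain: str = ""
    method: str = ""

    def as_tuple(self) -> tuple[str, str, str, str]:
        return (self.ligand_id, self.structure_id, self.chain, self.method)


@dataclass
class Fragment3D:
    """A chemical group frozen in its binding-site orientation.

    ``mol`` is a heavy-atom RDKit molecule with exactly one conformer in
    the shared aligned frame.  ``free_valence[i]`` counts the open bonding
    slots of atom *i* (bonds severed during fragmentation, or explicitly
    designated growth points on a seed).
    """

    mol: Chem.Mol
    free_valence: tuple[int, ...]
    provenance: Provenance
    fragment_id: str = ""

    def __post_init__(self) -> None:
        if self.mol.GetNumConformers() != 1:
            raise ValueError("Fragment3D requires exactly one 3D conformer")
        n = self.mol.GetNumAtoms()
        self.free_valence = tuple(int(v) for v in self.free_valence)
        if len(self.free_valence) != n:
            raise ValueError("free_valence length must match atom count")
        if any(v < 0 for v in self.free_valence):
            raise ValueError("free_valence entries must be non-negative")
        coords = self.coords
        if not np.all(np.isfinite(coords)):
            raise ValueError("fragment coordinates must be finite")
        for atom in self.mol.GetAtoms():
            fv = self.free_valence[atom.GetIdx()]
            if fv > atom.GetTotalNumHs():
                raise ValueError(
                    f"free_valence {fv} of atom {atom.GetIdx()} exceeds its "
                    f"open hydrogen capacity ({atom.GetTotalNumHs()})"
                )
        if not self.fragment_id:
            self.fragment_id = self._auto_id()

    # -- derived attributes -------------------------------------------------

    @property
    def coords(self) -> np.ndarray:
        return np.asarray(self.mol.GetConformer().GetPositions(), dtype=float)

    @property
    def canonical_form(self) -> str:
        """Stereo-aware canonical SMILES of the hydrogen-capped 2D structure."""
        return Chem.MolToSmiles(self.mol)

    @property
    def mw(self) -> float:
        """Molecular weight (Da) of the H-capped fragment."""
        return Descriptors.MolWt(self.mol)

    @property
    def attachment_atoms(self) -> tuple[int, ...]:
        return tuple(i for i, v in enumerate(self.free_valence) if v > 0)

    def hybridizations(self) -> tuple[str, ...]:
        return tuple(hybridization_tag(a) for a in self.mol.GetAtoms())

    def elements(self) -> tuple[str, ...]:
        return tuple(a.GetSymbol() for a in self.mol.GetAtoms())

    def _auto_id(self) -> str:
        payload = (
            self.canonical_form,
            np.round(self.coords, 4).tolist(),
            self.free_valence,
            self.provenance.as_tuple(),
        )
        digest = hashlib.sha1(repr(payload).encode()).hexdigest()[:12]
        lig = self.provenance.ligand_id or "frag"
        method = self.provenance.method or "manual"
        return f"{lig}:{method}:{digest}"

    def with_free_valence(self, free_valence) -> "Fragment3D":
        return replace(self, free_valence=tuple(free_valence), fragment_id="")


@dataclass(frozen=True)
class FragmentFilterVerdict:
    fragment_id: str
    kept: bool
    reasons: tuple[str, ...]

    def __post_init__(self):
        if self.kept != (len(self.reasons) == 0):
            raise ValueError("kept must be true iff reasons is empty")


# ---------------------------------------------------------------------------
# fragmentation
# ---------------------------------------------------------------------------

_CLEAVAGE_RULES = None


def _cleavage_rules() -> dict:
    global _CLEAVAGE_RULES
    if _CLEAVAGE_RULES is None:
        raw = _load_json("cleavage_rules.json")
        _CLEAVAGE_RULES = {
            method: [
                (rule["name"], Chem.MolFromSmarts(rule["smarts"]))
                for rule in rules
            ]
            for method, rules in raw.items()
            if method not in ("comment", "version")
        }
    return _CLEAVAGE_RULES


def find_cleavable_bonds(mol: Chem.Mol, method: str) -> list[int]:
    """Bond indices a rule-set would cut, in deterministic order."""
    if method == "brics":
        idx = set()
        for (a, b), _labels in BRICS.FindBRICSBonds(mol):
            bond = mol.GetBondBetweenAtoms(a, b)
            if bond is not None and not bond.IsInRing():
                idx.add(bond.GetIdx())
        return sorted(idx)
    try:
        rules = _cleavage_rules()[method]
    except KeyError:
        raise ValueError(f"unknown fragmentation method: {method!r}") from None
    idx = set()
    for _name, patt in rules:
        for match in mol.GetSubstructMatches(patt):
            bond = mol.GetBondBetweenAtoms(match[0], match[1])
            if bond is not None and not bond.IsInRing():
                idx.add(bond.GetIdx())
    return sorted(idx)


def _pieces_with_free_valence(mol: Chem.Mol, bond_indices: list[int]):
    """Cut the listed bonds at once; return (piece mol, free_valence) pairs.

    Coordinates are inherited untouched from the parent conformer.  Each
    severed bond adds its order to the free valence of its endpoint.
    """
    cut = Chem.FragmentOnBonds(mol, bond_indices, addDummies=True)
    pieces = Chem.GetMolFrags(cut, asMols=True, sanitizeFrags=False)
    out = []
    for piece in pieces:
        rw = Chem.RWMol(piece)
        gained: dict[int, int] = {}
        dummies = []
        for atom in rw.GetAtoms():
            if atom.GetAtomicNum() == 0:
                dummies.append(atom.GetIdx())
                (nbr,) = atom.GetNeighbors()
                bond = rw.GetBondBetweenAtoms(atom.GetIdx(), nbr.GetIdx())
                order = int(round(bond.GetBondTypeAsDouble()))
                gained[nbr.GetIdx()] = gained.get(nbr.GetIdx(), 0) + order
        # removing from the top keeps surviving indices stable
        keep_map = [i for i in range(rw.GetNumAtoms()) if i not in set(dummies)]
        for d in sorted(dummies, reverse=True):
            rw.RemoveAtom(d)
        clean = rw.GetMol()
        Chem.SanitizeMol(clean)
        fv = [0] * clean.GetNumAtoms()
        old_to_new = {old: new for new, old in enumerate(keep_map)}
        for old_idx, gain in gained.items():
            fv[old_to_new[old_idx]] += gain
        out.append((clean, tuple(fv)))
    return out


def fragment_ligand(
    ligand: Chem.Mol,
    methods,
    provenance: Provenance | None = None,
) -> list[Fragment3D]:
    """Cut a 3D ligand with each rule-set and return the union of fragments.

    Every output atom keeps the exact coordinates it had in the ligand.  A
    ligand with no rule-matching bond comes back whole, as a single
    fragment with no free valence.
    """
    methods = sorted(set(methods))
    if not methods:
        raise ValueError("at least one fragmentation method is required")
    known = set(_cleavage_rules()) | {"brics"}
    unknown = [m for m in methods if m not in known]
    if unknown:
        raise ValueError(f"unknown fragmentation method(s): {unknown}")
    if ligand.GetNumConformers() == 0:
        raise ValueError("ligand has no 3D coordinates")
    mol = Chem.RemoveHs(ligand)
    name = ligand.GetProp("_Name") if ligand.HasProp("_Name") else ""
    base = provenance or Provenance(ligand_id=name or "ligand")

    fragments: list[Fragment3D] = []
    for method in methods:
        prov = replace(base, method=method)
        bonds = find_cleavable_bonds(mol, method)
        if not bonds:
            whole = Chem.Mol(mol)
            fragments.append(
                Fragment3D(whole, (0,) * whole.GetNumAtoms(), prov)
            )
            continue
        for piece, fv in _pieces_with_free_valence(mol, bonds):
            fragments.append(Fragment3D(piece, fv, prov))
    return fragments


# ---------------------------------------------------------------------------
# fragment filter
# ---------------------------------------------------------------------------

_SUBSTRUCTURE_PATTERNS = None


def undesired_patterns() -> list[tuple[str, Chem.Mol]]:
    """Compiled undesired-substructure patterns (shared with module filters)."""
    global _SUBSTRUCTURE_PATTERNS
    if _SUBSTRUCTURE_PATTERNS is None:
        raw = _load_json("substructure_patterns.json")
        _SUBSTRUCTURE_PATTERNS = [
            (p["name"], Chem.MolFromSmarts(p["smarts"])) for p in raw["patterns"]
        ]
    return _SUBSTRUCTURE_PATTERNS


def is_carbohydrate(mol: Chem.Mol) -> bool:
    """Pyranose/furanose detector: a 5- or 6-membered saturated ring with a
    single ring oxygen, all-carbon otherwise, carrying >=2 hydroxyls on its
    ring carbons."""
    ri = mol.GetRingInfo()
    for ring in ri.AtomRings():
        if len(ring) not in (5, 6):
            continue
        ring_set = set(ring)
        oxygens = [i for i in ring if mol.GetAtomWithIdx(i).GetSymbol() == "O"]
        carbons = [i for i in ring if mol.GetAtomWithIdx(i).GetSymbol() == "C"]
        if len(oxygens) != 1 or len(carbons) != len(ring) - 1:
            continue
        if any(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            continue
        n_hydroxyl = 0
        for c in carbons:
            for nbr in mol.GetAtomWithIdx(c).GetNeighbors():
                if nbr.GetIdx() in ring_set:
                    continue
                if (
                    nbr.GetSymbol() == "O"
                    and nbr.GetDegree() == 1
                    and nbr.GetTotalNumHs() >= 1
                ):
                    n_hydroxyl += 1
        if n_hydroxyl >= 2:
            return True
    return False


def flag_undesired(mol: Chem.Mol) -> set[str]:
    """Undesired-substructure tags on any molecule (fragment or assembled)."""
    tags = {name for name, patt in undesired_patterns() if mol.HasSubstructMatch(patt)}
    if is_carbohydrate(mol):
        tags.add("carbohydrate")
    return tags


def filter_fragment(frag: Fragment3D, mw_cap: float = FRAGMENT_MW_CAP) -> FragmentFilterVerdict:
    """Library admission test: drop heavy fragments and pharmacokinetically
    undesired chemotypes (phosphate, carbohydrate, ester, acyclic N-N/N-O/O-O)."""
    reasons = []
    if frag.mw > mw_cap:
        reasons.append("mw_gt_300")
    reasons.extend(sorted(flag_undesired(frag.mol)))
    return FragmentFilterVerdict(frag.fragment_id, kept=not reasons, reasons=tuple(reasons))


# ---------------------------------------------------------------------------
# in-frame RMSD and deduplication
# ---------------------------------------------------------------------------

_MAX_AUTOMORPHISMS = 5000


def _inplace_rmsd_mols(ma: Chem.Mol, mb: Chem.Mol) -> float:
    matches = mb.GetSubstructMatches(
        ma, uniquify=False, useChirality=False, maxMatches=_MAX_AUTOMORPHISMS
    )
    if not matches:
        raise ValueError("structures are not isomorphic; RMSD undefined")
    pa = np.asarray(ma.GetConformer().GetPositions(), dtype=float)
    pb = np.asarray(mb.GetConformer().GetPositions(), dtype=float)
    best = np.inf
    for match in matches:
        diff = pa - pb[list(match)]
        rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
        best = min(best, rmsd)
    return best


def compute_inplace_rmsd(a: Fragment3D, b: Fragment3D) -> float:
    """Symmetry-aware heavy-atom RMSD in the shared frame (no superposition).

    Only defined between fragments of identical canonical form; the mapping
    minimizing the RMSD over all graph automorphisms is used.
    """
    if a.canonical_form != b.canonical_form:
        raise ValueError(
            "cannot compare fragments with different canonical forms: "
            f"{a.canonical_form} vs {b.canonical_form}"
        )
    return _inplace_rmsd_mols(a.mol, b.mol)


def deduplicate_fragments(
    frags: list[Fragment3D], rmsd_cut: float = FRAGMENT_DEDUP_RMSD
) -> list[Fragment3D]:
    """Greedy keep-first removal of in-frame near-duplicates.

    Fragments are ordered deterministically (provenance, then id), grouped
    by canonical form, and a fragment is dropped when an already-kept
    group member lies within ``rmsd_cut``.  Distinct 3D orientations of
    the same 2D structure all survive.
    """
    if rmsd_cut <= 0:
        raise ValueError("rmsd_cut must be positive")
    ordered = sorted(frags, key=lambda f: (f.provenance.as_tuple(), f.fragment_id))
    kept_by_form: dict[str, list[Fragment3D]] = {}
    survivors = []
    for frag in ordered:
        group = kept_by_form.setdefault(frag.canonical_form, [])
        if any(compute_inplace_rmsd(frag, other) < rmsd_cut for other in group):
            continue
        group.append(frag)
        survivors.append(frag)
    return survivors
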