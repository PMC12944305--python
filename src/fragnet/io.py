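"""Standard-format I/O: SDF in/out with structured data fields, reference
libraries for novelty search, and tabular reports."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from rdkit import Chem

from .assemble import AssembledMolecule
from .fragments import Fragment3D, Provenance

__all__ = [
    "read_ligands_sdf",
    "write_fragments_sdf",
    "read_fragments_sdf",
    "fragment_index",
    "write_molecules_sdf",
    "read_library",
]


def read_ligands_sdf(path: str | Path) -> list[Chem.Mol]:
    """All valid 3D records of an SDF (V2000/V3000), hydrogens stripped."""
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    mols = [m for m in supplier if m is not None]
    if not mols:
        raise ValueError(f"no valid molecules in {path}")
    return mols


def write_fragments_sdf(frags: list[Fragment3D], path: str | Path) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for f in frags:
            mol = Chem.Mol(f.mol)
            mol.SetProp("_Name", f.fragment_id)
            mol.SetProp("fragment_id", f.fragment_id)
            mol.SetProp("free_valence", ",".join(str(v) for v in f.free_valence))
            mol.SetProp("canonical_form", f.canonical_form)
            mol.SetProp("mw", f"{f.mw:.3f}")
            mol.SetProp("ligand_id", f.provenance.ligand_id)
            mol.SetProp("structure_id", f.provenance.structure_id)
            mol.SetProp("chain", f.provenance.chain)
            mol.SetProp("method", f.provenance.method)
            writer.write(mol)
    finally:
        writer.close()


def read_fragments_sdf(path: str | Path) -> list[Fragment3D]:
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    frags = []
    for mol in supplier:
        if mol is None:
            continue
        fv = tuple(int(v) for v in mol.GetProp("free_valence").split(","))
        prov = Provenance(
            ligand_id=mol.GetProp("ligand_id"),
            structure_id=mol.GetProp("structure_id"),
            chain=mol.GetProp("chain"),
            method=mol.GetProp("method"),
        )
        frags.append(Fragment3D(mol, fv, prov, fragment_id=mol.GetProp("fragment_id")))
    if not frags:
        raise ValueError(f"no fragments in {path}")
    return frags


def fragment_index(frags: list[Fragment3D]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "fragment_id": [f.fragment_id for f in frags],
            "canonical_form": [f.canonical_form for f in frags],
            "mw": [round(f.mw, 3) for f in frags],
            "ligand_id": [f.provenance.ligand_id for f in frags],
            "structure_id": [f.provenance.structure_id for f in frags],
            "chain": [f.provenance.chain for f in frags],
            "method": [f.provenance.method for f in frags],
        }
    )


def write_molecules_sdf(mols: list[AssembledMolecule], path: str | Path) -> None:
    """Self-describing result records: every molecule carries its fragment
    path, per-junction bond metadata, descriptors and filter verdicts."""
    writer = Chem.SDWriter(str(path))
    try:
        for am in mols:
            mol = Chem.Mol(am.mol)
            mol.SetProp("_Name", am.name)
            mol.SetProp("path_fragments", "|".join(am.path.fragment_ids))
            mol.SetProp("cumulative_mw", f"{am.path.cumulative_mw:.3f}")
            mol.SetProp("atom_provenance", "|".join(am.atom_provenance))
            links = [
                {
                    "atom_a": c.atom_a,
                    "atom_b": c.atom_b,
                    "bond_order": c.bond_order,
                    "measured_distance": round(c.measured_distance, 4),
                    "reference_distance": c.reference_distance,
                }
                for c in am.path.chosen_links
            ]
            mol.SetProp("junctions", json.dumps(links))
            if am.descriptors is not None:
                d = am.descriptors
                mol.SetProp("mw", f"{d.mw:.3f}")
                mol.SetProp("tpsa", f"{d.tpsa:.3f}")
                mol.SetProp("clogp", f"{d.clogp:.3f}")
                mol.SetProp("hba", str(d.hba))
                mol.SetProp("hbd", str(d.hbd))
                mol.SetProp("nrb", str(d.nrb))
                mol.SetProp("nar", str(d.nar))
                mol.SetProp("nca", str(d.nca))
                mol.SetProp("sa_score", f"{d.sa_score:.3f}")
                mol.SetProp("qed", f"{d.qed:.4f}")
                mol.SetProp("cns_mpo", f"{d.cns_mpo:.3f}")
                mol.SetProp("largest_ring_size", str(d.largest_ring_size))
            for key, value in getattr(am, "verdicts", {}).items():
                mol.SetProp(key, str(value))
            writer.write(mol)
    finally:
        writer.close()


def read_library(path: str | Path) -> list[tuple[str, Chem.Mol]]:
    """Reference compounds for novelty search, from SDF or SMILES files."""
    path = Path(path)
    out: list[tuple[str, Chem.Mol]] = []
    if path.suffix.lower() in (".smi", ".smiles", ".txt"):
        for k, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            mol = Chem.MolFromSmiles(parts[0])
            if mol is None:
                continue
            cid = parts[1] if len(parts) > 1 else f"{path.stem}:{k}"
            out.append((cid, mol))
    else:
        for k, mol in enumerate(Chem.SDMolSupplier(str(path), removeHs=True)):
            if mol is None:
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            out.append((name or f"{path.stem}:{k}", mol))
    if not out:
        raise ValueError(f"no reference compounds in {path}")
    return out
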