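# fragnet

**fragnet** grows candidate protein-kinase inhibitors from a 3D fragment
network. When many kinase–ligand complexes are superimposed into a common
binding-site frame, the fragments of their co-crystallized ligands become a
reusable 3D vocabulary: two fragments that happen to sit at covalent-bond
distance in that frame can be joined into a new molecule *without moving a
single atom*, because each already occupies an experimentally observed
pose. No docking, minimization or cavity exploration happens during
generation — geometric plausibility is enforced by force-field-derived
reference values at each junction.

It is written for computational and medicinal chemists doing
structure-based fragment growing: given aligned 3D ligands (SDF), an
aligned target structure (PDB) and a seed fragment positioned in the site
(typically the hinge binder), it enumerates every chemically and
geometrically valid assembly and pushes the results through a
kinase-inhibitor-likeness filter cascade.

## The model in brief

* **Fragment library.** Ligands are cut by BRICS, RECAP-style and
  ring/linker rule-sets, preserving coordinates; severed bonds become
  integer *free valences* (open bonding slots). Fragments > 300 Da or
  containing a phosphate, carbohydrate, ester or acyclic N–N/N–O/O–O motif
  are removed; near-duplicates (same canonical SMILES, in-frame RMSD
  < 0.25 Å) are collapsed, keeping distinct 3D orientations.
* **Fragment network.** Every fragment pair is classified as
  **inclusion** (a free-valence atom pair within `distance_pct`% of the
  reference bond length for the typed pair, with bend/out-of-plane/torsion
  angles within their tolerances), **exclusion** (steric clash below
  1.4 Å, or bonding distance with unrealistic angles — such pairs can
  never coexist in one molecule), or no relation (too far apart).
  Fragment–protein **compatibility** requires no approach below 1.4 Å and
  at least one contact within 3.5 Å.
* **Growth.** From the seed, all simple paths through the inclusion graph
  Gi are enumerated; a path is vetoed if *any* of its fragment pairs is in
  the exclusion graph Ge. Growth stops at 650 Da. Paths become molecules
  (one new bond per junction, coordinates untouched), deduplicated at
  1.0 Å RMSD.
* **Filters.** Kinase-inhibitor-likeness windows (MW 314–613, TPSA
  55–138, ClogP 0.7–6.3, HBA 3–10, HBD 0–4, rotatable bonds 1–11,
  aromatic rings 1–5, chiral atoms 0–2; ≤ 2 violations allowed), PAINS
  and undesired substructures, synthetic accessibility (< 4; < 5 for
  macrocycles, gated at largest ring ≥ 11), QED and CNS MPO scoring,
  optional pose-agreement gate (< 2.5 Å vs. externally docked poses) and
  Tanimoto novelty search (≥ 0.7) against reference libraries.

See `docs/methods.md` for the full model description, parameter semantics
and limitations.

## Worked example

The package ships a deterministic fixture generator (aligned chain ligands
with known answer keys), so the whole pipeline runs without any external
data. Build a five-ring fixture ligand, a pseudo-atom pocket shell, and
grow from the first library fragment with the `bcr-abl` distortion preset
(torsion/OOP/dihedral 15°, distance 10%):

```python
from rdkit import Chem
from fragnet import FixtureSpec, RunConfig, make_chain_ligand, run_pipeline
from fragnet.fixtures import make_pocket_shell

lig, _frags, _adj = make_chain_ligand(FixtureSpec(n_fragments=6, seed=7))
w = Chem.SDWriter("ligand.sdf"); w.write(lig); w.close()
# (write the shell as a PDB, or pass your own aligned protein structure)

cfg = RunConfig(ligands_sdf="ligand.sdf", protein_pdb="pocket.pdb",
                seed_index=0, preset="bcr-abl", outdir="out")
result = run_pipeline(cfg)
print(result.funnel.to_string(index=False))
```

which prints the stage funnel:

```
               stage  n_in  n_out
     fragment_filter    18     18
      fragment_dedup    18      6
pocket_compatibility     6      3
          generation     2      2
      molecule_dedup     2      2
            pki_like     2      2
 substructures_pains     2      2
            sa_score     2      2
```

Three rule-sets cut the 6-ring ligand into 18 fragments that deduplicate
to the 6 distinct rings; only the 3 rings near the pocket shell are
compatible with the target, so growth from the seed yields the 2 possible
chain prefixes, both passing every filter. The final molecules (in
`out/molecules.sdf`, with per-fragment provenance, junction metadata and
descriptors as SDF fields):

```
c1cnc(-c2cncnc2)cn1                 MW 158.2  TPSA 51.6  ClogP 0.93  SA 2.32  QED 0.619
c1cnc(-c2cnc(-c3cncnc3)cn2)cn1      MW 236.2  TPSA 77.3  ClogP 1.39  SA 2.56  QED 0.669
```

The same run is available from the shell: `fragnet fixtures generate`,
`fragnet library build`, `fragnet graph build`, `fragnet grow --config
run.yaml`, plus `fragnet filter`, `fragnet novelty` and `fragnet
roundtrip` (which fragments fixture ligands and rebuilds them from every
seed — printing, e.g., `recovered from 20/20 seeds (100.00%)`).

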