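# Methods

## The model

`fragnet` implements a structure-based fragment growing/linking engine for
kinase inhibitor design. Its premise: when many protein–ligand complexes
are superimposed into one binding-site frame, the fragments of their
ligands form a reusable 3D vocabulary. Two fragments that happen to sit at
covalent-bonding distance in that shared frame — even if they came from
different crystal structures — can be joined into a new molecule *without
moving any atom*, because each fragment already occupies an experimentally
observed pose. No minimization, conformer search or cavity exploration is
performed anywhere in the pipeline; geometric plausibility is enforced
purely by force-field-derived reference values at the junctions.

The engine operates on three relations over the fragment set:

* **inclusion** — two fragments can form a covalent bond: a pair of
  free-valence atoms sits within the allowed distance window around the
  reference bond length for that typed atom pair, and the junction angles
  are within their allowed deviations (details below);
* **exclusion** — the fragments can never coexist in one molecule: any
  inter-fragment atom pair closer than 1.4 Å (steric clash), or a
  bonding-distance candidate whose angles are unrealistic beyond the
  distortion ceiling;
* **compatibility** — a fragment fits a given target pocket.

Growth starts from a *seed* fragment positioned in the site (typically the
hinge binder). All simple paths from the seed through the inclusion graph
Gi are enumerated; a path is vetoed when *any* pair of its fragments —
adjacent or not — appears in the exclusion graph Ge. Each surviving path
is materialized by creating one covalent bond per junction (hydrogens
displaced by the new bonds vanish implicitly; aromaticity is
re-perceived), then the result set is deduplicated and filtered.

## Fragment library

Ligands are cut by three rule-sets — BRICS (via the published bond
finder), a RECAP-style pattern set, and a scaffold-oriented ring/linker
splitter — with all matching bonds of a rule-set cut simultaneously.
The RECAP and scaffold patterns are pinned in
`src/fragnet/data/cleavage_rules.json`; using several rule-sets enlarges
the fragment vocabulary. Every severed bond adds its order to the
endpoint's *free valence*, an integer attachment capacity (one atom may
accept several links); coordinates are inherited untouched.

Library admission removes fragments heavier than 300 Da and fragments
containing a phosphate, carbohydrate, ester, or acyclic N–N / N–O / O–O
motif (patterns pinned in `substructure_patterns.json`; the carbohydrate
test — a pyranose/furanose ring bearing ≥ 2 hydroxyls — is ring logic in
code and can be overridden by registering a pattern). The fragment weight
cap uses the full H-capped molecular weight; RMSD comparisons use heavy
atoms only.

Duplicates are removed per canonical SMILES group by a greedy keep-first
scan at 0.25 Å symmetry-aware in-frame RMSD (no superposition — all inputs
share the aligned frame; the atom mapping minimizing the RMSD over all
graph automorphisms is used). Input order for the scan is deterministic:
sorted by provenance, then fragment id. Distinct 3D orientations of the
same 2D structure deliberately survive.

## Junction geometry

Reference bond lengths are pinned per (element, hybridization) pair and
bond order in `bond_lengths.json`, derived from MMFF94-style equilibrium
values, with element-pair fallbacks; ideal bend angles follow
hybridization (sp³ 109.5°, sp²/aromatic 120°, sp 180°). When both atoms
offer two or more free valences, the bond order whose reference length is
nearest the measured distance is chosen (ties go to the lower order).

Four distortion parameters on a 0–45 scale bound the allowed deviation
from reference geometry; the three angle-type names are interpreted as:

* **dihedral** (`dihedral_deg`) — bend angles at both junction atoms
  against the hybridization ideal, worst heavy neighbor counted;
* **out-of-plane** (`oop_deg`) — angle between the nascent bond and the
  plane of a trigonal (sp²/aromatic) junction atom, against 0°;
* **torsion** (`torsion_deg`) — dihedral about the nascent bond against
  its nearest staggered minimum (sp³–sp³: ±60°, 180°) or planar minimum
  (any sp² end: 0°, 180°), worst neighbor pair counted;
* **distance** (`distance_pct`) — percent window around the reference
  bond length.

An angle whose deviation exceeds the 45° ceiling of the scale is treated
as unrealistic: if such a candidate sits at bonding distance, the pair is
*excluded* regardless of the run's tolerances. This keeps exclusion edges
tolerance-independent (only clashes and unrealistic geometry create them)
and makes the inclusion-edge set grow monotonically in every distortion
component — a property the test suite sweeps explicitly. All geometric
comparisons carry a 1e-6 float slack so exact reference geometry passes at
tolerance 0.

Named presets reproduce the published per-target growth settings
(torsion/OOP/dihedral/distance%): `bcr-abl` 15/15/15/10, `braf-v600e`
10/10/10/10, `melk-type-i` 10/10/10/10, `melk-type-ii` 14/14/14/12, `alk`
10/10/10/10.

## Pocket model and compatibility

The pocket is the set of protein heavy atoms within a radius (default
10 Å) of an anchor — a point or a reference ligand — extracted from a
pre-aligned PDB file by a plain distance scan (a deliberate simplification
of cavity-detection tooling; inputs are assumed aligned to the common
frame). Hydrogens are excluded, as crystal structures typically lack them.

The published compatibility window of 1.4–3.5 Å is ambiguous as written
(*all* fragment–protein distances inside the window would reject every
realistic fragment). It is read here as a clash floor and a contact
ceiling: compatible iff no fragment atom approaches the protein closer
than 1.4 Å **and** at least one fragment atom lies within 3.5 Å of it —
avoiding steric clashes while discarding fragments floating away from the
site. The contact condition is applied per fragment (any atom), not per
atom. Both readings of the thresholds are configurable on `PocketModel`.

## Growth

Path enumeration is depth-first from the seed: an extension is admitted
while the cumulative molecular weight is still below the cap (default
650 Da, the upper edge of the clinical kinase-inhibitor weight range), and
every intermediate path of ≥ 2 fragments is emitted, so the generator is
anytime. Cumulative weight is the sum of fragment weights minus 2 × 1.008
Da per junction bond order (displaced hydrogens). Free valences are
tracked along the path so two junctions cannot consume the same open slot;
at each junction the first feasible link candidate in a deterministic sort
(atom indices, then bond order) is chosen. Designated growth atoms
restrict which seed atoms may open links. Output ordering is deterministic
(path length, then fragment ids), making whole runs reproducible
byte-for-byte.

By default paths are linear chains. `allow_branching=True` enumerates
connected subtrees of Gi instead (each distinct tree once); the
reconstruction validation uses it because an interior seed of a chain
molecule must grow in two directions at once. Branching *within* a
fragment (a multi-valent atom) needs no special handling in either mode.

Molecule-level deduplication mirrors the fragment scan at 1.0 Å:
conformations of the same molecule further apart than that all survive.
Agreement between a generated molecule and an externally docked pose of
the same structure is measured as symmetry-aware in-frame RMSD, gated by
callers at 2.5 Å.

## Filter cascade

All stages are pure predicates on the molecule, so cascade order cannot
change verdicts, only the funnel counts. The kinase-inhibitor-likeness
window (closed intervals, boundary values pass) is MW 314–613 Da, TPSA
55–138 Å², ClogP 0.7–6.3, HBA 3–10, HBD 0–4, rotatable bonds 1–11,
aromatic rings 1–5, chiral atoms 0–2, with up to 2 of the 8 windows
violated. Chiral atoms count every potential stereocenter by default
(`nca_mode="all"`); assigned-only counting is available — generated
molecules inherit mostly unassigned stereocenters from their fragments.

Undesired-substructure tags are re-evaluated on the assembled molecule so
junction-created motifs (e.g. an acyclic N–N formed between two clean
fragments) are caught; PAINS matching uses the published catalog shipped
with the cheminformatics toolkit. Synthetic accessibility uses the
reference SA score implementation (1 easy – 10 hard; gate < 4, relaxed to
< 5 for macrocycles); drug-likeness uses QED. ClogP is the toolkit's
atom-contribution logP (the original ClogP algorithm is proprietary).

CNS MPO implements the published six-parameter desirability scheme
(ClogP, ClogD, MW, TPSA, HBD, most-basic pKa). No pKa predictor is a
dependency, so pKa is an optional argument whose absence scores the
component as fully desirable (neutral-compound assumption) and ClogD
defaults to ClogP; both can be supplied externally. The published
threshold of 4 is exposed as a configurable gate without fixing its
direction: desirability scores are conventionally good when *high*, yet
the source describes 4 as an *upper* threshold — an unresolved
discrepancy, so the gate is left to the caller.

Macrocycles are rings of ≥ 12 atoms; the screen gates at ≥ 11 atoms in the
largest smallest-set-of-smallest-rings ring to maximize yield. Novelty is
a Tanimoto search (2048-bit Morgan fingerprints, radius 2 — the
fingerprint type being unspecified in the source, this common default is
configurable) against user-supplied SDF/SMILES libraries at threshold
0.7; an empty hit list marks the molecule as new.

## Synthetic fixtures

The fixture generator builds linear chains of 2–n six-membered C/N
aromatic rings (benzene, pyridine, pyrazine, pyrimidine; junction vertices
always carbon) joined by single bonds at *exact* reference geometry:
regular hexagons of side 1.39 Å, junction bonds at the pinned
aromatic-C–aromatic-C length, 120° bends, coplanar rings. Restricting the
chemistry to ring–ring single bonds makes all three fragmentation
rule-sets cut identical bonds, removing rule-set disagreement from
round-trip tests. Jittered fixtures rigidly rotate each ring about its
entry atom (σ degrees) and translate it along the chain axis (σ Å),
distorting junction geometry only. Pocket shells place pseudo-atoms at
controlled distances above off-junction ring vertices, so compatibility
verdicts are known by construction.

Everything is deterministic under a fixed seed. These fixtures emulate
aligned-frame geometry and bookkeeping, not kinase pharmacophores,
hinge-binding chemistry, or crystallographic noise; a 100% fixture
reconstruction rate validates the engine's mechanics, not performance on
a real PDB-derived library (whose published reconstruction rate depends
on database coverage that is out of scope here).

## Problem sizes and numerical choices

The validation suite and the acceptance script use desk-scale problems
chosen to exercise every rule: 50 ideal fixtures of 3–6 fragments for
reconstruction; 1000 random ≤ 8-node graphs against a brute-force DFS
oracle; tolerance sweeps (0, 5, 10, 15, 30, 45) per component on jittered
fixtures (σ = 0.07 Å, 7°); 10,000 random descriptor vectors against a
brute-force window counter; planted near-duplicate sets against quadratic
greedy oracles; a ring ladder of sizes 6–15 for the macrocycle gate; and
byte-identity of repeated pipeline runs. Automorphism enumeration for
symmetry-aware RMSD is capped at 5000 mappings per pair.

## Known limitations

* Protonation states and tautomers are taken as given; no enumeration.
* The exclusion rule fires on any inter-fragment clash, including between
  fragments with no free-valence pair — the conservative reading.
* Whether a fragment node may occur twice in one path: simple-path
  semantics forbids node reuse (two identical chemotypes at different
  positions are distinct nodes and may co-occur).
* Docking is out of scope; pose agreement is computed against poses
  supplied as SDF by any docking engine.
* The graph lives in memory with JSON/CSV export; a graph-database
  backend would be an optional adapter, not a dependency.
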