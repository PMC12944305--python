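"""End-to-end workflow: library -> pocket -> graph -> growth -> filters.

Mirrors the tool's published workflow: fragment the aligned ligands,
admit/deduplicate fragments, model the pocket, build the fragment network,
grow from the seed, deduplicate conformations, then run the filter cascade
(kinase-inhibitor-likeness windows, undesired substructures and PAINS,
synthetic accessibility, optional macrocycle gate, optional pose-agreement
gate, optional novelty search) while logging a stage-by-stage funnel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml
from rdkit import Chem

from . import __version__
from .assemble import (
    MOLECULE_DEDUP_RMSD,
    MW_CAP,
    POSE_RMSD_GATE,
    assemble,
    deduplicate_molecules,
    enumerate_paths,
    pose_consistency,
)
from .filters import (
    FilterProfile,
    MACROCYCLE_SCREEN_MIN,
    SA_GATE,
    SA_GATE_MACROCYCLE,
    TC_THRESHOLD,
    compute_descriptors,
    flag_substructures,
    novelty_search,
)
from .fragments import (
    FRAGMENT_DEDUP_RMSD,
    Fragment3D,
    deduplicate_fragments,
    filter_fragment,
    fragment_ligand,
)
from .graph import DistortionParams, build_graph, split_graph
from .io import read_library, read_ligands_sdf, read_fragments_sdf, write_molecules_sdf
from .pocket import extract_pocket

__all__ = ["RunConfig", "RunResult", "PipelineError", "run_pipeline", "PRESETS"]

# named distortion presets from worked growth examples (torsion, oop, dihedral, distance%)
PRESETS = {
    "bcr-abl": DistortionParams(15, 15, 15, 10),
    "braf-v600e": DistortionParams(10, 10, 10, 10),
    "melk-type-i": DistortionParams(10, 10, 10, 10),
    "melk-type-ii": DistortionParams(14, 14, 14, 12),
    "alk": DistortionParams(10, 10, 10, 10),
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    ligands_sdf: str = ""
    protein_pdb: str = ""
    seed_sdf: str = ""
    seed_index: int | None = None  # alternative: pick a library fragment
    growth_atoms: tuple | None = None
    preset: str = ""
    params: DistortionParams = field(default_factory=DistortionParams)
    methods: tuple = ("brics", "recap", "scaffold_tree")
    pocket_radius: float = 10.0
    mw_cap: float = MW_CAP
    fragment_dedup_rmsd: float = FRAGMENT_DEDUP_RMSD
    molecule_dedup_rmsd: float = MOLECULE_DEDUP_RMSD
    pose_sdf: str = ""
    pose_rmsd_gate: float = POSE_RMSD_GATE
    profile: FilterProfile = field(default_factory=FilterProfile)
    macrocycle_mode: bool = False
    macrocycle_ring_min: int = MACROCYCLE_SCREEN_MIN
    novelty_libraries: tuple = ()
    tc_threshold: float = TC_THRESHOLD
    random_seed: int = 0
    outdir: str = "fragnet_out"

    def __post_init__(self):
        if self.preset:
            key = self.preset.lower()
            if key not in PRESETS:
                raise ValueError(f"unknown preset {self.preset!r}; known: {sorted(PRESETS)}")
            self.params = PRESETS[key]
        if isinstance(self.params, (list, tuple)):
            self.params = DistortionParams(*self.params)
        for name in ("mw_cap", "fragment_dedup_rmsd", "molecule_dedup_rmsd", "pose_rmsd_gate", "tc_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "params" in data and isinstance(data["params"], dict):
            data["params"] = DistortionParams(**data["params"])
        if "profile" in data and isinstance(data["profile"], dict):
            prof = {k: tuple(v) if isinstance(v, list) else v for k, v in data["profile"].items()}
            data["profile"] = FilterProfile(**prof)
        return cls(**data)


@dataclass
class RunResult:
    fragments: list
    graph: object
    paths: list
    molecules: list  # final survivors, descriptor-annotated
    funnel: pd.DataFrame
    manifest: dict
    outdir: Path


def _funnel_row(rows, stage, n_in, n_out):
    rows.append({"stage": stage, "n_in": n_in, "n_out": n_out})


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full workflow and write SDF results, a funnel CSV and a
    JSON run manifest into ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []

    # --- fragment library ----------------------------------------------------
    try:
        ligands = read_ligands_sdf(config.ligands_sdf)
        raw_frags = []
        for lig in ligands:
            raw_frags.extend(fragment_ligand(lig, config.methods))
        admitted = [f for f in raw_frags if filter_fragment(f).kept]
        _funnel_row(rows, "fragment_filter", len(raw_frags), len(admitted))
        frags = deduplicate_fragments(admitted, config.fragment_dedup_rmsd)
        _funnel_row(rows, "fragment_dedup", len(admitted), len(frags))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("library", str(exc)) from exc

    # --- seed -----------------------------------------------------------------
    try:
        if config.seed_sdf:
            seed_frag = read_fragments_sdf(config.seed_sdf)[0]
        elif config.seed_index is not None:
            seed_frag = frags[config.seed_index]
        else:
            raise ValueError("config must set seed_sdf or seed_index")
        if config.growth_atoms is not None and seed_frag.free_valence:
            bad = [
                i
                for i in config.growth_atoms
                if i >= len(seed_frag.free_valence) or seed_frag.free_valence[i] <= 0
            ]
            if bad:
                raise ValueError(f"growth atoms {bad} have no free valence on the seed")
        if seed_frag not in frags:
            frags = frags + [seed_frag]
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("seed", str(exc)) from exc

    # --- pocket ----------------------------------------------------------------
    pockets, target_id = [], None
    if config.protein_pdb:
        try:
            pocket = extract_pocket(
                config.protein_pdb, seed_frag, radius=config.pocket_radius
            )
            pocket.to_json(outdir / "pocket.json")
            pockets, target_id = [pocket], pocket.target_id
        except Exception as exc:
            raise PipelineError("pocket", str(exc)) from exc

    # --- graph -------------------------------------------------------------------
    try:
        graph = build_graph(frags, pockets, config.params)
        graph.to_json(outdir / "graph.json")
        gi, ge = split_graph(graph, target_id)
        if target_id is not None:
            _funnel_row(rows, "pocket_compatibility", len(graph.nodes), len(gi.nodes))
    except Exception as exc:
        raise PipelineError("graph", str(exc)) from exc

    # --- growth ---------------------------------------------------------------
    try:
        if seed_frag.fragment_id not in gi.nodes:
            raise ValueError("seed fragment is not compatible with the target pocket")
        paths = enumerate_paths(
            gi,
            ge,
            seed_frag.fragment_id,
            growth_atoms=config.growth_atoms,
            mw_cap=config.mw_cap,
        )
        store = {f.fragment_id: f for f in frags}
        built = [assemble(p, store) for p in paths]
        _funnel_row(rows, "generation", len(paths), len(built))
        mols = deduplicate_molecules(built, config.molecule_dedup_rmsd)
        _funnel_row(rows, "molecule_dedup", len(built), len(mols))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("growth", str(exc)) from exc

    # --- filter cascade ----------------------------------------------------------
    try:
        from .filters import pki_like, macrocycle_size

        for am in mols:
            am.descriptors = compute_descriptors(am.mol)
            am.verdicts = {}

        if config.macrocycle_mode:
            n_in = len(mols)
            for am in mols:
                am.verdicts["macrocycle"] = am.descriptors.largest_ring_size >= config.macrocycle_ring_min
            mols = [am for am in mols if am.verdicts["macrocycle"]]
            _funnel_row(rows, "macrocycle_gate", n_in, len(mols))
        else:
            n_in = len(mols)
            for am in mols:
                ok, violations = pki_like(am.descriptors, config.profile)
                am.verdicts["pki_like"] = ok
                am.verdicts["pki_violations"] = ",".join(violations)
            mols = [am for am in mols if am.verdicts["pki_like"]]
            _funnel_row(rows, "pki_like", n_in, len(mols))

        n_in = len(mols)
        for am in mols:
            tags = flag_substructures(am.mol)
            am.verdicts["substructure_tags"] = ";".join(sorted(tags))
        mols = [am for am in mols if not am.verdicts["substructure_tags"]]
        _funnel_row(rows, "substructures_pains", n_in, len(mols))

        sa_gate = SA_GATE_MACROCYCLE if config.macrocycle_mode else SA_GATE
        n_in = len(mols)
        for am in mols:
            am.verdicts["sa_pass"] = am.descriptors.sa_score < sa_gate
        mols = [am for am in mols if am.verdicts["sa_pass"]]
        _funnel_row(rows, "sa_score", n_in, len(mols))
    except Exception as exc:
        raise PipelineError("filters", str(exc)) from exc

    # --- pose-consistency gate (optional) -----------------------------------------
    if config.pose_sdf:
        try:
            poses = read_ligands_sdf(config.pose_sdf)
            by_form = {}
            for p in poses:
                by_form.setdefault(Chem.MolToSmiles(p), []).append(p)
            n_in = len(mols)
            survivors = []
            for am in mols:
                cands = by_form.get(am.canonical_form, [])
                rmsds = sorted(pose_consistency(am, p) for p in cands)
                am.verdicts["pose_rmsd"] = f"{rmsds[0]:.3f}" if rmsds else ""
                if rmsds and rmsds[0] < config.pose_rmsd_gate:
                    survivors.append(am)
            mols = survivors
            _funnel_row(rows, "pose_consistency", n_in, len(mols))
        except Exception as exc:
            raise PipelineError("pose", str(exc)) from exc

    # --- novelty (optional) ---------------------------------------------------------
    if config.novelty_libraries:
        try:
            library = []
            for lib in config.novelty_libraries:
                library.extend(read_library(lib))
            n_in = len(mols)
            for am in mols:
                hits = novelty_search(am.mol, library, config.tc_threshold)
                am.verdicts["novel"] = not hits
                am.verdicts["similar_compounds"] = ";".join(
                    f"{cid}:{tc:.2f}" for cid, tc in hits
                )
            mols = [am for am in mols if am.verdicts["novel"]]
            _funnel_row(rows, "novelty", n_in, len(mols))
        except Exception as exc:
            raise PipelineError("novelty", str(exc)) from exc

    # --- outputs ----------------------------------------------------------------------
    try:
        mols.sort(key=lambda am: (len(am.path.fragment_ids), am.path.fragment_ids))
        write_molecules_sdf(mols, outdir / "molecules.sdf")
        funnel = pd.DataFrame(rows, columns=["stage", "n_in", "n_out"])
        funnel.to_csv(outdir / "funnel.csv", index=False)
        manifest = {
            "version": __version__,
            "config": {
                **{
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in asdict(config).items()
                    if k not in ("params", "profile")
                },
                "params": asdict(config.params),
                "profile": asdict(config.profile),
            },
            "random_seed": config.random_seed,
            "n_final_molecules": len(mols),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    except Exception as exc:
        raise PipelineError("output", str(exc)) from exc

    return RunResult(
        fragments=frags,
        graph=graph,
        paths=paths,
        molecules=mols,
        funnel=funnel,
        manifest=manifest,
        outdir=outdir,
    )
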