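"""The 3D fragment network.

Fragments become nodes; unordered fragment pairs are classified into three
mutually exclusive verdicts by the geometry of their free-valence atoms:

* **inclusion** - some free-valence atom pair sits at a covalent-bond
  distance (within the allowed percentage of the force-field reference
  length for the typed atom pair) and the junction angles are within the
  allowed deviation from their ideal values.  The edge stores one
  :class:`LinkCandidate` per viable atom pair.
* **exclusion** - the two fragments can never coexist in one molecule:
  any inter-fragment atom pair below the clash threshold, or a candidate
  atom pair at bonding distance whose angles are unrealistic beyond repair
  (outside the 45-degree ceiling of the distortion scale).  Exclusion is
  therefore independent of the run's distortion tolerances.
* **none** - the fragments are simply too far apart to interact.

Fragment-protein compatibility edges complete the graph, which is split
per target into the inclusion graph Gi and the exclusion graph Ge before
molecule growth.

Four distortion parameters bound the allowed deviation from reference
geometry: three angle tolerances in degrees (torsion, out-of-plane,
dihedral/bend) and one distance tolerance in percent of the reference bond
length.  All live on a 0-45 scale; 0 admits only perfect geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from itertools import combinations
from pathlib import Path

import numpy as np

from .fragments import Fragment3D, hybridization_tag
from .pocket import PocketModel, check_compatibility

__all__ = [
    "DistortionParams",
    "AngleCheck",
    "LinkCandidate",
    "PairVerdict",
    "FragmentGraph",
    "reference_geometry",
    "evaluate_pair",
    "build_graph",
    "split_graph",
    "CLASH_THRESHOLD",
    "MAX_DISTORTION",
]

CLASH_THRESHOLD = 1.4  # angstrom, inter-fragment steric clash
MAX_DISTORTION = 45.0  # ceiling of the distortion scale (degrees / percent)
_EPS = 1e-6  # float slack so ideal geometry passes at tolerance 0


@dataclass(frozen=True)
class DistortionParams:
    """Allowed deviations from reference junction geometry.

    ``dihedral_deg`` bounds the bend angles at both junction atoms,
    ``oop_deg`` the out-of-plane angle at trigonal junction atoms, and
    ``torsion_deg`` the torsion about the nascent bond relative to its
    nearest staggered (sp3-sp3) or planar (any sp2) minimum.
    ``distance_pct`` is the bond-length window in percent of the reference.
    """

    torsion_deg: float = 10.0
    oop_deg: float = 10.0
    dihedral_deg: float = 10.0
    distance_pct: float = 10.0

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not 0 <= v <= MAX_DISTORTION:
                raise ValueError(f"{name} must be in [0, {MAX_DISTORTION}], got {v}")

    def as_tuple(self):
        return (self.torsion_deg, self.oop_deg, self.dihedral_deg, self.distance_pct)


@dataclass(frozen=True)
class AngleCheck:
    name: str  # bend_a | bend_b | oop_a | oop_b | torsion
    measured: float
    reference: float
    allowed: float

    @property
    def deviation(self) -> float:
        return abs(self.measured - self.reference)

    @property
    def ok(self) -> bool:
        return self.deviation <= self.allowed + _EPS


@dataclass(frozen=True)
class LinkCandidate:
    """A concrete bond proposal between atom_a of fragment A and atom_b of B."""

    atom_a: int
    atom_b: int
    bond_order: int
    measured_distance: float
    reference_distance: float
    angle_checks: tuple[AngleCheck, ...] = ()

    def swapped(self) -> "LinkCandidate":
        swap = {"bend_a": "bend_b", "bend_b": "bend_a", "oop_a": "oop_b", "oop_b": "oop_a"}
        return LinkCandidate(
            atom_a=self.atom_b,
            atom_b=self.atom_a,
            bond_order=self.bond_order,
            measured_distance=self.measured_distance,
            reference_distance=self.reference_distance,
            angle_checks=tuple(
                AngleCheck(swap.get(c.name, c.name), c.measured, c.reference, c.allowed)
                for c in self.angle_checks
            ),
        )


# ---------------------------------------------------------------------------
# reference geometry table
# ---------------------------------------------------------------------------

_GEOM = None


def _geometry_table():
    global _GEOM
    if _GEOM is None:
        with resources.files("fragnet.data").joinpath("bond_lengths.json").open() as fh:
            raw = json.load(fh)
        typed = {}
        for a, b, order, length in raw["typed"]:
            typed[(a, b, order)] = length
            typed[(b, a, order)] = length
        fallback = {}
        for a, b, order, length in raw["fallback"]:
            fallback[(a, b, order)] = length
            fallback[(b, a, order)] = length
        _GEOM = {"typed": typed, "fallback": fallback, "bend": raw["bend_ideal_deg"]}
    return _GEOM


def reference_geometry(
    element_a: str, hyb_a: str, element_b: str, hyb_b: str, bond_order: int
) -> tuple[float, tuple[float, float]]:
    """Reference bond length and ideal bend angles for a typed atom pair.

    Falls back to an element-pair default length when the exact typed
    entry is not pinned; raises ``KeyError`` naming the missing entry when
    neither exists.
    """
    geom = _geometry_table()
    key = (f"{element_a}.{hyb_a}", f"{element_b}.{hyb_b}", int(bond_order))
    length = geom["typed"].get(key)
    if length is None:
        length = geom["fallback"].get((element_a, element_b, int(bond_order)))
    if length is None:
        raise KeyError(
            f"no reference bond length for {element_a}.{hyb_a}-{element_b}.{hyb_b} "
            f"order {bond_order}; add it to data/bond_lengths.json"
        )
    bend = geom["bend"]
    return length, (bend[hyb_a], bend[hyb_b])


# ---------------------------------------------------------------------------
# angle machinery
# ---------------------------------------------------------------------------


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return 0.0
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _dihedral_deg(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def _circular_deviation(measured: float, ideals) -> tuple[float, float]:
    """Smallest angular distance (deg) from measured to any ideal torsion."""
    best_dev, best_ideal = 1e9, 0.0
    for ideal in ideals:
        d = abs((measured - ideal + 180.0) % 360.0 - 180.0)
        if d < best_dev:
            best_dev, best_ideal = d, ideal
    return best_dev, best_ideal


def _heavy_neighbors(frag: Fragment3D, idx: int) -> list[int]:
    return [n.GetIdx() for n in frag.mol.GetAtomWithIdx(idx).GetNeighbors()]


def _oop_angle(center: np.ndarray, neighbors: np.ndarray, target: np.ndarray) -> float:
    """Angle between the center->target vector and the plane of the center
    and its (>=2) neighbors; 0 for perfectly in-plane growth."""
    v1 = neighbors[0] - center
    v2 = neighbors[1] - center
    normal = np.cross(v1, v2)
    nn = np.linalg.norm(normal)
    if nn == 0:
        return 0.0
    u = target - center
    sin_oop = np.clip(np.dot(u / np.linalg.norm(u), normal / nn), -1.0, 1.0)
    return float(abs(np.degrees(np.arcsin(sin_oop))))


def _junction_angle_checks(
    a: Fragment3D,
    b: Fragment3D,
    ai: int,
    bi: int,
    ideal_bend: tuple[float, float],
    params: DistortionParams,
) -> tuple[AngleCheck, ...]:
    pa, pb = a.coords, b.coords
    hyb_a = hybridization_tag(a.mol.GetAtomWithIdx(ai))
    hyb_b = hybridization_tag(b.mol.GetAtomWithIdx(bi))
    nbrs_a = _heavy_neighbors(a, ai)
    nbrs_b = _heavy_neighbors(b, bi)
    checks: list[AngleCheck] = []

    for label, frag_pts, idx, other_pt, nbrs, ideal in (
        ("bend_a", pa, ai, pb[bi], nbrs_a, ideal_bend[0]),
        ("bend_b", pb, bi, pa[ai], nbrs_b, ideal_bend[1]),
    ):
        if not nbrs:
            continue
        worst_meas, worst_dev = ideal, -1.0
        for n in nbrs:
            meas = _angle_deg(frag_pts[n] - frag_pts[idx], other_pt - frag_pts[idx])
            dev = abs(meas - ideal)
            if dev > worst_dev:
                worst_meas, worst_dev = meas, dev
        checks.append(AngleCheck(label, worst_meas, ideal, params.dihedral_deg))

    for label, frag, frag_pts, idx, other_pt, nbrs, hyb in (
        ("oop_a", a, pa, ai, pb[bi], nbrs_a, hyb_a),
        ("oop_b", b, pb, bi, pa[ai], nbrs_b, hyb_b),
    ):
        if hyb in ("sp2", "aromatic") and len(nbrs) >= 2:
            oop = _oop_angle(frag_pts[idx], frag_pts[nbrs][: 2], other_pt)
            checks.append(AngleCheck(label, oop, 0.0, params.oop_deg))

    if nbrs_a and nbrs_b and hyb_a != "sp" and hyb_b != "sp":
        if hyb_a == "sp3" and hyb_b == "sp3":
            ideals = (60.0, 180.0, 300.0)  # staggered minima
        else:
            ideals = (0.0, 180.0)  # planar minima
        worst_dev, worst_meas, worst_ideal = -1.0, 0.0, ideals[0]
        for na in nbrs_a:
            for nb in nbrs_b:
                tors = _dihedral_deg(pa[na], pa[ai], pb[bi], pb[nb]) % 360.0
                dev, ideal = _circular_deviation(tors, ideals)
                if dev > worst_dev:
                    worst_dev, worst_meas, worst_ideal = dev, tors, ideal
        checks.append(AngleCheck("torsion", worst_meas, worst_ideal, params.torsion_deg))

    return tuple(checks)


# ---------------------------------------------------------------------------
# pair evaluation
# ---------------------------------------------------------------------------

_MAX_PARAMS = None


def _max_params() -> DistortionParams:
    global _MAX_PARAMS
    if _MAX_PARAMS is None:
        _MAX_PARAMS = DistortionParams(
            MAX_DISTORTION, MAX_DISTORTION, MAX_DISTORTION, MAX_DISTORTION
        )
    return _MAX_PARAMS


@dataclass(frozen=True)
class PairVerdict:
    kind: str  # inclusion | exclusion | none
    candidates: tuple[LinkCandidate, ...] = ()
    reason: str = ""


def _select_bond_order(frag_a, frag_b, ai, bi, distance):
    """Pick the bond order whose reference length is nearest the measured
    distance (ties -> lowest order), limited by both free valences."""
    ea, eb = frag_a.mol.GetAtomWithIdx(ai).GetSymbol(), frag_b.mol.GetAtomWithIdx(bi).GetSymbol()
    ha = hybridization_tag(frag_a.mol.GetAtomWithIdx(ai))
    hb = hybridization_tag(frag_b.mol.GetAtomWithIdx(bi))
    max_order = min(frag_a.free_valence[ai], frag_b.free_valence[bi], 3)
    best = None
    for order in range(1, max_order + 1):
        try:
            length, bend = reference_geometry(ea, ha, eb, hb, order)
        except KeyError:
            continue
        gap = abs(distance - length)
        if best is None or gap < best[0] - _EPS:
            best = (gap, order, length, bend)
    if best is None:
        return None
    _gap, order, length, bend = best
    return order, length, bend


def evaluate_pair(
    a: Fragment3D,
    b: Fragment3D,
    params: DistortionParams,
    clash_threshold: float = CLASH_THRESHOLD,
) -> PairVerdict:
    """Classify an unordered fragment pair as inclusion / exclusion / none.

    Candidate atoms in the returned LinkCandidates are oriented (atom_a in
    ``a``, atom_b in ``b``).  Exclusion depends only on the geometry, never
    on ``params``: it fires on a steric clash anywhere between the two
    fragments, or on a bonding-distance candidate whose angles deviate
    beyond the 45-degree distortion ceiling.
    """
    pa, pb = a.coords, b.coords
    diffs = pa[:, None, :] - pb[None, :, :]
    dists = np.sqrt(np.sum(diffs * diffs, axis=2))
    if float(dists.min()) < clash_threshold - _EPS:
        return PairVerdict("exclusion", reason="steric_clash")

    max_p = _max_params()
    candidates: list[LinkCandidate] = []
    irreparable = False
    for ai in a.attachment_atoms:
        for bi in b.attachment_atoms:
            d = float(dists[ai, bi])
            sel = _select_bond_order(a, b, ai, bi, d)
            if sel is None:
                continue
            order, ref_len, ideal_bend = sel
            max_window = ref_len * max_p.distance_pct / 100.0
            if abs(d - ref_len) > max_window + _EPS:
                continue  # beyond any admissible window: no relation
            checks = _junction_angle_checks(a, b, ai, bi, ideal_bend, params)
            if any(c.deviation > MAX_DISTORTION + _EPS for c in checks):
                irreparable = True
                continue
            window = ref_len * params.distance_pct / 100.0
            if abs(d - ref_len) <= window + _EPS and all(c.ok for c in checks):
                candidates.append(
                    LinkCandidate(ai, bi, order, d, ref_len, checks)
                )
    if irreparable:
        return PairVerdict("exclusion", reason="unrealistic_angle")
    if candidates:
        candidates.sort(key=lambda c: (c.atom_a, c.atom_b, c.bond_order))
        return PairVerdict("inclusion", candidates=tuple(candidates))
    return PairVerdict("none")


# ---------------------------------------------------------------------------
# the graph container
# ---------------------------------------------------------------------------


@dataclass
class FragmentGraph:
    """Nodes plus inclusion/exclusion/compatibility relations.

    Inclusion candidates for a pair are stored under the sorted id pair,
    oriented from the smaller to the larger id.  ``nodes`` maps fragment id
    to its attributes (mw and free_valence, needed during growth).
    """

    nodes: dict = field(default_factory=dict)
    inclusion_edges: dict = field(default_factory=dict)
    exclusion_edges: set = field(default_factory=set)
    compatibility: dict = field(default_factory=dict)

    # -- construction --------------------------------------------------------

    def add_node(self, fragment_id: str, mw: float, free_valence=()) -> None:
        self.nodes[fragment_id] = {
            "mw": float(mw),
            "free_valence": tuple(int(v) for v in free_valence),
        }
        self.compatibility.setdefault(fragment_id, set())

    @staticmethod
    def _key(u: str, v: str) -> tuple[str, str]:
        return (u, v) if u <= v else (v, u)

    def add_inclusion(self, u: str, v: str, candidates) -> None:
        key = self._key(u, v)
        if key in self.exclusion_edges:
            raise ValueError(f"pair {key} is already an exclusion edge")
        if key[0] != u:
            candidates = [c.swapped() for c in candidates]
        self.inclusion_edges[key] = tuple(candidates)

    def add_exclusion(self, u: str, v: str) -> None:
        key = self._key(u, v)
        if key in self.inclusion_edges:
            raise ValueError(f"pair {key} is already an inclusion edge")
        self.exclusion_edges.add(key)

    # -- queries ---------------------------------------------------------------

    def inclusion_neighbors(self, u: str) -> list[str]:
        out = []
        for x, y in self.inclusion_edges:
            if x == u:
                out.append(y)
            elif y == u:
                out.append(x)
        return sorted(out)

    def candidates(self, u: str, v: str) -> tuple[LinkCandidate, ...]:
        """Link candidates oriented from u to v."""
        key = self._key(u, v)
        cands = self.inclusion_edges.get(key, ())
        if key[0] != u:
            cands = tuple(c.swapped() for c in cands)
        return cands

    def excluded(self, u: str, v: str) -> bool:
        return self._key(u, v) in self.exclusion_edges

    # -- serialization ---------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "nodes": {
                k: {"mw": v["mw"], "free_valence": list(v["free_valence"])}
                for k, v in self.nodes.items()
            },
            "inclusion_edges": [
                {
                    "pair": list(pair),
                    "candidates": [
                        {
                            "atom_a": c.atom_a,
                            "atom_b": c.atom_b,
                            "bond_order": c.bond_order,
                            "measured_distance": c.measured_distance,
                            "reference_distance": c.reference_distance,
                            "angle_checks": [
                                [ch.name, ch.measured, ch.reference, ch.allowed]
                                for ch in c.angle_checks
                            ],
                        }
                        for c in cands
                    ],
                }
                for pair, cands in sorted(self.inclusion_edges.items())
            ],
            "exclusion_edges": sorted(list(p) for p in self.exclusion_edges),
            "compatibility": {k: sorted(v) for k, v in self.compatibility.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FragmentGraph":
        d = json.loads(Path(path).read_text())
        g = cls()
        for k, v in d["nodes"].items():
            g.add_node(k, v["mw"], v["free_valence"])
        for e in d["inclusion_edges"]:
            u, v = e["pair"]
            cands = [
                LinkCandidate(
                    c["atom_a"],
                    c["atom_b"],
                    c["bond_order"],
                    c["measured_distance"],
                    c["reference_distance"],
                    tuple(AngleCheck(*ch) for ch in c["angle_checks"]),
                )
                for c in e["candidates"]
            ]
            g.inclusion_edges[(u, v)] = tuple(cands)
        for u, v in d["exclusion_edges"]:
            g.exclusion_edges.add((u, v))
        for k, v in d["compatibility"].items():
            g.compatibility[k] = set(v)
        return g

    def to_networkx(self):
        import networkx as nx

        G = nx.Graph()
        for k, attrs in self.nodes.items():
            G.add_node(k, **attrs)
        for (u, v), cands in self.inclusion_edges.items():
            G.add_edge(u, v, kind="inclusion", candidates=cands)
        for u, v in self.exclusion_edges:
            G.add_edge(u, v, kind="exclusion")
        return G


def build_graph(
    frags: list[Fragment3D],
    pockets: list[PocketModel],
    params: DistortionParams,
    clash_threshold: float = CLASH_THRESHOLD,
) -> FragmentGraph:
    """Evaluate all unordered fragment pairs and all fragment-pocket pairs."""
    g = FragmentGraph()
    store = {}
    for f in frags:
        if f.fragment_id in store:
            raise ValueError(f"duplicate fragment id {f.fragment_id}")
        store[f.fragment_id] = f
        g.add_node(f.fragment_id, f.mw, f.free_valence)
    for fa, fb in combinations(sorted(store.values(), key=lambda f: f.fragment_id), 2):
        verdict = evaluate_pair(fa, fb, params, clash_threshold)
        if verdict.kind == "inclusion":
            g.add_inclusion(fa.fragment_id, fb.fragment_id, verdict.candidates)
        elif verdict.kind == "exclusion":
            g.add_exclusion(fa.fragment_id, fb.fragment_id)
    for f in store.values():
        for pocket in pockets:
            if check_compatibility(f, pocket):
                g.compatibility[f.fragment_id].add(pocket.target_id)
    return g


def split_graph(g: FragmentGraph, target_id: str | None) -> tuple[FragmentGraph, FragmentGraph]:
    """Restrict to fragments compatible with the target and split into the
    inclusion graph Gi and the exclusion graph Ge.

    ``target_id=None`` skips compatibility gating (useful when growing
    without a protein model, e.g. in reconstruction runs).
    """
    if target_id is None:
        keep = set(g.nodes)
    else:
        known = set().union(*g.compatibility.values()) if g.compatibility else set()
        if target_id not in known:
            raise KeyError(f"unknown target id: {target_id!r}")
        keep = {k for k, targets in g.compatibility.items() if target_id in targets}

    gi, ge = FragmentGraph(), FragmentGraph()
    for k in sorted(keep):
        attrs = g.nodes[k]
        gi.add_node(k, attrs["mw"], attrs["free_valence"])
        ge.add_node(k, attrs["mw"], attrs["free_valence"])
        if target_id is not None:
            gi.compatibility[k].add(target_id)
            ge.compatibility[k].add(target_id)
    for (u, v), cands in g.inclusion_edges.items():
        if u in keep and v in keep:
            gi.inclusion_edges[(u, v)] = cands
    for u, v in g.exclusion_edges:
        if u in keep and v in keep:
            ge.exclusion_edges.add((u, v))
    return gi, ge
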