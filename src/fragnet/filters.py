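"""Post-generation filter cascade.

Built molecules pass through a kinase-inhibitor-likeness window (eight
physicochemical descriptors bounded by the property ranges of clinical
kinase inhibitors, with up to two violations tolerated), undesired
substructure and PAINS screens, synthetic-accessibility and drug-likeness
scoring, CNS multiparameter optimization, macrocycle detection, and a
fingerprint-similarity novelty search against user-supplied reference
libraries.
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass, fields as dc_fields

from rdkit import Chem, RDConfig
from rdkit.Chem import Descriptors, FilterCatalog, QED, rdMolDescriptors
from rdkit import DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .fragments import flag_undesired

__all__ = [
    "FilterProfile",
    "DescriptorRecord",
    "compute_descriptors",
    "pki_like",
    "flag_substructures",
    "score_molecule",
    "sa_score",
    "cns_mpo",
    "macrocycle_size",
    "novelty_search",
    "MACROCYCLE_RING_MIN",
    "MACROCYCLE_SCREEN_MIN",
    "SA_GATE",
    "SA_GATE_MACROCYCLE",
    "TC_THRESHOLD",
]

MACROCYCLE_RING_MIN = 12  # ring size that defines a macrocycle
MACROCYCLE_SCREEN_MIN = 11  # looser screen used to maximize macrocycle yield
SA_GATE = 4.0
SA_GATE_MACROCYCLE = 5.0
TC_THRESHOLD = 0.7
CNS_MPO_THRESHOLD = 4.0

_WINDOWED = ("mw", "tpsa", "clogp", "hba", "hbd", "nrb", "nar", "nca")


@dataclass(frozen=True)
class FilterProfile:
    """Closed descriptor windows derived from clinical kinase inhibitors."""

    mw: tuple[float, float] = (314.0, 613.0)
    tpsa: tuple[float, float] = (55.0, 138.0)
    clogp: tuple[float, float] = (0.7, 6.3)
    hba: tuple[float, float] = (3, 10)
    hbd: tuple[float, float] = (0, 4)
    nrb: tuple[float, float] = (1, 11)
    nar: tuple[float, float] = (1, 5)
    nca: tuple[float, float] = (0, 2)
    max_violations: int = 2

    def __post_init__(self):
        for name in _WINDOWED:
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lower limit exceeds upper limit")
        if self.max_violations < 0:
            raise ValueError("max_violations must be >= 0")


@dataclass
class DescriptorRecord:
    mw: float
    tpsa: float
    clogp: float
    hba: int
    hbd: int
    nrb: int
    nar: int
    nca: int
    sa_score: float | None = None
    qed: float | None = None
    cns_mpo: float | None = None
    largest_ring_size: int = 0


def pki_like(rec: DescriptorRecord, profile: FilterProfile | None = None):
    """Window check with violation accounting.

    A descriptor violates when strictly outside its closed window; the
    molecule passes while the violation count stays within
    ``profile.max_violations`` (boundary values pass their window).
    """
    profile = profile or FilterProfile()
    violations = []
    for name in _WINDOWED:
        lo, hi = getattr(profile, name)
        value = getattr(rec, name)
        if value < lo or value > hi:
            violations.append(name)
    return len(violations) <= profile.max_violations, violations


# ---------------------------------------------------------------------------
# descriptors & scores
# ---------------------------------------------------------------------------

_SASCORER = None


def _load_sascorer():
    global _SASCORER
    if _SASCORER is None:
        sa_dir = os.path.join(RDConfig.RDContribDir, "SA_Score")
        if sa_dir not in sys.path:
            sys.path.append(sa_dir)
        import sascorer  # noqa: F401  (reference synthetic-accessibility score)

        _SASCORER = sascorer
    return _SASCORER


def sa_score(mol: Chem.Mol) -> float:
    """Synthetic accessibility, 1 (easy) to 10 (hard)."""
    return float(_load_sascorer().calculateScore(mol))


def macrocycle_size(mol: Chem.Mol) -> int:
    """Atom count of the largest smallest-set-of-smallest-rings ring (0 if acyclic)."""
    rings = mol.GetRingInfo().AtomRings()
    return max((len(r) for r in rings), default=0)


def _desirability_monotone(x: float, lo: float, hi: float) -> float:
    """1 below lo, 0 above hi, linear in between (Pfizer CNS MPO style)."""
    if x <= lo:
        return 1.0
    if x >= hi:
        return 0.0
    return (hi - x) / (hi - lo)


def _desirability_hump(x, x0, x1, x2, x3):
    if x <= x0 or x >= x3:
        return 0.0
    if x1 <= x <= x2:
        return 1.0
    if x < x1:
        return (x - x0) / (x1 - x0)
    return (x3 - x) / (x3 - x2)


def cns_mpo(
    clogp: float,
    mw: float,
    tpsa: float,
    hbd: float,
    clogd: float | None = None,
    pka: float | None = None,
) -> float:
    """Six-component CNS multiparameter optimization desirability sum (0-6).

    ClogD defaults to ClogP and an unknown most-basic pKa scores as fully
    desirable (neutral-compound assumption); both can be supplied when a
    predictor is available.
    """
    clogd = clogp if clogd is None else clogd
    t = [
        _desirability_monotone(clogp, 3.0, 5.0),
        _desirability_monotone(clogd, 2.0, 4.0),
        _desirability_monotone(mw, 360.0, 500.0),
        _desirability_hump(tpsa, 20.0, 40.0, 90.0, 120.0),
        _desirability_monotone(hbd, 0.5, 3.5),
        1.0 if pka is None else _desirability_monotone(pka, 8.0, 10.0),
    ]
    return float(sum(t))


def compute_descriptors(mol: Chem.Mol, nca_mode: str = "all") -> DescriptorRecord:
    """All cascade descriptors for one molecule.

    ``nca_mode`` counts chiral atoms as every potential stereocenter
    ("all") or only atoms with assigned stereochemistry ("assigned").
    """
    if nca_mode not in ("all", "assigned"):
        raise ValueError("nca_mode must be 'all' or 'assigned'")
    centers = Chem.FindMolChiralCenters(
        mol, includeUnassigned=(nca_mode == "all"), useLegacyImplementation=False
    )
    rec = DescriptorRecord(
        mw=Descriptors.MolWt(mol),
        tpsa=Descriptors.TPSA(mol),
        clogp=Descriptors.MolLogP(mol),
        hba=rdMolDescriptors.CalcNumHBA(mol),
        hbd=rdMolDescriptors.CalcNumHBD(mol),
        nrb=Descriptors.NumRotatableBonds(mol),
        nar=rdMolDescriptors.CalcNumAromaticRings(mol),
        nca=len(centers),
        largest_ring_size=macrocycle_size(mol),
    )
    rec.sa_score, rec.qed, rec.cns_mpo = score_molecule(mol)
    return rec


def score_molecule(mol: Chem.Mol) -> tuple[float, float, float]:
    """(synthetic accessibility, QED drug-likeness, CNS MPO)."""
    sa = sa_score(mol)
    qed = float(QED.qed(mol))
    mpo = cns_mpo(
        clogp=Descriptors.MolLogP(mol),
        mw=Descriptors.MolWt(mol),
        tpsa=Descriptors.TPSA(mol),
        hbd=rdMolDescriptors.CalcNumHBD(mol),
    )
    return sa, qed, mpo


# ---------------------------------------------------------------------------
# substructure screens
# ---------------------------------------------------------------------------

_PAINS = None


def _pains_catalog():
    global _PAINS
    if _PAINS is None:
        params = FilterCatalog.FilterCatalogParams()
        params.AddCatalog(FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS)
        _PAINS = FilterCatalog.FilterCatalog(params)
    return _PAINS


def flag_substructures(mol: Chem.Mol) -> set[str]:
    """PAINS matches plus the library's undesired-substructure tags.

    The undesired patterns are re-evaluated on the whole molecule so that
    motifs created by a junction bond (e.g. an acyclic N-N between two
    clean fragments) are caught.
    """
    tags = set(flag_undesired(mol))
    for entry in _pains_catalog().GetMatches(mol):
        tags.add(f"PAINS:{entry.GetDescription()}")
    return tags


# ---------------------------------------------------------------------------
# novelty search
# ---------------------------------------------------------------------------

_FPGEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def morgan_fingerprint(mol: Chem.Mol):
    """2048-bit circular fingerprint, radius 2 (the default similarity basis)."""
    return _FPGEN.GetFingerprint(mol)


def novelty_search(
    mol: Chem.Mol,
    library: list[tuple[str, Chem.Mol]],
    tc_threshold: float = TC_THRESHOLD,
) -> list[tuple[str, float]]:
    """Reference-library members at Tanimoto similarity >= threshold.

    An empty return means the molecule is novel with respect to the
    supplied libraries.  Results are sorted by descending similarity.
    """
    if not library:
        raise ValueError("reference library is empty")
    if not (0 < tc_threshold <= 1):
        raise ValueError("tc_threshold must be in (0, 1]")
    query = morgan_fingerprint(mol)
    fps = [morgan_fingerprint(m) for _cid, m in library]
    sims = DataStructs.BulkTanimotoSimilarity(query, fps)
    hits = [
        (cid, float(tc))
        for (cid, _m), tc in zip(library, sims)
        if tc >= tc_threshold
    ]
    hits.sort(key=lambda x: (-x[1], x[0]))
    return hits
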