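"""Sidechain and trajectory geometry for Trp34 orientation analysis.

The Trp34 indole sidechain of ApoE4 sits "flip-out", roughly parallel to the
protein's long axis, closing a small pocket; in ApoE2/E3 and in
stabilizer-bound ApoE4 it sits "flip-in", perpendicular to the axis. This
module computes χ1/χ2 dihedrals, the protein principal axis, the
flip-in/flip-out classification used both for structure triage and as a
trajectory observable, Kabsch superposition and RMSD time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .io import Structure, StructureMeta

__all__ = [
    "INDOLE_RING_ATOMS",
    "TRP_SIX_RING",
    "TRP_FIVE_RING",
    "FlipClassification",
    "DihedralSeries",
    "RMSDSeries",
    "TriageResult",
    "dihedral",
    "chi_angles",
    "protein_axis",
    "classify_flip",
    "classify_flip_chi",
    "triage_structures",
    "kabsch_superpose",
    "rmsd_series",
    "flip_fraction",
]

# Indole ring atom names (PDB convention for TRP)
TRP_FIVE_RING = ("CG", "CD1", "NE1", "CE2", "CD2")
TRP_SIX_RING = ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")
INDOLE_RING_ATOMS = ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2")


class UndefinedDihedralError(ValueError):
    """Three consecutive dihedral points are collinear."""


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, in (-180, 180].

    Standard atan2 convention: looking down the p2→p3 bond, a positive angle
    is a clockwise rotation of p4 relative to p1.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2_norm = np.linalg.norm(b2)
    if b2_norm < 1e-12:
        raise UndefinedDihedralError("central bond has zero length")
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise UndefinedDihedralError("collinear points leave the dihedral undefined")
    m1 = np.cross(n1, b2 / b2_norm)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = np.degrees(np.arctan2(y, x))
    # fold -180 to +180 so the range is (-180, 180]
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


def chi_angles(residue: Mapping[str, np.ndarray]) -> tuple[float, float]:
    """(χ1, χ2) of a Trp-like residue from its atom-name → coordinate map.

    χ1 = N-CA-CB-CG, χ2 = CA-CB-CG-CD1 (CD1 fixes the branch by convention).
    """
    for name in ("N", "CA", "CB", "CG", "CD1"):
        if name not in residue:
            raise ValueError(f"missing atom {name}")
    chi1 = dihedral(residue["N"], residue["CA"], residue["CB"], residue["CG"])
    chi2 = dihedral(residue["CA"], residue["CB"], residue["CG"], residue["CD1"])
    return chi1, chi2


def protein_axis(structure: Structure | np.ndarray,
                 resids: np.ndarray | None = None,
                 chain: str | None = None) -> np.ndarray:
    """Unit vector of the protein's long axis.

    Operationalised as the first principal axis of the CA coordinates.  The
    sign is fixed so the axis points from low to high residue numbers
    (positive regression of the projected coordinate on residue number).
    """
    if isinstance(structure, Structure):
        coords, order = structure.ca_coords(chain=chain)
    else:
        coords = np.asarray(structure, dtype=float)
        order = (np.arange(len(coords), dtype=float)
                 if resids is None else np.asarray(resids, dtype=float))
    if coords.shape[0] < 3:
        raise ValueError(f"need at least 3 CA atoms, got {coords.shape[0]}")
    centered = coords - coords.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-9:
        raise ValueError("degenerate geometry: CA coordinates have no spread")
    axis = vt[0]
    proj = centered @ axis
    slope = float(np.dot(order - order.mean(), proj))
    if slope < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


@dataclass(frozen=True)
class FlipClassification:
    angle_to_axis: float          # degrees in [0, 90]
    state: str                    # flip-in | flip-out
    threshold: float              # degrees
    orientation_vector: np.ndarray  # unit CB -> indole-ring centroid

    def __post_init__(self) -> None:
        if not 0.0 <= self.angle_to_axis <= 90.0:
            raise ValueError("angle_to_axis must be in [0, 90]")
        expected = "flip-out" if self.angle_to_axis <= self.threshold else "flip-in"
        if self.state != expected:
            raise ValueError(
                f"state {self.state!r} inconsistent with angle {self.angle_to_axis}"
                f" and threshold {self.threshold}"
            )


def classify_flip(structure: Structure, trp_res_id: int, axis,
                  threshold: float = 45.0, chain: str | None = None) -> FlipClassification:
    """Classify a Trp sidechain as flip-in or flip-out relative to ``axis``.

    The orientation vector runs from CB to the centroid of the nine indole
    ring atoms; the angle to the axis uses the absolute cosine, so it lies in
    [0, 90]° and the axis sign is irrelevant. Angles ≤ ``threshold`` (the
    sidechain pointing along the axis) are flip-out.
    """
    residue = structure.residue_atoms(trp_res_id, chain=chain)
    if "CB" not in residue:
        raise ValueError(f"residue {trp_res_id}: missing atom CB")
    missing = [a for a in INDOLE_RING_ATOMS if a not in residue]
    if missing:
        raise ValueError(f"residue {trp_res_id}: incomplete indole ring, missing {missing}")
    centroid = np.mean([residue[a] for a in INDOLE_RING_ATOMS], axis=0)
    v = centroid - residue["CB"]
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise ValueError("degenerate sidechain: CB coincides with ring centroid")
    v = v / norm
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    angle = float(np.degrees(np.arccos(np.clip(abs(np.dot(v, axis)), 0.0, 1.0))))
    state = "flip-out" if angle <= threshold else "flip-in"
    return FlipClassification(angle, state, threshold, v)


#: (χ1, χ2) centers of the two orientation states used by the χ-based
#: classifier and the synthetic trajectory generator (degrees).
DEFAULT_FLIP_CENTERS: dict[str, tuple[float, float]] = {
    "flip-in": (-65.0, 95.0),
    "flip-out": (-177.0, -100.0),
}


def _angdist(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def classify_flip_chi(chi1_deg: float, chi2_deg: float,
                      centers: Mapping[str, tuple[float, float]] = DEFAULT_FLIP_CENTERS,
                      ) -> str:
    """Nearest-center (χ1, χ2) classification, wrap-around metric."""
    def dist(center: tuple[float, float]) -> float:
        return _angdist(chi1_deg, center[0]) ** 2 + _angdist(chi2_deg, center[1]) ** 2

    return min(centers, key=lambda s: dist(centers[s]))


# ---------------------------------------------------------------------------
# Structure triage
# ---------------------------------------------------------------------------

#: Expected Trp34 orientation by (isoform, category)
EXPECTED_ORIENTATION = {
    ("E2", "apo"): "flip-in",
    ("E3", "apo"): "flip-in",
    ("E4", "apo"): "flip-out",
    ("E4", "holo"): "flip-in",
}


@dataclass
class TriageResult:
    selected: list[str]
    removed: list[tuple[str, str]]  # (pdb_id, reason)


def triage_structures(metadata: Sequence[StructureMeta],
                      strict: bool = False) -> TriageResult:
    """Shortlist receptor structures for ensemble docking.

    Keeps non-mutant X-ray entries at resolution ≤ 2 Å, then removes
    structures whose observed Trp34 orientation contradicts the expectation
    for their isoform/category (apo-E3 flip-in, apo-E4 flip-out, holo-E4
    flip-in). Removed ids are reported with reasons.
    """
    selected: list[str] = []
    removed: list[tuple[str, str]] = []
    for m in metadata:
        if m.method != "X-ray":
            removed.append((m.pdb_id, f"method {m.method}, not X-ray"))
            continue
        if m.resolution_A is None or m.resolution_A > 2.0:
            removed.append((m.pdb_id, f"resolution {m.resolution_A} Å > 2 Å"))
            continue
        if m.mutant:
            removed.append((m.pdb_id, "mutant construct"))
            continue
        expected = EXPECTED_ORIENTATION.get((m.isoform, m.category))
        if expected is None:
            removed.append((m.pdb_id, f"no expectation for {m.isoform}/{m.category}"))
            continue
        if m.trp34_orientation == "unknown":
            if strict:
                raise ValueError(f"{m.pdb_id}: Trp34 orientation unknown (strict mode)")
            selected.append(m.pdb_id)
            continue
        if m.trp34_orientation != expected:
            removed.append(
                (m.pdb_id,
                 f"Trp34 {m.trp34_orientation} contradicts expected {expected} "
                 f"for {m.category}-Apo{m.isoform}")
            )
            continue
        selected.append(m.pdb_id)
    return TriageResult(selected=selected, removed=removed)


# ---------------------------------------------------------------------------
# Superposition and RMSD series
# ---------------------------------------------------------------------------

def kabsch_superpose(reference: np.ndarray, mobile: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` with ``reference ≈ R @ mobile + t``; the
    rotation is proper (det +1) and the RMSD is the least-squares minimum
    over all rigid motions.
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError(f"matched (n, 3) coordinate sets required, got {ref.shape} vs {mob.shape}")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("at least 3 atoms are required for superposition")
    ref_c = ref.mean(axis=0)
    mob_c = mob.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ref - ref_c, mob - mob_c)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    return R, t, float(rssd / np.sqrt(n))


@dataclass
class RMSDSeries:
    time_ns: np.ndarray
    ligand_rmsd_A: np.ndarray
    backbone_rmsd_A: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.time_ns, self.ligand_rmsd_A, self.backbone_rmsd_A):
            if len(arr) != len(self.time_ns):
                raise ValueError("series length mismatch")
        if np.any(self.ligand_rmsd_A < -1e-9) or np.any(self.backbone_rmsd_A < -1e-9):
            raise ValueError("RMSD must be non-negative")


def rmsd_series(ligand_frames: Sequence[np.ndarray],
                backbone_frames: Sequence[np.ndarray],
                time_ns: Sequence[float] | None = None) -> RMSDSeries:
    """Backbone-superposed RMSD time series relative to the first frame.

    Each frame's backbone is Kabsch-superposed onto frame 0; the backbone
    RMSD is that minimum, and the ligand RMSD is measured after applying the
    *backbone* transform (no re-fit on the ligand), the usual convention for
    pocket-stability analyses.
    """
    if len(ligand_frames) != len(backbone_frames) or len(ligand_frames) == 0:
        raise ValueError("ligand and backbone frame lists must be non-empty and equal length")
    lig0 = np.asarray(ligand_frames[0], dtype=float)
    bb0 = np.asarray(backbone_frames[0], dtype=float)
    times = (np.arange(len(ligand_frames), dtype=float)
             if time_ns is None else np.asarray(time_ns, dtype=float))
    lig_rmsd = np.empty(len(ligand_frames))
    bb_rmsd = np.empty(len(ligand_frames))
    for i, (lig, bb) in enumerate(zip(ligand_frames, backbone_frames)):
        lig = np.asarray(lig, dtype=float)
        bb = np.asarray(bb, dtype=float)
        if lig.shape != lig0.shape or bb.shape != bb0.shape:
            raise ValueError(f"frame {i}: atom-set shape mismatch")
        R, t, bb_r = kabsch_superpose(bb0, bb)
        bb_rmsd[i] = bb_r
        moved = lig @ R.T + t
        lig_rmsd[i] = float(np.sqrt(np.mean(np.sum((moved - lig0) ** 2, axis=1))))
    return RMSDSeries(time_ns=times, ligand_rmsd_A=lig_rmsd, backbone_rmsd_A=bb_rmsd)


# ---------------------------------------------------------------------------
# Dihedral trajectories
# ---------------------------------------------------------------------------

@dataclass
class DihedralSeries:
    """Per-frame (χ1, χ2) observables of a Trp-like sidechain."""

    time_ns: np.ndarray
    chi1_deg: np.ndarray
    chi2_deg: np.ndarray
    state: np.ndarray  # "flip-in" / "flip-out" per frame

    def __post_init__(self) -> None:
        n = len(self.time_ns)
        for arr in (self.chi1_deg, self.chi2_deg, self.state):
            if len(arr) != n:
                raise ValueError("series length mismatch")
        for chi in (self.chi1_deg, self.chi2_deg):
            if np.any(chi < -180.0) or np.any(chi > 180.0):
                raise ValueError("χ angles must lie in [-180, 180]")

    def __len__(self) -> int:
        return len(self.time_ns)


def flip_fraction(series) -> float:
    """Fraction of frames in the flip-in state.

    Accepts a :class:`DihedralSeries`, an iterable of state strings, or an
    iterable of :class:`FlipClassification`.
    """
    if isinstance(series, DihedralSeries):
        states = list(series.state)
    else:
        states = [s.state if isinstance(s, FlipClassification) else str(s) for s in series]
    if not states:
        raise ValueError("empty series")
    bad = {s for s in states if s not in {"flip-in", "flip-out"}}
    if bad:
        raise ValueError(f"unknown states {sorted(bad)}")
    return sum(1 for s in states if s == "flip-in") / len(states)
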