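"""Synthetic inputs for every stage of the screening pipeline.

Real inputs to the analytics (docking engines, shape-overlay software, MD
integrators) are out of scope, so this module generates statistically and
geometrically controlled stand-ins:

* :func:`gen_screen` — a ligand × structure docking-score matrix whose
  holo-ApoE4 columns correlate positively and free-ApoE4 columns negatively
  with latent binding affinity (the sign pattern that motivates the
  consensus ratio), plus a censored Kd table and shape-similarity tables.
* :func:`build_pose_complex` — a toy Trp34-pocket/ligand complex built from
  idealized amino-acid geometry with prescribed H-bond, π-stacking and
  pocket-occupancy geometry, self-verified against the interaction
  detectors.
* :func:`gen_flip_trajectory` — a two-state Markov chain over the
  flip-in/flip-out orientations of a Trp-like sidechain, emitting per-frame
  (χ1, χ2) angles and on-demand residue coordinates.

All generators are pure functions of their spec (seed included): the same
spec yields bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import datasets
from .consensus import ScoreMatrix
from .geometry import (
    DEFAULT_FLIP_CENTERS,
    INDOLE_RING_ATOMS,
    DihedralSeries,
)
from .interactions import PoseComplex, detect_hbonds, detect_pi_stacking, pocket_occupancy
from .io import AtomRecord, Censor, KdRecord, Structure, StructureMeta

__all__ = [
    "SpecValidationError",
    "PoseConstructionError",
    "ScreenSpec",
    "SyntheticScreen",
    "gen_screen",
    "PoseSpec",
    "build_pose_complex",
    "TrajectorySpec",
    "FlipTrajectory",
    "gen_flip_trajectory",
    "gen_structure_metadata",
    "build_trp_residue",
]


class SpecValidationError(ValueError):
    """A generator spec field is out of range (the message names the field)."""


class PoseConstructionError(ValueError):
    """A requested pose geometry cannot be realized."""


# ---------------------------------------------------------------------------
# Docking-screen generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenSpec:
    """Conditions of a synthetic ensemble-docking screen.

    Couplings are target rank correlations between a ligand's latent log-Kd
    and its docking score per structure category; the free-ApoE4 coupling is
    negative in the regime the consensus ratio exploits. Defaults mirror the
    benchmark screen: a ~1250-compound library spiked with 8 known actives,
    Kd spanning 1–1000 µM with a 5 µM detection floor.
    """

    seed: int
    n_decoys: int = 1250
    n_actives: int = 8
    holo_coupling: float = 0.95
    free_coupling: float = -0.65
    kd_range_um: tuple[float, float] = (1.0, 1000.0)
    active_kd_max_um: float = 30.0
    detection_floor_um: float = 5.0
    noise_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.n_decoys < 0:
            raise SpecValidationError(f"n_decoys must be >= 0, got {self.n_decoys}")
        if self.n_actives < 0:
            raise SpecValidationError(f"n_actives must be >= 0, got {self.n_actives}")
        if self.n_decoys + self.n_actives < 2:
            raise SpecValidationError("n_decoys + n_actives must be >= 2")
        for name in ("holo_coupling", "free_coupling"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise SpecValidationError(f"{name} must be in [-1, 1], got {v}")
        lo, hi = self.kd_range_um
        if not (0 < lo < hi):
            raise SpecValidationError(f"kd_range_um requires 0 < low < high, got {self.kd_range_um}")
        if not (lo < self.active_kd_max_um < hi):
            raise SpecValidationError(
                f"active_kd_max_um must lie inside kd_range_um, got {self.active_kd_max_um}")
        if self.detection_floor_um <= 0:
            raise SpecValidationError(
                f"detection_floor_um must be positive, got {self.detection_floor_um}")
        if self.noise_sd < 0:
            raise SpecValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass
class SyntheticScreen:
    matrix: ScoreMatrix                  # docking scores (kcal/mol, lower better)
    kd: list[KdRecord]
    actives: list[str]
    shape_tables: dict[str, pd.Series]   # higher-better similarity per query
    log_kd: pd.Series                    # latent log10 Kd (µM), uncensored

    @property
    def ligand_ids(self) -> list[str]:
        return self.matrix.ligand_ids


#: Structure ids and categories of the synthetic six-structure ensemble.
SCREEN_STRUCTURES = dict(datasets.ENSEMBLE_CATEGORIES)

_SCORE_CENTER = -8.5     # kcal/mol
_SCORE_AMPLITUDE = 1.5   # kcal/mol spread of the activity-coupled component
_APOE3_ATTENUATION = 0.8  # apoE3 pockets track the holo signal, diluted


def gen_screen(spec: ScreenSpec) -> SyntheticScreen:
    """Generate a synthetic six-structure docking screen.

    Latent activity is log10 Kd: actives are log-uniform between the low end
    of ``kd_range_um`` and ``active_kd_max_um`` (true binders), decoys
    log-uniform between ``active_kd_max_um`` and the high end (presumed
    inactive, as in standard active/decoy screening benchmarks). Coupling is
    imposed through a Gaussian copula: with ligand activity z-score ``z``
    and per-cell noise ``ε``, a column with coupling ρ gets score
    ``center + A·(ρ z + sqrt(1-ρ²) ε) + noise_sd·η``.  Kd values below the
    detection floor are reported censored ("<floor").
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_decoys + spec.n_actives
    width = max(len(str(n)), 4)
    ids = [f"D{i:0{width}d}" for i in range(spec.n_decoys)] + \
          [f"A{i:0{width}d}" for i in range(spec.n_actives)]
    lo, hi = np.log10(spec.kd_range_um[0]), np.log10(spec.kd_range_um[1])
    split = (np.log10(spec.active_kd_max_um) - lo) / (hi - lo)
    u = np.concatenate([
        rng.uniform(split, 1.0, size=spec.n_decoys),
        rng.uniform(0.0, split, size=spec.n_actives),
    ])
    log_kd = lo + u * (hi - lo)
    z = stats.norm.ppf(np.clip(u, 1e-9, 1 - 1e-9))

    coupling = {
        "apoE3": _APOE3_ATTENUATION * spec.holo_coupling,
        "free-apoE4": spec.free_coupling,
        "holo-apoE4": spec.holo_coupling,
    }
    scores = {}
    for sid, category in SCREEN_STRUCTURES.items():
        rho = coupling[category]
        eps = rng.standard_normal(n)
        eta = rng.standard_normal(n)
        scores[sid] = (
            _SCORE_CENTER
            + _SCORE_AMPLITUDE * (rho * z + math.sqrt(1.0 - rho * rho) * eps)
            + spec.noise_sd * eta
        )
    values = pd.DataFrame(scores, index=pd.Index(ids, name="ligand_id"))
    matrix = ScoreMatrix(values=values, categories=dict(SCREEN_STRUCTURES),
                         value_kind="score")

    kd_um = 10.0 ** log_kd
    records = []
    for lig, kd in zip(ids, kd_um):
        if kd < spec.detection_floor_um:
            records.append(KdRecord(lig, spec.detection_floor_um, Censor.BELOW))
        else:
            records.append(KdRecord(lig, float(kd)))

    # Shape-similarity queries: TanimotoCombo-like, higher for tight binders
    shape_tables = {}
    for q in ("query1", "query2"):
        noise = rng.standard_normal(n)
        sim = np.clip(1.0 - 0.35 * z + 0.15 * noise, 0.05, 2.0)
        shape_tables[q] = pd.Series(sim, index=ids, name=q)

    return SyntheticScreen(
        matrix=matrix,
        kd=records,
        actives=ids[spec.n_decoys:],
        shape_tables=shape_tables,
        log_kd=pd.Series(log_kd, index=ids, name="log10_kd_um"),
    )


# ---------------------------------------------------------------------------
# Idealized Trp-like residue geometry
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Internal-coordinate (NeRF) placement: new atom bonded to ``c`` with
    bond length, b-c-new angle and a-b-c-new dihedral (package sign
    convention)."""
    theta = math.radians(angle_deg)
    phi = math.radians(torsion_deg)
    bc = _unit(np.asarray(c, float) - np.asarray(b, float))
    n = _unit(np.cross(np.asarray(b, float) - np.asarray(a, float), bc))
    m = np.cross(n, bc)
    d = bond * (-math.cos(theta) * bc
                + math.sin(theta) * (math.cos(phi) * m - math.sin(phi) * n))
    return np.asarray(c, float) + d


def _indole_template() -> dict[str, np.ndarray]:
    """2D idealized indole (bond length 1.40 Å) plus CB, hexagon centroid at
    the origin."""
    s = 1.40
    pts: dict[str, np.ndarray] = {}
    hex_angles = {"CE2": 90.0, "CD2": 150.0, "CE3": -150.0, "CZ3": -90.0,
                  "CH2": -30.0, "CZ2": 30.0}
    for name, ang in hex_angles.items():
        r = math.radians(ang)
        pts[name] = s * np.array([math.cos(r), math.sin(r)])
    mid = 0.5 * (pts["CD2"] + pts["CE2"])
    outward = _unit(mid)
    apothem5 = s / (2.0 * math.tan(math.pi / 5.0))
    radius5 = s / (2.0 * math.sin(math.pi / 5.0))
    c5 = mid + apothem5 * outward
    th_ce2 = math.atan2(*(pts["CE2"] - c5)[::-1])
    th_cd2 = math.atan2(*(pts["CD2"] - c5)[::-1])
    step = 2.0 * math.pi / 5.0
    # walk CE2 -> NE1 -> CD1 -> CG -> CD2 around the pentagon; pick the
    # rotation sense that lands on CD2 after four steps
    sense = 1.0
    if abs(_wrap_angle(th_ce2 + 4 * step - th_cd2)) > 1e-6:
        sense = -1.0
    for k, name in enumerate(("NE1", "CD1", "CG"), start=1):
        th = th_ce2 + sense * k * step
        pts[name] = c5 + radius5 * np.array([math.cos(th), math.sin(th)])
    pts["CB"] = pts["CG"] + 1.50 * _unit(pts["CG"] - c5)
    return pts


def _wrap_angle(rad: float) -> float:
    return (rad + math.pi) % (2.0 * math.pi) - math.pi


_TEMPLATE = _indole_template()
_TEMPLATE_ANGLE_CB_CG_CD1 = math.degrees(math.acos(float(np.dot(
    _unit(_TEMPLATE["CB"] - _TEMPLATE["CG"]), _unit(_TEMPLATE["CD1"] - _TEMPLATE["CG"])))))
_TEMPLATE_ANGLE_CB_CG_CD2 = math.degrees(math.acos(float(np.dot(
    _unit(_TEMPLATE["CB"] - _TEMPLATE["CG"]), _unit(_TEMPLATE["CD2"] - _TEMPLATE["CG"])))))


def build_trp_residue(chi1_deg: float = -65.0, chi2_deg: float = 95.0
                      ) -> dict[str, np.ndarray]:
    """Idealized Trp-like residue with prescribed χ1/χ2 (atom name → coords).

    Backbone N/CA/C/O plus CB and the nine indole ring atoms, built from
    standard bond lengths/angles and a planar regular-polygon indole.
    """
    coords: dict[str, np.ndarray] = {}
    coords["N"] = np.zeros(3)
    coords["CA"] = np.array([1.458, 0.0, 0.0])
    th = math.radians(69.5)  # gives an N-CA-CB angle of 110.5 deg
    coords["CB"] = coords["CA"] + 1.53 * np.array([math.cos(th), math.sin(th), 0.0])
    coords["C"] = _place_atom(coords["CB"], coords["N"], coords["CA"], 1.52, 111.0, 122.0)
    coords["O"] = _place_atom(coords["N"], coords["CA"], coords["C"], 1.23, 120.5, 0.0)
    coords["CG"] = _place_atom(coords["N"], coords["CA"], coords["CB"],
                               1.50, 114.0, chi1_deg)
    coords["CD1"] = _place_atom(coords["CA"], coords["CB"], coords["CG"],
                                1.40, _TEMPLATE_ANGLE_CB_CG_CD1, chi2_deg)
    coords["CD2"] = _place_atom(coords["CA"], coords["CB"], coords["CG"],
                                1.40, _TEMPLATE_ANGLE_CB_CG_CD2, chi2_deg + 180.0)
    # embed the remaining planar template atoms in the frame set by CG/CD1/CD2
    t_cg, t_cd1, t_cd2 = _TEMPLATE["CG"], _TEMPLATE["CD1"], _TEMPLATE["CD2"]
    e1 = _unit(t_cd1 - t_cg)
    e2 = np.array([-e1[1], e1[0]])
    if float(np.dot(t_cd2 - t_cg, e2)) < 0:
        e2 = -e2
    u1 = _unit(coords["CD1"] - coords["CG"])
    w = coords["CD2"] - coords["CG"]
    u2 = _unit(w - float(np.dot(w, u1)) * u1)
    for name in ("NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"):
        rel = _TEMPLATE[name] - t_cg
        coords[name] = coords["CG"] + float(np.dot(rel, e1)) * u1 + float(np.dot(rel, e2)) * u2
    return coords


# ---------------------------------------------------------------------------
# Toy pose-complex generator
# ---------------------------------------------------------------------------

_HBOND_SITES = {"ASP35": np.array([-3.2, 0.8, 3.2]),
                "ASP153": np.array([3.2, 0.8, 3.2])}


@dataclass(frozen=True)
class PoseSpec:
    """Requested interaction geometry of a toy Trp34-pocket pose.

    ``hbond_requests`` are (residue label, heavy-atom distance Å) pairs for
    the pocket aspartates; ``pistack_request`` is (centroid distance Å,
    interplanar angle °) against the Trp six-ring; ``occupancy_request`` is
    a count of ligand carbons to bury in the pocket.
    """

    hbond_requests: tuple[tuple[str, float], ...] = ()
    pistack_request: tuple[float, float] | None = None
    occupancy_request: int | None = None
    trp_flip: str = "flip-in"
    seed: int = 0

    def __post_init__(self) -> None:
        for res, dist in self.hbond_requests:
            if res not in _HBOND_SITES:
                raise SpecValidationError(
                    f"hbond_requests: unknown residue {res!r}; expected one of "
                    f"{sorted(_HBOND_SITES)}")
            if dist <= 0:
                raise SpecValidationError(f"hbond_requests: distance must be > 0, got {dist}")
        if self.pistack_request is not None:
            d, ang = self.pistack_request
            if d <= 0:
                raise SpecValidationError(f"pistack_request: distance must be > 0, got {d}")
            if not 0.0 <= ang <= 90.0:
                raise SpecValidationError(f"pistack_request: angle must be in [0, 90], got {ang}")
        if self.occupancy_request is not None and self.occupancy_request < 1:
            raise SpecValidationError(
                f"occupancy_request must be >= 1, got {self.occupancy_request}")
        if self.trp_flip not in {"flip-in", "flip-out"}:
            raise SpecValidationError(f"trp_flip must be flip-in/flip-out, got {self.trp_flip!r}")


def _embed_trp_sidechain(flip: str) -> dict[str, np.ndarray]:
    """Indole + CB in 3D: six-ring centroid at the origin, ring plane = xy;
    CB→centroid along +y (flip-in, perpendicular to the x protein axis) or
    +x (flip-out, parallel)."""
    t1 = np.array([0.0, 1.0, 0.0]) if flip == "flip-in" else np.array([1.0, 0.0, 0.0])
    t2 = np.array([1.0, 0.0, 0.0]) if flip == "flip-in" else np.array([0.0, 1.0, 0.0])
    f1 = _unit(-_TEMPLATE["CB"])  # CB -> hexagon centroid direction, 2D
    f2 = np.array([-f1[1], f1[0]])
    out = {}
    for name in (*INDOLE_RING_ATOMS, "CB"):
        p = _TEMPLATE[name]
        out[name] = float(np.dot(p, f1)) * t1 + float(np.dot(p, f2)) * t2
    return out


def build_pose_complex(spec: PoseSpec) -> PoseComplex:
    """Construct a toy pocket–ligand complex realizing the requested geometry.

    The protein fragment comprises two backbone segments along the x axis
    (the protein axis), a full Trp34 sidechain whose six-ring centroid sits
    at the pocket origin, and Asp35/Asp153 carboxylates flanking the pocket.
    Ligand atoms are placed to satisfy each request exactly; the result is
    self-verified with the interaction detectors and a 1.0 Å minimum
    inter-atomic distance, then rigidly rotated/translated by a
    seed-determined isometry.
    """
    protein_atoms: list[AtomRecord] = []
    serial = [0]

    def add(name: str, res_name: str, res_id: int, pos: np.ndarray, element: str,
            atoms: list[AtomRecord], hetero: bool = False, chain: str = "A") -> None:
        serial[0] += 1
        atoms.append(AtomRecord(serial[0], name, "", res_name, chain, res_id,
                                float(pos[0]), float(pos[1]), float(pos[2]),
                                element, hetero))

    side = _embed_trp_sidechain(spec.trp_flip)
    ca_trp = side["CB"] + 1.53 * _unit(np.array([0.0, -0.9, -1.2]))

    def backbone_ca(res_id: int) -> np.ndarray:
        if res_id <= 41:
            return ca_trp + np.array([(res_id - 34) * 3.8, 0.0, 0.0])
        return ca_trp + np.array([(res_id - 153) * 3.8 + 6.0, 0.0, -3.5])

    residues = [(i, "GLY") for i in range(30, 39)] + [(i, "GLY") for i in range(150, 157)]
    residues = [(i, "TRP") if i == 34 else (i, "ASP") if i in (35, 153) else (i, nm)
                for i, nm in residues]
    for res_id, res_name in residues:
        ca = backbone_ca(res_id)
        add("N", res_name, res_id, ca + np.array([-0.9, -1.0, -0.3]), "N", protein_atoms)
        add("CA", res_name, res_id, ca, "C", protein_atoms)
        add("C", res_name, res_id, ca + np.array([0.9, -1.0, -0.3]), "C", protein_atoms)
        add("O", res_name, res_id, ca + np.array([1.23, -2.0, 0.36]), "O", protein_atoms)
        if res_name == "TRP":
            for name in ("CB", *INDOLE_RING_ATOMS):
                element = "N" if name.startswith("N") else "C"
                add(name, "TRP", 34, side[name], element, protein_atoms)
        elif res_name == "ASP":
            site = _HBOND_SITES["ASP35" if res_id == 35 else "ASP153"]
            outward = -1.0 if res_id == 35 else 1.0  # away from the pocket center
            cg = site + np.array([0.0, 0.0, -1.25])
            od2 = cg + 1.25 * _unit(np.array([0.83 * outward, 0.0, -0.55]))
            cb = cg + 1.52 * _unit(ca - cg)
            add("CB", "ASP", res_id, cb, "C", protein_atoms)
            add("CG", "ASP", res_id, cg, "C", protein_atoms)
            add("OD1", "ASP", res_id, site, "O", protein_atoms)
            add("OD2", "ASP", res_id, od2, "O", protein_atoms)

    # --- ligand ---
    ligand_atoms: list[AtomRecord] = []
    per_residue_count: dict[str, int] = {}
    n_o = 0
    for res, dist in spec.hbond_requests:
        k = per_residue_count.get(res, 0)
        per_residue_count[res] = k + 1
        toward_center = 1.0 if res == "ASP35" else -1.0
        direction = _unit(np.array([0.45 * k * toward_center, 0.0, 1.0]))
        pos = _HBOND_SITES[res] + dist * direction
        n_o += 1
        add(f"O{n_o}", "LIG", 1, pos, "O", ligand_atoms, hetero=True, chain="L")
    n_c = 0
    if spec.pistack_request is not None:
        d, ang = spec.pistack_request
        theta = math.radians(ang)
        center = np.array([0.0, 0.0, d])
        a1 = np.array([1.0, 0.0, 0.0])
        a2 = np.array([0.0, math.cos(theta), math.sin(theta)])
        for k in range(6):
            phi = math.radians(60.0 * k + 30.0)
            pos = center + 1.40 * (math.cos(phi) * a1 + math.sin(phi) * a2)
            n_c += 1
            add(f"C{n_c}", "LIG", 1, pos, "C", ligand_atoms, hetero=True, chain="L")
    if spec.occupancy_request is not None:
        k = spec.occupancy_request
        start = side["CB"] + np.array([-(k - 1) * 0.75, -0.5, 3.5])
        for i in range(k):
            pos = start + np.array([i * 1.5, 0.0, 0.0])
            n_c += 1
            add(f"C{n_c}", "LIG", 1, pos, "C", ligand_atoms, hetero=True, chain="L")
    if not ligand_atoms:
        raise SpecValidationError("PoseSpec requests no interactions; nothing to build")

    pose = PoseComplex(
        protein=Structure(protein_atoms, source_id="toy-pocket"),
        ligand=Structure(ligand_atoms, source_id="toy-ligand"),
        pose_id=f"pose-seed{spec.seed}",
        source_structure="toy-pocket",
    )
    _verify_pose(pose, spec)

    # seed-determined rigid motion: detectors are isometry-invariant, so the
    # realized geometry is preserved
    rng = np.random.default_rng(spec.seed)
    from scipy.spatial.transform import Rotation
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-20.0, 20.0, size=3)
    return pose.transformed(R, t)


def _verify_pose(pose: PoseComplex, spec: PoseSpec) -> None:
    """Closed-loop self-check: every request detected, nothing spurious."""
    all_coords = np.vstack([pose.protein.coords(), pose.ligand.coords()])
    from scipy.spatial.distance import pdist
    if all_coords.shape[0] > 1 and float(pdist(all_coords).min()) < 1.0:
        raise PoseConstructionError(
            "unrealizable request: atoms closer than 1.0 Å after construction")
    for res, dist in spec.hbond_requests:
        found = detect_hbonds(pose, d_max=dist + 0.1, residues=[res])
        if not any(abs(h.distance_A - dist) <= 0.05 for h in found):
            raise PoseConstructionError(
                f"self-check failed: requested H-bond to {res} at {dist} Å not realized")
    requested_res = {res for res, dist in spec.hbond_requests if dist <= 3.5}
    detected_res = {h.residue for h in detect_hbonds(pose, d_max=3.5)
                    if h.residue.startswith("ASP")}
    if detected_res != requested_res:
        raise PoseConstructionError(
            f"self-check failed: H-bond residues {detected_res} != requested {requested_res}")
    if spec.pistack_request is not None:
        d, ang = spec.pistack_request
        stacks = detect_pi_stacking(pose, d_max=d + 0.1, angle_max=min(ang + 2.0, 90.0))
        ok = any(s.protein_ring.endswith("six-ring")
                 and abs(s.centroid_distance_A - d) <= 0.05
                 and abs(s.interplanar_angle_deg - ang) <= 2.0 for s in stacks)
        if not ok:
            raise PoseConstructionError(
                f"self-check failed: requested π-stack ({d} Å, {ang}°) not realized")
    elif detect_pi_stacking(pose):
        raise PoseConstructionError("self-check failed: unrequested π-stacking detected")
    occ = pocket_occupancy(pose, ("TRP34",), cutoff=4.5)
    if spec.occupancy_request is not None:
        frag = f"C{spec.occupancy_request} fragment" if spec.occupancy_request > 1 else "C atom"
        if occ.fragment_counts.get(frag, 0) != spec.occupancy_request:
            raise PoseConstructionError(
                f"self-check failed: occupancy fragment contributes "
                f"{occ.fragment_counts.get(frag, 0)} contacts, requested {spec.occupancy_request}")
    elif spec.pistack_request is None and occ.contact_count != 0:
        raise PoseConstructionError("self-check failed: unrequested pocket occupancy detected")


# ---------------------------------------------------------------------------
# Flip-trajectory generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectorySpec:
    """Two-state flip trajectory: per-state persistence and stationary mix.

    ``p_stay`` sets the larger of the two per-frame stay probabilities;
    switching rates are split so the chain's stationary flip-in probability
    equals ``stationary_flip_in``. Frames every ``frame_interval_ns``.
    """

    seed: int
    n_frames: int = 1000
    frame_interval_ns: float = 0.1
    p_stay: float = 0.98
    stationary_flip_in: float = 0.9
    chi_noise_sd_deg: float = 8.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise SpecValidationError(f"n_frames must be >= 1, got {self.n_frames}")
        if self.frame_interval_ns <= 0:
            raise SpecValidationError(
                f"frame_interval_ns must be positive, got {self.frame_interval_ns}")
        for name in ("p_stay", "stationary_flip_in"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise SpecValidationError(f"{name} must be in (0, 1), got {v}")
        if self.chi_noise_sd_deg < 0:
            raise SpecValidationError(
                f"chi_noise_sd_deg must be >= 0, got {self.chi_noise_sd_deg}")


@dataclass
class FlipTrajectory:
    series: DihedralSeries
    spec: TrajectorySpec

    def residue(self, frame: int) -> dict[str, np.ndarray]:
        """Coordinates of the Trp-like residue at one frame."""
        return build_trp_residue(float(self.series.chi1_deg[frame]),
                                 float(self.series.chi2_deg[frame]))

    def __len__(self) -> int:
        return len(self.series)


def _wrap_deg(a: np.ndarray) -> np.ndarray:
    return (a + 180.0) % 360.0 - 180.0


def gen_flip_trajectory(spec: TrajectorySpec) -> FlipTrajectory:
    """Simulate a two-state Markov chain over flip-in/flip-out.

    Leaving rates are ``q·(1-π)`` from flip-in and ``q·π`` from flip-out
    (scaled so the larger stay probability is ``p_stay``), which makes the
    stationary flip-in occupancy exactly ``π = stationary_flip_in``. Each
    state maps to a (χ1, χ2) center with Gaussian angular noise.
    """
    rng = np.random.default_rng(spec.seed)
    pi = spec.stationary_flip_in
    q = 1.0 - spec.p_stay
    m = max(pi, 1.0 - pi)
    leave = {"flip-in": q * (1.0 - pi) / m, "flip-out": q * pi / m}
    states = np.empty(spec.n_frames, dtype=object)
    state = "flip-in" if rng.uniform() < pi else "flip-out"
    for i in range(spec.n_frames):
        states[i] = state
        if rng.uniform() < leave[state]:
            state = "flip-out" if state == "flip-in" else "flip-in"
    centers = np.array([DEFAULT_FLIP_CENTERS[s] for s in states])
    noise = rng.normal(0.0, spec.chi_noise_sd_deg, size=(spec.n_frames, 2))
    chis = _wrap_deg(centers + noise)
    series = DihedralSeries(
        time_ns=np.arange(spec.n_frames) * spec.frame_interval_ns,
        chi1_deg=chis[:, 0],
        chi2_deg=chis[:, 1],
        state=states.astype(str),
    )
    return FlipTrajectory(series=series, spec=spec)


def gen_structure_metadata() -> list[StructureMeta]:
    """The eight-structure candidate set used for receptor triage."""
    return datasets.load_structure_metadata()
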