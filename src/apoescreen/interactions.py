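"""Geometric protein–ligand interaction detectors and checklists.

Turns coordinates into the interaction checklist used to triage docking
poses in the Trp34 pocket: hydrogen bonds to named residues (heavy-atom
donor–acceptor distance, since docked/crystal poses usually lack hydrogens),
parallel π-stacking with the Trp indole, hydrophobic pocket occupancy, and
per-frame persistence fractions over a trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import TRP_FIVE_RING, TRP_SIX_RING, FlipClassification
from .io import AtomRecord, Structure

__all__ = [
    "PoseComplex",
    "HBond",
    "PiStack",
    "Occupancy",
    "ChecklistRecord",
    "PersistenceProfile",
    "detect_hbonds",
    "detect_pi_stacking",
    "pocket_occupancy",
    "build_checklist",
    "persistence_profile",
    "count_all_key",
]

POLAR_ELEMENTS = {"N", "O"}
HYDROPHOBIC_ELEMENTS = {"C", "F", "CL", "BR", "I"}
BACKBONE_ATOMS = {"N", "CA", "C", "O"}
BOND_CUTOFF = 1.8  # Å; heavy atoms closer than this are treated as bonded


@dataclass
class PoseComplex:
    """A docked/crystal pose: receptor fragment plus ligand atoms."""

    protein: Structure
    ligand: Structure
    pose_id: str = ""
    source_structure: str = ""

    def __post_init__(self) -> None:
        prot = {(a.chain, a.res_id, a.name) for a in self.protein.atoms}
        lig = {(a.chain, a.res_id, a.name) for a in self.ligand.atoms}
        if prot & lig:
            raise ValueError("ligand and protein atom sets overlap")

    def transformed(self, rotation, translation) -> "PoseComplex":
        return PoseComplex(
            protein=self.protein.transformed(rotation, translation),
            ligand=self.ligand.transformed(rotation, translation),
            pose_id=self.pose_id,
            source_structure=self.source_structure,
        )


def _residue_label(atom: AtomRecord) -> str:
    return f"{atom.res_name}{atom.res_id}"


@dataclass(frozen=True)
class HBond:
    ligand_atom: str
    protein_atom: str
    residue: str
    distance_A: float


def detect_hbonds(pose: PoseComplex, d_max: float = 3.5,
                  residues: Sequence[str] | None = None) -> list[HBond]:
    """Interface N/O–N/O contacts within ``d_max`` Å (heavy-atom criterion).

    Without hydrogen positions donor/acceptor roles are not assigned; every
    polar heavy-atom pair across the interface within the cutoff is reported,
    annotated with its protein residue. ``residues`` restricts the protein
    side to labels like ``"ASP35"``.
    """
    lig = [a for a in pose.ligand.atoms if a.element.upper() in POLAR_ELEMENTS]
    prot = [a for a in pose.protein.atoms if a.element.upper() in POLAR_ELEMENTS]
    if residues is not None:
        wanted = set(residues)
        prot = [a for a in prot if _residue_label(a) in wanted]
    if not lig or not prot:
        return []
    d = cdist(np.array([a.coord for a in lig]), np.array([a.coord for a in prot]))
    out = []
    for i, j in zip(*np.nonzero(d <= d_max)):
        out.append(HBond(lig[i].name, prot[j].name, _residue_label(prot[j]),
                         float(d[i, j])))
    return sorted(out, key=lambda h: h.distance_A)


# ---------------------------------------------------------------------------
# Ring perception and π-stacking
# ---------------------------------------------------------------------------

def _bond_adjacency(coords: np.ndarray) -> list[list[int]]:
    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)
    adj: list[list[int]] = [list(np.nonzero(row <= BOND_CUTOFF)[0]) for row in d]
    return adj


def _connected_components(adj: list[list[int]]) -> list[list[int]]:
    seen: set[int] = set()
    comps = []
    for start in range(len(adj)):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            v = stack.pop()
            comp.append(v)
            for w in adj[v]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        comps.append(sorted(comp))
    return comps


def _find_rings(coords: np.ndarray, max_size: int = 7) -> list[list[int]]:
    """Simple cycles of size 3..max_size from distance-based connectivity."""
    adj = _bond_adjacency(coords)
    rings: set[tuple[int, ...]] = set()

    def walk(path: list[int]) -> None:
        head = path[-1]
        for nxt in adj[head]:
            if nxt == path[0] and len(path) >= 3:
                key = tuple(sorted(path))
                rings.add(key)
            elif nxt not in path and len(path) < max_size and nxt > path[0]:
                walk(path + [nxt])

    for start in range(len(coords)):
        walk([start])
    # drop rings that are unions of smaller ones (keep minimal cycles)
    minimal = []
    for r in sorted(rings, key=len):
        if not any(set(s) < set(r) for s in minimal):
            minimal.append(list(r))
    return minimal


def _ring_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of a ring via least-squares plane fit."""
    if coords.shape[0] < 3:
        raise ValueError("a ring needs at least 3 atoms")
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[-1]


@dataclass(frozen=True)
class PiStack:
    ligand_ring_atoms: tuple[str, ...]
    protein_ring: str              # residue label + ring tag
    centroid_distance_A: float
    interplanar_angle_deg: float   # in [0, 90]


def _protein_trp_rings(protein: Structure) -> list[tuple[str, np.ndarray]]:
    rings = []
    trp_res = sorted({(a.chain, a.res_id) for a in protein.atoms if a.res_name == "TRP"})
    for chain, res_id in trp_res:
        atoms = protein.residue_atoms(res_id, chain=chain)
        for tag, names in (("six-ring", TRP_SIX_RING), ("five-ring", TRP_FIVE_RING)):
            if all(n in atoms for n in names):
                coords = np.array([atoms[n] for n in names])
                rings.append((f"TRP{res_id} {tag}", coords))
    return rings


def detect_pi_stacking(pose: PoseComplex, d_max: float = 5.5,
                       angle_max: float = 30.0,
                       ligand_rings: Sequence[Sequence[str]] | None = None
                       ) -> list[PiStack]:
    """Parallel π-stacking between ligand rings and Trp indole rings.

    Ligand rings are perceived from distance-based connectivity unless given
    explicitly as atom-name sets. A pair qualifies when ring-centroid
    distance ≤ ``d_max`` and the angle between ring-plane normals (folded to
    [0, 90]°) is ≤ ``angle_max``; T-shaped contacts are out of scope.
    """
    name_by_index = [a.name for a in pose.ligand.atoms]
    coords = pose.ligand.coords()
    if ligand_rings is None:
        ring_indices = _find_rings(coords)
    else:
        index_of = {a.name: i for i, a in enumerate(pose.ligand.atoms)}
        ring_indices = [[index_of[n] for n in names] for names in ligand_rings]
    for ring in ring_indices:
        if len(ring) < 3:
            raise ValueError("a ring needs at least 3 atoms")
    out = []
    for prot_label, prot_coords in _protein_trp_rings(pose.protein):
        p_centroid, p_normal = _ring_plane(prot_coords)
        for ring in ring_indices:
            l_centroid, l_normal = _ring_plane(coords[ring])
            dist = float(np.linalg.norm(l_centroid - p_centroid))
            cosang = abs(float(np.dot(l_normal, p_normal)))
            angle = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
            if dist <= d_max and angle <= angle_max:
                out.append(PiStack(tuple(name_by_index[i] for i in ring),
                                   prot_label, dist, angle))
    return sorted(out, key=lambda s: s.centroid_distance_A)


# ---------------------------------------------------------------------------
# Pocket occupancy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Occupancy:
    contact_count: int
    fragment_label: str
    fragment_atoms: tuple[str, ...]
    fragment_counts: Mapping[str, int]


def _fragment_label(atoms: list[AtomRecord]) -> str:
    if len(atoms) == 1:
        el = atoms[0].element.capitalize()
        return f"{el} atom"
    counts: dict[str, int] = {}
    for a in atoms:
        el = a.element.capitalize()
        counts[el] = counts.get(el, 0) + 1
    formula = "".join(f"{el}{n if n > 1 else ''}" for el, n in sorted(counts.items()))
    return f"{formula} fragment"


def pocket_occupancy(pose: PoseComplex, pocket_residues: Sequence[str],
                     cutoff: float = 4.5) -> Occupancy:
    """Hydrophobic ligand atoms filling the pocket lined by given residues.

    Counts ligand carbon/halogen atoms within ``cutoff`` Å of any sidechain
    atom of the pocket residues and labels the connected ligand fragment
    contributing the most contacts.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    labels = {_residue_label(a) for a in pose.protein.atoms}
    unknown = [r for r in pocket_residues if r not in labels]
    if unknown:
        raise ValueError(f"unknown pocket residues: {unknown}")
    wanted = set(pocket_residues)
    pocket_atoms = [
        a for a in pose.protein.atoms
        if _residue_label(a) in wanted and a.name not in BACKBONE_ATOMS
    ]
    lig_atoms = pose.ligand.atoms
    hydrophobic = [i for i, a in enumerate(lig_atoms)
                   if a.element.upper() in HYDROPHOBIC_ELEMENTS]
    if not pocket_atoms or not hydrophobic:
        return Occupancy(0, "", (), {})
    lig_coords = pose.ligand.coords()
    d = cdist(lig_coords[hydrophobic], np.array([a.coord for a in pocket_atoms]))
    in_contact = {hydrophobic[i] for i in np.nonzero((d <= cutoff).any(axis=1))[0]}
    if not in_contact:
        return Occupancy(0, "", (), {})
    components = _connected_components(_bond_adjacency(lig_coords))
    frag_counts: dict[str, int] = {}
    best_component: list[int] = []
    best_count = -1
    for comp in components:
        count = len(set(comp) & in_contact)
        label = _fragment_label([lig_atoms[i] for i in comp])
        if count:
            frag_counts[label] = frag_counts.get(label, 0) + count
        if count > best_count:
            best_count, best_component = count, comp
    best_atoms = [lig_atoms[i] for i in best_component]
    return Occupancy(
        contact_count=len(in_contact),
        fragment_label=_fragment_label(best_atoms),
        fragment_atoms=tuple(a.name for a in best_atoms),
        fragment_counts=frag_counts,
    )


# ---------------------------------------------------------------------------
# Checklists and persistence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChecklistRecord:
    """One ligand's Trp34-pocket interaction checklist.

    ``all_key_interactions`` is the conjunction demanded of a structure
    corrector: Trp34 flipped in, H-bonds to both Asp35 and Asp153, and a
    hydrophobic group actually filling the opened pocket.
    """

    ligand_id: str
    trp34_orientation: str
    hbond_asp35: bool
    hbond_asp153: bool
    fill_count: int
    fill_label: str = ""

    @property
    def all_key_interactions(self) -> bool:
        return (self.trp34_orientation == "flip-in" and self.hbond_asp35
                and self.hbond_asp153 and self.fill_count > 0)


def build_checklist(pose: PoseComplex, flip: FlipClassification,
                    ligand_id: str | None = None,
                    hbond_d_max: float = 3.5,
                    pocket_residues: Sequence[str] = ("TRP34",),
                    occupancy_cutoff: float = 4.5,
                    asp35: str = "ASP35", asp153: str = "ASP153") -> ChecklistRecord:
    """Run all detectors on a pose and assemble its checklist record."""
    hbonds = detect_hbonds(pose, d_max=hbond_d_max)
    residues_bonded = {h.residue for h in hbonds}
    occ = pocket_occupancy(pose, pocket_residues, cutoff=occupancy_cutoff)
    return ChecklistRecord(
        ligand_id=ligand_id if ligand_id is not None else pose.pose_id,
        trp34_orientation=flip.state,
        hbond_asp35=asp35 in residues_bonded,
        hbond_asp153=asp153 in residues_bonded,
        fill_count=occ.contact_count,
        fill_label=occ.fragment_label,
    )


@dataclass(frozen=True)
class PersistenceProfile:
    """Fraction of trajectory frames in which each interaction is maintained."""

    fractions: Mapping[str, float]
    n_frames: int


def persistence_profile(checklists: Sequence[ChecklistRecord]) -> PersistenceProfile:
    if not checklists:
        raise ValueError("at least one frame is required")
    n = len(checklists)
    fractions = {
        "flip_in": sum(c.trp34_orientation == "flip-in" for c in checklists) / n,
        "hbond_asp35": sum(c.hbond_asp35 for c in checklists) / n,
        "hbond_asp153": sum(c.hbond_asp153 for c in checklists) / n,
        "pocket_filled": sum(c.fill_count > 0 for c in checklists) / n,
    }
    return PersistenceProfile(fractions=fractions, n_frames=n)


def count_all_key(records: Iterable[ChecklistRecord]) -> int:
    """Number of records exhibiting every key interaction."""
    return sum(1 for r in records if r.all_key_interactions)
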