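"""Readers and writers for screening-pipeline file formats.

Covers AutoDock-Vina-style log text, dissociation-constant (Kd) tables with
censoring marks, fixed-column PDB coordinate files, wide score matrices
(one column per receptor structure) and interaction-checklist tables.

Units follow crystallographic/biophysical convention throughout the package:
coordinates and distances in Å, times in ns, Kd in µM, docking scores in
kcal/mol (lower = better).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Censor",
    "KdRecord",
    "VinaMode",
    "VinaResult",
    "AtomRecord",
    "Structure",
    "StructureMeta",
    "ParseError",
    "parse_vina_log",
    "write_vina_log",
    "parse_kd_text",
    "format_kd_text",
    "read_kd_table",
    "write_kd_table",
    "read_pdb",
    "write_pdb",
    "read_score_table",
    "write_score_table",
    "read_interaction_table",
    "write_interaction_table",
]


class ParseError(ValueError):
    """Raised when an input file does not conform to its dialect."""


# ---------------------------------------------------------------------------
# Vina-style docking logs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VinaMode:
    index: int
    affinity_kcal: float
    rmsd_lb: float
    rmsd_ub: float


@dataclass
class VinaResult:
    """Parsed docking log: ordered binding modes for one ligand."""

    ligand_id: str
    modes: list[VinaMode]

    def __post_init__(self) -> None:
        if not self.modes:
            raise ValueError("VinaResult requires at least one mode")
        idx = [m.index for m in self.modes]
        if idx != list(range(1, len(idx) + 1)):
            raise ValueError(f"mode indices must be 1..k consecutive, got {idx}")
        aff = [m.affinity_kcal for m in self.modes]
        if any(b < a for a, b in zip(aff, aff[1:])):
            raise ValueError("affinities must be non-decreasing down the mode list")

    @property
    def best_affinity(self) -> float:
        return self.modes[0].affinity_kcal


_VINA_SEPARATOR = re.compile(r"^-{4,}\+-{4,}\+-{4,}\+-{4,}\s*$")
_VINA_ROW = re.compile(
    r"^\s*(\d+)\s+(-?\d+(?:\.\d+)?)\s+(-?\d+(?:\.\d+)?)\s+(-?\d+(?:\.\d+)?)\s*$"
)


def parse_vina_log(text: str, ligand_id: str = "ligand") -> VinaResult:
    """Parse a Vina-style log into a :class:`VinaResult`.

    The mode table is located by its ``-----+------+...`` separator line;
    rows after it are ``mode  affinity  rmsd_lb  rmsd_ub``.
    """
    lines = text.splitlines()
    start = None
    for i, line in enumerate(lines):
        if _VINA_SEPARATOR.match(line):
            start = i + 1
            break
    if start is None:
        raise ParseError(
            "no mode table found: expected a '-----+------------+----------+"
            "----------' separator line"
        )
    modes: list[VinaMode] = []
    for j, line in enumerate(lines[start:], start=start):
        if not line.strip():
            break
        m = _VINA_ROW.match(line)
        if m is None:
            if modes:
                break  # footer text after the table
            raise ParseError(f"line {j + 1}: malformed mode row: {line!r}")
        modes.append(
            VinaMode(int(m.group(1)), float(m.group(2)), float(m.group(3)), float(m.group(4)))
        )
    if not modes:
        raise ParseError(f"line {start + 1}: mode table has no data rows")
    return VinaResult(ligand_id=ligand_id, modes=modes)


def write_vina_log(result: VinaResult) -> str:
    """Render a :class:`VinaResult` as Vina-style log text (inverse of parse)."""
    out = [
        "mode |   affinity | dist from best mode",
        "     | (kcal/mol) | rmsd l.b.| rmsd u.b.",
        "-----+------------+----------+----------",
    ]
    for m in result.modes:
        out.append(
            f"{m.index:>4}  {m.affinity_kcal:>10.1f}  {m.rmsd_lb:>9.3f}  {m.rmsd_ub:>9.3f}"
        )
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Kd tables with censoring
# ---------------------------------------------------------------------------

class Censor(Enum):
    """Censoring status of a binding-affinity entry.

    ``BELOW`` means the printed value is an upper bound ("<5"), ``ABOVE`` a
    lower bound (">100"); ``NO_BINDING`` carries no numeric value at all.
    """

    NONE = "none"
    BELOW = "below"
    ABOVE = "above"
    NO_BINDING = "no_binding"


@dataclass(frozen=True)
class KdRecord:
    ligand_id: str
    kd_um: float | None
    censor: Censor = Censor.NONE
    uncertainty_um: float | None = None
    protein: str | None = None

    def __post_init__(self) -> None:
        if self.censor is Censor.NO_BINDING:
            if self.kd_um is not None:
                raise ValueError("no_binding records carry no numeric Kd")
        else:
            if self.kd_um is None:
                raise ValueError("non-censored record requires a Kd value")
            if self.kd_um <= 0:
                raise ValueError(f"Kd must be positive, got {self.kd_um}")


_KD_VALUE = re.compile(
    r"^\s*(\d+(?:\.\d+)?)\s*(?:±|\+/-|\+-)\s*(\d+(?:\.\d+)?)\s*$|^\s*(\d+(?:\.\d+)?)\s*$"
)


def parse_kd_text(text: str) -> tuple[float | None, Censor, float | None]:
    """Parse one Kd cell: ``"900 ± 108"``, ``"<5"``, ``">100"``, ``"No binding"``.

    Returns ``(kd_um, censor, uncertainty_um)``. Unknown tokens raise
    :class:`ParseError`; values are never silently coerced.
    """
    s = text.strip()
    if s.lower() in {"no binding", "no-binding", "nobinding"}:
        return None, Censor.NO_BINDING, None
    if s.startswith("<"):
        return _parse_positive(s[1:], s), Censor.BELOW, None
    if s.startswith(">"):
        return _parse_positive(s[1:], s), Censor.ABOVE, None
    m = _KD_VALUE.match(s)
    if m is None:
        raise ParseError(f"unparseable Kd entry: {text!r}")
    if m.group(1) is not None:
        return float(m.group(1)), Censor.NONE, float(m.group(2))
    return float(m.group(3)), Censor.NONE, None


def _parse_positive(token: str, original: str) -> float:
    try:
        v = float(token)
    except ValueError as exc:
        raise ParseError(f"unparseable Kd entry: {original!r}") from exc
    if v <= 0:
        raise ParseError(f"Kd bound must be positive: {original!r}")
    return v


def format_kd_text(record: KdRecord) -> str:
    if record.censor is Censor.NO_BINDING:
        return "No binding"
    if record.censor is Censor.BELOW:
        return f"<{record.kd_um:g}"
    if record.censor is Censor.ABOVE:
        return f">{record.kd_um:g}"
    if record.uncertainty_um is not None:
        return f"{record.kd_um:g} ± {record.uncertainty_um:g}"
    return f"{record.kd_um:g}"


def read_kd_table(
    source,
    kd_columns: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> list[KdRecord]:
    """Read a Kd table into :class:`KdRecord` objects.

    By default expects columns ``ligand_id`` and ``kd_text``. With
    ``kd_columns={"ApoE4 Kd (µM)": "ApoE4", ...}`` the named columns are
    parsed as one record per ligand × protein (wide assay tables).
    """
    df = pd.read_csv(source, sep=sep, dtype=str)
    if df.empty:
        raise ParseError("no data rows in Kd table")
    errors: list[str] = []
    records: list[KdRecord] = []
    if kd_columns is None:
        _require_columns(df, ["ligand_id", "kd_text"], "Kd table")
        items: Iterable[tuple[str, str, str | None]] = (
            (str(r.ligand_id), str(r.kd_text), None) for r in df.itertuples()
        )
    else:
        _require_columns(df, ["ligand_id", *kd_columns], "Kd table")
        items = (
            (str(row["ligand_id"]), str(row[col]), protein)
            for _, row in df.iterrows()
            for col, protein in kd_columns.items()
        )
    for ligand_id, text, protein in items:
        try:
            kd, censor, unc = parse_kd_text(text)
        except ParseError as exc:
            errors.append(f"{ligand_id}: {exc}")
            continue
        records.append(KdRecord(ligand_id, kd, censor, unc, protein))
    if errors:
        raise ParseError("unparseable Kd rows:\n  " + "\n  ".join(errors))
    return records


def write_kd_table(records: Sequence[KdRecord], path, sep: str = "\t") -> None:
    df = pd.DataFrame(
        {"ligand_id": [r.ligand_id for r in records],
         "kd_text": [format_kd_text(r) for r in records]}
    )
    df.to_csv(path, sep=sep, index=False)


def _require_columns(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{what} is missing required columns: {missing}")


# ---------------------------------------------------------------------------
# PDB coordinates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    altloc: str
    res_name: str
    chain: str
    res_id: int
    x: float
    y: float
    z: float
    element: str
    hetero: bool = False

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Structure:
    """Flat list of atom records with Å coordinates."""

    atoms: list[AtomRecord]
    source_id: str = ""

    def __post_init__(self) -> None:
        keys = set()
        for a in self.atoms:
            if not np.all(np.isfinite([a.x, a.y, a.z])):
                raise ValueError(f"non-finite coordinates for atom {a.serial} {a.name}")
            key = (a.chain, a.res_id, a.name, a.altloc)
            if key in keys:
                raise ValueError(f"duplicate atom {key} in structure {self.source_id!r}")
            keys.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def select(self, **criteria) -> "Structure":
        """Subset by atom-record fields, e.g. ``select(res_id=34, chain="A")``."""
        kept = [
            a for a in self.atoms
            if all(getattr(a, k) == v for k, v in criteria.items())
        ]
        return Structure(kept, source_id=self.source_id)

    def residue_atoms(self, res_id: int, chain: str | None = None) -> dict[str, np.ndarray]:
        """Map atom name -> coordinate for one residue."""
        out: dict[str, np.ndarray] = {}
        for a in self.atoms:
            if a.res_id == res_id and (chain is None or a.chain == chain):
                out[a.name] = a.coord
        return out

    def ca_coords(self, chain: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """CA coordinates and their residue numbers, in record order."""
        cas = [a for a in self.atoms if a.name == "CA" and (chain is None or a.chain == chain)]
        coords = np.array([[a.x, a.y, a.z] for a in cas], dtype=float).reshape(-1, 3)
        resids = np.array([a.res_id for a in cas], dtype=float)
        return coords, resids

    def translated(self, shift) -> "Structure":
        return self.transformed(np.eye(3), np.asarray(shift, dtype=float))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new = []
        for a in self.atoms:
            x, y, z = R @ a.coord + t
            new.append(
                AtomRecord(a.serial, a.name, a.altloc, a.res_name, a.chain,
                           a.res_id, float(x), float(y), float(z), a.element, a.hetero)
            )
        return Structure(new, source_id=self.source_id)


def read_pdb(path, source_id: str | None = None) -> Structure:
    """Read ATOM/HETATM records from a fixed-column PDB file.

    Alternate-location policy: atoms with altloc other than blank or 'A' are
    dropped (count logged); the kept altloc is normalised to blank.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(path)
    try:
        arr = pdb.get_structure(model=1, altloc="all", extra_fields=["atom_id"])
    except Exception as exc:  # biotite reports the offending line itself
        raise ParseError(f"malformed PDB file {path!r}: {exc}") from exc
    altloc = (
        arr.altloc_id if "altloc_id" in arr.get_annotation_categories()
        else np.array([" "] * arr.array_length())
    )
    keep = np.isin(altloc, [" ", "", "A"])
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d atoms with altloc other than blank/'A'", n_dropped)
    atoms = []
    for i in np.flatnonzero(keep):
        atoms.append(
            AtomRecord(
                serial=int(arr.atom_id[i]),
                name=str(arr.atom_name[i]),
                altloc="",
                res_name=str(arr.res_name[i]),
                chain=str(arr.chain_id[i]),
                res_id=int(arr.res_id[i]),
                x=float(arr.coord[i, 0]),
                y=float(arr.coord[i, 1]),
                z=float(arr.coord[i, 2]),
                element=str(arr.element[i]),
                hetero=bool(arr.hetero[i]),
            )
        )
    sid = source_id if source_id is not None else Path(str(path)).stem
    return Structure(atoms, source_id=sid)


def write_pdb(structure: Structure, path) -> None:
    """Write fixed-column ATOM/HETATM records (3-decimal coordinates)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = len(structure.atoms)
    arr = struc.AtomArray(n)
    arr.coord = structure.coords()
    arr.set_annotation("atom_id", np.array([a.serial for a in structure.atoms]))
    arr.chain_id = np.array([a.chain for a in structure.atoms])
    arr.res_id = np.array([a.res_id for a in structure.atoms])
    arr.res_name = np.array([a.res_name for a in structure.atoms])
    arr.atom_name = np.array([a.name for a in structure.atoms])
    arr.element = np.array([a.element for a in structure.atoms])
    arr.hetero = np.array([a.hetero for a in structure.atoms])
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(path)


# ---------------------------------------------------------------------------
# Structure metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StructureMeta:
    """Provenance and triage attributes of one receptor crystal structure."""

    pdb_id: str
    isoform: str              # E2 | E3 | E4
    category: str             # apo | holo
    method: str               # X-ray | NMR | EM
    resolution_A: float | None
    mutant: bool
    trp34_orientation: str    # flip-in | flip-out | unknown

    def __post_init__(self) -> None:
        if self.isoform not in {"E2", "E3", "E4"}:
            raise ValueError(f"unknown isoform {self.isoform!r}")
        if self.category not in {"apo", "holo"}:
            raise ValueError(f"unknown category {self.category!r}")
        if self.method == "X-ray" and (self.resolution_A is None or self.resolution_A <= 0):
            raise ValueError("X-ray entries require a positive resolution")
        if self.trp34_orientation not in {"flip-in", "flip-out", "unknown"}:
            raise ValueError(f"unknown orientation {self.trp34_orientation!r}")


# ---------------------------------------------------------------------------
# Score and interaction tables
# ---------------------------------------------------------------------------

def read_score_table(source, categories: Mapping[str, str],
                     value_kind: str = "rank", sep: str = "\t"):
    """Read a wide score/rank matrix (``ligand_id`` + one column per structure).

    ``categories`` maps each structure column to its ensemble category
    (``apoE3`` / ``free-apoE4`` / ``holo-apoE4``). Missing cells stay NaN and
    are flagged by downstream consumers, never imputed.
    """
    from .consensus import ScoreMatrix

    df = pd.read_csv(source, sep=sep)
    if df.empty:
        raise ParseError("no data rows in score table")
    _require_columns(df, ["ligand_id"], "score table")
    structure_cols = [c for c in df.columns if c != "ligand_id"]
    if not structure_cols:
        raise ParseError("score table has no structure columns")
    values = df.set_index(df["ligand_id"].astype(str))[structure_cols].astype(float)
    values.index.name = "ligand_id"
    return ScoreMatrix(values=values, categories=dict(categories), value_kind=value_kind)


def write_score_table(matrix, path, sep: str = "\t") -> None:
    matrix.values.reset_index().to_csv(path, sep=sep, index=False)


_CHECKLIST_COLUMNS = {
    "ligand_id": "ligand_id",
    "trp34_orientation": "trp34_orientation",
    "hbond_asp35": "hbond_asp35",
    "hbond_asp153": "hbond_asp153",
    "pocket_fill": "pocket_fill",
}
_NO_INTERACTION_TOKENS = {"", "-", "--", "----", "––––", "none", "nan"}


def read_interaction_table(source, sep: str = "\t"):
    """Read a Trp34-pocket interaction checklist table.

    Expected columns: ``ligand_id``, ``trp34_orientation`` ("Flip-in"/"Flip-out"),
    ``hbond_asp35`` / ``hbond_asp153`` ("H-bond" or a no-interaction dash) and
    ``pocket_fill`` (occupying-group label, dash if empty).
    """
    from .interactions import ChecklistRecord

    df = pd.read_csv(source, sep=sep, dtype=str)
    if df.empty:
        raise ParseError("no data rows in interaction table")
    _require_columns(df, list(_CHECKLIST_COLUMNS), "interaction table")
    records = []
    for i, row in df.iterrows():
        orientation = str(row["trp34_orientation"]).strip().lower()
        if orientation not in {"flip-in", "flip-out"}:
            raise ParseError(f"row {i}: unknown orientation {row['trp34_orientation']!r}")
        fill = str(row["pocket_fill"]).strip()
        has_fill = fill.lower() not in _NO_INTERACTION_TOKENS
        records.append(
            ChecklistRecord(
                ligand_id=str(row["ligand_id"]),
                trp34_orientation=orientation,
                hbond_asp35=_parse_hbond_cell(row["hbond_asp35"], i),
                hbond_asp153=_parse_hbond_cell(row["hbond_asp153"], i),
                fill_count=1 if has_fill else 0,
                fill_label=fill if has_fill else "",
            )
        )
    return records


def _parse_hbond_cell(cell, row_index: int) -> bool:
    token = str(cell).strip().lower()
    if token == "h-bond":
        return True
    if token in _NO_INTERACTION_TOKENS:
        return False
    raise ParseError(f"row {row_index}: unknown interaction token {cell!r}")


def write_interaction_table(records, path, sep: str = "\t") -> None:
    rows = []
    for r in records:
        rows.append({
            "ligand_id": r.ligand_id,
            "trp34_orientation": r.trp34_orientation.capitalize(),
            "hbond_asp35": "H-bond" if r.hbond_asp35 else "----",
            "hbond_asp153": "H-bond" if r.hbond_asp153 else "----",
            "pocket_fill": r.fill_label if r.fill_count else "----",
        })
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
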