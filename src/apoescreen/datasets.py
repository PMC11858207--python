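"""Reference benchmark tables for the ApoE4 screening pipeline.

Small published benchmark inputs bundled as text: the docking-rank matrix of
the eight known ApoE4 stabilizers (AbbVie series) against the six-structure
ApoE ensemble with their NMR Kd values, the two top-25 virtual-screening
hitlists (ensemble docking vs 3D shape), the induced-fit-docking interaction
checklist of the known stabilizers, the SPR Kd panel of Isobavachin and
related flavonoids, and the metadata of the candidate receptor structures.

All loaders parse the bundled text through the package's own readers, so the
benchmark data also exercise the I/O layer.
"""

from __future__ import annotations

from io import StringIO

from .consensus import ScoreMatrix
from .interactions import ChecklistRecord
from .io import (
    KdRecord,
    StructureMeta,
    read_interaction_table,
    read_kd_table,
    read_score_table,
)

__all__ = [
    "ENSEMBLE_CATEGORIES",
    "LIBRARY_SIZE",
    "SCREENED_LIBRARY_SIZE",
    "ACTIVITY_CUTOFF_UM",
    "DOCKING_TOP25",
    "SHAPE_TOP25",
    "load_known_ligand_ranks",
    "load_known_ligand_kd",
    "load_benchmark_checklist",
    "load_spr_kd_table",
    "load_structure_metadata",
]

#: Ensemble category of each receptor structure used for screening
ENSEMBLE_CATEGORIES = {
    "1NFN": "apoE3",
    "1BZ4": "apoE3",
    "8CE0": "free-apoE4",
    "8CDY": "free-apoE4",
    "6NCN": "holo-apoE4",
    "6NCO": "holo-apoE4",
}

#: Compound-library size of the screened natural-product database (~1250
#: molecules after molecular-weight filtering) and the screened total
#: including the eight known stabilizers.
LIBRARY_SIZE = 1250
SCREENED_LIBRARY_SIZE = LIBRARY_SIZE + 8

#: Kd cutoff (µM) separating the "more active" known stabilizers.
ACTIVITY_CUTOFF_UM = 30.0

# Docking ranks of the known stabilizers (PubChem CIDs) on each structure.
_KNOWN_RANKS_TSV = """\
ligand_id\t1NFN\t1BZ4\t8CE0\t8CDY\t6NCN\t6NCO
83673143\t1027\t1013\t1029\t993\t733\t853
155530661\t328\t490\t185\t204\t519\t572
137796780\t527\t565\t242\t298\t65\t45
155563897\t426\t208\t186\t628\t60\t18
155552638\t444\t400\t660\t664\t109\t76
155557185\t471\t652\t519\t505\t61\t25
155511476\t470\t651\t827\t774\t111\t95
155538646\t594\t611\t659\t744\t116\t148
"""

# NMR Kd panel (µM) of the known stabilizers; "<5" entries are upper bounds.
_KNOWN_KD_TSV = """\
ligand_id\tkd_text
83673143\t900 ± 108
155530661\t230 ± 24
137796780\t30 ± 4
155563897\t20 ± 3
155552638\t20 ± 4
155557185\t8 ± 3
155511476\t<5
155538646\t<5
"""

#: Published library ranks of the known stabilizers under consensus scoring,
#: keyed by CID (used as an ordering benchmark).
PUBLISHED_CONSENSUS_RANKS = {
    "83673143": 286,
    "155530661": 1167,
    "137796780": 28,
    "155563897": 9,
    "155552638": 14,
    "155557185": 6,
    "155511476": 11,
    "155538646": 21,
}

#: Top-25 hitlists (PubChem CIDs) from the two screening branches.
DOCKING_TOP25 = [
    "100781", "161294", "91510", "193679", "441805", "11556558", "94320",
    "9974201", "10114", "71773126", "163184367", "14077830", "9983614",
    "11003773", "64945", "102501232", "73347309", "9548703", "14463159",
    "91471", "5380976", "114850", "163005195", "92097", "151529",
]
SHAPE_TOP25 = [
    "53266", "160487", "5320382", "114829", "5282073", "632135", "193679",
    "46886723", "115067", "5281601", "5316844", "92775", "5280443", "96539",
    "5281617", "5322078", "10450045", "198910", "5319081", "5320053",
    "11601633", "439246", "5318980", "5281698", "72303",
]

# Induced-fit-docking interaction checklist of the known stabilizers.
_BENCHMARK_CHECKLIST_TSV = """\
ligand_id\ttrp34_orientation\thbond_asp35\thbond_asp153\tpocket_fill
83673143\tFlip-in\t----\tH-bond\tCl atom
155530661\tFlip-in\tH-bond\t----\tCl atom
137796780\tFlip-in\tH-bond\tH-bond\tCl atom
155563897\tFlip-in\tH-bond\tH-bond\tCl atom
155552638\tFlip-in\tH-bond\tH-bond\tCl atom
155557185\tFlip-in\tH-bond\tH-bond\tCl atom
155511476\tFlip-in\tH-bond\tH-bond\tCl atom
155538646\tFlip-in\tH-bond\tH-bond\tCl atom
"""

# SPR Kd panel (µM) of Isobavachin and related flavonoids against ApoE3,
# ApoE4 and the negative-control protein DNPH1.
_SPR_TSV = """\
ligand_id\tApoE3\tApoE4\tDNPH1
Isobavachin\t0.62\t0.54\t>100
Bavachin\t59\t64\tNo binding
Daidzein\t>100\t>100\t>100
Genistein\t>100\t>100\t>100
Glabrol\t>100\t77\t>100
Idronoxil\t>100\t>100\t>100
Isoxanthohumol\t38\t40\t>100
Morusin\t>100\t>100\t69
Mulberrin\t>100\t>100\t>100
"""

#: Names of the flavonoids assayed in addition to the primary hit.
ADDITIONAL_FLAVONOIDS = [
    "Bavachin", "Daidzein", "Genistein", "Glabrol", "Idronoxil",
    "Isoxanthohumol", "Morusin", "Mulberrin",
]

# Candidate receptor structures: high-resolution, non-mutant ApoE entries
# with their observed Trp34 orientation.
_STRUCTURE_METADATA = [
    # pdb_id, isoform, category, method, resolution, mutant, orientation
    ("1NFN", "E3", "apo", "X-ray", 1.90, False, "flip-in"),
    ("1BZ4", "E3", "apo", "X-ray", 1.85, False, "flip-in"),
    ("1OR3", "E3", "apo", "X-ray", 1.73, False, "flip-out"),
    ("8CE0", "E4", "apo", "X-ray", 1.40, False, "flip-out"),
    ("8CDY", "E4", "apo", "X-ray", 1.80, False, "flip-out"),
    ("1B68", "E4", "apo", "X-ray", 1.90, False, "flip-in"),
    ("6NCN", "E4", "holo", "X-ray", 1.70, False, "flip-in"),
    ("6NCO", "E4", "holo", "X-ray", 1.90, False, "flip-in"),
]


def load_known_ligand_ranks() -> ScoreMatrix:
    """8 × 6 rank matrix of the known stabilizers over the docking ensemble."""
    return read_score_table(StringIO(_KNOWN_RANKS_TSV),
                            categories=ENSEMBLE_CATEGORIES, value_kind="rank")


def load_known_ligand_kd() -> list[KdRecord]:
    """NMR Kd records of the known stabilizers (µM, with censoring)."""
    return read_kd_table(StringIO(_KNOWN_KD_TSV))


def load_benchmark_checklist() -> list[ChecklistRecord]:
    """Interaction checklist of the known stabilizers' induced-fit poses."""
    return read_interaction_table(StringIO(_BENCHMARK_CHECKLIST_TSV))


def load_spr_kd_table() -> list[KdRecord]:
    """SPR Kd panel: one record per flavonoid × protein."""
    return read_kd_table(
        StringIO(_SPR_TSV),
        kd_columns={"ApoE3": "ApoE3", "ApoE4": "ApoE4", "DNPH1": "DNPH1"},
    )


def load_structure_metadata() -> list[StructureMeta]:
    """Metadata of the eight candidate receptor structures."""
    return [
        StructureMeta(pdb_id=p, isoform=iso, category=cat, method=m,
                      resolution_A=res, mutant=mut, trp34_orientation=ori)
        for p, iso, cat, m, res, mut, ori in _STRUCTURE_METADATA
    ]
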