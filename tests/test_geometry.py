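"""Dihedral, axis, flip-classification, superposition and RMSD geometry."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from apoescreen.datasets import load_structure_metadata
from apoescreen.geometry import (
    DihedralSeries,
    FlipClassification,
    UndefinedDihedralError,
    chi_angles,
    classify_flip,
    classify_flip_chi,
    dihedral,
    flip_fraction,
    kabsch_superpose,
    protein_axis,
    rmsd_series,
    triage_structures,
)
from apoescreen.io import AtomRecord, Structure
from apoescreen.synthetic import build_trp_residue


def _random_isometry(rng):
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-10, 10, 3)
    return R, t


class TestDihedral:
    def test_planar_anti_arrangement(self):
        assert dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0)) == pytest.approx(180.0)

    def test_out_of_plane_quarter_turn(self):
        # sign fixed by the package convention (positive = clockwise looking
        # down the central bond)
        assert dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)) == pytest.approx(-90.0)

    def test_matches_independent_implementation_up_to_convention(self, rng):
        from MDAnalysis.lib.distances import calc_dihedrals

        for _ in range(50):
            pts = rng.normal(0, 3, size=(4, 3))
            try:
                ours = dihedral(*pts)
            except UndefinedDihedralError:
                continue
            other = np.degrees(calc_dihedrals(
                *[p[None, :].astype(np.float64) for p in pts]))[0]
            # MDAnalysis reports the opposite sign convention
            assert ours == pytest.approx(-other, abs=1e-4)

    def test_isometry_invariance_and_reflection_antisymmetry(self, rng):
        pts = rng.normal(0, 3, size=(4, 3))
        base = dihedral(*pts)
        R, t = _random_isometry(rng)
        moved = [R @ p + t for p in pts]
        assert dihedral(*moved) == pytest.approx(base, abs=1e-9)
        mirrored = [p * np.array([1, 1, -1]) for p in pts]
        assert dihedral(*mirrored) == pytest.approx(-base, abs=1e-9)

    def test_collinear_points_rejected(self):
        with pytest.raises(UndefinedDihedralError):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


class TestChiAngles:
    @pytest.mark.parametrize("chi1, chi2", [(-60.0, 95.0), (175.0, -100.0), (60.0, 0.0)])
    def test_constructed_residue_round_trip(self, chi1, chi2):
        residue = build_trp_residue(chi1, chi2)
        got1, got2 = chi_angles(residue)
        assert got1 == pytest.approx(chi1, abs=0.1)
        assert got2 == pytest.approx(chi2, abs=0.1)

    def test_rotation_about_ca_cb_shifts_chi1_only(self):
        residue = build_trp_residue(-60.0, 95.0)
        axis = residue["CB"] - residue["CA"]
        rot = Rotation.from_rotvec(np.radians(-30.0) * axis / np.linalg.norm(axis))
        moved = dict(residue)
        for name in ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"):
            moved[name] = rot.apply(residue[name] - residue["CB"]) + residue["CB"]
        chi1, chi2 = chi_angles(moved)
        assert chi1 == pytest.approx(-30.0, abs=0.1)
        assert chi2 == pytest.approx(95.0, abs=0.1)

    def test_missing_atom_named_in_error(self):
        residue = build_trp_residue()
        residue.pop("CG")
        with pytest.raises(ValueError, match="missing atom CG"):
            chi_angles(residue)


def _ca_structure(coords, start_resid=1):
    atoms = [
        AtomRecord(i + 1, "CA", "", "GLY", "A", start_resid + i,
                   float(x), float(y), float(z), "C")
        for i, (x, y, z) in enumerate(coords)
    ]
    return Structure(atoms)


class TestProteinAxis:
    def test_points_along_z(self):
        coords = [(0, 0, z) for z in range(6)]
        axis = protein_axis(_ca_structure(coords))
        np.testing.assert_allclose(axis, [0, 0, 1], atol=1e-12)

    def test_rotation_equivariance(self, rng):
        coords = rng.normal(0, 1, (20, 3)) + np.outer(np.arange(20), [1.0, 0.2, 0.0])
        axis = protein_axis(coords)
        R, _ = _random_isometry(rng)
        rotated_axis = protein_axis(coords @ R.T)
        np.testing.assert_allclose(rotated_axis, R @ axis, atol=1e-9)

    def test_helix_recovers_construction_axis(self):
        t = np.arange(30)
        helix = np.c_[2.3 * np.cos(t * 1.75), 2.3 * np.sin(t * 1.75), 1.5 * t]
        axis = protein_axis(helix)
        angle = np.degrees(np.arccos(abs(axis @ [0, 0, 1])))
        assert angle < 5.0

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            protein_axis(_ca_structure([(0, 0, 0), (0, 0, 1)]))


def _trp_structure_with_orientation(angle_deg):
    """Trp-like residue whose CB→ring-centroid vector makes the requested
    angle with the x axis."""
    residue = build_trp_residue()
    from apoescreen.geometry import INDOLE_RING_ATOMS

    centroid = np.mean([residue[a] for a in INDOLE_RING_ATOMS], axis=0)
    v = centroid - residue["CB"]
    target = np.array([np.cos(np.radians(angle_deg)), np.sin(np.radians(angle_deg)), 0.0])
    rot, _ = Rotation.align_vectors(target[None, :], (v / np.linalg.norm(v))[None, :])
    atoms = []
    for i, (name, pos) in enumerate(residue.items()):
        p = rot.apply(pos - residue["CB"])
        element = "N" if name.startswith("N") else "O" if name.startswith("O") else "C"
        atoms.append(AtomRecord(i + 1, name, "", "TRP", "A", 34,
                                float(p[0]), float(p[1]), float(p[2]), element))
    return Structure(atoms)


class TestClassifyFlip:
    @pytest.mark.parametrize("angle, state", [
        (0.0, "flip-out"), (30.0, "flip-out"), (60.0, "flip-in"), (90.0, "flip-in"),
    ])
    def test_constructed_orientations(self, angle, state):
        s = _trp_structure_with_orientation(angle)
        result = classify_flip(s, 34, axis=[1.0, 0.0, 0.0])
        assert result.angle_to_axis == pytest.approx(angle, abs=1e-6)
        assert result.state == state

    def test_axis_sign_is_irrelevant(self):
        s = _trp_structure_with_orientation(25.0)
        a = classify_flip(s, 34, axis=[1, 0, 0])
        b = classify_flip(s, 34, axis=[-1, 0, 0])
        assert a.angle_to_axis == pytest.approx(b.angle_to_axis)

    def test_small_perturbations_barely_move_the_angle(self, rng):
        s = _trp_structure_with_orientation(30.0)
        base = classify_flip(s, 34, axis=[1, 0, 0]).angle_to_axis
        for _ in range(5):
            jitter = rng.uniform(-0.01, 0.01, (len(s.atoms), 3))
            atoms = [
                AtomRecord(a.serial, a.name, a.altloc, a.res_name, a.chain, a.res_id,
                           a.x + d[0], a.y + d[1], a.z + d[2], a.element)
                for a, d in zip(s.atoms, jitter)
            ]
            moved = classify_flip(Structure(atoms), 34, axis=[1, 0, 0]).angle_to_axis
            assert abs(moved - base) < 1.0

    def test_incomplete_ring_is_an_error(self):
        s = _trp_structure_with_orientation(30.0)
        pruned = Structure([a for a in s.atoms if a.name != "CZ3"])
        with pytest.raises(ValueError, match="incomplete indole"):
            classify_flip(pruned, 34, axis=[1, 0, 0])

    def test_state_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            FlipClassification(30.0, "flip-in", 45.0, np.array([1.0, 0, 0]))

    def test_chi_based_classifier_agrees_on_state_centers(self):
        assert classify_flip_chi(-65.0, 95.0) == "flip-in"
        assert classify_flip_chi(-177.0, -100.0) == "flip-out"
        # wrap-around: χ1 = 179 is close to the flip-out center at -177
        assert classify_flip_chi(179.0, -100.0) == "flip-out"


class TestTriage:
    def test_benchmark_selection(self):
        result = triage_structures(load_structure_metadata())
        assert sorted(r[0] for r in result.removed) == ["1B68", "1OR3"]
        assert result.selected == ["1NFN", "1BZ4", "8CE0", "8CDY", "6NCN", "6NCO"]

    def test_empty_metadata_empty_selection(self):
        result = triage_structures([])
        assert result.selected == [] and result.removed == []

    def test_consistent_table_removes_nothing(self):
        meta = [m for m in load_structure_metadata() if m.pdb_id not in {"1OR3", "1B68"}]
        assert triage_structures(meta).removed == []

    def test_unknown_orientation_strict_mode(self):
        from apoescreen.io import StructureMeta

        meta = [StructureMeta("XXXX", "E4", "apo", "X-ray", 1.5, False, "unknown")]
        with pytest.raises(ValueError, match="strict"):
            triage_structures(meta, strict=True)
        assert triage_structures(meta).selected == ["XXXX"]


class TestKabsch:
    def test_identical_sets(self, rng):
        pts = rng.normal(0, 2, (10, 3))
        R, t, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)

    def test_rigid_motion_is_removed(self, rng):
        pts = rng.normal(0, 2, (12, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ rot.T + np.array([5.0, -3.0, 2.0])
        _, _, rmsd = kabsch_superpose(pts, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_matches_independent_superposition_rmsd(self, rng):
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd

        ref = np.array([[0, 0, 0], [1.5, 0, 0], [1.5, 1.5, 0], [0, 0, 1.5]])
        mob = ref.copy()
        mob[2] += [0.0, 1.0, 0.0]  # displace one vertex by 1 Å
        _, _, ours = kabsch_superpose(ref, mob)
        theirs = mda_rmsd(mob, ref, center=True, superposition=True)
        assert ours == pytest.approx(theirs, abs=1e-3)
        # no random rigid motion does better than the closed-form optimum
        ref_c = ref - ref.mean(axis=0)
        mob_c = mob - mob.mean(axis=0)
        for _ in range(2000):
            Rr = Rotation.random(rng=rng).as_matrix()
            trial = np.sqrt(np.mean(np.sum((mob_c @ Rr.T - ref_c) ** 2, axis=1)))
            assert trial >= ours - 1e-9

    def test_rotation_is_always_proper(self, rng):
        for _ in range(25):
            ref = rng.normal(0, 1, (5, 3))
            mob = rng.normal(0, 1, (5, 3))
            R, _, rmsd = kabsch_superpose(ref, mob)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
            unsuper = np.sqrt(np.mean(np.sum(
                ((mob - mob.mean(0)) - (ref - ref.mean(0))) ** 2, axis=1)))
            assert rmsd <= unsuper + 1e-9

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRmsdSeries:
    def test_identical_frames_are_zero(self, rng):
        lig = rng.normal(0, 2, (7, 3))
        bb = rng.normal(0, 2, (15, 3))
        series = rmsd_series([lig] * 5, [bb] * 5)
        np.testing.assert_allclose(series.ligand_rmsd_A, 0.0, atol=1e-9)
        np.testing.assert_allclose(series.backbone_rmsd_A, 0.0, atol=1e-9)

    def test_rigidly_moved_frames_have_zero_backbone_rmsd(self, rng):
        lig = rng.normal(0, 2, (7, 3))
        bb = rng.normal(0, 2, (15, 3))
        lig_frames, bb_frames = [lig], [bb]
        for _ in range(4):
            R, t = _random_isometry(rng)
            lig_frames.append(lig @ R.T + t)
            bb_frames.append(bb @ R.T + t)
        series = rmsd_series(lig_frames, bb_frames)
        np.testing.assert_allclose(series.backbone_rmsd_A, 0.0, atol=1e-9)
        np.testing.assert_allclose(series.ligand_rmsd_A, 0.0, atol=1e-9)

    def test_gaussian_jitter_matches_closed_form(self, rng):
        # per-atom isotropic jitter of SD σ has E[RMSD²] = 3σ²; with many
        # atoms the per-frame RMSD concentrates at σ√3
        sigma, n_atoms, n_frames = 0.5, 60, 200
        lig0 = rng.normal(0, 5, (n_atoms, 3))
        bb = rng.normal(0, 5, (20, 3))
        lig_frames = [lig0] + [lig0 + rng.normal(0, sigma, (n_atoms, 3))
                               for _ in range(n_frames)]
        series = rmsd_series(lig_frames, [bb] * (n_frames + 1))
        expected = sigma * np.sqrt(3)
        assert series.ligand_rmsd_A[1:].mean() == pytest.approx(expected, rel=0.10)

    def test_frame_mismatch_names_frame(self, rng):
        lig = rng.normal(0, 1, (5, 3))
        bb = rng.normal(0, 1, (6, 3))
        with pytest.raises(ValueError, match="frame 2"):
            rmsd_series([lig, lig, lig[:4]], [bb, bb, bb])


class TestFlipFraction:
    def test_all_and_alternating(self):
        assert flip_fraction(["flip-in"] * 4) == 1.0
        assert flip_fraction(["flip-in", "flip-out"] * 10) == 0.5

    def test_series_input(self):
        n = 4
        series = DihedralSeries(
            time_ns=np.arange(n, dtype=float),
            chi1_deg=np.zeros(n), chi2_deg=np.zeros(n),
            state=np.array(["flip-in", "flip-in", "flip-out", "flip-in"]))
        assert flip_fraction(series) == 0.75

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            flip_fraction([])
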