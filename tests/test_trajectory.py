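"""Trajectory I/O, rigid superposition, the two alignment modes, wrapping."""

import numpy as np
import pytest

from cdsolv.config import default_config, resolve_selections
from cdsolv.geometry import orientation_series
from cdsolv.synth import (
    ScaffoldSpec,
    SyntheticTrajectorySpec,
    WaterFieldSpec,
    build_scaffold,
    generate_trajectory,
)
from cdsolv.trajectory import (
    AlignmentReference,
    Frame,
    TrajectoryError,
    align_bulk,
    align_interface,
    body_frame,
    kabsch,
    read_trajectory,
    rigid_fit,
    water_sites,
    wrap_solvent,
    write_trajectory,
)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


class TestIO:
    def test_gro_is_read_in_angstrom(self, tmp_path):
        # GRO stores nm; the reader must hand back Angstrom
        gro = tmp_path / "three.gro"
        gro.write_text(
            "three atoms\n"
            "    3\n"
            "    1SOL     OW    1   0.100   0.200   0.300\n"
            "    1SOL    HW1    2   0.150   0.200   0.300\n"
            "    1SOL    HW2    3   0.100   0.250   0.300\n"
            "   2.00000   2.00000   2.00000\n"
        )
        traj = read_trajectory(gro)
        assert traj.n_frames == 1
        np.testing.assert_allclose(traj.positions[0, 0], [1.0, 2.0, 3.0], atol=1e-5)
        np.testing.assert_allclose(traj.boxes[0], [20.0, 20.0, 20.0], atol=1e-5)

    def test_structure_only_gives_single_frame(self, small_traj, tmp_path):
        write_trajectory(small_traj, tmp_path / "s.gro")
        back = read_trajectory(tmp_path / "s.gro")
        assert back.n_frames == 1
        assert back.n_atoms == small_traj.n_atoms

    def test_write_read_roundtrip_within_format_precision(self, small_traj, tmp_path):
        write_trajectory(small_traj, tmp_path / "s.gro", tmp_path / "t.trr")
        back = read_trajectory(tmp_path / "s.gro", tmp_path / "t.trr")
        assert back.n_frames == small_traj.n_frames
        assert np.abs(back.positions - small_traj.positions).max() < 1e-3
        assert list(back.atoms.names) == list(small_traj.atoms.names)

    def test_missing_file_is_a_clean_error(self, tmp_path):
        with pytest.raises(TrajectoryError):
            read_trajectory(tmp_path / "nope.gro")


class TestRigidFit:
    def test_identity_when_already_superposed(self, scaffold):
        f = Frame(scaffold.positions, np.array([50.0, 50.0, 50.0]))
        idx = np.arange(12)
        out = rigid_fit(f, scaffold.positions[idx], idx)
        np.testing.assert_allclose(out.positions, f.positions, atol=1e-9)

    def test_known_transform_recovered(self, scaffold, rng):
        R = random_rotation(rng)
        t = rng.normal(scale=5.0, size=3)
        moved = scaffold.positions @ R.T + t
        f = Frame(moved, np.array([50.0, 50.0, 50.0]))
        idx = np.arange(scaffold.n_atoms)
        out = rigid_fit(f, scaffold.positions, idx)
        rmsd = np.sqrt(((out.positions - scaffold.positions) ** 2).sum(axis=1).mean())
        assert rmsd < 1e-9

    def test_reflection_not_allowed(self, rng):
        # mirror-image reference: a proper rotation cannot fit it exactly
        pts = rng.normal(size=(6, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        R, t = kabsch(pts, mirrored)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        rmsd = np.sqrt(((pts @ R.T + t - mirrored) ** 2).sum(axis=1).mean())
        assert rmsd > 1e-3

    def test_matches_scipy_reference(self, rng):
        """Independent check against scipy's orthogonal-alignment solver."""
        from scipy.spatial.transform import Rotation

        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        R, t = kabsch(a, b)
        ac, bc = a - a.mean(0), b - b.mean(0)
        rot, _ = Rotation.align_vectors(bc, ac)
        np.testing.assert_allclose(R, rot.as_matrix(), atol=1e-8)

    def test_collinear_reference_rejected(self):
        line = np.column_stack([np.arange(6.0), np.zeros(6), np.zeros(6)])
        f = Frame(line + 1.0, np.array([50.0, 50.0, 50.0]))
        with pytest.raises(TrajectoryError, match="degenerate"):
            rigid_fit(f, line, np.arange(6))


class TestAlignBulk:
    def test_axis_on_target_every_frame(self, small_traj, selections):
        al = align_bulk(small_traj, selections.alignment)
        for i in range(al.n_frames):
            bf = body_frame(al.positions[i], selections.alignment)
            assert abs(bf.axis @ np.array([1.0, 0.0, 0.0]) - 1.0) < 1e-9
            np.testing.assert_allclose(bf.origin, 0.0, atol=1e-9)

    def test_idempotent(self, small_traj, selections):
        once = align_bulk(small_traj, selections.alignment)
        twice = align_bulk(once, selections.alignment)
        assert np.abs(twice.positions - once.positions).max() < 1e-9

    def test_rigid_core_pinned_across_frames(self, small_traj, selections):
        # the scaffold moves rigidly, so aligned O4 coordinates are static
        al = align_bulk(small_traj, selections.alignment)
        o4 = al.positions[:, selections.alignment.indices, :]
        assert np.abs(o4 - o4[0]).max() < 1e-9

    def test_distances_invariant(self, small_traj, selections, rng):
        al = align_bulk(small_traj, selections.alignment)
        pairs = rng.integers(0, small_traj.n_atoms, size=(30, 2))
        for i, j in pairs:
            d0 = np.linalg.norm(
                small_traj.positions[:, i] - small_traj.positions[:, j], axis=1
            )
            d1 = np.linalg.norm(al.positions[:, i] - al.positions[:, j], axis=1)
            np.testing.assert_allclose(d0, d1, atol=1e-9)


class TestAlignInterface:
    def test_already_aligned_final_frame_is_fixed_point(self, scaffold):
        from cdsolv.trajectory import Trajectory
        from cdsolv.synth import WaterFieldSpec, SyntheticTrajectorySpec, generate_trajectory

        traj = generate_trajectory(
            scaffold, WaterFieldSpec(n_waters=50, seed=7),
            SyntheticTrajectorySpec(n_frames=4), seed=8,
        )
        sel = resolve_selections(default_config(), traj.atoms)
        al = align_interface(traj, sel.alignment)
        # generator placed the axis along x already: stage 1 must not rotate
        bf = body_frame(al.positions[-1], sel.alignment)
        assert abs(abs(bf.axis[0]) - 1.0) < 1e-9

    def test_normal_drift_preserved_in_plane_drift_removed(self, scaffold):
        wspec = WaterFieldSpec(n_waters=80, seed=9)
        traj = generate_trajectory(
            scaffold, wspec, SyntheticTrajectorySpec(n_frames=6), seed=10
        )
        drift = traj.copy()
        for i in range(drift.n_frames):
            drift.positions[i] += np.array([1.5 * i, -0.7 * i, 2.0 * i])
        sel = resolve_selections(default_config(), drift.atoms)
        al = align_interface(drift, sel.alignment)
        origins = np.array(
            [body_frame(al.positions[i], sel.alignment).origin for i in range(al.n_frames)]
        )
        # in-plane drift of the complex removed by the fit
        assert np.abs(origins[:, :2] - origins[0, :2]).max() < 1e-9
        # the relative complex-to-water geometry along the normal is intact
        series = orientation_series(al, sel.alignment)
        series_raw = orientation_series(drift, sel.alignment)
        np.testing.assert_allclose(series.com_distance, series_raw.com_distance, atol=1e-6)

    def test_pitch_step_survives_alignment(self, scaffold):
        traj = generate_trajectory(
            scaffold, WaterFieldSpec(n_waters=60, seed=11),
            SyntheticTrajectorySpec(n_frames=20, flip_frame=10), seed=12,
        )
        sel = resolve_selections(default_config(), traj.atoms)
        al = align_interface(traj, sel.alignment)
        series = orientation_series(al, sel.alignment)
        assert np.abs(series.pitch[:10]).max() < 1.0
        np.testing.assert_allclose(series.pitch[10:], 90.0, atol=1.0)


class TestWrapSolvent:
    def test_far_image_brought_near(self, small_traj):
        f = small_traj.frame(0)
        sites = water_sites(small_traj.atoms)
        box = f.box
        center = box / 2.0
        shifted = f.positions.copy()
        w0 = sites[0]
        shifted[w0] += np.array([0.9, 0.0, 0.0]) * box  # push one water a box away
        moved = Frame(shifted, box)
        wrapped = wrap_solvent(moved, center, sites)
        assert np.all(np.abs(wrapped.positions[w0[0]] - center) <= box / 2 + 1e-9)

    def test_near_image_untouched(self, scaffold):
        # motionless fixture: every water already in the image nearest the centre
        traj = generate_trajectory(
            scaffold, WaterFieldSpec(n_waters=100, seed=13),
            SyntheticTrajectorySpec(n_frames=1), seed=14,
        )
        f = traj.frame(0)
        sites = water_sites(traj.atoms)
        wrapped = wrap_solvent(f, f.box / 2.0, sites)
        np.testing.assert_allclose(wrapped.positions, f.positions, atol=1e-12)

    def test_intramolecular_geometry_preserved(self, small_traj, rng):
        f = small_traj.frame(0)
        sites = water_sites(small_traj.atoms)
        shifted = f.positions.copy()
        per_mol = rng.integers(1, 3, size=(sites.shape[0], 1)) * f.box[0]
        for col in range(3):
            shifted[sites[:, col], 0] += per_mol[:, 0]
        wrapped = wrap_solvent(Frame(shifted, f.box), f.box / 2.0, sites)
        oh_before = np.linalg.norm(
            f.positions[sites[:, 1]] - f.positions[sites[:, 0]], axis=1
        )
        oh_after = np.linalg.norm(
            wrapped.positions[sites[:, 1]] - wrapped.positions[sites[:, 0]], axis=1
        )
        np.testing.assert_allclose(oh_before, oh_after, atol=1e-9)
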