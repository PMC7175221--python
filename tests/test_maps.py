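"""Water dipoles, slice/shell geometry and density/dipole map accumulation."""

import numpy as np
import pytest
from scipy import stats

from cdsolv.config import default_config, resolve_selections
from cdsolv.maps import (
    SPC,
    E_ANGSTROM_TO_DEBYE,
    MapError,
    accumulate_shell_map,
    accumulate_slice_map,
    build_shells,
    build_slice_set,
    read_map,
    water_dipole,
    water_dipoles,
    write_map,
)
from cdsolv.synth import (
    SyntheticTrajectorySpec,
    WaterFieldSpec,
    build_scaffold,
    generate_trajectory,
    water_sites_from_dipoles,
)
from cdsolv.trajectory import align_bulk


def ideal_spc_sites(direction, origin=np.zeros(3)):
    """One SPC water with its dipole along ``direction``."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    helper = np.array([0.57, -0.81, 0.11])
    p = helper - (helper @ d) * d
    p /= np.linalg.norm(p)
    half = np.deg2rad(109.47 / 2)
    o = np.asarray(origin, float)
    h1 = o + np.cos(half) * d + np.sin(half) * p
    h2 = o + np.cos(half) * d - np.sin(half) * p
    return o, h1, h2


class TestWaterDipole:
    def test_ideal_spc_magnitude(self):
        """|mu| = 2 q_H l_OH cos(theta/2) converted to Debye = 2.27 D."""
        o, h1, h2 = ideal_spc_sites([0.0, 0.0, 1.0])
        mu = water_dipole(o, h1, h2, SPC)
        expected = 2 * 0.41 * np.cos(np.deg2rad(109.47 / 2)) * E_ANGSTROM_TO_DEBYE
        assert np.linalg.norm(mu) == pytest.approx(expected, abs=1e-12)
        assert np.linalg.norm(mu) == pytest.approx(2.27, abs=0.005)
        np.testing.assert_allclose(mu / np.linalg.norm(mu), [0, 0, 1], atol=1e-12)

    def test_collapsed_sites_cancel(self):
        o = np.array([3.0, -1.0, 2.0])
        mu = water_dipole(o, o, o, SPC)
        np.testing.assert_allclose(mu, 0.0, atol=1e-12)

    def test_rotation_equivariance(self, rng):
        def random_rotation(rng):
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            w, x, y, z = q
            return np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ])

        o, h1, h2 = ideal_spc_sites([1.0, 2.0, -0.5], origin=[5.0, 5.0, 5.0])
        mu = water_dipole(o, h1, h2, SPC)
        R = random_rotation(rng)
        mu_rot = water_dipole(o @ R.T, h1 @ R.T, h2 @ R.T, SPC)
        np.testing.assert_allclose(mu_rot, mu @ R.T, atol=1e-10)

    def test_origin_independence(self):
        o, h1, h2 = ideal_spc_sites([0.0, 1.0, 0.0])
        shift = np.array([100.0, -40.0, 7.0])
        mu1 = water_dipole(o, h1, h2, SPC)
        mu2 = water_dipole(o + shift, h1 + shift, h2 + shift, SPC)
        np.testing.assert_allclose(mu1, mu2, atol=1e-9)

    def test_vectorised_matches_scalar(self, rng):
        n = 20
        dirs = rng.normal(size=(n, 3))
        o = rng.uniform(-5, 5, size=(n, 3))
        sites = water_sites_from_dipoles(o, dirs, rng)
        pos = sites.reshape(-1, 3)
        idx = np.arange(3 * n).reshape(n, 3)
        mus = water_dipoles(pos, idx, SPC)
        for k in range(n):
            np.testing.assert_allclose(
                mus[k], water_dipole(*sites[k], SPC), atol=1e-12
            )


class TestRegionGeometry:
    def test_slice_set_count_and_ranges(self):
        slices = build_slice_set()
        perp = [s for s in slices if s.orientation == "perpendicular"]
        par = [s for s in slices if s.orientation == "parallel"]
        assert len(perp) == 9 and len(par) == 1
        ranges = sorted(s.axial_range for s in perp)
        assert (-1.5, 1.5) in ranges
        for lo, hi in ((1, 4), (4, 7), (7, 10), (10, 13)):
            assert (float(lo), float(hi)) in ranges
            assert (float(-hi), float(-lo)) in ranges

    def test_band_between_1_and_1p5_double_counted(self):
        slices = build_slice_set()
        hit = [
            s for s in slices
            if s.orientation == "perpendicular"
            and s.axial_range[0] <= 1.2 < s.axial_range[1]
        ]
        assert len(hit) == 2

    def test_shells_cover_0_to_13(self):
        shells = build_shells()
        assert len(shells) == 13
        assert (shells[0].r_min, shells[0].r_max) == (0.0, 1.0)
        assert (shells[-1].r_min, shells[-1].r_max) == (12.0, 13.0)
        for a, b in zip(shells, shells[1:]):
            assert a.r_max == b.r_min


@pytest.fixture(scope="module")
def uniform_aligned():
    """Aligned trajectory with spatially uniform waters (isotropic dipoles)."""
    sc = build_scaffold()
    traj = generate_trajectory(
        sc,
        WaterFieldSpec(n_waters=2000, box=(36.0, 36.0, 36.0), mode="uniform", seed=21),
        SyntheticTrajectorySpec(n_frames=12),
        seed=22,
    )
    sel = resolve_selections(default_config(), traj.atoms)
    return align_bulk(traj, sel.alignment), sel


class TestSliceMaps:
    def test_unaligned_trajectory_rejected(self, small_traj):
        with pytest.raises(MapError, match="align"):
            accumulate_slice_map(small_traj, build_slice_set()[0], SPC)

    def test_uniform_water_is_flat(self, uniform_aligned):
        """Chi-square test: uniform input gives Poisson-flat bin counts."""
        al, _ = uniform_aligned
        spec = build_slice_set()[0]
        m = accumulate_slice_map(al, spec, SPC, extent=12.0)
        counts = m.counts.ravel()
        assert counts.sum() > 500
        # coarsen to 3x3 A blocks so expected counts are large enough
        c = m.counts.reshape(8, 6, 8, 6).sum(axis=(1, 3)).ravel()
        chi2 = ((c - c.mean()) ** 2 / c.mean()).sum()
        p = stats.chi2.sf(chi2, df=len(c) - 1)
        assert p > 0.001

    def test_single_bin_oriented_dipole(self, scaffold):
        """All waters in one bin, dipoles +z: that bin's mean is (0,0,2.27)."""
        sc = scaffold
        traj = generate_trajectory(
            sc, WaterFieldSpec(n_waters=40, box=(36.0, 36.0, 36.0), seed=23),
            SyntheticTrajectorySpec(n_frames=2), seed=24,
        )
        sel = resolve_selections(default_config(), traj.atoms)
        # overwrite the waters: all oxygens at one point, dipoles along +z
        from cdsolv.trajectory import water_sites

        sites = water_sites(traj.atoms)
        rng = np.random.default_rng(25)
        spot = np.array([0.6, 0.1, 0.2])
        for fi in range(traj.n_frames):
            o = np.tile(spot, (sites.shape[0], 1))
            d = np.tile([0.0, 0.0, 1.0], (sites.shape[0], 1))
            w = water_sites_from_dipoles(o, d, rng)
            half = traj.boxes[fi] / 2.0
            traj.positions[fi][sites.ravel()] = w.reshape(-1, 3) + half
        al = align_bulk(traj, sel.alignment)
        m = accumulate_slice_map(al, build_slice_set()[0], SPC, extent=12.0)
        occupied = np.nonzero(m.counts)
        assert len(occupied[0]) == 1
        mu = m.dipole[occupied][0]
        np.testing.assert_allclose(mu, [0.0, 0.0, SPC.dipole_magnitude], atol=1e-9)

    def test_no_waters_in_range_gives_empty_map(self, uniform_aligned):
        al, sel = uniform_aligned
        from cdsolv.maps import SliceSpec

        far = SliceSpec("perpendicular", (60.0, 63.0))
        m = accumulate_slice_map(al, far, SPC)
        assert m.occupancy == 0.0
        assert np.isnan(m.dipole).all()

    def test_frame_permutation_invariance(self, uniform_aligned):
        al, _ = uniform_aligned
        spec = build_slice_set()[1]
        m1 = accumulate_slice_map(al, spec, SPC)
        perm = np.random.default_rng(1).permutation(al.n_frames)
        shuffled = al.copy()
        shuffled.positions = al.positions[perm]
        m2 = accumulate_slice_map(shuffled, spec, SPC)
        np.testing.assert_allclose(m1.density, m2.density)
        np.testing.assert_allclose(m1.dipole, m2.dipole, equal_nan=True)

    def test_isotropic_dipoles_cancel(self, uniform_aligned):
        """Mean dipole magnitude in well-sampled bins is consistent with 0."""
        al, _ = uniform_aligned
        m = accumulate_slice_map(al, build_slice_set()[0], SPC, extent=12.0)
        # pool all waters of the slice: n ~ 1e4, null sigma ~ |mu|/sqrt(3n)
        tot = np.nansum(m.dipole * m.counts[:, :, None], axis=(0, 1))
        n = m.counts.sum()
        sigma = SPC.dipole_magnitude / np.sqrt(3.0) * np.sqrt(n)
        assert np.all(np.abs(tot) < 3.0 * sigma)

    def test_last_n_limits_frames(self, uniform_aligned):
        al, _ = uniform_aligned
        spec = build_slice_set()[0]
        m = accumulate_slice_map(al, spec, SPC, last_n=3)
        assert m.n_frames == 3
        with pytest.raises(MapError, match="last_n"):
            accumulate_slice_map(al, spec, SPC, last_n=al.n_frames + 1)


class TestShellMaps:
    def test_annulus_area_ratio_recovered(self, uniform_aligned):
        """Uniform density: occupancy([8,9]) / occupancy([4,5]) = 17/9."""
        al, _ = uniform_aligned
        shells = build_shells()
        m89 = accumulate_shell_map(al, shells[8], SPC, axial_extent=14.0)
        m45 = accumulate_shell_map(al, shells[4], SPC, axial_extent=14.0)
        ratio = m89.occupancy / m45.occupancy
        expected = 17.0 / 9.0
        n = m45.counts.sum()
        assert ratio == pytest.approx(expected, rel=4.0 / np.sqrt(n))

    def test_half_open_radial_binning(self, scaffold):
        traj = generate_trajectory(
            scaffold, WaterFieldSpec(n_waters=2, box=(36.0,) * 3, seed=26),
            SyntheticTrajectorySpec(n_frames=1), seed=27,
        )
        sel = resolve_selections(default_config(), traj.atoms)
        from cdsolv.trajectory import water_sites
        from cdsolv.synth import water_sites_from_dipoles

        sites = water_sites(traj.atoms)
        rng = np.random.default_rng(28)
        o = np.array([[0.0, 7.5, 0.0], [0.0, 0.0, 7.5]])
        w = water_sites_from_dipoles(o, np.array([[0, 0, 1.0], [0, 1.0, 0]]), rng)
        traj.positions[0][sites.ravel()] = w.reshape(-1, 3) + traj.boxes[0] / 2
        al = align_bulk(traj, sel.alignment)
        shells = build_shells()
        assert accumulate_shell_map(al, shells[7], SPC).occupancy == 2.0
        assert accumulate_shell_map(al, shells[6], SPC).occupancy == 0.0
        assert accumulate_shell_map(al, shells[8], SPC).occupancy == 0.0

    def test_radial_dipole_field_points_outward(self):
        """kappa -> inf: every occupied bin's dipole is along the local +r."""
        sc = build_scaffold()
        traj = generate_trajectory(
            sc,
            WaterFieldSpec(
                n_waters=2000, box=(34.0,) * 3, mode="oriented", kappa=None,
                core_radius=2.0, seed=29,
            ),
            SyntheticTrajectorySpec(n_frames=3),
            seed=30,
        )
        sel = resolve_selections(default_config(), traj.atoms)
        al = align_bulk(traj, sel.alignment)
        m = accumulate_shell_map(al, build_shells()[8], SPC)
        phi_mid = 0.5 * (m.x_edges[:-1] + m.x_edges[1:]) / m.geometry.r_mid
        for i, j in zip(*np.nonzero(m.counts)):
            mu = m.dipole[i, j]
            rhat = np.array([0.0, np.cos(phi_mid[i]), np.sin(phi_mid[i])])
            assert mu @ rhat / np.linalg.norm(mu) > 0.95


class TestSerialisation:
    def test_text_roundtrip(self, uniform_aligned, tmp_path):
        al, _ = uniform_aligned
        m = accumulate_slice_map(al, build_slice_set()[0], SPC, extent=8.0)
        path = tmp_path / "map.dat"
        write_map(m, path)
        back = read_map(path)
        np.testing.assert_allclose(back["density"], m.density, rtol=1e-6)
        np.testing.assert_allclose(back["dipole_z"], m.dipole[:, :, 2], rtol=1e-6, equal_nan=True)
        assert int(back["meta"]["n_frames"]) == m.n_frames
        np.testing.assert_allclose(back["x_edges"], m.x_edges, atol=1e-9)
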