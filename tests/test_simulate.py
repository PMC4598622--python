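"""Phantom construction, scene geometry, CTF and tilt-series projection."""

import math

import numpy as np
import pytest

from tomopipe.core import DensityMap, WedgeSpec
from tomopipe.simulate import (CTFParams, PhantomSpec, TiltSeries,
                               build_phantom, build_scene, load_tilt_series,
                               make_subtomograms, project_tilt_series,
                               project_volume, save_tilt_series)

from conftest import (FIXTURE_SNR, PARTICLE_DIAMETER_A, SUB_BOX, SUB_VOXEL_A,
                      random_pose)


class TestBuildPhantom:
    def test_trna_variants_differ_only_at_trna_site(self):
        spec = PhantomSpec(optional_subdensities=[
            ("tRNA", np.array([0.0, 35.0, 40.0]), 30.0, 0.29)])
        ph = build_phantom(spec, SUB_VOXEL_A, SUB_BOX, seed=1)
        assert set(ph.variants) == {"base", "base+tRNA"}
        diff = ph.variants["base+tRNA"].grid - ph.variants["base"].grid
        assert diff.max() > 0
        site = (np.array([SUB_BOX // 2] * 3)
                + np.array([0.0, 35.0, 40.0]) / SUB_VOXEL_A)
        nz = np.array(np.nonzero(np.abs(diff) > 1e-6)).T
        dist = np.linalg.norm(nz - site, axis=1) * SUB_VOXEL_A
        # rendering box extends 4 sigma per axis (sqrt(3)*4 sigma corners)
        assert dist.max() <= math.sqrt(3) * 4 * 30.0 + 2 * SUB_VOXEL_A

    def test_same_seed_is_bit_identical(self):
        a = build_phantom(PhantomSpec(), SUB_VOXEL_A, SUB_BOX, seed=7)
        b = build_phantom(PhantomSpec(), SUB_VOXEL_A, SUB_BOX, seed=7)
        for name in a.variants:
            assert np.array_equal(a.variants[name].grid,
                                  b.variants[name].grid)

    def test_conformer_offset_survives_screw_decomposition(self):
        """A 22 deg domain rotation planted in a conformer is recovered
        exactly from the generating transform."""
        from scipy.spatial.transform import Rotation
        from tomopipe.core import RigidTransform
        from tomopipe.fitmodel import screw_decompose
        rot = Rotation.from_rotvec(np.radians(22.0)
                                   * np.array([0, 0, 1.0])).as_matrix()
        gate = RigidTransform(rot, np.array([0.0, 0.0, 13.8]))
        spec = PhantomSpec(conformer_set={"closed": {},
                                          "open": {"foot": gate}},
                          optional_subdensities=[])
        ph = build_phantom(spec, SUB_VOXEL_A, SUB_BOX, seed=1)
        assert set(ph.variants) == {"closed", "open"}
        sd = screw_decompose(gate)
        assert abs(sd.angle_deg - 22.0) < 1e-9
        assert abs(sd.translation_along_axis_A - 13.8) < 1e-9

    def test_occupancy_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="occupancy"):
            PhantomSpec(optional_subdensities=[("x", np.zeros(3), 10.0, 1.5)])


class TestBuildScene:
    def test_bound_particles_have_foot_in_membrane(self):
        spec = PhantomSpec()
        scene = build_scene(spec, box=96, voxel_size=10.5,
                            vesicle_radius_A=200, n_particles=4,
                            bound_fraction=1.0, false_positive_count=0,
                            orientation_jitter_deg=0.0, seed=3)
        foot_local = np.array([0, 0, -0.72 * spec.particle_diameter_A / 2])
        for p in scene.particles:
            foot = p.transform.apply(foot_local)
            err = abs(np.linalg.norm(foot) - scene.vesicle_radius_A)
            assert err <= scene.membrane_thickness_A / 2

    def test_class_fractions_binomial(self):
        """Empirical tRNA occupancy over many particles stays within 3 sigma
        of the 0.29 generator setting (label bookkeeping, no rendering)."""
        spec = PhantomSpec()
        rng = np.random.default_rng(11)
        n = 2000
        draws = rng.random(n) < 0.29
        frac = draws.mean()
        sigma = math.sqrt(0.29 * 0.71 / n)
        assert abs(frac - 0.29) <= 3 * sigma
        # and the scene labels use the same occupancy machinery
        scene = build_scene(spec, box=96, voxel_size=10.5,
                            vesicle_radius_A=200, n_particles=6,
                            bound_fraction=1.0, false_positive_count=0,
                            seed=5)
        assert all("tRNA" in p.labels for p in scene.particles)

    def test_fiducial_count_recorded_exactly(self):
        scene = build_scene(PhantomSpec(), box=96, voxel_size=10.5,
                            vesicle_radius_A=200, n_particles=2,
                            bound_fraction=1.0, false_positive_count=5,
                            seed=2)
        assert len(scene.fiducials_A) == 5

    def test_overflow_raises(self):
        with pytest.raises(ValueError, match="fit"):
            build_scene(PhantomSpec(), box=64, voxel_size=10.5,
                        vesicle_radius_A=400, n_particles=1, seed=0)


class TestCTF:
    def test_underfocus_required(self):
        with pytest.raises(ValueError):
            CTFParams(defocus_um=-1.0)

    def test_wavelength_300kv(self):
        assert abs(CTFParams().wavelength_A - 0.0197) < 2e-4

    def test_first_zero_moves_with_defocus(self):
        ctf = CTFParams(cs_mm=2.7, amplitude_contrast=0.07)
        s = np.linspace(1e-4, 0.05, 4000)
        def first_zero(dz):
            v = ctf.ctf(s, dz)
            sign_change = np.nonzero(np.diff(np.sign(v)))[0]
            return s[sign_change[0]]
        assert first_zero(2.0) > first_zero(4.0)


class TestProjectTiltSeries:
    def test_zero_tilt_equals_z_sum(self, phantom_sub):
        vol = phantom_sub.variants["base"]
        ts = project_tilt_series(vol, [0.0], ctf=None, noise_sigma=0.0)
        ref = vol.grid.sum(axis=2)
        assert np.abs(ts.images[0] - ref).max() <= 1e-5 * np.abs(ref).max()

    def test_61_images_and_dose_bookkeeping(self, phantom_sub):
        angles = np.arange(-60, 61, 2.0)
        dose = 95.0 / 61
        ts = project_tilt_series(phantom_sub.variants["base"], angles,
                                 ctf=None, dose_per_image=dose)
        assert len(ts) == 61
        assert abs(ts.dose.sum() - 95.0) < 1e-9
        reduced = ts.subset(-20, 20)
        assert len(reduced) == 21
        assert abs(reduced.dose.sum() - 21 * dose) < 1e-9
        assert 28 < reduced.dose.sum() < 34        # ~30 e/A^2

    def test_central_slice_theorem(self):
        """|FFT| of a tilted projection matches the central slice of the 3D
        transform perpendicular to the beam."""
        from scipy.ndimage import map_coordinates
        spec = PhantomSpec()
        scene = build_scene(spec, box=128, voxel_size=10.5,
                            vesicle_radius_A=330, n_particles=6,
                            bound_fraction=1.0, false_positive_count=1,
                            seed=2)
        theta = 30.0
        img = project_volume(scene.volume, theta)
        n = 128
        c = n // 2
        f3 = np.abs(np.fft.fftshift(np.fft.fftn(scene.volume.grid)))
        t = math.radians(theta)
        a = np.array([math.cos(t), 0.0, -math.sin(t)])
        ks = np.arange(n) - c
        pts = (ks[:, None, None] * a[None, None, :]
               + np.stack([np.zeros(n), ks, np.zeros(n)], -1)[None]) + c
        sl = map_coordinates(f3, pts.reshape(-1, 3).T, order=3).reshape(n, n)
        f2 = np.abs(np.fft.fftshift(np.fft.fft2(img)))
        r = np.hypot(*np.meshgrid(ks, ks, indexing="ij"))
        sel = r < 0.95 * c
        assert np.corrcoef(f2[sel], sl[sel])[0, 1] > 0.99

    def test_noise_scales_inversely_with_dose(self, phantom_sub):
        vol = phantom_sub.variants["base"]
        lo = project_tilt_series(vol, [0.0], ctf=None, dose_per_image=1.0,
                                 noise_sigma=1.0, seed=1)
        hi = project_tilt_series(vol, [0.0], ctf=None, dose_per_image=4.0,
                                 noise_sigma=1.0, seed=1)
        clean = project_tilt_series(vol, [0.0], ctf=None).images[0]
        r_lo = (lo.images[0] - clean).std()
        r_hi = (hi.images[0] - clean).std()
        assert abs(r_lo / r_hi - 2.0) < 0.1

    def test_determinism_and_shift_recording(self, phantom_sub):
        vol = phantom_sub.variants["base"]
        a = project_tilt_series(vol, [-10.0, 0.0, 10.0], ctf=None,
                                noise_sigma=0.5, shift_jitter_px=2.0, seed=9)
        b = project_tilt_series(vol, [-10.0, 0.0, 10.0], ctf=None,
                                noise_sigma=0.5, shift_jitter_px=2.0, seed=9)
        assert np.array_equal(a.images, b.images)
        assert np.array_equal(a.true_shift_px, b.true_shift_px)
        assert np.abs(a.true_shift_px).max() <= 2.0

    def test_empty_angle_list_rejected(self, phantom_sub):
        with pytest.raises(ValueError, match="empty"):
            project_tilt_series(phantom_sub.variants["base"], [])


class TestMakeSubtomograms:
    def test_wedge_support_and_snr(self, phantom_sub, rng):
        poses = [random_pose(rng) for _ in range(3)]
        subs = make_subtomograms(phantom_sub, ["base"] * 3, poses,
                                 WedgeSpec(-20, 20), snr=FIXTURE_SNR,
                                 box=SUB_BOX, seed=4)
        from tomopipe.core import make_wedge_mask
        wm = make_wedge_mask((SUB_BOX,) * 3, WedgeSpec(-20, 20))
        f = np.abs(np.fft.fftn(subs[0])) ** 2
        assert f[wm == 0].sum() / f.sum() < 1e-9

    def test_noise_free_subtomogram_matches_rendered_pose(self, phantom_sub,
                                                          rng):
        from tomopipe.core import make_wedge_mask
        pose = random_pose(rng)
        subs = make_subtomograms(phantom_sub, ["base"], [pose],
                                 WedgeSpec(-90, 90), snr=np.inf,
                                 box=SUB_BOX, seed=0)
        assert np.isfinite(subs).all()
        assert subs[0].std() > 0


class TestTiltSeriesIO:
    def test_mrc_tsv_roundtrip(self, tmp_path, phantom_sub):
        ts = project_tilt_series(phantom_sub.variants["base"],
                                 [-10.0, 0.0, 10.0], ctf=CTFParams(),
                                 noise_sigma=0.3, shift_jitter_px=1.0,
                                 seed=3)
        save_tilt_series(ts, tmp_path / "s.mrc", tmp_path / "s.tsv")
        back = load_tilt_series(tmp_path / "s.mrc", tmp_path / "s.tsv")
        assert np.allclose(back.images, ts.images, atol=1e-6)
        assert np.allclose(back.tilt_deg, ts.tilt_deg)
        assert np.allclose(back.defocus_um, ts.defocus_um)
        assert np.allclose(back.true_shift_px, ts.true_shift_px)
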