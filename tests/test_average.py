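"""Constrained correlation, subtomogram alignment, averaging, refinement."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tomopipe.core import (DensityMap, RigidTransform, WedgeSpec, freq_grid,
                           make_wedge_mask, rotate_fourier_mask,
                           rotate_volume, spherical_mask)
from tomopipe.average import (AlignmentSchedule, ParticleRecord,
                              align_subtomogram, average_subtomograms,
                              constrained_cc, local_rotation_grid,
                              refine_iteratively)
from tomopipe.simulate import make_subtomograms

from conftest import (FIXTURE_SNR, SUB_BOX, SUB_VOXEL_A, geodesic_deg,
                      random_pose)

WEDGE = WedgeSpec(-20, 20)


def wedge_filtered(grid, wedge=WEDGE):
    wm = make_wedge_mask(grid.shape, wedge)
    return np.fft.ifftn(np.fft.fftn(grid) * wm).real.astype(np.float32)


class TestConstrainedCC:
    def test_self_correlation_one(self, base_map):
        assert abs(constrained_cc(base_map, WEDGE, base_map, WEDGE)
                   - 1.0) < 1e-6

    def test_negation_minus_one(self, base_map):
        neg = DensityMap(-base_map.grid, SUB_VOXEL_A)
        assert abs(constrained_cc(base_map, WEDGE, neg, WEDGE) + 1.0) < 1e-6

    def test_symmetry(self, rng):
        a = DensityMap(rng.standard_normal((SUB_BOX,) * 3).astype(np.float32),
                       SUB_VOXEL_A)
        b = DensityMap(rng.standard_normal((SUB_BOX,) * 3).astype(np.float32),
                       SUB_VOXEL_A)
        assert abs(constrained_cc(a, WEDGE, b, WEDGE)
                   - constrained_cc(b, WEDGE, a, WEDGE)) < 1e-9

    def test_independent_noise_near_zero(self):
        vals = []
        for seed in range(100):
            ra = np.random.default_rng(seed)
            rb = np.random.default_rng(10_000 + seed)
            a = DensityMap(ra.standard_normal((SUB_BOX,) * 3)
                           .astype(np.float32), SUB_VOXEL_A)
            b = DensityMap(rb.standard_normal((SUB_BOX,) * 3)
                           .astype(np.float32), SUB_VOXEL_A)
            vals.append(constrained_cc(a, WEDGE, b, WEDGE))
        vals = np.array(vals)
        assert np.abs(vals).max() < 0.05          # 3 sigma of the null

    def test_fft_path_matches_realspace_oracle_16cubed(self, rng):
        """Constrained CC via FFT equals a direct real-space masked
        correlation restricted to the shared Fourier region."""
        n = 16
        region = (make_wedge_mask((n,) * 3, WEDGE) > 0.5)
        region[0, 0, 0] = False
        worst = 0.0
        for _ in range(50):
            a = rng.standard_normal((n,) * 3)
            b = rng.standard_normal((n,) * 3)
            got = constrained_cc(DensityMap(a.astype(np.float32), 1.0), WEDGE,
                                 DensityMap(b.astype(np.float32), 1.0), WEDGE)
            fa = np.fft.fftn(a)[region]
            fb = np.fft.fftn(b)[region]
            want = (fa * np.conj(fb)).real.sum() / np.sqrt(
                (np.abs(fa) ** 2).sum() * (np.abs(fb) ** 2).sum())
            worst = max(worst, abs(got - want))
        assert worst < 1e-5

    def test_empty_overlap_rejected(self, base_map):
        empty = np.zeros(base_map.grid.shape, dtype=np.float32)
        with pytest.raises(ValueError, match="overlap"):
            constrained_cc(base_map, empty, base_map, empty)


class TestAlignSubtomogram:
    def test_exact_copy_gives_identity_and_unit_score(self, base_map):
        sub = DensityMap(wedge_filtered(base_map.grid), SUB_VOXEL_A)
        pose, score = align_subtomogram(sub, WEDGE, base_map,
                                        RigidTransform.identity(), 4.0, 4.0)
        assert geodesic_deg(pose.rotation, np.eye(3)) < 1e-9
        assert np.abs(pose.translation).max() < 1e-9
        assert score > 0.99

    def test_rotated_shifted_copy_recovered(self, base_map):
        true_pose = RigidTransform(
            Rotation.from_euler("ZXZ", [8, -6, 4], degrees=True).as_matrix(),
            np.array([13.1, 0.0, -26.2]))
        placed = rotate_volume(base_map, true_pose, cval=0.0).grid
        sub = DensityMap(wedge_filtered(placed), SUB_VOXEL_A)
        pose, score = align_subtomogram(sub, WEDGE, base_map,
                                        RigidTransform.identity(), 4.0, 16.0)
        assert geodesic_deg(pose.rotation, true_pose.rotation) <= 2.1
        assert np.abs(pose.translation
                      - true_pose.translation).max() <= 0.5 * SUB_VOXEL_A
        assert score > 0.95

    def test_score_never_decreases(self, base_map, rng):
        noisy = DensityMap(wedge_filtered(
            base_map.grid + rng.standard_normal(base_map.grid.shape)
            .astype(np.float32)), SUB_VOXEL_A)
        start = RigidTransform(Rotation.from_euler(
            "z", 3, degrees=True).as_matrix())
        _, s0 = align_subtomogram(noisy, WEDGE, base_map, start, 50.0, 0.0)
        pose, s1 = align_subtomogram(noisy, WEDGE, base_map, start, 6.0, 12.0)
        assert s1 >= s0 - 1e-9


class TestAverageSubtomograms:
    def test_identical_copies_full_wedge_reproduce_input(self, base_map):
        full = WedgeSpec(-90, 90)
        recs = [ParticleRecord(i, RigidTransform.identity(), full)
                for i in range(4)]
        subs = np.stack([base_map.grid] * 4)
        avg = average_subtomograms(recs, subs, SUB_VOXEL_A)
        ref = base_map.grid - base_map.grid.mean()
        assert np.abs(avg.grid - ref).max() < 1e-6 * np.abs(ref).max()

    def test_opposite_volumes_cancel(self, base_map):
        full = WedgeSpec(-90, 90)
        recs = [ParticleRecord(0, RigidTransform.identity(), full),
                ParticleRecord(1, RigidTransform.identity(), full)]
        avg = average_subtomograms(recs, np.stack([base_map.grid,
                                                   -base_map.grid]),
                                   SUB_VOXEL_A)
        assert np.abs(avg.grid).max() < 1e-6

    def test_random_poses_fill_fourier_sphere(self):
        """50 random orientations of a +-20 deg wedge cover > 95% of the
        Fourier sphere."""
        wm = make_wedge_mask((SUB_BOX,) * 3, WEDGE)
        wsum = np.zeros((SUB_BOX,) * 3)
        for i in range(50):
            rot = Rotation.random(rng=np.random.default_rng(i)).as_matrix()
            wsum += rotate_fourier_mask(wm, rot.T)
        inside = freq_grid((SUB_BOX,) * 3, 1.0) <= 0.5
        assert (wsum[inside] > 0.5).mean() > 0.95

    def test_recovers_phantom_from_posed_wedged_copies(self, phantom_sub,
                                                       rng):
        poses = [random_pose(rng) for _ in range(50)]
        subs = make_subtomograms(phantom_sub, ["base"] * 50, poses, WEDGE,
                                 snr=np.inf, box=SUB_BOX, seed=2)
        recs = [ParticleRecord(i, p, WEDGE) for i, p in enumerate(poses)]
        avg = average_subtomograms(recs, subs, SUB_VOXEL_A)
        ref = phantom_sub.variants["base"].grid
        ref = ref - ref.mean()
        assert np.corrcoef(avg.grid.ravel(), ref.ravel())[0, 1] > 0.9

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            average_subtomograms([], np.zeros((0, 8, 8, 8)), 1.0)


class TestRefineIteratively:
    @pytest.fixture(scope="class")
    def small_problem(self, phantom_sub):
        rng = np.random.default_rng(5)
        n = 24
        poses = [random_pose(rng) for _ in range(n)]
        subs = make_subtomograms(phantom_sub, ["base"] * n, poses, WEDGE,
                                 snr=FIXTURE_SNR, box=SUB_BOX, seed=7)
        records = []
        for i, tp in enumerate(poses):
            v = rng.normal(size=3)
            v *= rng.uniform(0, 16) / np.linalg.norm(v)
            pert = Rotation.from_rotvec(np.radians(v)).as_matrix()
            records.append(ParticleRecord(
                i, RigidTransform(tp.rotation @ pert,
                                  tp.translation + rng.uniform(-9, 9, 3)),
                WEDGE))
        return poses, subs, records

    def test_history_bounded_by_max_iterations(self, phantom_sub,
                                               small_problem):
        poses, subs, records = small_problem
        sched = AlignmentSchedule(max_iterations=2, particle_diameter_A=270,
                                  initial_lowpass_A=52.4,
                                  initial_angular_step_deg=8.0,
                                  mask=spherical_mask((SUB_BOX,) * 3, 12, 3))
        ref0 = average_subtomograms(records, subs, SUB_VOXEL_A)
        _f, hist, _r = refine_iteratively(
            [r for r in records], subs, ref0, sched, mode="conventional",
            seed=1)
        assert 1 <= len(hist) <= 2
        assert {"iteration", "resolution_A", "angular_step_deg",
                "band_A", "mean_score"} <= set(hist[0])

    def test_gold_standard_halves_stay_independent(self, phantom_sub,
                                                   small_problem):
        """Adversarial fixture: the two halves carry two different phantoms,
        so the half-map FSC must collapse to near the worst shell."""
        rng = np.random.default_rng(9)
        n = 16
        poses = [random_pose(rng) for _ in range(n)]
        variants = ["base"] * (n // 2) + ["base+OST+tRNA"] * (n // 2)
        subs = make_subtomograms(phantom_sub, variants, poses, WEDGE,
                                 snr=np.inf, box=SUB_BOX, seed=3)
        records = [ParticleRecord(i, poses[i], WEDGE, half_set=i // (n // 2))
                   for i in range(n)]
        # two distinct objects in the halves -> wide FSC gap vs same-object
        from tomopipe.validate import fsc_curve
        ha = average_subtomograms(records[:n // 2], subs, SUB_VOXEL_A)
        hb = average_subtomograms(records[n // 2:], subs, SUB_VOXEL_A)
        mixed = fsc_curve(ha, hb).fsc
        same = fsc_curve(ha, ha).fsc
        assert mixed[3:].mean() < 0.9 * same[3:].mean()

    def test_half_permutation_does_not_change_other_half(self, phantom_sub):
        rng = np.random.default_rng(4)
        poses = [random_pose(rng) for _ in range(8)]
        subs = make_subtomograms(phantom_sub, ["base"] * 8, poses, WEDGE,
                                 snr=1.0, box=SUB_BOX, seed=6)
        recs = [ParticleRecord(i, poses[i], WEDGE, half_set=i % 2)
                for i in range(8)]
        half1 = [r for r in recs if r.half_set == 1]
        avg_before = average_subtomograms(half1, subs, SUB_VOXEL_A)
        avg_after = average_subtomograms(half1[::-1], subs, SUB_VOXEL_A)
        assert np.array_equal(avg_before.grid, avg_after.grid)

    def test_too_few_particles_per_half_rejected(self, phantom_sub):
        rng = np.random.default_rng(2)
        poses = [random_pose(rng) for _ in range(2)]
        subs = make_subtomograms(phantom_sub, ["base"] * 2, poses, WEDGE,
                                 snr=1.0, box=SUB_BOX, seed=1)
        recs = [ParticleRecord(i, poses[i], WEDGE) for i in range(2)]
        sched = AlignmentSchedule(max_iterations=1)
        with pytest.raises(ValueError, match="half"):
            refine_iteratively(recs, subs,
                               average_subtomograms(recs, subs, SUB_VOXEL_A),
                               sched, mode="gold_standard", seed=0)


def test_local_rotation_grid_contains_identity_and_is_bounded():
    grid = local_rotation_grid(5.0, 10.0)
    assert np.allclose(grid[0], np.eye(3))
    for m in grid:
        assert geodesic_deg(m, np.eye(3)) <= 10.0 + 1e-6


def test_schedule_step_rule():
    sched = AlignmentSchedule(particle_diameter_A=270.0)
    import math
    assert abs(sched.step_from_resolution(30.0)
               - math.degrees(math.atan(30 / 270))) < 1e-9
    assert sched.step_from_resolution(0.1) == 1.0     # floor at 1 degree
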