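"""Frame alignment, defocus estimation, phase flipping, tilt alignment, WBP."""

import numpy as np
import pytest

from tomopipe.core import DensityMap, WedgeSpec, make_wedge_mask
from tomopipe.reconstruct import (align_frames, align_tilt_series,
                                  estimate_defocus, phase_flip,
                                  reconstruct_subtomogram,
                                  weighted_backprojection)
from tomopipe.simulate import (CTFParams, PhantomSpec, TiltSeries,
                               _fourier_shift_2d, build_phantom,
                               project_tilt_series, project_volume)


@pytest.fixture(scope="module")
def centered_scene():
    """Compact particle cluster centered in a 96^3 volume at 10.5 A."""
    ph = build_phantom(PhantomSpec(), 10.5, 64, seed=1)
    g = np.zeros((96,) * 3, np.float32)
    g[16:80, 16:80, 16:80] = ph.variants["base"].grid
    return DensityMap(g, 10.5)


@pytest.fixture(scope="module")
def full_series(centered_scene):
    return project_tilt_series(centered_scene, np.arange(-60, 61, 2.0),
                               ctf=None, dose_per_image=95 / 61)


class TestAlignFrames:
    def test_identical_frames_zero_shifts(self, rng):
        base = rng.standard_normal((64, 64))
        _summed, shifts = align_frames([base, base, base])
        assert np.abs(shifts).max() < 1e-6

    def test_known_drifts_recovered(self, rng):
        from scipy.ndimage import gaussian_filter
        base = gaussian_filter(rng.standard_normal((64, 64)), 2.0)
        drifts = np.array([[0, 0], [1, 0], [2, 0], [3, 0]], float)
        frames = [_fourier_shift_2d(base, d) for d in drifts]
        _summed, shifts = align_frames(frames)
        centered = drifts - drifts.mean(axis=0)
        assert np.abs(-shifts - centered).max() < 0.1

    def test_noisy_frames_alignment_and_snr_gain(self, rng):
        from scipy.ndimage import gaussian_filter
        base = gaussian_filter(rng.standard_normal((128, 128)), 2.0)
        base /= base.std()
        drifts = rng.uniform(-5, 5, (6, 2))
        drifts -= drifts.mean(axis=0)
        sigma = np.sqrt(1 / 0.5)             # per-frame SNR 0.5
        frames = [_fourier_shift_2d(base, d)
                  + rng.normal(scale=sigma, size=base.shape) for d in drifts]
        summed, shifts = align_frames(frames)
        assert np.abs(-shifts - drifts).max() < 0.5
        resid_sum = summed - base
        single = frames[0] - _fourier_shift_2d(base, drifts[0])
        assert resid_sum.std() < single.std()     # averaging won

    def test_single_frame_rejected(self, rng):
        with pytest.raises(ValueError):
            align_frames([rng.standard_normal((16, 16))])


class TestEstimateDefocus:
    def test_noise_free_self_consistency(self, rng):
        ctf = CTFParams(defocus_um=3.0)
        img = rng.standard_normal((512, 512))
        img = np.fft.ifft2(np.fft.fft2(img)
                           * ctf.ctf_2d((512, 512), 2.62, 3.0)).real
        est = estimate_defocus(img, 2.62, ctf, strip_width_px=128)
        assert abs(est.defocus_um - 3.0) < 0.05
        assert est.quality > 0.5

    def test_noisy_within_02um(self, rng):
        ctf = CTFParams(defocus_um=3.0)
        img = rng.standard_normal((512, 512))
        sig = np.fft.ifft2(np.fft.fft2(img)
                           * ctf.ctf_2d((512, 512), 2.62, 3.0)).real
        noisy = sig + rng.standard_normal((512, 512))    # SNR ~ 1
        est = estimate_defocus(noisy, 2.62, ctf, strip_width_px=128)
        assert abs(est.defocus_um - 3.0) < 0.2

    def test_range_excluding_truth_flags_low_quality(self, rng):
        ctf = CTFParams(defocus_um=3.0)
        img = rng.standard_normal((512, 512))
        sig = np.fft.ifft2(np.fft.fft2(img)
                           * ctf.ctf_2d((512, 512), 2.62, 3.0)).real
        est = estimate_defocus(sig, 2.62, ctf, search_range_um=(4.5, 6.0))
        assert est.quality <= 0.2
        assert 4.5 <= est.defocus_um <= 6.0

    def test_featureless_image_quality_zero(self):
        est = estimate_defocus(np.zeros((512, 512)), 2.62, CTFParams(),
                               strip_width_px=128)
        assert est.quality == 0.0


class TestPhaseFlip:
    def test_no_zero_crossing_band_is_identity(self, rng):
        # tiny defocus: first CTF zero far beyond Nyquist at 10.5 A pixel
        ctf = CTFParams(defocus_um=0.05, amplitude_contrast=0.0)
        img = rng.standard_normal((64, 64))
        out = phase_flip(img, 10.5, ctf, 0.05)
        assert np.abs(out - img).max() < 1e-10

    def test_double_application_is_identity(self, rng):
        ctf = CTFParams(defocus_um=3.5)
        img = rng.standard_normal((64, 64))
        once = phase_flip(img, 10.5, ctf, 3.5)
        twice = phase_flip(once, 10.5, ctf, 3.5)
        assert np.abs(twice - img).max() < 1e-9

    def test_amplitudes_preserved(self, rng):
        ctf = CTFParams(defocus_um=3.5)
        img = rng.standard_normal((64, 64))
        out = phase_flip(img, 10.5, ctf, 3.5)
        assert np.allclose(np.abs(np.fft.fft2(out)),
                           np.abs(np.fft.fft2(img)), rtol=1e-6)

    def test_correlation_improves_on_ctf_corrupted_projection(
            self, centered_scene):
        ctf = CTFParams(defocus_um=3.0)
        proj = project_volume(centered_scene, 0.0)
        corrupted = np.fft.ifft2(np.fft.fft2(proj) * ctf.ctf_2d(
            proj.shape, 10.5, 3.0)).real
        flipped = phase_flip(corrupted, 10.5, ctf, 3.0)
        cc = lambda a, b: np.corrcoef(a.ravel(), b.ravel())[0, 1]
        assert cc(flipped, proj) > cc(corrupted, proj)


class TestAlignTiltSeries:
    def _observations(self, rng, tilts, markers, shifts, noise=0.0):
        c, s = np.cos(np.radians(tilts)), np.sin(np.radians(tilts))
        obs = np.zeros((len(tilts), len(markers), 2))
        obs[:, :, 0] = (markers[:, 0][None] * c[:, None]
                        - markers[:, 2][None] * s[:, None]
                        + shifts[:, 0][:, None])
        obs[:, :, 1] = markers[:, 1][None] + shifts[:, 1][:, None]
        if noise:
            obs += rng.normal(scale=noise, size=obs.shape)
        return obs

    def test_zero_shifts_recovered_exactly(self, rng):
        tilts = np.arange(-60, 61, 2.0)
        markers = rng.uniform(-200, 200, (5, 3))
        markers -= markers.mean(axis=0)
        obs = self._observations(rng, tilts, markers,
                                 np.zeros((len(tilts), 2)))
        ta = align_tilt_series(tilts, obs)
        assert np.abs(ta.shifts_px).max() < 1e-6
        assert ta.residual_rms_px < 1e-6

    def test_known_random_shifts_recovered(self, rng):
        tilts = np.arange(-60, 61, 2.0)
        markers = rng.uniform(-200, 200, (5, 3))
        markers -= markers.mean(axis=0)       # centroid gauge
        shifts = rng.uniform(-10, 10, (len(tilts), 2))
        obs = self._observations(rng, tilts, markers, shifts)
        ta = align_tilt_series(tilts, obs)
        assert np.abs(ta.shifts_px - shifts).max() < 0.1
        assert np.abs(ta.marker_positions - markers).max() < 0.1

    def test_single_marker_rejected(self, rng):
        tilts = np.arange(-20, 21, 2.0)
        with pytest.raises(ValueError, match="3"):
            align_tilt_series(tilts, np.zeros((len(tilts), 1, 2)))


class TestWeightedBackprojection:
    def test_single_zero_tilt_point_backprojects_to_z_line(self):
        pt = np.zeros((32,) * 3, np.float32)
        pt[16, 16, 16] = 1.0
        ts = TiltSeries(project_volume(DensityMap(pt, 1.0), 0.0)[None],
                        [0.0], 1.0)
        line = weighted_backprojection(ts)
        along = np.abs(line.grid[16, 16, :]).mean()
        across = np.abs(np.delete(line.grid[:, 16, 16], 16)).mean()
        assert along > 10 * across

    def test_full_range_matches_wedge_filtered_truth(self, centered_scene,
                                                     full_series):
        rec = weighted_backprojection(full_series)
        wm = make_wedge_mask(centered_scene.grid.shape, WedgeSpec(-60, 60))
        truth = np.fft.ifftn(np.fft.fftn(centered_scene.grid) * wm).real
        assert np.corrcoef(rec.grid.ravel(), truth.ravel())[0, 1] > 0.9

    def test_reduced_range_fourier_support_in_wedge(self, full_series):
        rec = weighted_backprojection(full_series, tilt_range=(-20, 20))
        f = np.abs(np.fft.fftn(rec.grid)) ** 2
        wm = make_wedge_mask(rec.grid.shape, WedgeSpec(-20, 20))
        assert f[wm == 0].sum() / f.sum() < 0.02

    def test_linearity_in_projections(self, full_series):
        sub = full_series.subset(-20, 20)
        double = TiltSeries(2.0 * sub.images, sub.tilt_deg, sub.pixel_size)
        a = weighted_backprojection(sub)
        b = weighted_backprojection(double)
        assert np.abs(b.grid - 2 * a.grid).max() < 1e-5 * np.abs(
            b.grid).max()

    def test_support_shrinks_with_tilt_range(self, full_series):
        rec20 = weighted_backprojection(full_series, tilt_range=(-20, 20))
        rec60 = weighted_backprojection(full_series)
        f20 = np.abs(np.fft.fftn(rec20.grid)) ** 2
        f60 = np.abs(np.fft.fftn(rec60.grid)) ** 2
        wm20 = make_wedge_mask(rec20.grid.shape, WedgeSpec(-20, 20))
        wm60 = make_wedge_mask(rec60.grid.shape, WedgeSpec(-60, 60))
        # the region measured at +-60 but not +-20 carries energy in the
        # full reconstruction and almost none in the reduced one
        extra = (wm60 > 0) & (wm20 == 0)
        assert f60[extra].sum() / f60.sum() > 10 * f20[extra].sum() / f20.sum()

    def test_empty_subset_rejected(self, full_series):
        with pytest.raises(ValueError, match="selects no images"):
            weighted_backprojection(full_series, tilt_range=(80, 85))


class TestReconstructSubtomogram:
    def test_center_crop_equivalence(self, full_series):
        rec = weighted_backprojection(full_series)
        sub, wspec = reconstruct_subtomogram(full_series, (0.0, 0.0, 0.0), 32)
        crop = rec.grid[32:64, 32:64, 32:64]
        assert np.abs(sub.grid - crop).max() <= 1e-3 * np.abs(crop).max()
        assert wspec.tilt_min == -60 and wspec.tilt_max == 60

    def test_reduced_range_attaches_wedge_and_dose(self, full_series):
        sub, wspec = reconstruct_subtomogram(full_series, (0, 0, 0), 32,
                                             tilt_range=(-20, 20))
        assert (wspec.tilt_min, wspec.tilt_max) == (-20, 20)
        reduced = full_series.subset(-20, 20)
        assert abs(reduced.dose.sum() - 21 * 95 / 61) < 1e-9

    def test_edge_position_rejected_with_margin(self, full_series):
        with pytest.raises(ValueError, match="margin"):
            reconstruct_subtomogram(full_series, (470.0, 0.0, 0.0), 32)

    def test_empty_subset_rejected(self, full_series):
        with pytest.raises(ValueError):
            reconstruct_subtomogram(full_series, (0, 0, 0), 32,
                                    tilt_range=(70, 80))
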