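"""Tilt series to tomograms and subtomograms.

Covers the per-projection preprocessing of a single-axis acquisition
(movie-frame drift correction, strip-based defocus estimation, CTF phase
flipping, gold-marker tilt alignment) and weighted backprojection with a
selectable tilt subset, both for full tomograms and for per-particle
subtomogram reconstruction.

Geometry (matching :mod:`tomopipe.simulate`): the tilt axis is y, the beam
at tilt theta runs along d(theta) = (sin t, 0, cos t) in the specimen frame,
and a specimen point (x, y, z) relative to the volume center projects to
image coordinates u = x cos(t) - z sin(t) + shift_x, v = y + shift_y
relative to the image center.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from tomopipe.core import DensityMap, WedgeSpec
from tomopipe.simulate import CTFParams, TiltSeries, _fourier_shift_2d

__all__ = [
    "align_frames", "estimate_defocus", "DefocusEstimate", "phase_flip",
    "align_tilt_series", "TiltAlignment", "weighted_backprojection",
    "reconstruct_subtomogram",
]


# ---------------------------------------------------------------------------
# movie-frame alignment
# ---------------------------------------------------------------------------

def _correlation_peak(a: np.ndarray, b: np.ndarray):
    """Shift d maximizing overlap of shift(a, d) with b, subpixel parabola."""
    c = np.fft.ifft2(np.fft.fft2(b) * np.conj(np.fft.fft2(a))).real
    idx = np.unravel_index(np.argmax(c), c.shape)
    peak = []
    for axis, i in enumerate(idx):
        n = c.shape[axis]
        sel = [slice(None)] * 2
        sel[axis] = [(i - 1) % n, i, (i + 1) % n]
        other = idx[1 - axis]
        tri = c[tuple(sel)][:, other] if axis == 0 else c[other, sel[1]]
        denom = tri[0] - 2 * tri[1] + tri[2]
        frac = 0.0 if abs(denom) < 1e-12 else 0.5 * (tri[0] - tri[2]) / denom
        d = i + np.clip(frac, -0.5, 0.5)
        peak.append(d - n if d > n / 2 else d)
    return np.array(peak), float(c[idx])


def align_frames(frames, max_iters: int = 10, tol_px: float = 0.05):
    """Drift-correct dose-fractionated movie frames by iterated re-summation.

    Alternates (E) estimating each frame's shift from its correlation peak
    against the running sum of the other frames, with subpixel parabola
    interpolation, and (M) re-summing the shifted frames; stops when the
    largest shift update falls below ``tol_px`` or after ``max_iters``.
    A frame whose correlation peak lands implausibly far out (beyond a
    quarter of the field) is flagged with a warning and left unshifted.

    Returns (aligned mean image, per-frame shifts in px).
    """
    frames = [np.asarray(f, dtype=np.float64) for f in frames]
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValueError("all frames must share a shape")
    n = len(frames)
    shifts = np.zeros((n, 2))
    shifted = list(frames)
    limit = min(shape) / 4
    for _ in range(max_iters):
        total = np.sum(shifted, axis=0)
        max_update = 0.0
        for i in range(n):
            ref = (total - shifted[i]) / (n - 1)
            d, _score = _correlation_peak(frames[i], ref)
            if np.any(np.abs(d) > limit):
                warnings.warn(f"frame {i}: correlation peak at border, "
                              "leaving frame unshifted")
                d = np.zeros(2)
            max_update = max(max_update, float(np.max(np.abs(d - shifts[i]))))
            shifts[i] = d
            shifted[i] = _fourier_shift_2d(frames[i], d)
        shifts -= shifts.mean(axis=0)        # gauge: zero-mean drift
        shifted = [_fourier_shift_2d(frames[i], shifts[i]) for i in range(n)]
        if max_update < tol_px:
            break
    return np.mean(shifted, axis=0), shifts


# ---------------------------------------------------------------------------
# defocus estimation and phase flipping
# ---------------------------------------------------------------------------

@dataclass
class DefocusEstimate:
    defocus_um: float
    quality: float          # peak profile/model correlation, 0 = featureless
    grid_spacing_um: float  # reported error bound of the grid search


def _radial_average(power: np.ndarray, pixel_size: float, n_bins: int):
    fx = np.fft.fftfreq(power.shape[0], d=pixel_size)[:, None]
    fy = np.fft.fftfreq(power.shape[1], d=pixel_size)[None, :]
    s = np.sqrt(fx * fx + fy * fy)
    s_max = 0.5 / pixel_size
    bins = np.minimum((s / s_max * n_bins).astype(int), n_bins - 1)
    prof = np.bincount(bins.ravel(), weights=power.ravel(), minlength=n_bins)
    counts = np.bincount(bins.ravel(), minlength=n_bins)
    centers = (np.arange(n_bins) + 0.5) / n_bins * s_max
    return centers, prof / np.maximum(counts, 1)


def estimate_defocus(projection: np.ndarray, pixel_size: float,
                     ctf: CTFParams, strip_width_px: int = 128,
                     search_range_um=(1.0, 6.0), n_grid: int = 101,
                     n_bins: int = 128) -> DefocusEstimate:
    """Estimate defocus from Thon rings by strip-based periodogram averaging.

    The image is cut into half-overlapping strips parallel to the tilt axis
    (y); strip periodograms are averaged and radially averaged, the smooth
    background is removed, and the defocus whose simulated ``|CTF|^2`` ring
    pattern best correlates with the residual is located by grid search over
    ``search_range_um`` followed by a parabolic refinement.
    """
    projection = np.asarray(projection, dtype=np.float64)
    if projection.shape[0] < 2 * strip_width_px:
        raise ValueError("projection narrower than two strips")
    step = strip_width_px // 2
    window = np.hanning(strip_width_px)[:, None] * np.hanning(
        projection.shape[1])[None, :]
    power = np.zeros((strip_width_px, projection.shape[1]))
    n_strips = 0
    for x0 in range(0, projection.shape[0] - strip_width_px + 1, step):
        strip = projection[x0:x0 + strip_width_px]
        strip = (strip - strip.mean()) * window
        power += np.abs(np.fft.fft2(strip)) ** 2
        n_strips += 1
    power /= n_strips
    s, prof = _radial_average(power, pixel_size, n_bins)

    band = slice(max(3, n_bins // 16), int(n_bins * 0.9))
    resid = prof - gaussian_filter1d(prof, n_bins / 16)
    resid = resid[band]
    if prof.max() <= 0 or np.std(resid) < 1e-12 * max(1.0, prof.max()):
        return DefocusEstimate(float(np.mean(search_range_um)), 0.0,
                               float(np.ptp(search_range_um) / (n_grid - 1)))

    def score(dz_um: float) -> float:
        model = ctf.ctf(s, dz_um) ** 2
        m = model - gaussian_filter1d(model, n_bins / 16)
        m = m[band]
        denom = np.std(resid) * np.std(m)
        return float(np.mean((resid - resid.mean()) * (m - m.mean())) / denom) \
            if denom > 0 else 0.0

    grid = np.linspace(search_range_um[0], search_range_um[1], n_grid)
    scores = np.array([score(dz) for dz in grid])
    i = int(np.argmax(scores))
    spacing = float(grid[1] - grid[0])
    best = grid[i]
    if 0 < i < n_grid - 1:     # parabolic + bounded local refine
        from scipy.optimize import minimize_scalar
        res = minimize_scalar(lambda d: -score(d),
                              bounds=(grid[i - 1], grid[i + 1]),
                              method="bounded")
        best = float(res.x)
    quality = max(0.0, float(scores[i]))
    if i in (0, n_grid - 1):
        quality = min(quality, 0.1)     # truth likely outside the range
    return DefocusEstimate(float(best), quality, spacing)


def phase_flip(projection: np.ndarray, pixel_size: float, ctf: CTFParams,
               defocus_um: float | None = None) -> np.ndarray:
    """Correct CTF phase reversals by multiplying with sign(CTF) per frequency.

    Amplitudes are preserved exactly (the sign factor is +/-1 everywhere,
    including at zero crossings), so applying the correction twice is the
    identity.
    """
    projection = np.asarray(projection)
    c = ctf.ctf_2d(projection.shape, pixel_size, defocus_um)
    sign = np.where(c < 0, -1.0, 1.0)      # +1 at DC by convention
    return np.fft.ifft2(np.fft.fft2(projection) * sign).real.astype(
        projection.dtype)


# ---------------------------------------------------------------------------
# marker-based tilt alignment
# ---------------------------------------------------------------------------

@dataclass
class TiltAlignment:
    shifts_px: np.ndarray        # (n_images, 2) estimated in-plane shifts
    marker_positions: np.ndarray  # (n_markers, 3) fitted 3D positions (px)
    residual_rms_px: float


def align_tilt_series(tilt_deg, marker_obs) -> TiltAlignment:
    """Solve per-image shifts from tracked gold-marker image coordinates.

    ``marker_obs`` has shape (n_images, n_markers, 2): observed (u, v)
    relative to the image center.  With known tilt angles the projection
    model ``u = p_x cos t - p_z sin t + s_x``, ``v = p_y + s_y`` is linear in
    the unknown marker positions and shifts and is solved by least squares.
    The gauge freedom (a common translation of all markers absorbed into the
    shifts) is fixed by constraining the marker centroid to the origin.
    """
    tilt_deg = np.asarray(tilt_deg, dtype=float)
    obs = np.asarray(marker_obs, dtype=float)
    n_img, n_mark = obs.shape[0], obs.shape[1]
    if n_mark < 3 or n_img < 3:
        raise ValueError("need >= 3 markers tracked in >= 3 images")
    c = np.cos(np.radians(tilt_deg))
    s = np.sin(np.radians(tilt_deg))
    n_unk = 3 * n_mark + 2 * n_img
    rows, rhs = [], []
    for i in range(n_img):
        for j in range(n_mark):
            r = np.zeros(n_unk)
            r[3 * j], r[3 * j + 2], r[3 * n_mark + 2 * i] = c[i], -s[i], 1.0
            rows.append(r)
            rhs.append(obs[i, j, 0])
            r = np.zeros(n_unk)
            r[3 * j + 1], r[3 * n_mark + 2 * i + 1] = 1.0, 1.0
            rows.append(r)
            rhs.append(obs[i, j, 1])
    w = 1e6
    for axis in range(3):          # centroid gauge constraint
        r = np.zeros(n_unk)
        r[axis:3 * n_mark:3] = w
        rows.append(r)
        rhs.append(0.0)
    a = np.array(rows)
    b = np.array(rhs)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    markers = sol[:3 * n_mark].reshape(n_mark, 3)
    shifts = sol[3 * n_mark:].reshape(n_img, 2)
    pred_u = markers[:, 0][None, :] * c[:, None] \
        - markers[:, 2][None, :] * s[:, None] + shifts[:, 0][:, None]
    pred_v = markers[:, 1][None, :] + shifts[:, 1][:, None]
    resid = np.stack([obs[:, :, 0] - pred_u, obs[:, :, 1] - pred_v])
    return TiltAlignment(shifts, markers, float(np.sqrt(np.mean(resid ** 2))))


# ---------------------------------------------------------------------------
# weighted backprojection
# ---------------------------------------------------------------------------

def _ramp_filter(images: np.ndarray) -> np.ndarray:
    """1D ramp |k| along the image axis perpendicular to the tilt axis."""
    k = np.abs(np.fft.fftfreq(images.shape[1]))[None, :, None]
    return np.fft.ifft(np.fft.fft(images, axis=1) * k, axis=1).real


def _angular_taper(n_images: int, width: int) -> np.ndarray:
    """Raised-cosine weights over the outermost ``width`` tilt images.

    The extreme projections sit exactly on the wedge boundary; tapering
    their quadrature weight suppresses the perpendicular ringing their
    finite-box spectra would otherwise spill outside the sampled wedge.
    """
    w = np.ones(n_images)
    for j in range(min(width, n_images // 2)):
        f = 0.5 * (1 - math.cos(math.pi * (j + 0.5) / width))
        w[j] = f
        w[n_images - 1 - j] = f
    return w


def _backproject(images: np.ndarray, tilt_deg: np.ndarray, shifts: np.ndarray,
                 out_shape, center_offset_px=(0.0, 0.0, 0.0),
                 binning: int = 1, taper_width: int = 2) -> np.ndarray:
    """Smear ramp-filtered projections back along their viewing directions.

    ``center_offset_px`` places the output-box center at that (unbinned)
    pixel offset from the projection center, which is how per-particle
    subtomogram reconstruction recenters a particle.
    """
    nx_img, ny_img = images.shape[1], images.shape[2]
    cx, cy = nx_img // 2, ny_img // 2
    ox, oy, oz = [int(v) for v in out_shape]
    xs = (np.arange(ox) - ox // 2) * binning + center_offset_px[0]
    ys = (np.arange(oy) - oy // 2) * binning + center_offset_px[1]
    zs = (np.arange(oz) - oz // 2) * binning + center_offset_px[2]
    out = np.zeros((ox, oy, oz), dtype=np.float64)
    filtered = _ramp_filter(images) * _angular_taper(len(images),
                                                     taper_width)[:, None, None]
    for i, theta in enumerate(tilt_deg):
        t = math.radians(theta)
        u = (xs[:, None] * math.cos(t) - zs[None, :] * math.sin(t)
             + shifts[i, 0] + cx)                     # (ox, oz)
        v = ys + shifts[i, 1] + cy                    # (oy,)
        u0 = np.floor(u).astype(int)
        wu = u - u0
        valid_u = (u0 >= 0) & (u0 < nx_img - 1)
        u0c = np.clip(u0, 0, nx_img - 2)
        img = filtered[i]
        rows = (img[u0c.ravel(), :] * (1 - wu.ravel())[:, None]
                + img[u0c.ravel() + 1, :] * wu.ravel()[:, None])
        rows[~valid_u.ravel(), :] = 0.0
        rows = rows.reshape(ox, oz, ny_img)
        v0 = np.floor(v).astype(int)
        wv = v - v0
        valid_v = (v0 >= 0) & (v0 < ny_img - 1)
        v0c = np.clip(v0, 0, ny_img - 2)
        vals = rows[:, :, v0c] * (1 - wv) + rows[:, :, v0c + 1] * wv
        vals[:, :, ~valid_v] = 0.0
        out += vals.transpose(0, 2, 1)                # (x, y, z)
    return (out * math.pi / (2 * len(tilt_deg))).astype(np.float32)


def weighted_backprojection(series: TiltSeries, tilt_range=None,
                            size: int | None = None, binning: int = 1,
                            shifts: np.ndarray | None = None) -> DensityMap:
    """Reconstruct a tomogram from a (subset of a) tilt series.

    Each projection is ramp-filtered along the direction perpendicular to
    the tilt axis and smeared back along its viewing direction.  ``shifts``
    (per-image, px, e.g. from :func:`align_tilt_series`) correct the
    projection sampling; the output voxel size is ``pixel_size * binning``.
    """
    sub = series if tilt_range is None else series.subset(*tilt_range)
    n = sub.images.shape[1] // binning if size is None else size
    sh = (shifts if shifts is not None else
          np.zeros((len(sub), 2)))
    if shifts is not None and tilt_range is not None:
        sel = (series.tilt_deg >= tilt_range[0]) & (series.tilt_deg <= tilt_range[1])
        sh = np.asarray(shifts)[sel]
    grid = _backproject(sub.images, sub.tilt_deg, np.asarray(sh),
                        (n, n, n), binning=binning)
    return DensityMap(grid, sub.pixel_size * binning)


def reconstruct_subtomogram(series: TiltSeries, position_A, box: int,
                            tilt_range=None,
                            shifts: np.ndarray | None = None):
    """Per-particle backprojection centered on a physical position.

    ``position_A`` is the particle position in Angstrom relative to the
    tomogram/scene center.  Projection coordinates are offset so the
    particle lands at the box center; only images within ``tilt_range``
    contribute, and the returned :class:`~tomopipe.core.WedgeSpec` records
    the tilt coverage actually used.
    """
    sub = series if tilt_range is None else series.subset(*tilt_range)
    sh = np.zeros((len(sub), 2)) if shifts is None else np.asarray(shifts)
    if shifts is not None and tilt_range is not None:
        sel = (series.tilt_deg >= tilt_range[0]) & (series.tilt_deg <= tilt_range[1])
        sh = np.asarray(shifts)[sel]
    pos_px = np.asarray(position_A, dtype=float) / sub.pixel_size
    nx_img, ny_img = sub.images.shape[1], sub.images.shape[2]
    margin = box / 2 * math.sqrt(2.0)
    for theta in sub.tilt_deg:
        t = math.radians(theta)
        u = pos_px[0] * math.cos(t) - pos_px[2] * math.sin(t)
        if (abs(u) + margin > nx_img / 2 - 1
                or abs(pos_px[1]) + box / 2 > ny_img / 2 - 1):
            raise ValueError(
                f"position too close to the field edge at tilt {theta:g} deg "
                f"(needs {margin:.0f} px margin)")
    grid = _backproject(sub.images, sub.tilt_deg, sh, (box,) * 3,
                        center_offset_px=pos_px)
    return DensityMap(grid, sub.pixel_size), sub.wedge
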