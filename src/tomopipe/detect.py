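"""Six-dimensional template matching in tomograms.

Scans a quasi-uniform grid of orientations; for each orientation the
template is rotated, limited to the tomogram's missing-wedge support, and
correlated against the tomogram at every position with local normalization
(fast local correlation via FFT).  The per-voxel maximum over orientations
and its argmax orientation index form the score and orientation volumes from
which candidate particles are extracted as non-overlapping peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from tomopipe.core import (DensityMap, RigidTransform, SoftMask, WedgeSpec,
                           make_wedge_mask, rotate_volume, volume_center)

__all__ = [
    "CandidateParticle", "so3_grid", "match_template", "extract_peaks",
    "candidates_to_table", "normalized_cc_at", "detection_valid_mask",
    "refine_candidates",
]


@dataclass
class CandidateParticle:
    """One template-matching hit: position, best orientation, score."""
    tomo_id: str
    position: np.ndarray          # voxel indices in the tomogram
    rotation: np.ndarray          # 3x3 matrix of the best-matching grid node
    score: float

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-9 <= self.score <= 1.0 + 1e-9):
            raise ValueError(f"score {self.score} outside [-1, 1]")

    @property
    def euler_zxz(self) -> np.ndarray:
        return RigidTransform(self.rotation).as_euler_zxz()


def so3_grid(increment_deg: float) -> list:
    """Quasi-uniform orientation grid with the given angular spacing.

    Template-orientation directions come from a Fibonacci spiral on the
    sphere with one point per ``increment_deg``-sized cap, combined with
    in-plane rotations at the same spacing; every node's nearest neighbour
    is within one increment.  Returns a list of 3x3 rotation matrices.
    """
    if increment_deg <= 0:
        raise ValueError("angular increment must be positive")
    from scipy.spatial.transform import Rotation
    delta = math.radians(increment_deg)
    n_sphere = max(1, int(math.ceil(4 * math.pi / (delta * delta
                                                   * math.sqrt(3) / 2))))
    n_psi = max(1, int(math.ceil(360.0 / increment_deg)))
    golden = math.pi * (3.0 - math.sqrt(5.0))
    mats = []
    for i in range(n_sphere):
        z = 1.0 - 2.0 * (i + 0.5) / n_sphere
        r = math.sqrt(max(0.0, 1.0 - z * z))
        phi = golden * i
        direction = np.array([r * math.cos(phi), r * math.sin(phi), z])
        theta = math.acos(np.clip(z, -1, 1))
        azimuth = math.atan2(direction[1], direction[0])
        for j in range(n_psi):
            psi = 2 * math.pi * j / n_psi
            mats.append(Rotation.from_euler(
                "ZYZ", [azimuth, theta, psi]).as_matrix())
    return mats


def _local_std_denominator(tomo: np.ndarray, mask_origin: np.ndarray,
                           floor_rel: float = 1e-3) -> np.ndarray:
    """sqrt(local sum of squares - local mean energy) under the mask.

    ``mask_origin`` must be in FFT (origin-centered) layout, exactly like
    the embedded template in the numerator path.  Computed by FFT
    convolution of the tomogram and its square with the mask (Roseman's
    fast local correlation).  The denominator is floored at ``floor_rel``
    of its maximum so that featureless (zero-variance) regions score ~0
    instead of dividing by numerical noise.
    """
    shape = tomo.shape
    n_mask = mask_origin.sum()
    conj = np.conj(np.fft.rfftn(mask_origin))
    local_sum = np.fft.irfftn(np.fft.rfftn(tomo) * conj, s=shape, axes=(0, 1, 2))
    local_ss = np.fft.irfftn(np.fft.rfftn(tomo * tomo) * conj, s=shape, axes=(0, 1, 2))
    var = local_ss - local_sum * local_sum / n_mask
    denom = np.sqrt(np.maximum(var, 0.0))
    return np.maximum(denom, floor_rel * denom.max() + 1e-20)


def _prepare_template(template_grid: np.ndarray, mask: np.ndarray,
                      wedge_filter: np.ndarray | None):
    """Wedge-filter, make mean-free under the mask, mask, and normalize."""
    t = template_grid
    if wedge_filter is not None:
        t = np.fft.ifftn(np.fft.fftn(np.fft.ifftshift(t))
                         * wedge_filter).real
        t = np.fft.fftshift(t)
    n_mask = mask.sum()
    t = (t - (t * mask).sum() / n_mask) * mask
    norm = math.sqrt(float((t * t).sum()))
    return t / max(norm, 1e-20)


def _embed(small: np.ndarray, shape) -> np.ndarray:
    """Center a small centered volume in a large FFT-layout volume."""
    out = np.zeros(shape, dtype=small.dtype)
    n = small.shape[0]
    c = [s // 2 for s in shape]
    sl = tuple(slice(ci - n // 2, ci - n // 2 + n) for ci in c)
    out[sl] = small
    return np.fft.ifftshift(out)


def match_template(tomogram: DensityMap, template: DensityMap,
                   template_mask: SoftMask, angular_increment_deg: float,
                   wedge: WedgeSpec | None = None, tomo_id: str = "tomo0",
                   rotations: list | None = None):
    """Locally normalized 6D cross-correlation search.

    For each orientation on the SO(3) grid the template and mask are
    rotated, the rotated template is limited to the wedge's Fourier support,
    and the correlation with the tomogram is evaluated at every position via
    FFT; the score volume keeps the per-voxel maximum over orientations and
    the orientation volume its argmax index.  The local-normalization
    denominator is computed once from the (assumed rotation-symmetric,
    typically spherical) matching mask.

    Returns (score volume, orientation-index volume, rotations list).
    """
    nt = template.require_cubic()
    shape = tomogram.grid.shape
    if any(nt > s for s in shape):
        raise ValueError("template must be smaller than the tomogram")
    if angular_increment_deg <= 0:
        raise ValueError("angular increment must be positive")
    mask_grid = template_mask.grid
    if mask_grid.sum() <= 0:
        raise ValueError("empty template mask")
    if rotations is None:
        rotations = so3_grid(angular_increment_deg)
    wedge_filter = (make_wedge_mask((nt,) * 3, wedge)
                    if wedge is not None and not wedge.is_full else None)

    tomo = tomogram.grid.astype(np.float64)
    f_tomo = np.fft.rfftn(tomo)
    denom = _local_std_denominator(tomo, _embed(mask_grid.astype(np.float64),
                                                shape))
    score = np.full(shape, -np.inf)
    orient = np.zeros(shape, dtype=np.int32)
    tmpl = DensityMap(template.grid - template.grid.mean(),
                      template.voxel_size)
    mask_dm = DensityMap(mask_grid, template.voxel_size)
    for idx, rot in enumerate(rotations):
        rt = RigidTransform(rot)
        t_rot = rotate_volume(tmpl, rt, cval=0.0).grid.astype(np.float64)
        m_rot = np.clip(rotate_volume(mask_dm, rt, cval=0.0).grid, 0, 1)
        t_prep = _prepare_template(t_rot, np.asarray(m_rot, np.float64),
                                   wedge_filter)
        num = np.fft.irfftn(np.conj(np.fft.rfftn(_embed(t_prep, shape)))
                            * f_tomo, s=shape, axes=(0, 1, 2))
        cc = num / denom
        better = cc > score
        score[better] = cc[better]
        orient[better] = idx
    return np.clip(score, -1.0, 1.0), orient, rotations


def normalized_cc_at(tomogram: DensityMap, template: DensityMap,
                     template_mask: SoftMask, rotation: np.ndarray,
                     position, wedge: WedgeSpec | None = None) -> float:
    """Direct real-space locally normalized CC at one position/orientation.

    Independent slow path over the same quantities as
    :func:`match_template`; used as a cross-check oracle.
    """
    nt = template.require_cubic()
    rt = RigidTransform(np.asarray(rotation))
    t_rot = rotate_volume(DensityMap(template.grid - template.grid.mean(),
                                     template.voxel_size), rt,
                          cval=0.0).grid.astype(np.float64)
    m_rot = np.clip(rotate_volume(DensityMap(template_mask.grid,
                                             template.voxel_size), rt,
                                  cval=0.0).grid, 0, 1).astype(np.float64)
    wedge_filter = (make_wedge_mask((nt,) * 3, wedge)
                    if wedge is not None and not wedge.is_full else None)
    t_prep = _prepare_template(t_rot, m_rot, wedge_filter)
    mask = np.fft.fftshift(_embed(template_mask.grid.astype(np.float64),
                                  tomogram.grid.shape))
    pos = np.asarray(position, dtype=int)
    c = nt // 2
    sl = tuple(slice(p - c, p - c + nt) for p in pos)
    region = tomogram.grid[sl].astype(np.float64)
    n_mask = template_mask.grid.sum()
    local_sum = float((region * template_mask.grid).sum())
    local_ss = float((region * region * template_mask.grid).sum())
    denom = math.sqrt(max(local_ss - local_sum ** 2 / n_mask, 1e-20))
    return float((t_prep * region).sum() / denom)


def detection_valid_mask(shape, margin_vox: float) -> np.ndarray:
    """Region of a tomogram where template matches are trustworthy.

    Excludes voxels within ``margin_vox`` of the y faces and outside the
    inscribed x-z cylinder shrunk by the margin: those regions of a
    weighted backprojection are only partially sampled (projections zero
    outside the detector field), so their low local variance inflates
    normalized correlation scores.
    """
    nx, ny, nz = shape
    cx, cy, cz = nx // 2, ny // 2, nz // 2
    x = np.arange(nx) - cx
    y = np.arange(ny) - cy
    z = np.arange(nz) - cz
    r_xz = np.sqrt(x[:, None] ** 2 + z[None, :] ** 2)
    cyl = r_xz <= (min(cx, cz) - margin_vox)
    slab = np.abs(y) <= (cy - margin_vox)
    return cyl[:, None, :] & slab[None, :, None]


def extract_peaks(score: np.ndarray, n_peaks: int, exclusion_radius_vox: float,
                  orient: np.ndarray | None = None,
                  rotations: list | None = None,
                  tomo_id: str = "tomo0",
                  valid: np.ndarray | None = None) -> list:
    """Greedy descending-score peak extraction with spherical suppression.

    After each pick a sphere of ``exclusion_radius_vox`` is suppressed; ties
    break in lexicographic voxel order (C-order argmax).  ``valid`` (e.g.
    from :func:`detection_valid_mask`) restricts picking to trustworthy
    voxels.  Returns at most ``n_peaks`` :class:`CandidateParticle` records.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    work = np.array(score, dtype=float, copy=True)
    if valid is not None:
        work[~valid] = -np.inf
    shape = work.shape
    r = int(math.ceil(exclusion_radius_vox))
    ball_ax = np.arange(-r, r + 1)
    ball = (ball_ax[:, None, None] ** 2 + ball_ax[None, :, None] ** 2
            + ball_ax[None, None, :] ** 2) <= exclusion_radius_vox ** 2
    out = []
    for _ in range(n_peaks):
        idx = np.unravel_index(np.argmax(work), shape)
        val = work[idx]
        if not np.isfinite(val):
            break
        rot = (rotations[int(orient[idx])] if orient is not None
               and rotations is not None else np.eye(3))
        out.append(CandidateParticle(tomo_id, np.array(idx), np.asarray(rot),
                                     float(np.clip(val, -1, 1))))
        lo = [max(0, idx[a] - r) for a in range(3)]
        hi = [min(shape[a], idx[a] + r + 1) for a in range(3)]
        bsl = tuple(slice(lo[a] - (idx[a] - r), ball.shape[a]
                          - ((idx[a] + r + 1) - hi[a])) for a in range(3))
        region = tuple(slice(lo[a], hi[a]) for a in range(3))
        work[region][ball[bsl]] = -np.inf
    return out


def refine_candidates(tomogram: DensityMap, template: DensityMap,
                      template_mask: SoftMask, candidates: list,
                      wedge: WedgeSpec | None = None,
                      angular_step_deg: float = 6.0,
                      angular_range_deg: float = 13.0,
                      position_range_vox: int = 1,
                      dedupe_radius_vox: float | None = None) -> list:
    """Re-score candidates with a local orientation/position search.

    The coarse SO(3) grid quantizes orientations, which depresses the score
    of a true match far more than that of a rotationally featureless false
    positive (a gold bead looks the same from every direction).  For each
    candidate, rotations in a rotation-vector ball around its grid
    orientation and positions within ``position_range_vox`` are evaluated
    with the same locally normalized correlation, and candidates are
    returned re-sorted by their refined scores.
    """
    from tomopipe.average import local_rotation_grid
    perts = local_rotation_grid(angular_step_deg, angular_range_deg)
    offs = np.array([[dx, dy, dz]
                     for dx in range(-position_range_vox,
                                     position_range_vox + 1)
                     for dy in range(-position_range_vox,
                                     position_range_vox + 1)
                     for dz in range(-position_range_vox,
                                     position_range_vox + 1)])
    shape = np.array(tomogram.grid.shape)
    nt = template.require_cubic()
    c = nt // 2
    wedge_filter = (make_wedge_mask((nt,) * 3, wedge)
                    if wedge is not None and not wedge.is_full else None)
    tmpl0 = DensityMap(template.grid - template.grid.mean(),
                       template.voxel_size)
    mask_dm = DensityMap(template_mask.grid, template.voxel_size)
    mgrid = template_mask.grid.astype(np.float64)
    n_mask = mgrid.sum()
    tomo = tomogram.grid.astype(np.float64)
    out = []
    for cand in candidates:
        best_score, best_rot, best_pos = cand.score, cand.rotation, \
            np.asarray(cand.position)
        # alternate orientation polish and position hill-climb until the
        # candidate settles on its local score maximum
        for _round in range(8):
            improved = False
            for pert in perts:
                rot = best_rot @ pert
                rt = RigidTransform(rot)
                t_rot = rotate_volume(tmpl0, rt,
                                      cval=0.0).grid.astype(np.float64)
                m_rot = np.clip(rotate_volume(mask_dm, rt, cval=0.0).grid,
                                0, 1)
                t_prep = _prepare_template(t_rot,
                                           np.asarray(m_rot, np.float64),
                                           wedge_filter)
                for off in offs:
                    pos = best_pos + off
                    if np.any(pos < c) or np.any(pos > shape - c - 1):
                        continue
                    sl = tuple(slice(p - c, p - c + nt) for p in pos)
                    region = tomo[sl]
                    lsum = float((region * mgrid).sum())
                    lss = float((region * region * mgrid).sum())
                    den = math.sqrt(max(lss - lsum ** 2 / n_mask, 1e-20))
                    sc = float((t_prep * region).sum() / den)
                    if sc > best_score + 1e-9:
                        best_score, best_rot, best_pos = sc, rot, pos
                        improved = True
            if not improved:
                break
        out.append(CandidateParticle(cand.tomo_id, best_pos,
                                     np.asarray(best_rot),
                                     float(np.clip(best_score, -1, 1))))
    out.sort(key=lambda cd: -cd.score)
    if dedupe_radius_vox is not None:
        kept = []
        for cand in out:
            if all(np.linalg.norm(cand.position - k.position)
                   > dedupe_radius_vox for k in kept):
                kept.append(cand)
        out = kept
    return out


def candidates_to_table(candidates: list) -> pd.DataFrame:
    """Particle table: tomo_id, position, ZXZ Euler angles, score."""
    rows = []
    for c in candidates:
        phi, theta, psi = c.euler_zxz
        rows.append(dict(tomo_id=c.tomo_id, x=int(c.position[0]),
                         y=int(c.position[1]), z=int(c.position[2]),
                         phi=phi, theta=theta, psi=psi, score=c.score))
    return pd.DataFrame(rows)
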