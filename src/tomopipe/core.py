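"""Shared volumetric types, rigid-transform algebra, Fourier utilities and MRC I/O.

Conventions used throughout the package
---------------------------------------
* Volumes are cubic with an even edge length; arrays are indexed ``[x, y, z]``.
* The rotation center of a volume of edge ``n`` is voxel ``floor(n/2)`` on each
  axis, which coincides with the ``fftshift`` center for even ``n``.
* Euler angles are intrinsic ZXZ in degrees, right-handed, active rotations.
* The single tilt axis is the volume y axis; projections integrate along z.
* Coordinates are 0-based voxel indices; physical position in Angstrom is
  ``origin + index * voxel_size``.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

__all__ = [
    "DensityMap",
    "RigidTransform",
    "WedgeSpec",
    "SoftMask",
    "rotate_volume",
    "compose_transforms",
    "make_wedge_mask",
    "bandpass",
    "read_mrc",
    "write_mrc",
    "freq_grid",
    "lowpass_mask",
    "spherical_mask",
    "rotate_fourier_mask",
    "volume_center",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class DensityMap:
    """A 3D scalar field on a regular grid with a physical voxel size.

    Parameters
    ----------
    grid : ndarray, shape (nx, ny, nz)
        Scalar density values; stored as float32.
    voxel_size : float
        Isotropic voxel edge in Angstrom; must be positive.
    origin : ndarray, shape (3,)
        Physical coordinate (Angstrom) of voxel (0, 0, 0).
    """

    grid: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3:
            raise ValueError(f"grid must be 3D, got shape {self.grid.shape}")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid contains non-finite values")
        if self.voxel_size <= 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple:
        return self.grid.shape

    @property
    def center(self) -> np.ndarray:
        """Rotation-center voxel, floor(n/2) per axis."""
        return np.array([s // 2 for s in self.grid.shape], dtype=float)

    def require_cubic(self) -> int:
        nx, ny, nz = self.grid.shape
        if not (nx == ny == nz):
            raise ValueError(f"map must be cubic, got shape {self.grid.shape}")
        if nx % 2:
            raise ValueError(f"map edge must be even, got {nx}")
        return nx

    def copy(self) -> "DensityMap":
        return DensityMap(self.grid.copy(), self.voxel_size, self.origin.copy())


@dataclass
class RigidTransform:
    """Proper rigid-body transform: y = R x + t with t in Angstrom.

    ``rotation`` must be a proper rotation (det = +1, orthonormal within
    1e-9).  Points are taken relative to the volume rotation center when the
    transform is applied to a :class:`DensityMap`.
    """

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation determinant must be +1")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3))

    @classmethod
    def from_euler_zxz(cls, phi: float, theta: float, psi: float,
                       translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Build from intrinsic ZXZ Euler angles in degrees."""
        rot = Rotation.from_euler("ZXZ", [phi, theta, psi], degrees=True)
        return cls(rot.as_matrix(), np.asarray(translation, dtype=float))

    def as_euler_zxz(self) -> np.ndarray:
        """Intrinsic ZXZ Euler angles (phi, theta, psi) in degrees."""
        return Rotation.from_matrix(self.rotation).as_euler("ZXZ", degrees=True)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) array of points (Angstrom)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.rotation.T + self.translation
        return out if np.asarray(points).ndim == 2 else out[0]

    def matrix4(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


@dataclass
class WedgeSpec:
    """Single-axis tilt coverage: tilts about the volume y axis.

    The Fourier region left unsampled by the limited tilt range is the
    "missing wedge"; it surrounds the beam (kz) axis.
    """

    tilt_min: float
    tilt_max: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.tilt_min < self.tilt_max <= 90.0):
            raise ValueError(
                f"need -90 <= tilt_min < tilt_max <= 90, got "
                f"[{self.tilt_min}, {self.tilt_max}]")

    @property
    def is_full(self) -> bool:
        return self.tilt_min <= -90.0 and self.tilt_max >= 90.0


@dataclass
class SoftMask:
    """Real-space mask in [0, 1] with a cosine-edge falloff."""

    grid: np.ndarray
    edge_width: float = 0.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.min() < -1e-6 or self.grid.max() > 1.0 + 1e-6:
            raise ValueError("mask values must lie in [0, 1]")
        np.clip(self.grid, 0.0, 1.0, out=self.grid)

    def apply(self, volume: np.ndarray) -> np.ndarray:
        if volume.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.grid.shape} != volume shape {volume.shape}")
        return volume * self.grid


def spherical_mask(shape, radius_vox: float, edge_width: float = 3.0,
                   center=None) -> SoftMask:
    """Soft spherical mask: 1 inside ``radius_vox``, cosine edge outside."""
    shape = tuple(shape)
    if center is None:
        center = [s // 2 for s in shape]
    ax = [np.arange(s) - c for s, c in zip(shape, center)]
    r = np.sqrt(ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
                + ax[2][None, None, :] ** 2)
    m = np.zeros(shape, dtype=np.float32)
    m[r <= radius_vox] = 1.0
    if edge_width > 0:
        edge = (r > radius_vox) & (r < radius_vox + edge_width)
        m[edge] = 0.5 * (1 + np.cos(np.pi * (r[edge] - radius_vox) / edge_width))
    return SoftMask(m, edge_width)


def volume_center(shape) -> np.ndarray:
    return np.array([s // 2 for s in shape], dtype=float)


# ---------------------------------------------------------------------------
# transforms on volumes
# ---------------------------------------------------------------------------

def compose_transforms(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Composite transform applying ``b`` first, then ``a``."""
    return RigidTransform(a.rotation @ b.rotation,
                          a.rotation @ b.translation + a.translation)


def rotate_volume(dmap: DensityMap, transform: RigidTransform,
                  order: int = 1, cval=None) -> DensityMap:
    """Apply a rigid transform to a cubic volume (trilinear interpolation).

    A feature at position ``x`` (Angstrom, relative to the rotation center)
    moves to ``R x + t``.  Values are obtained by inverse mapping; samples
    falling outside the input grid are filled with the map mean (or ``cval``).
    """
    n = dmap.require_cubic()
    c = dmap.center
    t_vox = transform.translation / dmap.voxel_size
    rinv = transform.rotation.T
    # output index o maps to input index rinv @ (o - c - t) + c
    offset = c - rinv @ (c + t_vox)
    fill = float(dmap.grid.mean()) if cval is None else cval
    out = ndimage.affine_transform(dmap.grid, rinv, offset=offset, order=order,
                                   mode="constant", cval=fill,
                                   output=np.float32, prefilter=(order > 1))
    return DensityMap(out, dmap.voxel_size, dmap.origin.copy())


# ---------------------------------------------------------------------------
# Fourier utilities
# ---------------------------------------------------------------------------

def freq_grid(shape, voxel_size: float) -> np.ndarray:
    """Radial spatial frequency |s| in 1/Angstrom, numpy FFT layout."""
    axes = [np.fft.fftfreq(s, d=voxel_size) for s in shape]
    return np.sqrt(axes[0][:, None, None] ** 2 + axes[1][None, :, None] ** 2
                   + axes[2][None, None, :] ** 2)


def make_wedge_mask(shape, wedge: WedgeSpec) -> np.ndarray:
    """Binary Fourier mask of the region sampled by a single-axis tilt range.

    Tilting about y while projecting along z measures, at tilt angle theta,
    the central plane whose in-plane angle in the (kx, kz) plane is theta away
    from the kx axis.  A Fourier voxel is sampled iff that angle, wrapped to
    [-90, 90), lies within [tilt_min, tilt_max].  The mask is returned in
    numpy FFT layout, is centrosymmetric (Friedel symmetry), contains the DC
    voxel, and is independent of ky.
    """
    shape = tuple(shape)
    if len(shape) != 3 or len(set(shape)) != 1:
        raise ValueError(f"shape must be cubic, got {shape}")
    kx = np.fft.fftfreq(shape[0])[:, None]
    kz = np.fft.fftfreq(shape[2])[None, :]
    # angle of the measured plane through (kx, kz); 0 on the kx axis
    psi = np.degrees(np.arctan2(-kz, kx + np.zeros_like(kz)))
    psi = (psi + 90.0) % 180.0 - 90.0
    # the 1e-9 deg tolerance keeps Friedel-mate pairs that land exactly on
    # a boundary plane on the same side of it
    mask2d = ((psi >= wedge.tilt_min - 1e-9)
              & (psi <= wedge.tilt_max + 1e-9))
    mask2d[(kx + np.zeros_like(kz) == 0) & (kz + np.zeros_like(kx) == 0)] = True
    # the Nyquist row/column of an even grid aliases +0.5 and -0.5 cycles;
    # symmetrize explicitly so Friedel symmetry holds there too
    neg = (-np.arange(shape[0])) % shape[0]
    mask2d = mask2d | mask2d[np.ix_(neg, neg)]
    mask = np.broadcast_to(mask2d[:, None, :], shape).copy()
    return mask.astype(np.float32)


def rotate_fourier_mask(mask: np.ndarray, rotation: np.ndarray) -> np.ndarray:
    """Rotate a Fourier-domain mask (FFT layout) by a rotation matrix.

    The mask is shifted to a centered layout, rotated about the center voxel
    with linear interpolation, and shifted back.
    """
    centered = np.fft.fftshift(mask)
    c = volume_center(mask.shape)
    rinv = np.asarray(rotation).T
    offset = c - rinv @ c
    rot = ndimage.affine_transform(centered.astype(np.float32), rinv,
                                   offset=offset, order=1, mode="constant",
                                   cval=0.0)
    return np.clip(np.fft.ifftshift(rot), 0.0, 1.0)


def lowpass_mask(shape, voxel_size: float, resolution: float,
                 soft_shells: float = 2.0) -> np.ndarray:
    """Soft low-pass Fourier multiplier: unity below 1/resolution, Gaussian edge."""
    s = freq_grid(shape, voxel_size)
    s_hi = 1.0 / resolution
    sigma = soft_shells / (shape[0] * voxel_size)
    out = np.ones(shape, dtype=np.float32)
    beyond = s > s_hi
    out[beyond] = np.exp(-((s[beyond] - s_hi) ** 2) / (2 * sigma ** 2))
    return out


def bandpass(dmap: DensityMap, low_res: float | None = None,
             high_res: float | None = None,
             soft_shells: float = 2.0) -> DensityMap:
    """Band-pass filter between resolutions ``low_res`` and ``high_res`` (Angstrom).

    Fourier amplitudes outside [1/low_res, 1/high_res] are attenuated with a
    Gaussian edge of width ``soft_shells`` Fourier shells.  ``None`` (or
    infinity) disables the corresponding cut.  The mean (DC) is removed
    whenever a finite low-resolution cut is given.
    """
    shape = dmap.grid.shape
    nyquist = 2.0 * dmap.voxel_size
    lo = None if (low_res is None or not np.isfinite(low_res)) else float(low_res)
    hi = None if (high_res is None or not np.isfinite(high_res)) else float(high_res)
    if lo is not None and hi is not None and hi >= lo:
        raise ValueError(f"need high_res < low_res, got {hi} >= {lo}")
    for cut in (lo, hi):
        if cut is not None and cut < nyquist:
            raise ValueError(
                f"cutoff {cut} A is beyond Nyquist ({nyquist} A)")
    filt = np.ones(shape, dtype=np.float32)
    s = freq_grid(shape, dmap.voxel_size)
    sigma = soft_shells / (shape[0] * dmap.voxel_size)
    if hi is not None:
        s_hi = 1.0 / hi
        sel = s > s_hi
        filt[sel] *= np.exp(-((s[sel] - s_hi) ** 2) / (2 * sigma ** 2))
    if lo is not None:
        s_lo = 1.0 / lo
        sel = s < s_lo
        filt[sel] *= np.exp(-((s[sel] - s_lo) ** 2) / (2 * sigma ** 2))
        filt[0, 0, 0] = 0.0  # remove mean
    out = np.fft.ifftn(np.fft.fftn(dmap.grid) * filt).real.astype(np.float32)
    return DensityMap(out, dmap.voxel_size, dmap.origin.copy())


# ---------------------------------------------------------------------------
# MRC2014 I/O (mode 2, float32)
# ---------------------------------------------------------------------------

_MRC_HEADER_BYTES = 1024


def write_mrc(dmap: DensityMap, path) -> None:
    """Write a volume as an MRC2014 file (MODE 2, 32-bit float).

    The array axis order (x, y, z) is stored with x as the fastest axis
    (MAPC/MAPR/MAPS = 1/2/3); cell dimensions encode the voxel size.
    """
    grid = np.ascontiguousarray(dmap.grid.T, dtype="<f4")  # file order z,y,x
    nx, ny, nz = dmap.grid.shape
    vx = dmap.voxel_size
    header = bytearray(_MRC_HEADER_BYTES)
    struct.pack_into("<3i", header, 0, nx, ny, nz)          # NX NY NZ
    struct.pack_into("<i", header, 12, 2)                    # MODE 2
    struct.pack_into("<3i", header, 16, 0, 0, 0)             # NXSTART..
    struct.pack_into("<3i", header, 28, nx, ny, nz)          # MX MY MZ
    struct.pack_into("<3f", header, 40, nx * vx, ny * vx, nz * vx)  # CELLA
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)    # CELLB
    struct.pack_into("<3i", header, 64, 1, 2, 3)             # MAPC MAPR MAPS
    struct.pack_into("<3f", header, 76, float(grid.min()), float(grid.max()),
                     float(grid.mean()))                     # DMIN DMAX DMEAN
    struct.pack_into("<i", header, 88, 1)                    # ISPG volume
    struct.pack_into("<i", header, 92, 0)                    # NSYMBT
    struct.pack_into("<3f", header, 196, *map(float, dmap.origin))  # ORIGIN
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])        # MACHST little-endian
    struct.pack_into("<f", header, 216, float(grid.std()))   # RMS
    struct.pack_into("<i", header, 220, 0)                   # NLABL
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(grid.tobytes())


def read_mrc(path) -> DensityMap:
    """Read an MRC2014 mode-2 volume written with the package conventions."""
    with open(path, "rb") as fh:
        header = fh.read(_MRC_HEADER_BYTES)
        if len(header) < _MRC_HEADER_BYTES:
            raise ValueError("malformed MRC file: truncated header")
        if header[208:212] != b"MAP ":
            raise ValueError("malformed MRC file: missing 'MAP ' magic (word 53)")
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        mode, = struct.unpack_from("<i", header, 12)
        if mode != 2:
            raise ValueError(f"unsupported MRC MODE {mode} (only mode 2 float32)")
        mx, = struct.unpack_from("<i", header, 28)
        cella_x, = struct.unpack_from("<f", header, 40)
        if mx <= 0 or cella_x <= 0:
            raise ValueError("malformed MRC file: non-positive MX or CELLA")
        origin = np.array(struct.unpack_from("<3f", header, 196), dtype=float)
        nsymbt, = struct.unpack_from("<i", header, 92)
        fh.seek(_MRC_HEADER_BYTES + nsymbt)
        data = np.frombuffer(fh.read(4 * nx * ny * nz), dtype="<f4")
        if data.size != nx * ny * nz:
            raise ValueError("malformed MRC file: truncated data block")
    grid = data.reshape(nz, ny, nx).T.copy()
    return DensityMap(grid, cella_x / mx, origin)
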