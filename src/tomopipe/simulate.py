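"""Synthetic ground-truth scenes and tilt series.

The simulator emulates the raw data of a rough-ER cryo-tomography experiment
at desk scale: membrane vesicles (100-300 nm) densely decorated with large
two-part particles -- a cytosolic "ribosome" body joined to a
membrane-embedded "translocon" foot -- plus compositional heterogeneity
(an OST-like lumenal sub-density present in roughly half the particles, a
tRNA-like sub-density present in a minority), 10-nm gold fiducials, and
single-axis tilt series with CTF, dose-dependent noise and stage jitter.

Particles are sums of Gaussian blobs rather than atomic scattering
potentials: blobs rotate rigidly with the particle pose, project
analytically, and keep every downstream recovery target exact.  Every random
draw flows from an explicit seed and all ground truth (poses, class labels,
shifts, defoci) is recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tomopipe.core import (DensityMap, RigidTransform, WedgeSpec,
                           make_wedge_mask, volume_center)

__all__ = [
    "Blob", "PhantomSpec", "Phantom", "CTFParams", "TiltSeries",
    "GroundTruthParticle", "GroundTruthScene",
    "build_phantom", "build_scene", "project_tilt_series",
    "make_subtomograms", "rotation_about_y",
    "save_tilt_series", "load_tilt_series",
]

GOLD_BEAD_RADIUS_A = 50.0       # 10 nm colloidal gold
DEFAULT_MEMBRANE_THICKNESS_A = 45.0


def rotation_about_y(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------

@dataclass
class Blob:
    """One Gaussian lobe of a phantom, in the particle frame (Angstrom)."""
    name: str
    center: np.ndarray
    sigma: float
    weight: float
    domain: str

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)


@dataclass
class PhantomSpec:
    """Geometry and heterogeneity of the two-part particle.

    The body (ribosome-like) occupies the +z half of the particle frame, the
    foot (translocon-like) sits at -z so that a membrane-bound particle with
    its frame -z axis along the inward membrane normal has its foot embedded
    in the membrane shell.  ``optional_subdensities`` are
    (name, offset_A, radius_A, occupancy) tuples; ``conformer_set`` maps a
    conformer name to {domain: RigidTransform} rigid offsets.
    """
    particle_diameter_A: float = 270.0
    body_blob_count: int = 6
    foot_blob_count: int = 3
    fine_blob_count: int = 18
    fine_blob_sigma_A: float = 10.0
    optional_subdensities: list = field(default_factory=lambda: [
        ("OST", np.array([70.0, 0.0, -125.0]), 40.0, 0.55),
        ("tRNA", np.array([0.0, 35.0, 40.0]), 30.0, 0.29),
    ])
    conformer_set: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.particle_diameter_A <= 0:
            raise ValueError("particle diameter must be positive")
        for name, _off, radius, occ in self.optional_subdensities:
            if not (0.0 <= occ <= 1.0):
                raise ValueError(f"occupancy of {name!r} outside [0, 1]")
            if radius <= 0:
                raise ValueError(f"radius of {name!r} must be positive")


@dataclass
class Phantom:
    """Rendered phantom variants plus their generating blob lists."""
    variants: dict            # name -> DensityMap
    blobs: dict               # name -> list[Blob]
    spec: PhantomSpec
    voxel_size: float

    def variant_names(self) -> list:
        return list(self.variants)


def _base_blobs(spec: PhantomSpec, rng: np.random.Generator) -> list:
    """Deterministic body+foot blob layout for a given seed.

    Large lobes set the low-resolution envelope; a set of small internal
    blobs gives the particle power in the 2-4 nm band, where a real
    ribosome-sized assembly carries most of the information that drives
    subtomogram alignment at this sampling.
    """
    d = spec.particle_diameter_A
    blobs = []
    # body: large lobes scattered in a sphere of radius d/4 centered at +z d/5
    body_center = np.array([0.0, 0.0, 0.30 * d / 2])
    for i in range(spec.body_blob_count):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        r = (0.55 * d / 2) * rng.uniform(0.2, 1.0) ** (1 / 3)
        blobs.append(Blob(f"body{i}", body_center + r * u,
                          sigma=0.16 * d / 2, weight=1.0, domain="body"))
    # foot: compact cluster at -z, embedded half a diameter below the body
    foot_center = np.array([0.0, 0.0, -0.72 * d / 2])
    for i in range(spec.foot_blob_count):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        r = (0.22 * d / 2) * rng.uniform(0.2, 1.0) ** (1 / 3)
        blobs.append(Blob(f"foot{i}", foot_center + r * u,
                          sigma=0.12 * d / 2, weight=0.8, domain="foot"))
    # fine internal structure, mostly in the body
    for i in range(spec.fine_blob_count):
        in_body = i % 4 != 3
        center = body_center if in_body else foot_center
        radius = (0.55 if in_body else 0.22) * d / 2
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        r = radius * rng.uniform(0.1, 1.0) ** (1 / 3)
        blobs.append(Blob(f"fine{i}", center + r * u,
                          sigma=spec.fine_blob_sigma_A, weight=0.7,
                          domain="body" if in_body else "foot"))
    return blobs


def build_phantom(spec: PhantomSpec, voxel_size: float, box: int,
                  seed: int) -> Phantom:
    """Render every conformer x sub-density-occupancy variant of the phantom.

    Variants are named ``<conformer>`` for the bare particle and
    ``<conformer>+<sub1>+<sub2>`` for particles carrying optional
    sub-densities; with an empty ``conformer_set`` the bare conformer is
    called ``base``.  Maps are deterministic given the seed.
    """
    if box % 2:
        raise ValueError("box must be even")
    rng = np.random.default_rng(seed)
    base = _base_blobs(spec, rng)
    half_box = box * voxel_size / 2
    for b in base:
        if np.any(np.abs(b.center) + 3 * b.sigma > half_box):
            raise ValueError(f"blob {b.name} exceeds the box")

    conformers = dict(spec.conformer_set) or {"base": {}}
    sub_names = [s[0] for s in spec.optional_subdensities]
    subsets = [[]]
    for name in sub_names:
        subsets = subsets + [s + [name] for s in subsets]

    variants, blob_lists = {}, {}
    for cname, domain_offsets in conformers.items():
        for subset in subsets:
            blobs = []
            for b in base:
                off = domain_offsets.get(b.domain)
                center = off.apply(b.center) if off is not None else b.center
                blobs.append(Blob(b.name, center, b.sigma, b.weight, b.domain))
            for name, off, radius, _occ in spec.optional_subdensities:
                if name in subset:
                    blobs.append(Blob(name, np.asarray(off, dtype=float),
                                      sigma=radius, weight=0.9, domain=name))
            vname = cname + "".join(f"+{s}" for s in subset)
            grid = np.zeros((box,) * 3, dtype=np.float32)
            _render_blobs(grid, voxel_size, blobs, RigidTransform.identity(),
                          volume_center((box,) * 3))
            variants[vname] = DensityMap(grid, voxel_size)
            blob_lists[vname] = blobs
    return Phantom(variants, blob_lists, spec, voxel_size)


def _render_blobs(grid: np.ndarray, voxel_size: float, blobs,
                  transform: RigidTransform, center_vox: np.ndarray) -> None:
    """Splat transformed Gaussian blobs into ``grid`` (in place)."""
    shape = np.array(grid.shape)
    for b in blobs:
        c_vox = (transform.apply(b.center)) / voxel_size + center_vox
        s_vox = b.sigma / voxel_size
        lo = np.maximum(np.floor(c_vox - 4 * s_vox).astype(int), 0)
        hi = np.minimum(np.ceil(c_vox + 4 * s_vox).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        ax = [np.arange(lo[i], hi[i]) - c_vox[i] for i in range(3)]
        r2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
              + ax[2][None, None, :] ** 2)
        grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += (
            b.weight * np.exp(-r2 / (2 * s_vox ** 2))).astype(np.float32)


# ---------------------------------------------------------------------------
# scene
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthParticle:
    position_A: np.ndarray          # relative to the volume center
    transform: RigidTransform       # particle frame -> scene frame
    variant: str                    # phantom variant rendered
    labels: dict                    # sub-density name -> bool
    membrane_bound: bool


@dataclass
class GroundTruthScene:
    volume: DensityMap
    particles: list
    vesicle_center_A: np.ndarray
    vesicle_radius_A: float
    membrane_thickness_A: float
    fiducials_A: list
    phantom: Phantom


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    return Rotation.random(rng=rng).as_matrix()


def _rotation_z_to(direction: np.ndarray, twist_deg: float) -> np.ndarray:
    """Rotation taking +z to ``direction`` with an in-plane twist about it."""
    from scipy.spatial.transform import Rotation
    d = direction / np.linalg.norm(direction)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, d)
    s = np.linalg.norm(v)
    if s < 1e-12:
        align = np.eye(3) if d[2] > 0 else Rotation.from_euler(
            "x", 180, degrees=True).as_matrix()
    else:
        angle = math.atan2(s, float(np.dot(z, d)))
        align = Rotation.from_rotvec(v / s * angle).as_matrix()
    twist = Rotation.from_rotvec(d * math.radians(twist_deg)).as_matrix()
    return twist @ align


def build_scene(spec: PhantomSpec, *, box: int = 192, voxel_size: float = 10.5,
                vesicle_radius_A: float = 650.0,
                membrane_thickness_A: float = DEFAULT_MEMBRANE_THICKNESS_A,
                n_particles: int = 20, bound_fraction: float = 0.8,
                false_positive_count: int = 10, orientation_jitter_deg: float = 8.0,
                render_membrane: bool = True,
                seed: int = 0, max_retries: int = 2000) -> GroundTruthScene:
    """Place particles on and around a vesicle and render the clean volume.

    Membrane-bound particles sit outside the vesicle with the particle -z
    axis along the inward normal (+/- jitter) so the foot is centered in the
    membrane shell; unbound particles take uniform random poses elsewhere.
    Gold fiducials are dense 10-nm spheres and double as the planted false
    positives for detection.  Class labels (which optional sub-densities a
    particle carries) are drawn per occupancy fraction.
    """
    rng = np.random.default_rng(seed)
    phantom = build_phantom(spec, voxel_size,
                            int(2 ** math.ceil(math.log2(
                                2.4 * spec.particle_diameter_A / voxel_size))),
                            seed)
    half = box * voxel_size / 2
    if vesicle_radius_A + spec.particle_diameter_A > half * 0.98:
        raise ValueError("vesicle plus particle margin does not fit the box")

    d = spec.particle_diameter_A
    foot_offset = 0.72 * d / 2          # particle center sits this far outside
    placed, particles = [], []
    n_bound = int(round(bound_fraction * n_particles))
    for i in range(n_particles):
        bound = i < n_bound
        ok = False
        for _ in range(max_retries):
            if bound:
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                pos = u * (vesicle_radius_A + foot_offset)
                rot = _rotation_z_to(u, rng.uniform(0, 360))
                if orientation_jitter_deg > 0:
                    from scipy.spatial.transform import Rotation
                    jit = Rotation.from_rotvec(
                        rng.normal(scale=math.radians(orientation_jitter_deg),
                                   size=3)).as_matrix()
                    rot = rot @ jit
            else:
                pos = rng.uniform(-half + d, half - d, size=3)
                if (render_membrane
                        and abs(np.linalg.norm(pos) - vesicle_radius_A)
                        < 0.5 * d):
                    continue   # keep unbound particles off the membrane
                rot = _random_rotation(rng)
            if np.all(np.abs(pos) < half - 0.7 * d) and all(
                    np.linalg.norm(pos - q) >= d for q in placed):
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place particle {i} without overlap")
        labels = {name: bool(rng.random() < occ)
                  for name, _o, _r, occ in spec.optional_subdensities}
        conformers = list(spec.conformer_set) or ["base"]
        cname = conformers[int(rng.integers(len(conformers)))]
        vname = cname + "".join(
            f"+{n}" for n, *_ in spec.optional_subdensities if labels[n])
        placed.append(pos)
        particles.append(GroundTruthParticle(pos, RigidTransform(rot, pos),
                                             vname, labels, bound))

    fiducials = []
    for _ in range(false_positive_count):
        for _ in range(max_retries):
            pos = rng.uniform(-half + 2 * GOLD_BEAD_RADIUS_A,
                              half - 2 * GOLD_BEAD_RADIUS_A, size=3)
            if (abs(np.linalg.norm(pos) - vesicle_radius_A) > 2 * GOLD_BEAD_RADIUS_A
                    and all(np.linalg.norm(pos - q) >= d for q in placed)):
                fiducials.append(pos)
                placed.append(pos)
                break
        else:
            raise RuntimeError("could not place fiducial")

    grid = np.zeros((box,) * 3, dtype=np.float32)
    center = volume_center(grid.shape)
    if render_membrane:
        ax = (np.arange(box) - center[0]) * voxel_size
        r = np.sqrt(ax[:, None, None] ** 2 + ax[None, :, None] ** 2
                    + ax[None, None, :] ** 2)
        grid += 0.5 * np.exp(-((r - vesicle_radius_A) ** 2)
                             / (2 * (membrane_thickness_A / 2.355) ** 2))
    for p in particles:
        _render_blobs(grid, voxel_size, phantom.blobs[p.variant],
                      p.transform, center)
    bead_sigma = GOLD_BEAD_RADIUS_A / 1.5
    for pos in fiducials:
        _render_blobs(grid, voxel_size,
                      [Blob("gold", np.zeros(3), bead_sigma, 4.0, "gold")],
                      RigidTransform(np.eye(3), np.asarray(pos)), center)
    return GroundTruthScene(DensityMap(grid, voxel_size), particles,
                            np.zeros(3), vesicle_radius_A,
                            membrane_thickness_A, fiducials, phantom)


# ---------------------------------------------------------------------------
# CTF and tilt-series projection
# ---------------------------------------------------------------------------

@dataclass
class CTFParams:
    """Contrast transfer function parameters (underfocus positive)."""
    voltage_kV: float = 300.0
    cs_mm: float = 2.7
    amplitude_contrast: float = 0.07
    defocus_um: float = 3.5

    def __post_init__(self) -> None:
        if self.defocus_um <= 0:
            raise ValueError("defocus must be positive (underfocus convention)")
        if not (0.0 <= self.amplitude_contrast < 1.0):
            raise ValueError("amplitude contrast must be in [0, 1)")

    @property
    def wavelength_A(self) -> float:
        v = self.voltage_kV * 1e3
        return 12.2639 / math.sqrt(v + 0.97845e-6 * v * v)

    def ctf(self, s: np.ndarray, defocus_um: float | None = None) -> np.ndarray:
        """Signed CTF at spatial frequency ``s`` (1/Angstrom)."""
        dz = (self.defocus_um if defocus_um is None else defocus_um) * 1e4
        lam = self.wavelength_A
        chi = (math.pi * lam * dz * s ** 2
               - 0.5 * math.pi * (self.cs_mm * 1e7) * lam ** 3 * s ** 4)
        a = self.amplitude_contrast
        # sign convention: positive at low frequency, so simulated images
        # keep the specimen's contrast until the first zero crossing
        return math.sqrt(1 - a * a) * np.sin(chi) + a * np.cos(chi)

    def ctf_2d(self, shape, pixel_size: float,
               defocus_um: float | None = None) -> np.ndarray:
        fx = np.fft.fftfreq(shape[0], d=pixel_size)[:, None]
        fy = np.fft.fftfreq(shape[1], d=pixel_size)[None, :]
        return self.ctf(np.sqrt(fx * fx + fy * fy), defocus_um)


@dataclass
class TiltSeries:
    """Ordered single-axis tilt projections with per-image metadata."""
    images: np.ndarray            # (n, nx, ny), beam along z, tilt axis y
    tilt_deg: np.ndarray
    pixel_size: float
    defocus_um: np.ndarray | None = None
    dose: np.ndarray | None = None
    true_shift_px: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        self.tilt_deg = np.asarray(self.tilt_deg, dtype=float)
        if self.images.ndim != 3 or len(self.tilt_deg) != len(self.images):
            raise ValueError("images must be (n, nx, ny) matching tilt_deg")
        if np.any(np.diff(np.sort(self.tilt_deg)) <= 0):
            raise ValueError("tilt angles must be unique")

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, lo: float, hi: float) -> "TiltSeries":
        sel = (self.tilt_deg >= lo) & (self.tilt_deg <= hi)
        if not np.any(sel):
            raise ValueError(f"tilt subset [{lo}, {hi}] selects no images")
        pick = lambda a: None if a is None else a[sel]
        return TiltSeries(self.images[sel], self.tilt_deg[sel], self.pixel_size,
                          pick(self.defocus_um), pick(self.dose),
                          pick(self.true_shift_px))

    @property
    def wedge(self) -> WedgeSpec:
        return WedgeSpec(float(self.tilt_deg.min()), float(self.tilt_deg.max()))


def _fourier_shift_2d(image: np.ndarray, shift) -> np.ndarray:
    fx = np.fft.fftfreq(image.shape[0])[:, None]
    fy = np.fft.fftfreq(image.shape[1])[None, :]
    ramp = np.exp(-2j * np.pi * (fx * shift[0] + fy * shift[1]))
    return np.fft.ifft2(np.fft.fft2(image) * ramp).real.astype(np.float32)


def project_volume(volume: DensityMap, tilt_deg: float,
                   order: int = 3) -> np.ndarray:
    """Parallel-beam projection along z of the volume tilted about y.

    Image coordinate u = x cos(theta) - z sin(theta), v = y; the beam
    direction in the specimen frame is d(theta) = (sin(theta), 0, cos(theta)).
    Cubic-spline resampling keeps the central-slice identity accurate.
    """
    from scipy import ndimage
    grid = volume.grid
    if tilt_deg == 0.0:
        return grid.sum(axis=2).astype(np.float32)
    rot = ndimage.rotate(grid, tilt_deg, axes=(0, 2), reshape=False,
                         order=order, mode="constant", cval=0.0)
    return rot.sum(axis=2).astype(np.float32)


def project_tilt_series(volume: DensityMap, tilt_deg, *,
                        ctf: CTFParams | None = None,
                        defocus_um=None,
                        dose_per_image: float = 1.5,
                        noise_sigma: float = 0.0,
                        shift_jitter_px: float = 0.0,
                        seed: int = 0) -> TiltSeries:
    """Simulate a single-axis tilt series of the scene volume.

    Each projection is the line integral along the beam after tilting the
    specimen about y, multiplied in Fourier space by the signed CTF for its
    defocus, shifted by a recorded random in-plane jitter, and corrupted by
    additive white Gaussian noise whose variance scales inversely with
    ``dose_per_image`` (``sigma = noise_sigma / sqrt(dose)``).
    """
    tilt_deg = np.asarray(tilt_deg, dtype=float)
    if tilt_deg.size == 0:
        raise ValueError("empty tilt-angle list")
    if np.any(np.abs(tilt_deg) >= 90):
        raise ValueError("tilt angles must lie in (-90, 90)")
    if len(np.unique(tilt_deg)) != tilt_deg.size:
        raise ValueError("tilt angles must be unique")
    rng = np.random.default_rng(seed)
    n = tilt_deg.size
    if defocus_um is None:
        defocus_um = np.full(n, ctf.defocus_um if ctf else 3.5)
    defocus_um = np.broadcast_to(np.asarray(defocus_um, float), (n,)).copy()
    shifts = (rng.uniform(-shift_jitter_px, shift_jitter_px, size=(n, 2))
              if shift_jitter_px > 0 else np.zeros((n, 2)))
    sigma = (noise_sigma / math.sqrt(dose_per_image)
             if (noise_sigma > 0 and dose_per_image > 0) else 0.0)

    images = np.empty((n, volume.grid.shape[0], volume.grid.shape[1]),
                      dtype=np.float32)
    for i, theta in enumerate(tilt_deg):
        img = project_volume(volume, float(theta))
        if ctf is not None:
            img = np.fft.ifft2(np.fft.fft2(img) * ctf.ctf_2d(
                img.shape, volume.voxel_size, defocus_um[i])).real
        if np.any(shifts[i]):
            img = _fourier_shift_2d(img, shifts[i])
        if sigma > 0:
            img = img + rng.normal(scale=sigma, size=img.shape)
        images[i] = img
    return TiltSeries(images, tilt_deg, volume.voxel_size, defocus_um,
                      np.full(n, float(dose_per_image)), shifts)


# ---------------------------------------------------------------------------
# direct subtomogram synthesis (desk-scale shortcut around full scenes)
# ---------------------------------------------------------------------------

def make_subtomograms(phantom: Phantom, variants, poses, wedge: WedgeSpec,
                      snr: float, box: int, seed: int = 0) -> np.ndarray:
    """Wedge-filtered noisy subtomograms of given variants at given poses.

    For each particle, the phantom variant is rendered at its pose, white
    Gaussian noise is added at the requested SNR (signal variance within the
    particle region / noise variance, matching the reconstruction-scale
    statistics of subtomograms extracted from a tomogram), and both signal
    and noise are limited to the wedge's Fourier support -- exactly the
    support a reduced-tilt-range per-particle reconstruction would have.
    Returns an array of shape (n, box, box, box).
    """
    rng = np.random.default_rng(seed)
    wmask = make_wedge_mask((box,) * 3, wedge)
    center = volume_center((box,) * 3)
    vs = phantom.voxel_size
    out = np.empty((len(poses), box, box, box), dtype=np.float32)
    for i, (vname, pose) in enumerate(zip(variants, poses)):
        grid = np.zeros((box,) * 3, dtype=np.float32)
        _render_blobs(grid, vs, phantom.blobs[vname], pose, center)
        grid -= grid.mean()
        sig_var = float(grid[np.abs(grid) > 0.05 * np.abs(grid).max()].var()) \
            if np.any(grid) else 1.0
        if snr > 0 and np.isfinite(snr):
            grid = grid + rng.normal(scale=math.sqrt(sig_var / snr),
                                     size=grid.shape).astype(np.float32)
        out[i] = np.fft.ifftn(np.fft.fftn(grid) * wmask).real
    return out


# ---------------------------------------------------------------------------
# persistence: MRC stack + TSV sidecar
# ---------------------------------------------------------------------------

def save_tilt_series(ts: TiltSeries, mrc_path, tsv_path) -> None:
    """Persist images as an MRC stack and metadata as a TSV sidecar."""
    from tomopipe import core
    stack = DensityMap(np.ascontiguousarray(np.moveaxis(ts.images, 0, 2)),
                       ts.pixel_size)
    core.write_mrc(stack, mrc_path)
    n = len(ts)
    df = pd.DataFrame({
        "image_index": np.arange(n),
        "tilt_deg": ts.tilt_deg,
        "defocus_um": ts.defocus_um if ts.defocus_um is not None else np.nan,
        "dose_e_per_A2": ts.dose if ts.dose is not None else np.nan,
        "true_shift_x": (ts.true_shift_px[:, 0]
                         if ts.true_shift_px is not None else 0.0),
        "true_shift_y": (ts.true_shift_px[:, 1]
                         if ts.true_shift_px is not None else 0.0),
    })
    df.to_csv(tsv_path, sep="\t", index=False)


def load_tilt_series(mrc_path, tsv_path) -> TiltSeries:
    from tomopipe import core
    stack = core.read_mrc(mrc_path)
    images = np.moveaxis(stack.grid, 2, 0)
    df = pd.read_csv(tsv_path, sep="\t")
    return TiltSeries(images, df["tilt_deg"].to_numpy(), stack.voxel_size,
                      df["defocus_um"].to_numpy(), df["dose_e_per_A2"].to_numpy(),
                      df[["true_shift_x", "true_shift_y"]].to_numpy())
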