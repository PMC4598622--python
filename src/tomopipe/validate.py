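"""Resolution estimation and map post-processing.

Fourier shell correlation (FSC) between half-maps or against an external
reference, resolution read-out at a threshold (0.5 for conventional
half-set averages, 0.143 for gold-standard independent halves, 0.33 for
cross-resolution against an external map), windowed local-resolution
mapping, and B-factor sharpening.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from tomopipe.core import DensityMap, SoftMask, lowpass_mask

__all__ = [
    "FSCCurve", "fsc_curve", "resolution_at_threshold", "local_resolution",
    "sharpen",
]

FSC_CONVENTIONAL = 0.5
FSC_GOLD_STANDARD = 0.143
FSC_CROSS = 0.33


@dataclass
class FSCCurve:
    """Per-shell correlation between two maps.

    ``freq`` holds shell-center spatial frequencies in 1/Angstrom (strictly
    increasing, shell width one Fourier voxel), ``fsc`` the real correlation
    per shell in [-1, 1], ``counts`` the number of Fourier voxels per shell.
    """
    freq: np.ndarray
    fsc: np.ndarray
    counts: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        if len(self.freq) == 0:
            raise ValueError("empty FSC curve")
        if np.any(np.diff(self.freq) <= 0):
            raise ValueError("shell frequencies must increase")

    def to_table(self):
        import pandas as pd
        return pd.DataFrame({"freq_inv_A": self.freq, "fsc": self.fsc})


def _shell_index(shape) -> tuple:
    n = shape[0]
    k = [np.fft.fftfreq(s) * s for s in shape]
    r = np.sqrt(k[0][:, None, None] ** 2 + k[1][None, :, None] ** 2
                + k[2][None, None, :] ** 2)
    shells = np.rint(r).astype(int)
    n_shells = n // 2 + 1
    shells[shells >= n_shells] = n_shells - 1   # corner voxels -> last shell
    return shells, n_shells


def fsc_curve(map_a: DensityMap, map_b: DensityMap,
              mask: SoftMask | None = None) -> FSCCurve:
    """Fourier shell correlation between two same-grid maps.

    Both maps are (optionally) soft-masked in real space; per concentric
    shell of width one Fourier voxel the correlation is
    ``Re(sum F_a conj(F_b)) / sqrt(sum |F_a|^2 sum |F_b|^2)``.
    """
    if map_a.grid.shape != map_b.grid.shape:
        raise ValueError(f"shape mismatch {map_a.grid.shape} vs "
                         f"{map_b.grid.shape}")
    a = map_a.grid.astype(np.float64)
    b = map_b.grid.astype(np.float64)
    if mask is not None:
        a, b = mask.apply(a), mask.apply(b)
    fa, fb = np.fft.fftn(a), np.fft.fftn(b)
    shells, n_shells = _shell_index(a.shape)
    cross = np.bincount(shells.ravel(),
                        weights=(fa * np.conj(fb)).real.ravel(),
                        minlength=n_shells)
    pa = np.bincount(shells.ravel(), weights=np.abs(fa).ravel() ** 2,
                     minlength=n_shells)
    pb = np.bincount(shells.ravel(), weights=np.abs(fb).ravel() ** 2,
                     minlength=n_shells)
    counts = np.bincount(shells.ravel(), minlength=n_shells)
    denom = np.sqrt(pa * pb)
    fsc = np.where(denom > 0, cross / np.maximum(denom, 1e-30), 0.0)
    # shells 1..n/2 (skip the DC-only shell 0, whose value is ~1 trivially)
    n = a.shape[0]
    freq = np.arange(1, n // 2 + 1) / (n * map_a.voxel_size)
    return FSCCurve(freq, np.clip(fsc[1:], -1.0, 1.0), counts[1:],
                    map_a.voxel_size)


def resolution_at_threshold(curve: FSCCurve, threshold: float):
    """Resolution (Angstrom) where the curve first drops below the threshold.

    Linear interpolation between the bracketing shells; if the curve never
    crosses, the Nyquist-limit resolution is returned with the bound flag
    set.  Returns ``(resolution_A, at_nyquist_bound)``.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    fsc, freq = curve.fsc, curve.freq
    below = np.nonzero(fsc < threshold)[0]
    if len(below) == 0:
        return 2.0 * curve.voxel_size, True
    i = below[0]
    if i == 0:
        return 1.0 / freq[0], False
    f0, f1 = freq[i - 1], freq[i]
    v0, v1 = fsc[i - 1], fsc[i]
    f_cross = f0 + (threshold - v0) / (v1 - v0) * (f1 - f0)
    return float(1.0 / f_cross), False


def local_resolution(map_a: DensityMap, map_b: DensityMap, box_vox: int = 20,
                     stride: int | None = None,
                     threshold: float = FSC_CONVENTIONAL) -> DensityMap:
    """Windowed-FSC local resolution map between two half-maps.

    A cubic window (default 20^3 voxels) slides on a stride grid; each
    window is apodized with a raised cosine over its outer 20%, the
    windowed FSC is evaluated and the resolution at ``threshold`` assigned
    to the window center; voxels between grid nodes take the nearest node's
    value.
    """
    if box_vox < 8:
        raise ValueError("box must be >= 8 voxels for reliable shells")
    shape = map_a.grid.shape
    if any(box_vox > s for s in shape):
        raise ValueError("box larger than the map")
    if map_a.grid.shape != map_b.grid.shape:
        raise ValueError("shape mismatch")
    if box_vox % 2:
        box_vox += 1          # even box keeps Fourier centering unambiguous
    stride = stride or max(1, box_vox // 2)
    # separable raised-cosine apodization over the outer 20 % of the box
    edge = max(1, int(round(0.2 * box_vox)))
    w1 = np.ones(box_vox)
    ramp = 0.5 * (1 - np.cos(np.pi * (np.arange(edge) + 0.5) / edge))
    w1[:edge] = ramp
    w1[-edge:] = ramp[::-1]
    w3 = w1[:, None, None] * w1[None, :, None] * w1[None, None, :]

    nodes = [np.arange(box_vox // 2, s - box_vox // 2 + 1, stride)
             for s in shape]
    res_nodes = np.empty([len(a) for a in nodes], dtype=np.float32)
    for i, x in enumerate(nodes[0]):
        for j, y in enumerate(nodes[1]):
            for k, z in enumerate(nodes[2]):
                sl = tuple(slice(c - box_vox // 2, c + box_vox // 2)
                           for c in (x, y, z))
                wa = DensityMap(map_a.grid[sl] * w3, map_a.voxel_size)
                wb = DensityMap(map_b.grid[sl] * w3, map_b.voxel_size)
                curve = fsc_curve(wa, wb)
                res, _bound = resolution_at_threshold(curve, threshold)
                res_nodes[i, j, k] = res
    # nearest-node fill
    out = np.empty(shape, dtype=np.float32)
    idx = [np.clip(np.rint((np.arange(s) - nodes[a][0]) / stride).astype(int),
                   0, len(nodes[a]) - 1) for a, s in enumerate(shape)]
    out[:] = res_nodes[np.ix_(idx[0], idx[1], idx[2])]
    return DensityMap(out, map_a.voxel_size)


def sharpen(dmap: DensityMap, b_factor: float,
            resolution_cutoff: float) -> DensityMap:
    """B-factor sharpening with a soft low-pass at the resolution cutoff.

    Fourier amplitudes are multiplied by ``exp(-B s^2 / 4)`` with ``s`` in
    1/Angstrom (the Rosenthal-Henderson convention: negative B amplifies
    high frequencies), then limited to ``resolution_cutoff`` with a soft
    Gaussian edge.
    """
    if resolution_cutoff < 2.0 * dmap.voxel_size:
        raise ValueError("cutoff beyond Nyquist")
    from tomopipe.core import freq_grid
    s = freq_grid(dmap.grid.shape, dmap.voxel_size)
    gain = np.exp(-b_factor * s * s / 4.0)
    lp = lowpass_mask(dmap.grid.shape, dmap.voxel_size, resolution_cutoff)
    out = np.fft.ifftn(np.fft.fftn(dmap.grid) * gain * lp).real
    return DensityMap(out.astype(np.float32), dmap.voxel_size,
                      dmap.origin.copy())
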