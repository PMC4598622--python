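"""Constrained-PCA classification of subtomograms.

Subtomograms are aligned, wedge-compensated (unmeasured Fourier voxels
filled from the current average so missing-wedge orientation cannot leak
into the features), band-limited, and restricted to a focus mask; principal
components of the masked voxels feed k-means clustering.  Focused masks
select the classification target of each round: membrane/large-subunit
region for separating membrane-bound particles from false positives,
the translocon foot for compositional (OST) heterogeneity, and the tRNA
sites for translational-state classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from tomopipe.core import (DensityMap, SoftMask, lowpass_mask,
                           make_wedge_mask, rotate_fourier_mask,
                           rotate_volume)
from tomopipe.average import average_subtomograms
from tomopipe.validate import FSC_CONVENTIONAL, fsc_curve, resolution_at_threshold

__all__ = ["ClassResult", "cpca_features", "kmeans_classify", "class_averages"]


@dataclass
class ClassResult:
    """Outcome of one classification round."""
    labels: np.ndarray
    sizes: np.ndarray
    fractions: np.ndarray
    class_maps: dict          # label -> DensityMap (absent for empty classes)
    resolutions_A: dict       # label -> FSC=0.5 random-half resolution
    features: np.ndarray | None = None
    explained_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")

    def summary_table(self):
        import pandas as pd
        return pd.DataFrame({
            "class": np.arange(len(self.sizes)),
            "n": self.sizes,
            "percent": 100.0 * self.fractions,
            "resolution_A": [self.resolutions_A.get(i, np.nan)
                             for i in range(len(self.sizes))],
        })


def cpca_features(records, subtomos, voxel_size: float,
                  current_average: DensityMap, focus_mask: SoftMask,
                  band_lowpass_A: float | None = None,
                  n_components: int = 10):
    """Wedge-compensated, mask-focused principal-component features.

    Each subtomogram is rotated to the reference frame by the inverse of
    its pose; Fourier voxels outside its (equally rotated) wedge support
    are replaced by the current average's values; the volume is band
    limited, and the voxels under the focus mask are extracted, centered,
    scale-normalized and decomposed by PCA.

    Returns ``(features (n, n_components), explained_variance)``; the
    variance spectrum is non-negative and non-increasing.
    """
    n = len(records)
    if n_components >= n:
        raise ValueError("n_components must be smaller than the particle count")
    sel = focus_mask.grid > 0.1
    if not sel.any():
        raise ValueError("empty focus mask")
    shape = focus_mask.grid.shape
    avg_f = np.fft.fftn(current_average.grid)
    band = (lowpass_mask(shape, voxel_size, band_lowpass_A)
            if band_lowpass_A is not None else None)
    wedge_cache = {}
    vectors = np.empty((n, int(sel.sum())), dtype=np.float64)
    weights = focus_mask.grid[sel]
    for row, rec in enumerate(records):
        key = (rec.wedge.tilt_min, rec.wedge.tilt_max)
        if key not in wedge_cache:
            wedge_cache[key] = make_wedge_mask(shape, rec.wedge)
        inv = rec.pose.inverse()
        moved = rotate_volume(DensityMap(np.asarray(subtomos[rec.index],
                                                    dtype=np.float32),
                                         voxel_size), inv, cval=0.0).grid
        w_rot = rotate_fourier_mask(wedge_cache[key], inv.rotation) > 0.5
        f = np.fft.fftn(moved)
        f[~w_rot] = avg_f[~w_rot]
        if band is not None:
            f = f * band
        vol = np.fft.ifftn(f).real
        vectors[row] = vol[sel] * weights
    vectors -= vectors.mean(axis=0, keepdims=True)
    scale = np.sqrt((vectors ** 2).sum() / n)
    if scale > 0:
        vectors /= scale          # global-intensity invariance
    from sklearn.decomposition import PCA
    pca = PCA(n_components=n_components, svd_solver="auto", random_state=0)
    feats = pca.fit_transform(vectors)
    return feats, pca.explained_variance_


def kmeans_classify(features: np.ndarray, k: int, n_restarts: int = 10,
                    seed: int = 0) -> np.ndarray:
    """K-means labels on feature vectors, best of ``n_restarts`` by WCSS.

    Deterministic given the seed; output labels are renumbered by
    descending class size (label 0 = largest class).
    """
    features = np.asarray(features, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(features):
        raise ValueError("k exceeds the particle count")
    if np.allclose(features, features[0], atol=1e-12):
        warnings.warn("degenerate features: all particles identical; "
                      "returning a single cluster")
        return np.zeros(len(features), dtype=int)
    from sklearn.cluster import KMeans
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(features)
    order = np.argsort(-np.bincount(raw, minlength=k), kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[raw]


def class_averages(records, subtomos, voxel_size: float, labels,
                   compute_resolution: bool = True, seed: int = 0,
                   features: np.ndarray | None = None,
                   explained_variance: np.ndarray | None = None) -> ClassResult:
    """Wedge-compensated average, size, fraction and resolution per class."""
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(records):
        raise ValueError("labels must cover all particles")
    k = labels.max() + 1
    sizes = np.bincount(labels, minlength=k)
    fractions = sizes / sizes.sum()
    rng = np.random.default_rng(seed)
    maps, resolutions = {}, {}
    for c in range(k):
        members = [r for r, l in zip(records, labels) if l == c]
        if not members:
            continue           # empty class: size 0, no map
        maps[c] = average_subtomograms(members, subtomos, voxel_size)
        if compute_resolution and len(members) >= 4:
            split = rng.permutation(len(members)) % 2
            ha = average_subtomograms(
                [m for m, s in zip(members, split) if s == 0], subtomos,
                voxel_size)
            hb = average_subtomograms(
                [m for m, s in zip(members, split) if s == 1], subtomos,
                voxel_size)
            res, _ = resolution_at_threshold(fsc_curve(ha, hb),
                                             FSC_CONVENTIONAL)
            resolutions[c] = res
    return ClassResult(labels, sizes, fractions, maps, resolutions,
                       features, explained_variance)
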