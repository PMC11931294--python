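"""Region-of-interest definition: SD-threshold activation maps, PCA vessel masks,
and manual mask ingestion.

The activated whisker-barrel region is the set of pixels whose stimulus-evoked
response exceeds mean + k·SD of the spatial map (k = 1.5 by default), reduced
to its largest connected component. Vessel ROIs are derived from a principal
component analysis of the pixel time series: pixels loading strongly on a
hemodynamic component mark the vessel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

__all__ = ["RoiMask", "ActivationMap", "activation_mask", "pca_vessel_mask", "load_manual_mask"]

VALID_LABELS = (
    "whisker_region",
    "artery",
    "whisker_vein",
    "parenchyma",
    "draining_vein",
    "meningeal",
)
VALID_ORIGINS = ("threshold", "pca", "manual")


@dataclass
class RoiMask:
    """A labeled boolean raster for one vascular compartment."""

    mask: np.ndarray
    label: str
    origin: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be a 2-D raster")
        if not self.mask.any():
            raise ValueError("empty ROI mask")
        if self.label not in VALID_LABELS:
            raise ValueError(f"unknown compartment label {self.label!r}")
        if self.origin not in VALID_ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class ActivationMap:
    """Mean stimulus response per pixel (μM) with an SD-multiplier threshold."""

    values: np.ndarray
    threshold: float = 1.5

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("activation map must be 2-D")
        if self.threshold <= 0:
            raise ValueError("threshold multiplier must be positive")


def activation_mask(amap: ActivationMap) -> RoiMask:
    """Whisker-region ROI: pixels above mean + k·SD, largest connected component.

    The mean and SD are computed over all pixels of the map (population SD).
    A constant map has no activation contrast and is rejected.
    """
    values = amap.values
    mu = values.mean()
    sd = values.std()
    if sd == 0:
        raise ValueError("no activation contrast: spatial map is constant")
    raw = values > mu + amap.threshold * sd
    if not raw.any():
        raise ValueError("no pixel exceeds the activation threshold")
    labeled = measure.label(raw)
    sizes = np.bincount(labeled.ravel())
    sizes[0] = 0  # background
    keep = int(np.argmax(sizes))
    return RoiMask(mask=labeled == keep, label="whisker_region", origin="threshold")


def pca_vessel_mask(
    movie: np.ndarray,
    label: str,
    n_components: int = 5,
    component_index: "int | None" = None,
    loading_quantile: float = 0.95,
    locomotion: "np.ndarray | None" = None,
) -> RoiMask:
    """Vessel ROI from the principal components of the pixel time series.

    ``movie`` is (frames, rows, cols). Pixel time series are mean-centered and
    decomposed by SVD; the chosen component's per-pixel loading map is
    thresholded at the ``loading_quantile`` quantile of |loading|. The
    component's sign is flipped so its peak temporal score is positive.

    Component choice: explicit ``component_index`` if given; otherwise, when a
    concurrent ``locomotion`` trace (resampled to the frame grid) is supplied,
    the component whose temporal score correlates best with it; else the first.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3 or movie.shape[0] < 2:
        raise ValueError("movie must be (frames, rows, cols) with >= 2 frames")
    nf, h, w = movie.shape
    x = movie.reshape(nf, -1).T  # pixels × time
    x = x - x.mean(axis=1, keepdims=True)
    if not np.any(x):
        raise ValueError("constant movie: no temporal structure to decompose")
    n_components = min(n_components, min(x.shape))
    if component_index is not None and component_index >= n_components:
        raise ValueError("component_index must be < n_components")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    # sign convention: peak temporal score positive
    for k in range(n_components):
        if np.abs(vt[k].min()) > vt[k].max():
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]
    if component_index is None:
        if locomotion is not None:
            loco = np.asarray(locomotion, dtype=float)
            if loco.size != nf:
                raise ValueError("locomotion trace must match the frame count")
            lc = loco - loco.mean()
            if not np.any(lc):
                raise ValueError("constant locomotion trace cannot select a component")
            corr = np.abs(vt @ lc) / (np.linalg.norm(vt, axis=1) * np.linalg.norm(lc))
            component_index = int(np.argmax(corr))
        else:
            component_index = 0
    loading = (u[:, component_index] * s[component_index]).reshape(h, w)
    thr = np.quantile(np.abs(loading), loading_quantile)
    # >= keeps tied suprathreshold loadings (exact low-rank movies); a zero
    # threshold falls back to strict positivity so flat pixels stay excluded
    mask = np.abs(loading) >= thr if thr > 0 else np.abs(loading) > 0
    return RoiMask(mask=mask, label=label, origin="pca")


def load_manual_mask(raster: np.ndarray, label: str, expect_shape: "tuple | None" = None) -> RoiMask:
    """Wrap a manually drawn boolean raster (e.g. decoded from a 0/255 PNG).

    Rejects empty masks and, if ``expect_shape`` is given, shape mismatches
    against the source stack.
    """
    raster = np.asarray(raster)
    mask = raster.astype(bool)
    if expect_shape is not None and mask.shape != tuple(expect_shape):
        raise ValueError(f"mask shape {mask.shape} does not match stack shape {tuple(expect_shape)}")
    return RoiMask(mask=mask, label=label, origin="manual")
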