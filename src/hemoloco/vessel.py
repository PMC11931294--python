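"""Vessel caliber from single-wavelength images: line-profile FWHM and dark-pixel counts.

A surface vessel appears darker than the surrounding tissue at green
illumination. Its apparent diameter is estimated from an intensity profile
sampled along a line perpendicular to the vessel: the profile is inverted into
a dip height above a background level, and the full width at half maximum of
the dip — with sub-pixel crossings by linear interpolation — is the diameter
estimate. A cruder dark-pixel count below a threshold tracks the same
quantity. Changes are reported as percent of the baseline width; negative
means constriction. At widefield resolution this is an index of caliber
change, not a micrometer-accurate diameter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "VesselProfile",
    "post_onset_mean_image",
    "extract_profile",
    "fwhm_width",
    "dark_pixel_count",
    "percent_change",
]


@dataclass
class VesselProfile:
    """Intensity samples along a perpendicular line across a vessel.

    The vessel is assumed darker than the background (fixed polarity).
    """

    positions: np.ndarray  # pixel index along the line
    intensities: np.ndarray  # a.u.

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.shape != self.intensities.shape or self.positions.ndim != 1:
            raise ValueError("positions and intensities must be matching 1-D arrays")
        if self.positions.size < 8:
            raise ValueError("profile needs at least 8 samples")


def post_onset_mean_image(movie: np.ndarray, onsets, rate: float, window_s: float = 2.0) -> np.ndarray:
    """Pixelwise mean image over [0, window_s) s after each onset, across onsets."""
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3:
        raise ValueError("movie must be (frames, rows, cols)")
    w = int(round(window_s * rate))
    maps = []
    for o in onsets:
        o = int(o)
        if o < 0 or o + w > movie.shape[0]:
            logger.warning("post_onset_mean_image: dropped onset %d (incomplete window)", o)
            continue
        maps.append(movie[o : o + w].mean(axis=0))
    if not maps:
        raise ValueError("no onset admits the requested window")
    return np.mean(maps, axis=0)


def extract_profile(image: np.ndarray, start: tuple[float, float], end: tuple[float, float],
                    n_samples: "int | None" = None) -> VesselProfile:
    """Sample an intensity profile along a line between two (row, col) endpoints."""
    image = np.asarray(image, dtype=float)
    r0, c0 = start
    r1, c1 = end
    for r, c in (start, end):
        if not (0 <= r <= image.shape[0] - 1 and 0 <= c <= image.shape[1] - 1):
            raise ValueError("line endpoints must lie inside the raster")
    if n_samples is None:
        n_samples = int(np.hypot(r1 - r0, c1 - c0)) + 1
    rows = np.linspace(r0, r1, n_samples)
    cols = np.linspace(c0, c1, n_samples)
    vals = ndimage.map_coordinates(image, [rows, cols], order=1)
    return VesselProfile(positions=np.arange(n_samples, dtype=float), intensities=vals)


def _dip_height(profile: VesselProfile, smooth_sigma_px: float = 0.0) -> tuple[np.ndarray, float]:
    intens = profile.intensities
    if smooth_sigma_px > 0:
        intens = ndimage.gaussian_filter1d(intens, smooth_sigma_px)
    n = intens.size
    k = max(n // 8, 1)  # outer 25% of samples: k from each end
    background = float(np.median(np.concatenate([intens[:k], intens[-k:]])))
    return background - intens, background


def fwhm_width(profile: VesselProfile, smooth_sigma_px: float = 0.0) -> float:
    """Full width at half maximum of the vessel's intensity dip, in pixels.

    The background is the median of the outer 25% of samples; the dip height
    is background − intensity; the width is the distance between the two
    half-maximum crossings flanking the dip minimum, each located by linear
    interpolation between bracketing samples. Raises when the profile has no
    resolvable dip (no crossing on one side). Invariant under affine intensity
    transforms a·I + b with a > 0.
    """
    h, _ = _dip_height(profile, smooth_sigma_px)
    x = profile.positions
    imax = int(np.argmax(h))
    half = h[imax] / 2.0
    if h[imax] <= 0 or half <= 0:
        raise ValueError("vessel not resolved: profile has no dip")

    def cross(indices) -> float:
        for i in indices:  # bracketing pair (i, i+1), nearest to the dip first
            lo, hi = h[i], h[i + 1]
            if (lo - half) * (hi - half) <= 0:
                if hi == lo:
                    if lo != half:
                        continue
                    return float(x[i])
                return float(x[i] + (half - lo) / (hi - lo) * (x[i + 1] - x[i]))
        raise ValueError("vessel not resolved: no half-maximum crossing on one side")

    left = cross(range(imax - 1, -1, -1))
    right = cross(range(imax, len(h) - 1))
    return right - left


def dark_pixel_count(profile_or_line, threshold: float) -> int:
    """Number of samples darker than ``threshold`` along the line.

    The threshold should sit between the background level and the dip minimum;
    on a flat profile no valid threshold exists and the count (typically 0) is
    returned with a warning. Lower thresholds give non-increasing counts.
    """
    intens = np.asarray(getattr(profile_or_line, "intensities", profile_or_line), dtype=float)
    if np.ptp(intens) == 0:
        warnings.warn("flat profile: no valid dark-pixel threshold exists", stacklevel=2)
    return int(np.count_nonzero(intens < threshold))


def percent_change(width_post: float, width_baseline: float) -> float:
    """Width change as % of baseline; negative values indicate constriction."""
    if width_baseline <= 0:
        raise ValueError("baseline width must be positive")
    return 100.0 * (width_post - width_baseline) / width_baseline
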