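"""Spectral conversion of multi-wavelength reflectance to hemoglobin concentration maps.

Widefield optical imaging spectroscopy (2D-OIS) records remitted light at a
small number of illumination bands. Under the modified Beer-Lambert law the
attenuation change at band ``λ`` relative to a baseline intensity ``I0`` is

    ΔA(λ) = -log10(I(λ) / I0(λ)) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR] · X(λ)

with ε the band-averaged molar extinction coefficients (cm⁻¹·M⁻¹), X(λ) the
differential path length (cm), and concentration changes in mol/L. Solving the
over-determined linear system across bands per pixel and frame yields ΔHbO and
ΔHbR maps in μM; total hemoglobin is ΔHbT = ΔHbO + ΔHbR and proxies cerebral
blood volume. The differential inversion uses a fixed X(λ); per-compartment
baseline saturation only enters absolute-concentration reporting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "WavelengthBand",
    "ChromophoreSpectra",
    "BaselineSpec",
    "OpticalFrameStack",
    "HemoStack",
    "attenuation",
    "unmix_stack",
    "percent_change_trace",
    "trial_average_map",
]


@dataclass(frozen=True)
class WavelengthBand:
    """One illumination band: center wavelength and half-bandwidth, in nm."""

    center: float
    half_bandwidth: float

    def __post_init__(self) -> None:
        if self.center <= 0:
            raise ValueError("band center must be positive (nm)")
        if self.half_bandwidth < 0:
            raise ValueError("half bandwidth must be >= 0 (nm)")

    def __str__(self) -> str:  # e.g. "494±20 nm"
        return f"{self.center:g}±{self.half_bandwidth:g} nm"


#: The default four-band illumination set of the imaging system.
DEFAULT_BANDS: tuple[WavelengthBand, ...] = (
    WavelengthBand(494.0, 20.0),
    WavelengthBand(560.0, 5.0),
    WavelengthBand(575.0, 14.0),
    WavelengthBand(595.0, 5.0),
)

# Band-averaged molar extinction coefficients (cm^-1 M^-1) from a standard
# hemoglobin compilation, and default differential path lengths (cm) for
# green-light reflectance in cortex. Both are package defaults, overridable;
# the pipeline's correctness contract is forward/inverse self-consistency,
# not agreement with any particular Monte-Carlo path-length table.
_DEFAULT_EXTINCTION = {
    494.0: (20900.0, 23900.0),
    560.0: (32610.0, 53700.0),
    575.0: (59900.0, 37020.0),
    595.0: (4900.0, 19010.0),
}
_DEFAULT_PATH_CM = {494.0: 0.040, 560.0: 0.023, 575.0: 0.018, 595.0: 0.060}


@dataclass(frozen=True)
class ChromophoreSpectra:
    """Band-averaged extinction coefficients and path lengths for the unmixing.

    Parameters
    ----------
    bands
        The illumination bands, in the order matching the coefficient arrays.
    eps_hbo, eps_hbr
        Molar extinction of oxy-/deoxyhemoglobin per band, cm⁻¹·M⁻¹.
    path_cm
        Differential path length X(λ) per band, cm.
    """

    bands: tuple[WavelengthBand, ...]
    eps_hbo: tuple[float, ...]
    eps_hbr: tuple[float, ...]
    path_cm: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.bands)
        if not (len(self.eps_hbo) == len(self.eps_hbr) == len(self.path_cm) == n):
            raise ValueError("eps_hbo, eps_hbr and path_cm must match the band count")
        if n < 2:
            raise ValueError("need at least 2 bands to separate HbO and HbR")
        if any(e <= 0 for e in self.eps_hbo + self.eps_hbr):
            raise ValueError("extinction coefficients must be positive")
        if any(x <= 0 for x in self.path_cm):
            raise ValueError("path lengths must be positive")
        if np.linalg.matrix_rank(self.design_matrix()) < 2:
            raise ValueError("design matrix [ε_HbO·X, ε_HbR·X] is rank deficient")

    @classmethod
    def default(cls) -> "ChromophoreSpectra":
        """The bundled four-band coefficient set."""
        bands = DEFAULT_BANDS
        hbo, hbr = zip(*(_DEFAULT_EXTINCTION[b.center] for b in bands))
        x = tuple(_DEFAULT_PATH_CM[b.center] for b in bands)
        return cls(bands=bands, eps_hbo=hbo, eps_hbr=hbr, path_cm=x)

    def design_matrix(self) -> np.ndarray:
        """(n_bands, 2) matrix mapping (ΔHbO, ΔHbR) in μM to ΔA per band."""
        hbo = np.asarray(self.eps_hbo, dtype=float)
        hbr = np.asarray(self.eps_hbr, dtype=float)
        x = np.asarray(self.path_cm, dtype=float)
        # 1e-6 converts μM to mol/L so that ΔA is dimensionless.
        return np.column_stack([hbo * x, hbr * x]) * 1e-6

    def reorder(self, order: "list[int] | tuple[int, ...]") -> "ChromophoreSpectra":
        """Return the same spectra with bands permuted by ``order``."""
        pick = lambda t: tuple(t[i] for i in order)  # noqa: E731
        return replace(
            self,
            bands=pick(self.bands),
            eps_hbo=pick(self.eps_hbo),
            eps_hbr=pick(self.eps_hbr),
            path_cm=pick(self.path_cm),
        )


# Baseline tissue assumptions used for absolute-concentration reporting:
# 100 μM total hemoglobin, with compartment-specific oxygen saturation.
DEFAULT_SO2 = {
    "whisker_region": 0.80,
    "artery": 0.90,
    "whisker_vein": 0.70,
    "parenchyma": 0.80,
    "draining_vein": 0.70,
    "meningeal": 0.70,
}


@dataclass(frozen=True)
class BaselineSpec:
    """Baseline hemoglobin assumptions: total concentration and SO2 per compartment."""

    total_hb: float = 100.0  # μM
    so2: dict = field(default_factory=lambda: dict(DEFAULT_SO2))

    def __post_init__(self) -> None:
        if self.total_hb <= 0:
            raise ValueError("total_hb must be positive (μM)")
        for comp, s in self.so2.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"so2 for {comp!r} must be in [0, 1]")

    def baseline_hbo(self, compartment: str) -> float:
        return self.total_hb * self.so2[compartment]

    def baseline_hbr(self, compartment: str) -> float:
        return self.total_hb * (1.0 - self.so2[compartment])


@dataclass
class OpticalFrameStack:
    """Per-band remitted-intensity movie with acquisition metadata.

    ``intensities`` has shape (n_bands, n_frames, n_rows, n_cols), arbitrary
    camera units. ``baseline_frames`` indexes the frames whose per-pixel mean
    defines I0; ``None`` means the full recording (the default, since the
    acquisition protocol does not single out a baseline window).
    """

    intensities: np.ndarray
    frame_rate: float
    bands: tuple[WavelengthBand, ...] = DEFAULT_BANDS
    baseline_frames: "slice | np.ndarray | None" = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 4:
            raise ValueError("intensities must be (bands, frames, rows, cols)")
        if self.intensities.shape[0] != len(self.bands):
            raise ValueError("band axis does not match the band list")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape[2:]

    def i0(self) -> np.ndarray:
        """Per-band, per-pixel baseline intensity (mean over baseline_frames)."""
        idx = slice(None) if self.baseline_frames is None else self.baseline_frames
        return self.intensities[:, idx].mean(axis=1)


@dataclass
class HemoStack:
    """Per-frame ΔHbO/ΔHbR maps in μM; ΔHbT = ΔHbO + ΔHbR by construction."""

    hbo: np.ndarray  # (frames, rows, cols), μM
    hbr: np.ndarray
    frame_rate: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.hbo.shape != self.hbr.shape or self.hbo.ndim != 3:
            raise ValueError("hbo and hbr must be matching (frames, rows, cols) arrays")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def hbt(self) -> np.ndarray:
        """ΔHbT in μM — exactly ΔHbO + ΔHbR."""
        return self.hbo + self.hbr

    @property
    def n_frames(self) -> int:
        return self.hbo.shape[0]


def attenuation(stack: OpticalFrameStack) -> np.ndarray:
    """Per-band attenuation-change maps ΔA = -log10(I / I0).

    Returns an array of the same shape as ``stack.intensities``. Raises if any
    intensity or baseline value is non-positive (log undefined), reporting how
    many pixels offend.
    """
    i0 = stack.i0()
    bad_i0 = int(np.count_nonzero(i0 <= 0))
    if bad_i0:
        raise ValueError(f"non-positive baseline intensity at {bad_i0} pixel-band entries")
    bad = int(np.count_nonzero(stack.intensities <= 0))
    if bad:
        raise ValueError(f"non-positive intensity at {bad} pixel-frame entries")
    return -np.log10(stack.intensities / i0[:, None])


def unmix_stack(
    delta_a: np.ndarray,
    spectra: ChromophoreSpectra,
    baseline: "BaselineSpec | None" = None,
    frame_rate: float = 32.0,
    provenance: "dict | None" = None,
) -> HemoStack:
    """Least-squares inversion of ΔA maps to ΔHbO/ΔHbR maps in μM.

    Per pixel and frame, solves ``ΔA(λ) = [ε_HbO(λ)ΔHbO + ε_HbR(λ)ΔHbR]·X(λ)``
    over all bands in the least-squares sense (the path-length-scaled spectral
    analysis). ``baseline`` is carried in provenance so absolute concentrations
    (baseline + Δ) can be derived downstream.
    """
    delta_a = np.asarray(delta_a, dtype=float)
    if delta_a.ndim != 4:
        raise ValueError("delta_a must be (bands, frames, rows, cols)")
    if delta_a.shape[0] != len(spectra.bands):
        raise ValueError(
            f"band mismatch: ΔA has {delta_a.shape[0]} bands, spectra {len(spectra.bands)}"
        )
    design = spectra.design_matrix()
    if np.linalg.matrix_rank(design) < 2:
        raise ValueError("design matrix is rank deficient")
    solver = np.linalg.pinv(design)  # (2, n_bands)
    nb, nf, nr, nc = delta_a.shape
    conc = solver @ delta_a.reshape(nb, -1)  # (2, frames*pixels), μM
    prov = dict(provenance or {})
    prov.setdefault("spectra_bands", [str(b) for b in spectra.bands])
    if baseline is not None:
        prov["baseline"] = {"total_hb": baseline.total_hb, "so2": dict(baseline.so2)}
    return HemoStack(
        hbo=conc[0].reshape(nf, nr, nc),
        hbr=conc[1].reshape(nf, nr, nc),
        frame_rate=frame_rate,
        provenance=prov,
    )


def percent_change_trace(hemo: HemoStack, roi, baseline: BaselineSpec) -> np.ndarray:
    """ROI-mean ΔHbT expressed as % of the baseline total hemoglobin.

    ``trace(t) = 100 · mean_over_roi(ΔHbT(t)) / total_hb``. ``roi`` is a
    boolean raster or an object with a boolean ``mask`` attribute.
    """
    mask = np.asarray(getattr(roi, "mask", roi), dtype=bool)
    if mask.shape != hemo.hbo.shape[1:]:
        raise ValueError("ROI shape does not match the concentration maps")
    if not mask.any():
        raise ValueError("empty ROI mask")
    return 100.0 * hemo.hbt[:, mask].mean(axis=1) / baseline.total_hb


def absolute_trace(hemo: HemoStack, roi, baseline: BaselineSpec, compartment: str) -> np.ndarray:
    """ROI-mean absolute HbT in μM: baseline total_hb + ΔHbT.

    The compartment label is accepted (and validated against the baseline
    table) because absolute HbO/HbR reporting depends on the compartment's
    resting saturation; total hemoglobin does not.
    """
    if compartment not in baseline.so2:
        raise KeyError(f"no baseline SO2 entry for compartment {compartment!r}")
    mask = np.asarray(getattr(roi, "mask", roi), dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    return baseline.total_hb + hemo.hbt[:, mask].mean(axis=1)


def trial_average_map(
    hemo: HemoStack,
    onsets,
    window_s: tuple[float, float] = (-1.0, 5.0),
) -> np.ndarray:
    """Event-triggered spatial map: per-pixel mean ΔHbT over a window across onsets.

    ``onsets`` are frame indices of event starts; the default window spans 1 s
    before to 5 s after onset. Onsets whose window runs off the recording are
    excluded with a logged warning.
    """
    lo = int(round(window_s[0] * hemo.frame_rate))
    hi = int(round(window_s[1] * hemo.frame_rate))
    if hi <= lo:
        raise ValueError("window must have positive length")
    maps = []
    dropped = 0
    for onset in onsets:
        a, b = int(onset) + lo, int(onset) + hi
        if a < 0 or b > hemo.n_frames:
            dropped += 1
            continue
        maps.append(hemo.hbt[a:b].mean(axis=0))
    if dropped:
        msg = f"trial_average_map: excluded {dropped} onset(s) outside the recording"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    if not maps:
        raise ValueError("no onset admits the requested window")
    return np.mean(maps, axis=0)
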