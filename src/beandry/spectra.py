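"""Hyperspectral cube calibration and spectral preprocessing.

A push-broom Vis-NIR camera (400-1000 nm, 112 bands) images beans on a stage;
raw signal is converted to reflectance against white/dark reference frames,
the bean region is segmented, a median spectrum is extracted, converted to
absorbance and smoothed with a Savitzky-Golay filter before chemometric
modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_coeffs
from skimage.filters import threshold_otsu

__all__ = [
    "HyperCube",
    "ReferenceFrames",
    "SpectralProfile",
    "SGConfig",
    "correct_reflectance",
    "segment_roi",
    "median_profile",
    "to_absorbance",
    "savgol_smooth",
    "value_at",
]

logger = logging.getLogger(__name__)

_EPS_DENOM = 1e-9        # white-minus-dark below this masks the pixel
_EPS_REFLECTANCE = 1e-6  # floor applied before taking log10


@dataclass
class HyperCube:
    """H x W x B reflectance (or raw-signal) cube with its wavelength grid.

    Invalid pixels (e.g. where the white reference is not above the dark) are
    stored as NaN and excluded from downstream statistics.
    """

    data: np.ndarray
    wavelengths_nm: np.ndarray
    calibrated: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be H x W x B")
        if self.wavelengths_nm.size != self.data.shape[2]:
            raise ValueError("wavelength count must match the cube's band axis")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class ReferenceFrames:
    """White and dark reference frames, full-frame (H x W x B) or per-column line (1 x W x B)."""

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self):
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark references must share a shape")
        if self.white.ndim != 3:
            raise ValueError("references must be H x W x B (H may be 1 for line references)")


@dataclass
class SpectralProfile:
    """A single spectrum (reflectance or absorbance) with metadata."""

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: str = "reflectance"
    sample_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths_nm.shape != self.values.shape:
            raise ValueError("wavelengths and values must have equal length")
        if self.kind not in ("reflectance", "absorbance"):
            raise ValueError(f"unknown profile kind {self.kind!r}")
        if self.kind == "reflectance" and np.any(self.values < 0):
            raise ValueError("reflectance must be non-negative")


@dataclass(frozen=True)
class SGConfig:
    """Savitzky-Golay window (odd, 2M+1) and polynomial degree (N < window)."""

    window: int = 23
    order: int = 2

    def __post_init__(self):
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("window must be an odd integer >= 3")
        if not 0 <= self.order < self.window:
            raise ValueError("polynomial order must satisfy 0 <= order < window")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def correct_reflectance(raw: HyperCube, refs: ReferenceFrames) -> HyperCube:
    """Reflectance calibration Rc = (S - D) / (W - D) against white/dark frames.

    Line references (1 x W x B) broadcast over rows.  Pixels where the white
    signal does not exceed the dark signal are masked NaN; negative corrected
    values (noise below the dark level) are clipped to zero.
    """
    s = raw.data
    w, d = refs.white, refs.dark
    try:
        np.broadcast_shapes(s.shape, w.shape)
    except ValueError as exc:
        raise ValueError("reference frames are not broadcastable to the cube") from exc
    denom = w - d
    bad = denom <= _EPS_DENOM
    rc = (s - d) / np.where(bad, 1.0, denom)
    rc = np.where(np.broadcast_to(bad, rc.shape), np.nan, rc)
    rc = np.clip(rc, 0.0, None)
    return HyperCube(rc, raw.wavelengths_nm, calibrated=True)


def segment_roi(cube: HyperCube, foreground: str = "dark") -> np.ndarray:
    """Otsu-threshold the band-averaged reflectance image into a sample mask.

    By default the foreground is the class with the lower mean reflectance
    (dark beans on a bright stage); pass ``foreground="bright"`` to invert.
    Raises if the image has no contrast or either class is empty.
    """
    if not cube.calibrated:
        raise ValueError("segment an intensity-calibrated cube, not raw signal")
    img = np.nanmean(cube.data, axis=2)
    finite = img[np.isfinite(img)]
    if finite.size == 0 or np.ptp(finite) == 0:
        raise ValueError("cannot segment a uniform image (no bimodality)")
    thr = threshold_otsu(finite)
    logger.info("segment_roi: Otsu threshold %.6g", thr)
    below = img <= thr
    mask = below if foreground == "dark" else ~below
    if not mask.any() or mask.all():
        raise ValueError("thresholding produced an empty class; "
                         "check illumination or the foreground flag")
    return mask


def median_profile(cube: HyperCube, mask: np.ndarray,
                   sample_id: str = "", **metadata) -> SpectralProfile:
    """Per-band median spectrum over the masked pixels (NaN pixels excluded)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.data.shape[:2]:
        raise ValueError("mask shape must match the cube's spatial extent")
    if not mask.any():
        raise ValueError("empty mask")
    values = np.nanmedian(cube.data[mask], axis=0)
    return SpectralProfile(cube.wavelengths_nm, values, kind="reflectance",
                           sample_id=sample_id, metadata=metadata)


def to_absorbance(profile: SpectralProfile, log_base: float = 10.0) -> SpectralProfile:
    """Absorbance A = -log10(R) (Beer-Lambert convention; base configurable).

    Zero reflectance values are floored at 1e-6 with a warning; an all-zero
    profile is an error.
    """
    if profile.kind != "reflectance":
        raise ValueError("to_absorbance expects a reflectance profile")
    r = profile.values
    if np.all(r <= 0):
        raise ValueError("all-zero reflectance profile")
    n_floor = int(np.sum(r <= 0))
    if n_floor:
        logger.warning("to_absorbance: floored %d non-positive value(s) at %g",
                       n_floor, _EPS_REFLECTANCE)
    a = -np.log(np.where(r <= 0, _EPS_REFLECTANCE, r)) / np.log(log_base)
    return SpectralProfile(profile.wavelengths_nm, a, kind="absorbance",
                           sample_id=profile.sample_id,
                           metadata=dict(profile.metadata))


def savgol_smooth(profile: SpectralProfile, cfg: SGConfig = SGConfig()) -> SpectralProfile:
    """Savitzky-Golay smoothing: local least-squares polynomial per window.

    Interior points use the standard convolution coefficients; near the edges
    the polynomial is refit within the truncated window, which preserves
    exactness on polynomials of degree <= order everywhere.
    """
    y = profile.values
    n = y.size
    if cfg.window > n:
        raise ValueError("window exceeds profile length")
    m = cfg.window // 2
    out = np.empty_like(y)
    coeffs = savgol_coeffs(cfg.window, cfg.order)[::-1]
    for i in range(n):
        lo, hi = max(0, i - m), min(n, i + m + 1)
        if hi - lo == cfg.window:
            out[i] = coeffs @ y[lo:hi]
        else:  # truncated edge window: refit the polynomial
            x = np.arange(lo, hi) - i
            out[i] = np.polynomial.polynomial.polyfit(x, y[lo:hi], cfg.order)[0]
    if profile.kind == "reflectance":
        # least-squares overshoot can dip just below zero; keep it physical
        out = np.clip(out, 0.0, None)
    res = SpectralProfile(profile.wavelengths_nm, out, kind=profile.kind,
                          sample_id=profile.sample_id,
                          metadata=dict(profile.metadata))
    return res


def value_at(profile: SpectralProfile, wavelengths_nm):
    """Profile values at the grid bands nearest the requested wavelengths."""
    wl = np.atleast_1d(np.asarray(wavelengths_nm, dtype=float))
    idx = np.argmin(np.abs(profile.wavelengths_nm[:, None] - wl[None, :]), axis=0)
    out = profile.values[idx]
    return out if np.ndim(wavelengths_nm) else float(out[0])
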