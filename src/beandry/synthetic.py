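"""Synthetic drying curves, hyperspectral cubes and sensory tables.

The study's raw data (moisture time series, reflectance cubes, cupping
sheets) were never deposited, so every analysis stage is exercised against
generators that emulate the study conditions and emit their own ground
truth: drying curves follow the eigenfunction sphere solution forward model;
cubes carry Gaussian absorbance features at 480/600/720/940 nm whose
amplitudes are linked exactly to a drawn cup score through the published
fixed-coefficient model; sensory tables draw replicate cup scores from the
published per-temperature means and spreads.

Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .chemometrics import EQ16_INTERCEPT, EQ16_WAVELENGTHS_NM, eq16_band_weights
from .kinetics import (DryingCurve, TransportParams, biot_from_mu,
                       roots_for_biot, series_phi, shape_intercept)
from .spectra import HyperCube, ReferenceFrames, SGConfig, savgol_smooth, SpectralProfile

__all__ = [
    "CurveGenSpec",
    "CubeGenSpec",
    "SyntheticCurve",
    "SyntheticCubeSample",
    "SyntheticCubeBundle",
    "gen_drying_curve",
    "gen_hypercube",
    "gen_sensory_table",
]


# ---------------------------------------------------------------------------
# drying curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurveGenSpec:
    """Forward-model conditions for one synthetic drying curve.

    Defaults reflect the study conditions: bean radius 3.968e-4 m, initial
    moisture 45% wet basis (81.82% dry basis), drying to an equilibrium near
    12% wet basis (13.64% dry basis), sampled every 2 h.
    """

    d_eff_true: float = 5e-13          # m^2/s
    biot_true: float = 3.0
    radius_L: float = reference.BEAN_RADIUS_M
    m0: float = 81.8182                # dry-basis %
    meq: float = 13.6364               # dry-basis %
    temp_C: float = 40.0
    dt_h: float = 2.0
    duration_h: float = 34.0
    noise_sd: float = 0.0              # on moisture, %
    n_terms: int = 1                   # 1 = first-term; >= 50 = series oracle
    seed: int = 0

    def __post_init__(self):
        if self.d_eff_true <= 0 or self.biot_true <= 0 or self.radius_L <= 0:
            raise ValueError("d_eff_true, biot_true and radius_L must be positive")
        if self.m0 <= self.meq:
            raise ValueError("m0 must exceed meq")
        if self.dt_h <= 0 or self.duration_h < self.dt_h:
            raise ValueError("need duration_h >= dt_h > 0")


@dataclass(frozen=True)
class SyntheticCurve:
    """A generated curve plus the transport parameters that produced it."""

    curve: DryingCurve
    truth: TransportParams
    slope_a: float
    intercept_b: float


def gen_drying_curve(spec: CurveGenSpec) -> SyntheticCurve:
    """Forward-evaluate the sphere solution at the surface and add noise.

    ``M(t) = Meq + (M0 - Meq) * phi(x/L=1, Fo(t), Biot)``.  With
    ``n_terms=1`` the first sample is taken at ``dt_h`` (the first-term curve
    does not pass through M0 at t=0); with more terms the series is evaluated
    from t=0.  Gaussian noise is applied to moisture, the instrument domain.
    """
    t0 = spec.dt_h if spec.n_terms == 1 else 0.0
    times = np.arange(t0, spec.duration_h + 0.5 * spec.dt_h, spec.dt_h)
    fo = spec.d_eff_true * (times * 3600.0) / spec.radius_L ** 2
    phi = series_phi(1.0, fo, spec.biot_true, spec.n_terms)
    m = spec.meq + (spec.m0 - spec.meq) * phi
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        m = m + rng.normal(0.0, spec.noise_sd, size=m.shape)
    m = np.maximum(m, 1e-3)  # moisture meter cannot read <= 0
    mu = float(roots_for_biot(spec.biot_true, 1).roots[0])
    truth = TransportParams(
        mu=mu, biot=biot_from_mu(mu), d_eff=spec.d_eff_true,
        h_m=spec.biot_true * spec.d_eff_true / spec.radius_L,
        radius_L=spec.radius_L, temperature=spec.temp_C)
    slope_a = -mu ** 2 * spec.d_eff_true / spec.radius_L ** 2
    return SyntheticCurve(
        curve=DryingCurve(spec.temp_C, times, m, basis="dry",
                          replicate_id=f"sim-{spec.seed}"),
        truth=truth, slope_a=slope_a, intercept_b=shape_intercept(mu))


# ---------------------------------------------------------------------------
# hyperspectral cubes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CubeGenSpec:
    """Conditions for a batch of synthetic bean cubes linked to cup scores.

    The per-band score linkage inverts the published four-band model exactly:
    deviations of equal magnitude (sign-matched to the model's effective band
    weights) are planted at all four centers so each carries score-linked
    variance, and the planted amplitudes pre-compensate the Savitzky-Golay
    response so the *smoothed* absorbance at the centers hits the target.
    See docs/methods.md for why the band absorbances are far above a physical
    scale: the published model's tiny band weights must span a +-4 point
    score range.
    """

    image_size: tuple = (32, 32)
    n_bands: int = 112
    wavelength_range: tuple = (400.0, 1000.0)
    peak_centers: tuple = EQ16_WAVELENGTHS_NM
    peak_fwhm_nm: float = 60.0
    baseline_absorbance: float = 50.0
    score_mean: float = 83.4
    score_sd: float = 1.5
    score_range: tuple = reference.CUP_SCORE_RANGE
    noise_sd: float = 0.0              # absorbance, per pixel per band
    background_reflectance: float = 0.9
    bean_axes_frac: tuple = (0.35, 0.25)
    white_level: float = 0.95
    dark_level: float = 0.0  # nonzero offsets absorb tiny bean reflectances in float64
    temps_C: tuple = reference.TEMPERATURES_C
    n_samples: int = 80
    sg: SGConfig = field(default_factory=SGConfig)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.wavelength_range
        if any(not lo < c < hi for c in self.peak_centers):
            raise ValueError("peak centers must lie inside the wavelength range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SyntheticCubeSample:
    """One raw cube with its ground truth."""

    sample_id: str
    temperature: float
    cube: HyperCube                 # raw signal, uncalibrated
    truth_score: float
    truth_absorbances: np.ndarray   # post-smoothing targets at the 4 centers
    truth_amplitudes: np.ndarray    # planted Gaussian peak amplitudes
    truth_spectrum: np.ndarray | None = None  # noise-free bean absorbance


@dataclass
class SyntheticCubeBundle:
    """A batch of samples sharing reference frames and a wavelength grid."""

    samples: list
    refs: ReferenceFrames
    wavelengths_nm: np.ndarray
    scores: pd.DataFrame
    spec: CubeGenSpec

    def bean_spectra(self) -> np.ndarray:
        """Noise-free planted bean absorbance spectra, samples x bands."""
        return np.stack([s.truth_spectrum for s in self.samples])


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    n = 0
    while n < size:
        draw = rng.normal(mean, sd, size=size)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, size - n)
        out[n:n + take] = keep[:take]
        n += take
    return out


def gen_hypercube(spec: CubeGenSpec) -> SyntheticCubeBundle:
    """Generate raw cubes, reference frames and a matching score table.

    For each sample a cup score is drawn from a truncated normal, band
    absorbance targets are solved so the published four-band model returns
    exactly that score, and the bean ellipse is embedded in a brighter
    background.  Raw signal is synthesized as S = D + R (W - D) so that
    reflectance calibration recovers R.
    """
    h, w = spec.image_size
    wl = np.linspace(*spec.wavelength_range, spec.n_bands)
    centers = np.asarray(spec.peak_centers, dtype=float)
    center_idx = np.argmin(np.abs(wl[:, None] - centers[None, :]), axis=0)
    sigma = spec.peak_fwhm_nm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    peaks = np.exp(-((wl[:, None] - centers[None, :]) ** 2) / (2 * sigma ** 2))

    # Savitzky-Golay response of each unit peak at each center band; the
    # planted amplitudes pre-compensate this so smoothed absorbance at the
    # centers equals the target exactly (a constant baseline is SG-invariant).
    G = np.empty((centers.size, centers.size))
    for k in range(centers.size):
        sm = savgol_smooth(SpectralProfile(wl, peaks[:, k], kind="absorbance"),
                           spec.sg)
        G[:, k] = sm.values[center_idx]

    wts = eq16_band_weights()
    direction = np.sign(wts)
    gain = float(wts @ direction)          # sum of |effective weights|
    base_term = spec.baseline_absorbance * float(wts.sum())

    rng = np.random.default_rng(spec.seed)
    scores_drawn = _truncated_normal(rng, spec.score_mean, spec.score_sd,
                                     *spec.score_range, spec.n_samples)

    yy, xx = np.mgrid[0:h, 0:w]
    ay, ax = spec.bean_axes_frac[0] * h, spec.bean_axes_frac[1] * w
    bean = (((yy - (h - 1) / 2) / ay) ** 2 + ((xx - (w - 1) / 2) / ax) ** 2) <= 1.0

    white = np.full((1, w, spec.n_bands), spec.white_level)
    dark = np.full((1, w, spec.n_bands), spec.dark_level)
    span = spec.white_level - spec.dark_level

    samples = []
    rows = []
    for i, score in enumerate(scores_drawn):
        temp = spec.temps_C[i % len(spec.temps_C)]
        beta = (score - EQ16_INTERCEPT - base_term) / gain
        targets = spec.baseline_absorbance + beta * direction
        amps = np.linalg.solve(G, targets - spec.baseline_absorbance)
        absorb = spec.baseline_absorbance + peaks @ amps   # noise-free spectrum

        cube_a = np.broadcast_to(absorb, (h, w, spec.n_bands)).copy()
        if spec.noise_sd > 0:
            cube_a += rng.normal(0.0, spec.noise_sd, size=cube_a.shape)
        refl = np.where(bean[:, :, None], 10.0 ** (-cube_a),
                        spec.background_reflectance)
        raw = spec.dark_level + refl * span
        sid = f"s{i:03d}"
        sample = SyntheticCubeSample(
            sample_id=sid, temperature=temp,
            cube=HyperCube(raw.astype(float), wl, calibrated=False),
            truth_score=float(score),
            truth_absorbances=targets, truth_amplitudes=amps,
            truth_spectrum=absorb)
        samples.append(sample)
        rows.append({"sample_id": sid, "temperature_C": temp,
                     "cup_score": float(score)})

    return SyntheticCubeBundle(
        samples=samples, refs=ReferenceFrames(white=white, dark=dark),
        wavelengths_nm=wl, scores=pd.DataFrame(rows), spec=spec)


# ---------------------------------------------------------------------------
# sensory tables
# ---------------------------------------------------------------------------

def gen_sensory_table(means=None, sds=None, n_replicates: int = 3,
                      seed: int = 0) -> pd.DataFrame:
    """Seeded Gaussian replicate cup scores per temperature, clipped to [0, 100].

    Defaults use the published per-temperature cup-score means and spreads.
    Returns a tidy frame with columns temperature_C, replicate, cup_score.
    """
    if means is None:
        means = {t: reference.CUP_SCORE_TABLE[t][0]
                 for t in reference.TEMPERATURES_C}
    if sds is None:
        sds = {t: reference.CUP_SCORE_TABLE[t][1]
               for t in reference.TEMPERATURES_C}
    if set(means) != set(sds):
        raise ValueError("means and sds must cover the same temperatures")
    rng = np.random.default_rng(seed)
    rows = []
    for t in sorted(means):
        draws = np.clip(rng.normal(means[t], sds[t], size=n_replicates), 0, 100)
        rows += [{"temperature_C": t, "replicate": r + 1,
                  "cup_score": float(v)} for r, v in enumerate(draws)]
    return pd.DataFrame(rows)
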