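"""Moisture-transport parameter estimation from thin-layer drying curves.

Drying of a (near-)spherical grain at constant air temperature is modelled by
Fick's second law.  The analytical solution for the dimensionless moisture
ratio at the bean surface is an eigenfunction series in the roots ``mu_n`` of

    1 - mu*cot(mu) = Bi          (mass-transfer Biot number)

whose slowest-decaying term dominates at large Fourier number
``Fo = D_eff*t/L**2``.  Keeping only that first term, ln(MR) is linear in
time; the slope carries the effective diffusivity and the intercept is a pure
function of the first eigenvalue, so one ordinary least-squares fit of the
log moisture ratio plus one transcendental root solve recovers
(mu, Bi, D_eff, h_m) for each drying temperature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DryingCurve",
    "MoistureRatioSeries",
    "KineticFit",
    "TransportParams",
    "RootSet",
    "CriticalMoistureResult",
    "convert_basis",
    "drying_rate",
    "critical_moisture",
    "equilibrium_moisture",
    "moisture_ratio",
    "linearized_fit",
    "shape_intercept",
    "solve_mu_from_intercept",
    "biot_from_mu",
    "roots_for_biot",
    "d_eff_from_slope",
    "h_m_from",
    "transport_from_line",
    "estimate_transport",
    "series_phi",
]

logger = logging.getLogger(__name__)

_SECONDS_PER_HOUR = 3600.0
#: Exclusion margin around the singular endpoints of eigenvalue brackets.
_BRACKET_DELTA = 1e-9


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DryingCurve:
    """Moisture content vs time for one replicate at one air temperature.

    Parameters
    ----------
    temperature : float
        Drying-air temperature, °C.
    times : array-like
        Sampling times in hours, non-negative and strictly increasing.
    moisture : array-like
        Moisture content (%) at each time, on the basis given by ``basis``.
    basis : {"wet", "dry"}
        Whether moisture is per total mass (wet) or per dry solids (dry).
    replicate_id : str
        Label of the replicate.
    """

    temperature: float
    times: np.ndarray
    moisture: np.ndarray
    basis: str = "dry"
    replicate_id: str = "r1"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        m = np.asarray(self.moisture, dtype=float)
        if t.shape != m.shape or t.ndim != 1:
            raise ValueError("times and moisture must be equal-length 1-D arrays")
        if t.size and t[0] < 0:
            raise ValueError("times must be non-negative")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if self.basis not in ("wet", "dry"):
            raise ValueError(f"unknown moisture basis {self.basis!r}")
        if self.basis == "wet" and np.any((m <= 0) | (m >= 100)):
            raise ValueError("wet-basis moisture must lie in (0, 100)")
        if self.basis == "dry" and np.any(m <= 0):
            raise ValueError("dry-basis moisture must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "moisture", m)

    def to_basis(self, basis: str) -> "DryingCurve":
        """Return the curve with moisture converted to ``basis``."""
        if basis == self.basis:
            return self
        m = convert_basis(self.moisture, self.basis, basis)
        return DryingCurve(self.temperature, self.times, m, basis,
                           self.replicate_id)


@dataclass(frozen=True)
class MoistureRatioSeries:
    """Log moisture ratio ln[(M - Meq)/(M0 - Meq)] vs time in seconds."""

    times_s: np.ndarray
    log_ratio: np.ndarray
    m0: float
    meq: float

    def __post_init__(self):
        if self.m0 <= self.meq:
            raise ValueError("initial moisture must exceed equilibrium moisture")


@dataclass(frozen=True)
class KineticFit:
    """Least-squares line through the log moisture ratio series."""

    slope_a: float   # 1/s, negative for a drying curve
    intercept_b: float
    mse: float

    def __post_init__(self):
        if self.mse < 0:
            raise ValueError("mse must be non-negative")


@dataclass(frozen=True)
class TransportParams:
    """Transport parameters of the first-term sphere solution.

    ``h_m = biot * d_eff / radius_L`` holds by construction and
    ``biot = 1 - mu*cot(mu)`` to solver tolerance.
    """

    mu: float
    biot: float
    d_eff: float
    h_m: float
    radius_L: float
    temperature: float = math.nan
    fit_mse: float = math.nan

    def __post_init__(self):
        if not 0 < self.mu < math.pi:
            raise ValueError("mu must lie in (0, pi)")
        if self.biot <= 0 or self.d_eff <= 0 or self.radius_L <= 0:
            raise ValueError("biot, d_eff and radius_L must be positive")


@dataclass(frozen=True)
class RootSet:
    """First k positive roots of 1 - mu*cot(mu) = Biot."""

    biot: float
    roots: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        r = np.asarray(self.roots, dtype=float)
        n = np.arange(1, r.size + 1)
        if not (np.all(r > (n - 1) * math.pi) and np.all(r < n * math.pi)):
            raise ValueError("root n must lie strictly inside ((n-1)pi, n*pi)")
        object.__setattr__(self, "roots", r)


@dataclass(frozen=True)
class CriticalMoistureResult:
    """Breakpoint of the drying-rate curve, if a transition was detected."""

    critical_moisture: float | None
    sse_two_segment: float
    sse_single: float
    detected: bool


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def convert_basis(moisture, from_basis: str, to_basis: str):
    """Convert moisture % between wet (per total mass) and dry (per solids) basis.

    wet -> dry: 100*w/(100-w); dry -> wet: 100*d/(100+d).
    """
    m = np.asarray(moisture, dtype=float)
    for b in (from_basis, to_basis):
        if b not in ("wet", "dry"):
            raise ValueError(f"unknown moisture basis {b!r}")
    if from_basis == "wet" and np.any((m <= 0) | (m >= 100)):
        raise ValueError("wet-basis moisture must lie in (0, 100)")
    if from_basis == "dry" and np.any(m <= 0):
        raise ValueError("dry-basis moisture must be positive")
    if from_basis == to_basis:
        out = m
    elif from_basis == "wet":
        out = 100.0 * m / (100.0 - m)
    else:
        out = 100.0 * m / (100.0 + m)
    return out if out.ndim else float(out)


def drying_rate(curve: DryingCurve):
    """Finite-difference drying rate paired with interval-midpoint moisture.

    Returns
    -------
    mean_moisture, rate : ndarray
        ``rate[i] = (M[i+1]-M[i]) / (t[i+1]-t[i])`` in %/h, and the mean
        moisture of each interval; both of length ``n - 1``.
    """
    if curve.times.size < 2:
        raise ValueError("need at least 2 points to compute a drying rate")
    dt = np.diff(curve.times)
    rate = np.diff(curve.moisture) / dt
    mid = 0.5 * (curve.moisture[:-1] + curve.moisture[1:])
    return mid, rate


def critical_moisture(curve: DryingCurve, f_ratio: float = 2.0) -> CriticalMoistureResult:
    """Locate the constant-rate/falling-rate transition of a drying curve.

    The drying rate is expressed as a function of mean moisture and every
    two-segment partition (>= 2 points per segment) is fitted by ordinary
    least squares; the partition minimizing total SSE defines the breakpoint,
    reported as the moisture midway between the segments.  The segmented fit
    must reduce the single-line SSE by at least ``f_ratio``, otherwise no
    transition is reported.
    """
    if curve.times.size < 4:
        raise ValueError("need at least 4 points to locate a rate transition")
    mid, rate = drying_rate(curve)

    def line_sse(x, y):
        if x.size < 2 or np.ptp(x) == 0:
            return 0.0
        coef = np.polyfit(x, y, 1)
        return float(np.sum((np.polyval(coef, x) - y) ** 2))

    sse_single = line_sse(mid, rate)
    best = (math.inf, None)
    for i in range(2, mid.size - 1):  # segments [0:i] and [i:]
        sse = line_sse(mid[:i], rate[:i]) + line_sse(mid[i:], rate[i:])
        if sse < best[0]:
            best = (sse, i)
    sse_two, i = best
    breakpoint_m = 0.5 * (mid[i - 1] + mid[i])
    # perfectly linear rate curves leave both SSEs ~0: no transition
    detected = sse_two < math.inf and sse_single > f_ratio * sse_two and \
        sse_single > 1e-12
    return CriticalMoistureResult(
        critical_moisture=float(breakpoint_m) if detected else None,
        sse_two_segment=sse_two, sse_single=sse_single, detected=detected)


def equilibrium_moisture(curve: DryingCurve, plateau_tol: float = 0.1):
    """Lowest moisture reached, with the first time it is attained.

    Returns ``(meq, t_plateau_h)`` where ``t_plateau_h`` is the earliest
    sampling time whose moisture lies within ``plateau_tol`` (absolute %) of
    the minimum.
    """
    if curve.times.size == 0:
        raise ValueError("empty curve")
    meq = float(np.min(curve.moisture))
    idx = int(np.argmax(curve.moisture <= meq + plateau_tol))
    return meq, float(curve.times[idx])


def moisture_ratio(curve: DryingCurve, meq: float,
                   m0: float | None = None) -> MoistureRatioSeries:
    """Log dimensionless moisture ratio of a dry-basis drying curve.

    Times are converted h -> s.  ``m0`` defaults to the first sampled
    moisture.  Points at or below ``meq`` have an undefined log ratio and are
    dropped with a logged count (measurement noise can cross the asymptote).
    """
    if curve.basis != "dry":
        raise ValueError("moisture ratio is defined on dry-basis moisture; "
                         "convert with DryingCurve.to_basis('dry')")
    if m0 is None:
        m0 = float(curve.moisture[0])
    if m0 <= meq:
        raise ValueError("initial moisture must exceed equilibrium moisture")
    keep = curve.moisture > meq
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        logger.warning("moisture_ratio: dropped %d point(s) with M <= Meq",
                       n_dropped)
    ratio = (curve.moisture[keep] - meq) / (m0 - meq)
    return MoistureRatioSeries(times_s=curve.times[keep] * _SECONDS_PER_HOUR,
                               log_ratio=np.log(ratio), m0=m0, meq=meq)


def linearized_fit(series: MoistureRatioSeries) -> KineticFit:
    """Ordinary least squares of the log moisture ratio on time (seconds)."""
    t, y = series.times_s, series.log_ratio
    if t.size < 3:
        raise ValueError("need at least 3 points for the linearized fit")
    if np.ptp(t) == 0:
        raise ValueError("degenerate series: all times equal")
    a, b = np.polyfit(t, y, 1)
    resid = y - (a * t + b)
    return KineticFit(slope_a=float(a), intercept_b=float(b),
                      mse=float(np.mean(resid ** 2)))


# ---------------------------------------------------------------------------
# eigenvalue algebra of the sphere solution
# ---------------------------------------------------------------------------

def _surface_shape(mu):
    """Spatial first-term factor at the surface (x/L = 1)."""
    s, c = np.sin(mu), np.cos(mu)
    return 2.0 * s * (s - mu * c) / (mu * (mu - s * c))


def shape_intercept(mu: float) -> float:
    """Intercept b(mu) = ln[2 sin(mu) (sin(mu) - mu cos(mu)) / (mu (mu - sin(mu)cos(mu)))].

    Strictly decreasing on (0, pi) with b -> 0 as mu -> 0+.
    """
    if not 0 < mu < math.pi:
        raise ValueError("mu must lie in (0, pi)")
    return float(np.log(_surface_shape(mu)))


def _bisect(f, lo: float, hi: float, width: float = 1e-12,
            max_iter: int = 60) -> float:
    """Plain bisection for a sign change of ``f`` on [lo, hi]."""
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0:
        raise ValueError("no sign change on the bracket")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if fm == 0.0:
            return mid
        if flo * fm < 0:
            hi = mid
        else:
            lo, flo = mid, fm
        if hi - lo < width:
            break
    return 0.5 * (lo + hi)


def solve_mu_from_intercept(b: float) -> float:
    """First eigenvalue mu solving shape_intercept(mu) = b by bisection.

    ``b`` must be negative (the surface shape factor is < 1 for mu > 0); the
    unique root is bracketed on (delta, pi - delta) and bisected until the
    interval width falls below 1e-12.
    """
    if b >= 0:
        raise ValueError("intercept must be negative; no root exists for b >= 0")
    lo, hi = 1e-6, math.pi - _BRACKET_DELTA
    # near mu=0 the intercept tends to 0 from below; shrink lo if needed
    while shape_intercept(lo) < b:
        lo *= 0.1
        if lo < 1e-300:
            raise ValueError(f"intercept {b} out of range")
    return _bisect(lambda m: shape_intercept(m) - b, lo, hi)


def biot_from_mu(mu: float) -> float:
    """Biot number Bi = 1 - mu*cot(mu), strictly increasing on (0, pi)."""
    if not 0 < mu < math.pi:
        raise ValueError("mu must lie strictly inside (0, pi)")
    return float(1.0 - mu / math.tan(mu))


def roots_for_biot(biot: float, k: int = 6) -> RootSet:
    """First ``k`` positive roots of 1 - mu*cot(mu) = Biot.

    Root ``n`` lies strictly inside ((n-1)pi, n*pi) — the brackets are set by
    the vertical asymptotes of 1 - mu*cot(mu) — and is found by bisection.
    """
    if biot <= 0:
        raise ValueError("biot must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    roots = []
    for n in range(1, k + 1):
        lo = (n - 1) * math.pi + _BRACKET_DELTA
        hi = n * math.pi - _BRACKET_DELTA
        roots.append(_bisect(lambda m: 1.0 - m / math.tan(m) - biot, lo, hi))
    return RootSet(biot=biot, roots=np.asarray(roots))


def d_eff_from_slope(slope_a: float, mu: float, radius_L: float) -> float:
    """Effective diffusivity D = |a| L^2 / mu^2 from the drying-line slope (1/s)."""
    if slope_a >= 0:
        raise ValueError("drying-line slope must be negative")
    if not 0 < mu < math.pi:
        raise ValueError("mu must lie in (0, pi)")
    if radius_L <= 0:
        raise ValueError("radius_L must be positive")
    return abs(slope_a) * radius_L ** 2 / mu ** 2


def h_m_from(biot: float, d_eff: float, radius_L: float) -> float:
    """Convective mass-transfer coefficient h_m = Bi * D / L."""
    if biot <= 0 or d_eff <= 0 or radius_L <= 0:
        raise ValueError("biot, d_eff and radius_L must all be positive")
    return biot * d_eff / radius_L


def transport_from_line(slope_a: float, intercept_b: float, radius_L: float,
                        temperature: float = math.nan,
                        fit_mse: float = math.nan) -> TransportParams:
    """Chain (a, b) -> mu -> Biot -> D_eff -> h_m for one drying line."""
    mu = solve_mu_from_intercept(intercept_b)
    biot = biot_from_mu(mu)
    d_eff = d_eff_from_slope(slope_a, mu, radius_L)
    h_m = h_m_from(biot, d_eff, radius_L)
    return TransportParams(mu=mu, biot=biot, d_eff=d_eff, h_m=h_m,
                           radius_L=radius_L, temperature=temperature,
                           fit_mse=fit_mse)


def estimate_transport(curve: DryingCurve, meq: float, radius_L: float,
                       m0: float | None = None,
                       t_min_h: float = 0.0) -> TransportParams:
    """Estimate (mu, Biot, D_eff, h_m) from one drying curve.

    Composes moisture_ratio -> linearized_fit -> eigenvalue/transport algebra.
    ``t_min_h`` optionally restricts the fit to times past the early transient
    where the first-term approximation is invalid (small Fourier number).
    """
    curve = curve.to_basis("dry")
    if t_min_h > 0:
        keep = curve.times >= t_min_h
        curve = DryingCurve(curve.temperature, curve.times[keep],
                            curve.moisture[keep], curve.basis,
                            curve.replicate_id)
    series = moisture_ratio(curve, meq, m0=m0)
    fit = linearized_fit(series)
    return transport_from_line(fit.slope_a, fit.intercept_b, radius_L,
                               temperature=curve.temperature,
                               fit_mse=fit.mse)


def series_phi(x_over_L: float, fourier_number, biot: float,
               n_terms: int = 50):
    """Eigenfunction-series dimensionless moisture of the sphere solution.

    phi = sum_n  2 (sin mu_n - mu_n cos mu_n) / (mu_n - sin mu_n cos mu_n)
                 * sin(mu_n x/L) / (mu_n x/L) * exp(-mu_n^2 Fo)

    with the sin(z)/z limit taken at the centre (x/L -> 0).  ``fourier_number``
    may be an array; one term (``n_terms=1``) is the first-term approximation,
    many terms (>= 50) serve as a numerical oracle.
    """
    if not 0 <= x_over_L <= 1:
        raise ValueError("x_over_L must lie in [0, 1]")
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    fo = np.asarray(fourier_number, dtype=float)
    if np.any(fo < 0):
        raise ValueError("fourier_number must be non-negative")
    mus = roots_for_biot(biot, n_terms).roots
    s, c = np.sin(mus), np.cos(mus)
    coef = 2.0 * (s - mus * c) / (mus - s * c)
    z = mus * x_over_L
    spatial = np.where(z == 0, 1.0, np.sin(z) / np.where(z == 0, 1.0, z))
    terms = coef * spatial * np.exp(-np.outer(np.atleast_1d(fo), mus ** 2))
    out = terms.sum(axis=-1)
    return out if fo.ndim else float(out[0])
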