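"""Arrhenius temperature dependence of moisture-transport coefficients.

Both the effective diffusivity and the convective mass-transfer coefficient
follow ``k(T) = k0 * exp(-Ea / (R (T + 273.15)))`` over the 30-60 °C drying
range, so ln(k) is linear in reciprocal absolute temperature and the
activation energy falls out of an ordinary least-squares slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reference import GAS_CONSTANT

__all__ = ["ArrheniusFit", "fit_arrhenius", "predict_arrhenius"]


@dataclass(frozen=True)
class ArrheniusFit:
    """OLS fit of ln(value) on 1/(T + 273.15).

    ``pre_factor = exp(intercept)`` and
    ``activation_energy_kJ_mol = -slope * R / 1000`` by construction.
    """

    slope: float
    intercept: float
    pre_factor: float
    activation_energy_kJ_mol: float
    r2: float
    gas_constant: float = GAS_CONSTANT

    def __post_init__(self):
        if not 0 <= self.r2 <= 1 + 1e-12:
            raise ValueError("r2 must lie in [0, 1]")


def fit_arrhenius(temps_C, values) -> ArrheniusFit:
    """Fit the Arrhenius line through positive coefficients at several temperatures.

    Parameters
    ----------
    temps_C : array-like
        Temperatures in °C, at least two distinct.
    values : array-like
        Positive transport coefficients (e.g. D_eff in m^2/s or h_m in m/s).
    """
    T = np.asarray(temps_C, dtype=float)
    v = np.asarray(values, dtype=float)
    if T.shape != v.shape or T.ndim != 1:
        raise ValueError("temps_C and values must be equal-length 1-D arrays")
    if np.unique(T).size < 2:
        raise ValueError("need at least 2 distinct temperatures")
    if np.any(v <= 0):
        raise ValueError("all coefficient values must be positive")
    x = 1.0 / (T + 273.15)
    y = np.log(v)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - float(np.sum((y - yhat) ** 2)) / sst
    return ArrheniusFit(slope=float(slope), intercept=float(intercept),
                        pre_factor=float(np.exp(intercept)),
                        activation_energy_kJ_mol=float(-slope * GAS_CONSTANT / 1000.0),
                        r2=min(r2, 1.0))


def predict_arrhenius(fit: ArrheniusFit, temp_C):
    """Evaluate the fitted line: exp(intercept + slope / (T + 273.15))."""
    T = np.asarray(temp_C, dtype=float)
    out = np.exp(fit.intercept + fit.slope / (T + 273.15))
    return out if out.ndim else float(out)
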