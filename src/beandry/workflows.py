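"""End-to-end workflows composing the analysis stages.

These are the library backends of the command-line interface: drying curves
to transport/Arrhenius reports, and spectra plus cup scores to a validated
PLSR model with influential-wavelength tables.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import arrhenius as arr
from . import chemometrics as chem
from . import kinetics as kin
from .spectra import (HyperCube, ReferenceFrames, SGConfig, correct_reflectance,
                      median_profile, savgol_smooth, segment_roi, to_absorbance)

__all__ = [
    "preprocess_cube",
    "run_kinetics_workflow",
    "run_chemometrics_workflow",
]

logger = logging.getLogger(__name__)


def preprocess_cube(cube: HyperCube, refs: ReferenceFrames,
                    sg: SGConfig = SGConfig(), foreground: str = "dark",
                    sample_id: str = "", **metadata):
    """Raw cube -> smoothed absorbance profile.

    Chains reflectance calibration, Otsu ROI segmentation, per-band median
    extraction, absorbance conversion and Savitzky-Golay smoothing.
    """
    rc = correct_reflectance(cube, refs)
    mask = segment_roi(rc, foreground=foreground)
    prof = median_profile(rc, mask, sample_id=sample_id, **metadata)
    return savgol_smooth(to_absorbance(prof), sg)


def run_kinetics_workflow(curves, radius_L: float, meq_mode: str = "min",
                          meq_fixed: float | None = None,
                          m0: float | None = None,
                          predict_temps=(25, 35, 45, 55, 65, 70)):
    """Drying curves -> transport parameters, Arrhenius fits and predictions.

    Returns a dict of tidy DataFrames: ``transport`` (per temperature),
    ``arrhenius`` (per coefficient) and ``predictions`` (at ``predict_temps``).
    ``meq_mode`` selects the equilibrium moisture: the per-curve series
    minimum (``min``) or a fixed value (``fixed`` with ``meq_fixed``).
    ``m0`` is the known initial dry-basis moisture; when omitted, each
    curve's first sample is used (appropriate when sampling starts at t=0).
    """
    if not curves:
        raise ValueError("no drying curves supplied")
    if meq_mode not in ("min", "fixed"):
        raise ValueError("meq_mode must be 'min' or 'fixed'")
    if meq_mode == "fixed" and meq_fixed is None:
        raise ValueError("meq_mode='fixed' requires meq_fixed")

    params = []
    for curve in curves:
        curve = curve.to_basis("dry")
        meq = (kin.equilibrium_moisture(curve)[0] - 1e-6 if meq_mode == "min"
               else meq_fixed)
        try:
            params.append(kin.estimate_transport(curve, meq, radius_L, m0=m0))
        except ValueError as exc:
            raise ValueError(
                f"kinetics stage failed for {curve.temperature} °C "
                f"replicate {curve.replicate_id}: {exc}") from exc
    transport = pd.DataFrame(
        [{"temperature_C": p.temperature, "mu": p.mu, "d_eff_m2_s": p.d_eff,
          "biot": p.biot, "h_m_m_s": p.h_m, "fit_mse": p.fit_mse}
         for p in params]).sort_values("temperature_C", ignore_index=True)

    by_temp = transport.groupby("temperature_C").mean().reset_index()
    fits = {col: arr.fit_arrhenius(by_temp["temperature_C"], by_temp[col])
            for col in ("d_eff_m2_s", "h_m_m_s")}
    arrhenius_df = pd.DataFrame(
        [{"coefficient": name, "slope": f.slope, "intercept": f.intercept,
          "pre_factor": f.pre_factor,
          "activation_energy_kJ_mol": f.activation_energy_kJ_mol, "r2": f.r2}
         for name, f in fits.items()])
    temps = np.asarray(predict_temps, dtype=float)
    predictions = pd.DataFrame({
        "temperature_C": temps,
        "d_eff_m2_s": arr.predict_arrhenius(fits["d_eff_m2_s"], temps),
        "h_m_m_s": arr.predict_arrhenius(fits["h_m_m_s"], temps)})
    return {"transport": transport, "arrhenius": arrhenius_df,
            "predictions": predictions}


def run_chemometrics_workflow(X, y, temperatures, wavelengths_nm,
                              sample_ids=None, max_lv: int = 10,
                              folds: int = 5, cal_fraction: float = 0.7,
                              seed: int = 0, vip_threshold: float = 1.0,
                              loading_threshold: float = 0.1):
    """Spectra + cup scores -> stratified split, LV selection, fit, validation.

    Returns a dict with the fitted model, calibration/validation metrics, the
    Q2 curve and the influential-wavelength table (VIP and loading flags).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    temperatures = np.asarray(temperatures)
    if sample_ids is not None and len(sample_ids) != y.size:
        raise ValueError("sample_ids length mismatch")
    if X.shape[0] != y.size or temperatures.size != y.size:
        raise ValueError("spectra, scores and temperature labels disagree "
                         "on the number of samples")

    cal, val = chem.stratified_split(temperatures, cal_fraction, seed=seed)
    n_lv, q2_curve = chem.select_n_lv(X[cal], y[cal], max_lv=max_lv,
                                      folds=folds, seed=seed)
    if n_lv == 0:
        logger.warning("Q2 selection found no informative components; "
                       "fitting 1 LV for reporting")
        n_lv = 1
    model = chem.fit_plsr(X[cal], y[cal], n_lv, wavelengths_nm=wavelengths_nm)
    sd_cal = float(np.std(y[cal], ddof=1))
    cal_metrics = chem.metrics(y[cal], chem.predict_plsr(model, X[cal]),
                               reference_sd=sd_cal,
                               q2=float(q2_curve[n_lv - 1]),
                               set_label="calibration")
    val_metrics = chem.metrics(y[val], chem.predict_plsr(model, X[val]),
                               reference_sd=sd_cal, set_label="validation")
    vip = chem.vip_scores(model)
    loading_hit = np.any(
        np.abs(model.x_loadings[:, :min(2, model.n_lv)]) > loading_threshold,
        axis=1)
    wavelength_table = pd.DataFrame({
        "wavelength_nm": np.asarray(wavelengths_nm, dtype=float),
        "vip": vip, "vip_influential": vip > vip_threshold,
        "loading_influential": loading_hit})
    return {"model": model, "n_lv": n_lv, "q2_curve": q2_curve,
            "calibration": cal_metrics, "validation": val_metrics,
            "wavelengths": wavelength_table,
            "split": {"calibration": cal, "validation": val}}
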