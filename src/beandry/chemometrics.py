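"""PLSR cup-score modelling, wavelength selection and sensory statistics.

The spectral matrix X (samples x wavelengths, absorbance) and the cup score y
are mean-centered and decomposed by NIPALS partial least squares into latent
variables maximizing their covariance.  Influential wavelengths are flagged
by Wold's variable importance in projection (VIP > 1) and by loading
magnitude on the leading components; model quality is summarized by R2, RMSE,
cross-validated Q2 and the residual predictive deviation RPD = SD/RMSE.

The published fixed-coefficient cup-score model (two 4-wavelength components
at 480/600/720/940 nm) is provided as a standalone evaluator.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PLSRModel",
    "ModelMetrics",
    "SensoryTable",
    "EQ16_INTERCEPT",
    "EQ16_WAVELENGTHS_NM",
    "fit_plsr",
    "predict_plsr",
    "select_n_lv",
    "vip_scores",
    "influential_loadings",
    "rpd",
    "stratified_split",
    "metrics",
    "eq16_predict",
    "eq16_band_weights",
    "anova_oneway",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

#: Published cup-score model: Y = 83.14 + 0.38*Comp1 - 0.21*Comp2 with
#: Comp1/Comp2 linear in the absorbances at 480, 600, 720 and 940 nm.
EQ16_INTERCEPT = 83.14
EQ16_COMPONENT_WEIGHTS = (0.38, -0.21)
EQ16_COMP1 = (0.15, 0.09, -0.12, 0.07)
EQ16_COMP2 = (-0.08, 0.13, 0.05, -0.04)
EQ16_WAVELENGTHS_NM = (480.0, 600.0, 720.0, 940.0)

_NIPALS_TOL = 1e-12


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PLSRModel:
    """Mean-centered NIPALS decomposition with the assembled coefficient vector.

    ``beta`` acts on centered spectra: ``y_hat = y_mean + (X - x_mean) @ beta``.
    """

    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray      # p x k, unit-norm per component
    x_loadings: np.ndarray   # p x k
    y_loadings: np.ndarray   # k
    scores: np.ndarray       # n x k
    beta: np.ndarray         # p
    wavelengths_nm: np.ndarray | None = None
    residuals: np.ndarray | None = None


@dataclass(frozen=True)
class ModelMetrics:
    """Goodness-of-fit summary for one evaluation set."""

    r2: float
    rmse: float
    q2: float | None = None
    rpd: float | None = None
    set_label: str = "calibration"

    def __post_init__(self):
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")


@dataclass
class SensoryTable:
    """Long-format sensory scores: one row per (temperature, replicate)."""

    temperatures: np.ndarray
    replicates: np.ndarray
    cup_scores: np.ndarray
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.replicates = np.asarray(self.replicates)
        self.cup_scores = np.asarray(self.cup_scores, dtype=float)
        if not (self.temperatures.shape == self.replicates.shape
                == self.cup_scores.shape):
            raise ValueError("columns must have equal length")
        if np.any((self.cup_scores < 0) | (self.cup_scores > 100)):
            raise ValueError("cup scores must lie in [0, 100]")
        for name, col in self.attributes.items():
            col = np.asarray(col, dtype=float)
            if np.any((col < 0) | (col > 10)):
                raise ValueError(f"attribute {name!r} scores must lie in [0, 10]")
            self.attributes[name] = col

    def groups(self) -> list[np.ndarray]:
        """Cup scores grouped by temperature, ordered by temperature."""
        return [self.cup_scores[self.temperatures == t]
                for t in np.unique(self.temperatures)]


# ---------------------------------------------------------------------------
# PLSR core
# ---------------------------------------------------------------------------

def fit_plsr(X, y, n_lv: int, wavelengths_nm=None) -> PLSRModel:
    """NIPALS PLS1 with mean-centering and X/y deflation.

    Components whose residual covariance vanishes (X already exhausted, e.g.
    low-rank noiseless data) terminate the decomposition early with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y disagree on the number of samples")
    if np.any(~np.isfinite(X)) or np.any(~np.isfinite(y)):
        raise ValueError("missing or non-finite values are not supported")
    if np.ptp(y) == 0:
        raise ValueError("constant response: nothing to regress")
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError(f"n_lv must lie in [1, min(n-1, p)] = [1, {min(n-1, p)}]")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_mean
    f = y - y_mean
    scale0 = float(np.linalg.norm(E) * np.linalg.norm(f)) or 1.0

    W, P, Q, T = [], [], [], []
    for k in range(n_lv):
        cov = E.T @ f
        if np.linalg.norm(cov) / scale0 < _NIPALS_TOL:
            warnings.warn(f"NIPALS exhausted the data after {k} component(s); "
                          f"requested {n_lv}", stacklevel=2)
            break
        w = cov / np.linalg.norm(cov)
        t = E @ w
        tt = float(t @ t)
        p_k = E.T @ t / tt
        q_k = float(f @ t) / tt
        E = E - np.outer(t, p_k)
        f = f - q_k * t
        W.append(w)
        P.append(p_k)
        Q.append(q_k)
        T.append(t)

    W = np.column_stack(W)
    P = np.column_stack(P)
    Q = np.asarray(Q)
    T = np.column_stack(T)
    # beta on centered X: W (P'W)^-1 q
    beta = W @ np.linalg.solve(P.T @ W, Q)
    model = PLSRModel(n_lv=W.shape[1], x_mean=x_mean, y_mean=y_mean,
                      weights=W, x_loadings=P, y_loadings=Q, scores=T,
                      beta=beta,
                      wavelengths_nm=None if wavelengths_nm is None
                      else np.asarray(wavelengths_nm, dtype=float),
                      residuals=f)
    return model


def predict_plsr(model: PLSRModel, X, wavelengths_nm=None):
    """Predict responses: y_mean + centered X @ beta.

    If both the model and the query carry a wavelength grid they must match.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.x_mean.size:
        raise ValueError("wavelength grid mismatch: expected "
                         f"{model.x_mean.size} bands, got {X.shape[1]}")
    if wavelengths_nm is not None and model.wavelengths_nm is not None:
        if not np.allclose(wavelengths_nm, model.wavelengths_nm):
            raise ValueError("wavelength grid mismatch")
    return model.y_mean + (X - model.x_mean) @ model.beta


def select_n_lv(X, y, max_lv: int, folds: int = 5, seed: int = 0,
                q2_tol: float = 1e-3):
    """Choose the component count by seeded k-fold cross-validated Q2.

    Q2(k) = 1 - PRESS(k)/TSS with TSS about the full-sample mean.  Returns
    ``(n_lv, q2_curve)`` where ``n_lv`` is the smallest count attaining the
    maximum Q2 — counts whose Q2 lies within ``q2_tol`` of the maximum are
    treated as ties and the most parsimonious wins, since cross-validation
    differences at that scale are noise — or 0 (with a warning) when no
    component predicts better than the mean (max Q2 <= 0).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < folds:
        raise ValueError("need at least as many samples as folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % folds
    tss = float(np.sum((y - y.mean()) ** 2))

    max_lv = min(max_lv, min(n - int(np.bincount(fold_of).max()) - 1, X.shape[1]))
    press = np.zeros(max_lv)
    for f in range(folds):
        tr, te = fold_of != f, fold_of == f
        for k in range(1, max_lv + 1):
            m = fit_plsr(X[tr], y[tr], k)
            yhat = predict_plsr(m, X[te])
            press[k - 1] += float(np.sum((yhat - y[te]) ** 2))
    q2 = 1.0 - press / tss
    if q2.max() <= 0:
        warnings.warn("no informative components: max Q2 <= 0", stacklevel=2)
        return 0, q2
    # smallest k attaining the maximum, with near-ties resolved to parsimony
    best = int(np.argmax(q2 >= q2.max() - q2_tol)) + 1
    return best, q2


def vip_scores(model: PLSRModel) -> np.ndarray:
    """Wold's variable importance in projection.

    VIP_j = sqrt( p * sum_k SS_k (w_jk/||w_k||)^2 / sum_k SS_k ) with
    SS_k = q_k^2 t_k't_k the y-variance explained by component k; the mean of
    squared VIPs is exactly 1.
    """
    W = model.weights
    p, k = W.shape
    ss = model.y_loadings ** 2 * np.einsum("ij,ij->j", model.scores, model.scores)
    wnorm2 = (W / np.linalg.norm(W, axis=0)) ** 2
    return np.sqrt(p * (wnorm2 @ ss) / ss.sum())


def influential_loadings(model: PLSRModel, threshold: float = 0.1,
                         components: int = 2) -> np.ndarray:
    """Wavelengths with |x-loading| above ``threshold`` in the first components.

    Returns wavelengths when the model carries a grid, else band indices.
    """
    if components > model.x_loadings.shape[1]:
        raise ValueError("components exceeds the fitted latent-variable count")
    hit = np.any(np.abs(model.x_loadings[:, :components]) > threshold, axis=1)
    idx = np.flatnonzero(hit)
    if model.wavelengths_nm is not None:
        return model.wavelengths_nm[idx]
    return idx


def rpd(reference_sd: float, rmse_pred: float) -> float:
    """Residual predictive deviation SD/RMSE of prediction."""
    if rmse_pred <= 0:
        raise ValueError("rmse_pred must be positive")
    return reference_sd / rmse_pred


def stratified_split(labels, cal_fraction: float = 0.7, seed: int = 0):
    """Per-stratum random calibration/validation split of sample indices.

    Within each stratum (e.g. drying temperature) the calibration size is
    rounded half-up from ``cal_fraction * n``.  Deterministic for a given
    seed; the two index arrays partition ``range(len(labels))``.
    """
    labels = np.asarray(labels)
    if not 0 < cal_fraction < 1:
        raise ValueError("cal_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    cal, val = [], []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size < 2:
            raise ValueError(f"stratum {lab!r} has fewer than 2 samples")
        n_cal = int(np.floor(cal_fraction * idx.size + 0.5))
        n_cal = min(max(n_cal, 1), idx.size - 1)
        perm = rng.permutation(idx)
        cal.append(perm[:n_cal])
        val.append(perm[n_cal:])
    return np.sort(np.concatenate(cal)), np.sort(np.concatenate(val))


def metrics(y_true, y_pred, reference_sd: float | None = None,
            q2: float | None = None, set_label: str = "calibration") -> ModelMetrics:
    """R2, RMSE and optionally RPD of predictions against reference values."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size or y_true.size < 2:
        raise ValueError("need equal-length arrays of at least 2 values")
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    if sst == 0:
        raise ValueError("zero-variance reference values: R2 undefined")
    sse = float(np.sum((y_true - y_pred) ** 2))
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    return ModelMetrics(r2=1.0 - sse / sst, rmse=rmse, q2=q2,
                        rpd=None if reference_sd is None else rpd(reference_sd, rmse)
                        if rmse > 0 else None,
                        set_label=set_label)


# ---------------------------------------------------------------------------
# published cup-score model and sensory ANOVA
# ---------------------------------------------------------------------------

def eq16_predict(abs480, abs600, abs720, abs940):
    """Published fixed-coefficient cup-score model on four band absorbances.

    Two intermediate components combine the absorbances; the score is affine
    in them: Y = 83.14 + 0.38*Comp1 - 0.21*Comp2.
    """
    a = np.broadcast_arrays(*(np.asarray(v, dtype=float)
                              for v in (abs480, abs600, abs720, abs940)))
    comp1 = sum(c * v for c, v in zip(EQ16_COMP1, a))
    comp2 = sum(c * v for c, v in zip(EQ16_COMP2, a))
    out = (EQ16_INTERCEPT + EQ16_COMPONENT_WEIGHTS[0] * comp1
           + EQ16_COMPONENT_WEIGHTS[1] * comp2)
    return out if np.ndim(out) else float(out)


def eq16_band_weights() -> np.ndarray:
    """Effective per-band weights of the published model, d(score)/d(absorbance)."""
    g1, g2 = EQ16_COMPONENT_WEIGHTS
    return np.array([g1 * c1 + g2 * c2
                     for c1, c2 in zip(EQ16_COMP1, EQ16_COMP2)])


def anova_oneway(groups):
    """One-way ANOVA over replicate cup scores grouped by temperature.

    Returns ``(F, p, (df_between, df_within))``.  Identical constant groups
    (no variance anywhere) are reported as F=0, p=1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    df_b = len(groups) - 1
    df_w = sum(g.size for g in groups) - len(groups)
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:
        return 0.0, 1.0, (df_b, df_w)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*groups)
    if not np.isfinite(f):  # zero within-group variance, nonzero between
        return float("inf"), 0.0, (df_b, df_w)
    return float(f), float(p), (df_b, df_w)


# ---------------------------------------------------------------------------
# model serialization
# ---------------------------------------------------------------------------

def save_model(model: PLSRModel, path):
    """Serialize a fitted model to portable JSON."""
    payload = {
        "n_lv": model.n_lv,
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "weights": model.weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "beta": model.beta.tolist(),
        "wavelengths_nm": None if model.wavelengths_nm is None
        else model.wavelengths_nm.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> PLSRModel:
    """Load a model saved by :func:`save_model` (scores/residuals not kept)."""
    with open(path) as fh:
        d = json.load(fh)
    return PLSRModel(
        n_lv=d["n_lv"], x_mean=np.asarray(d["x_mean"]), y_mean=d["y_mean"],
        weights=np.asarray(d["weights"]), x_loadings=np.asarray(d["x_loadings"]),
        y_loadings=np.asarray(d["y_loadings"]),
        scores=np.empty((0, d["n_lv"])), beta=np.asarray(d["beta"]),
        wavelengths_nm=None if d["wavelengths_nm"] is None
        else np.asarray(d["wavelengths_nm"]))
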