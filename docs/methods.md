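# Methods

## Drying kinetics: the first-term sphere inverse problem

A bean drying in hot air at constant temperature is treated as a homogeneous
sphere of radius `L` losing moisture by Fickian diffusion with convective
exchange at its surface. The dimensionless moisture ratio

    MR(t) = (M(t) - Meq) / (M0 - Meq)

at the surface is an eigenfunction series in the positive roots `mu_n` of the
transcendental equation `1 - mu*cot(mu) = Bi`, where `Bi = h_m L / D_eff` is
the mass-transfer Biot number. Root `n` lies strictly inside
`((n-1)*pi, n*pi)` (the brackets are the vertical asymptotes of
`1 - mu*cot(mu)`), so each is found by plain bisection, iterated until the
bracket width falls below 1e-12 (at most 60 iterations).

At Fourier numbers `Fo = D_eff t / L^2` large enough that the first term
dominates, `ln(MR)` is linear in time:

    ln MR(t) = b(mu) + a t,
    a = -mu^2 D_eff / L^2,
    b(mu) = ln[ 2 sin(mu) (sin(mu) - mu cos(mu)) / (mu (mu - sin(mu) cos(mu))) ]

with the spatial factor evaluated at the surface (`x/L = 1`). The inverse
chain is then: ordinary least squares of `ln(MR)` on time in seconds gives
`(a, b)`; `b` is inverted for `mu` by bisection (the intercept function is
strictly decreasing on `(0, pi)`); `Bi = 1 - mu*cot(mu)`;
`D_eff = |a| L^2 / mu^2`; `h_m = Bi D_eff / L`. Every derived quantity is
exact algebra once `mu` is known, so `h_m L = Bi D_eff` holds identically.

Assumptions inherited from the model: isothermal drying, constant
diffusivity, no shrinkage, spherical geometry. Times are converted hours to
seconds before fitting so that `D_eff` comes out in m²/s.

### The characteristic length

The source text prints `L = 0.003968 m` as the mean bean radius, but the
published transport tables are reproducible from the published drying-line
coefficients only with `L = 3.968e-4 m` — a factor-100 inconsistency. The
package default is `3.968e-4 m` (it reproduces the tables), `L` is a
required explicit parameter everywhere, and no claim is made about which
number is the physically measured radius.

### Initial moisture

Because the first-term line does not pass through `M0` at `t = 0`, the
intercept carries information only if `M0` is known independently (it was
measured gravimetrically in the study: 45% wet basis = 81.82% dry basis).
`moisture_ratio`, `estimate_transport` and the kinetics workflow therefore
accept an explicit `m0`, defaulting to the first sample's moisture, which is
appropriate only when sampling starts at `t = 0`. Points at or below `Meq`
are dropped with a logged count rather than erroring, since meter noise can
cross the asymptote.

### Critical and equilibrium moisture

The drying rate is the first difference of moisture over time, paired with
interval-midpoint moisture. The constant-rate/falling-rate transition is
located by exhaustive two-segment piecewise-linear least squares over all
interior partitions (at least two points per segment); a transition is
reported only when the segmented fit reduces the single-line SSE by at least
a factor of 2 (F-ratio guard), which makes the procedure deterministic and
testable against planted breakpoints. Equilibrium moisture is the series
minimum, with the plateau-entry time reported at an absolute tolerance of
0.1% moisture.

## Arrhenius modelling

Both transport coefficients follow
`k(T) = k0 exp(-Ea / (R (T + 273.15)))` over 30-60 °C; an OLS fit of
`ln(k)` on reciprocal absolute temperature gives `Ea = -slope * R` with
`R = 8.31446 J/(mol K)`. The pre-factor is computed from the fitted
intercept, `k0 = exp(intercept)`. Note: the source's summary table prints
`h0 = 7.006e-8 m/s` next to intercept −11.869, but `exp(-11.869) = 7.006e-6`
and the published predicted `h_m` values are consistent only with `1e-6` —
the printed exponent is treated as a typo.

When reproducing the published summaries, the fits are run on the *printed*
per-temperature transport values, not on re-estimated ones, isolating
rounding drift; both paths are available.

## Hyperspectral pipeline

1. **Reflectance calibration** `Rc = (S - D)/(W - D)` against white/dark
   reference frames; per-column line references (1 x W x B) broadcast over
   rows, as push-broom systems calibrate per column. Pixels without white
   headroom (`W - D <= 1e-9`) are masked NaN and excluded downstream;
   negative corrected values are clipped to zero.
2. **Segmentation**: Otsu threshold on the band-averaged reflectance image;
   the foreground is the lower-reflectance class by default (dark beans on a
   bright stage), invertible by flag. The threshold is logged. A uniform
   image raises.
3. **Extraction**: per-band median over the masked pixels (median rather
   than mean for robustness to specular/hot pixels).
4. **Absorbance** `A = -log10(R)` (decadic Beer-Lambert convention; the log
   base is configurable since the downstream regression is scale-equivariant
   after centering). Only non-positive reflectances are floored (at 1e-6,
   with a warning); small positive values pass through, so deep absorbances
   are representable.
5. **Savitzky-Golay smoothing**, default window 23, order 2. Interior points
   use the standard convolution coefficients; edge points are refit within
   the truncated window, which preserves exactness on polynomials of degree
   <= 2 everywhere (mirror padding would not).

No scatter correction or derivative spectra are applied. The optional
"normalization" step of the original workflow is unspecified there and is
left off by default.

## PLSR and wavelength selection

PLS1 by NIPALS with X and y mean-centering (no autoscaling) and deflation of
both X and y; the coefficient vector is assembled as
`beta = W (P'W)^{-1} q`, acting on centered spectra. Successive score
vectors are mutually orthogonal; components are terminated early with a
warning when the residual covariance vanishes (noiseless low-rank data).

The component count is chosen by seeded 5-fold cross-validation maximizing
`Q2 = 1 - PRESS/TSS` (TSS about the full-sample mean). Q2 values within
`q2_tol = 1e-3` of the maximum are treated as ties resolved to the smallest
model: cross-validation differences below that scale are fold noise, and the
strict argmax systematically overselects by one or two components on
low-noise data. When no component beats the mean (max Q2 <= 0) the selection
reports zero with a warning.

Influential wavelengths are flagged by Wold's VIP
(`VIP_j = sqrt(p * sum_k SS_k (w_jk/||w_k||)^2 / sum_k SS_k)`, with `SS_k`
the y-variance explained by component k; mean squared VIP is exactly 1) at
the conventional VIP > 1 cut, and independently by |loading| > 0.1 on the
first two components. Calibration/validation splitting is stratified by
drying temperature, 70/30 with per-stratum round-half-up, seeded. Model
quality: R², RMSE, Q², and `RPD = SD(reference)/RMSE`.

The published four-band cup-score model
(`Y = 83.14 + 0.38*Comp1 - 0.21*Comp2`, with Comp1/Comp2 fixed linear
combinations of the absorbances at 480/600/720/940 nm) is implemented as a
standalone evaluator with the printed coefficients; it is not derived from
the fitted PLSR model, since no derivation connecting the two is available.

## Synthetic data: what it emulates and what it does not

**Drying curves** are forward evaluations of the sphere series at the
surface (1 term = the model being fitted; >= 50 terms = an independent
numerical oracle), with Gaussian noise applied to moisture — the instrument
domain — not to the log ratio. With one term the first sample is generated
at `t = dt` (`Fo > 0`); with many terms the series is evaluated from `t = 0`.
Defaults mirror the study conditions: sampling every 2 h, durations
52/34/30/20 h at 30/40/50/60 °C, `M0 = 81.82%`, `Meq ~ 13.64%` dry basis.

**Cubes**: per sample a cup score is drawn from N(83.4, 1.5²) truncated to
[80, 88]; four Gaussian absorbance features at 480/600/720/940 nm are
planted on a flat baseline inside an elliptical "bean" on a brighter stage,
with matching flat white/dark reference frames, and per-pixel Gaussian noise
added in absorbance. The feature amplitudes are solved so that the published
four-band model evaluated on the *smoothed* absorbances at the four centers
returns exactly the drawn score:

* the four target absorbances are `baseline + beta * sign(w_j)`, where `w`
  is the model's effective band-weight vector and `beta` scales with the
  score. The sign-matched equal-magnitude direction is chosen over the
  least-squares direction (proportional to `w`) so that *all four* bands
  carry equal score-linked variance — under the least-squares direction the
  600 and 940 nm bands, whose effective weights are tiny, would never reach
  VIP > 1;
* the planted amplitudes pre-compensate the Savitzky-Golay response via a
  4x4 linear solve of the smoothed unit-peak responses at the centers, so
  the linkage is exact after the full pipeline. Peak FWHM defaults to 60 nm:
  the (23, 2) filter on the ~5.4 nm grid attenuates a 30 nm peak to 0.54 of
  its height, which would force the compensated pre-smoothing absorbance
  negative, while 60 nm (attenuation 0.85, negligible inter-peak cross-talk)
  leaves the inversion feasible;
* the baseline absorbance defaults to 50 — far above any physical scale —
  because the published model's effective band weights sum to only ~0.17 in
  absolute value, so spanning a ±4-point score range requires band
  absorbance swings of ~±45. The generator targets statistical structure
  (linear score linkage, band placement, segmentation geometry, calibration
  arithmetic), not radiometric realism. For the same reason the synthetic
  dark reference is exactly zero and cubes are serialized in float64:
  reflectances as small as 1e-90 must survive the raw-signal encoding.

Consequently, passing tests demonstrate that the pipeline is exact and that
planted signal is recovered under the stated noise; they say nothing about
instrument artifacts (stray light, wavelength miscalibration, scatter) or
about chemistry-driven spectra of real beans.

**Sensory tables** draw replicate cup scores per temperature from the
published means and spreads (clipped to [0, 100]). The resulting one-way
ANOVA is non-significant at a rate near the 5% size of the F test; note that
a "non-significant in >= 95% of seeds" check is at the edge of attainability
by construction, since the test's own false-positive rate is 5% before any
mean differences are added.

## Numerical choices

* Bisection everywhere a transcendental root is needed: deterministic,
  bracket-safe, tolerance 1e-12 bracket width / 60 iterations.
* The intercept inversion brackets on `(1e-6, pi - 1e-9)`, shrinking the
  lower endpoint when needed; `b >= 0` is a domain error (no root).
* OLS via `numpy.polyfit`; ANOVA via `scipy.stats.f_oneway` with the
  all-constant case mapped to `F = 0, p = 1` and zero within-group variance
  to `F = inf, p = 0`.
* Degenerate inputs raise `ValueError` with a stage-specific message; the
  CLI exits non-zero on any stage failure.

## Problem sizes used by the test suite

Synthetic recovery tests run at deliberately small scale: cubes of
16x16-32x32 pixels x 112 bands, 12-80 samples, 10-seed Monte-Carlo for VIP
recovery, 100-200 seeds for scalar Monte-Carlo checks (drying-noise
recovery, ANOVA rates). The entire suite runs in well under a minute.

## Known limitations

* Only the analytical sphere solution: no shrinkage, non-isothermal or
  moisture-dependent-diffusivity models; no 2-D/3-D simulation.
* The published transport table carries ~0.01-0.15% internal inconsistency
  in its diffusivity column (its own D-solve wobble); exact algebra here
  reproduces mu and Biot to 6-7 significant figures but cannot reproduce the
  two 30 °C transport cells beyond that inconsistency.
* The PLSR performance of the original study on real spectra is not
  reproducible (raw data not deposited); synthetic-recovery properties stand
  in for it.
* The ENVI reader covers plain uncompressed BIL/BIP/BSQ pairs only.
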