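"""Published reference values for Caturra coffee convective drying (30-60 °C).

These constants are the printed results of the source study's thin-layer
drying experiments and serve as regression fixtures and as inputs when the
raw time series (which were never deposited) are unavailable: linearized
drying-line coefficients per temperature, the transport parameters derived
from them, the eigenvalue table of the sphere solution, and the Arrhenius
summaries.
"""

from __future__ import annotations

#: Mean bean radius (m) that reproduces the published transport tables.
#: The study's text also prints 0.003968 m; the factor-100 inconsistency is
#: documented in docs/methods.md.  L is always an explicit parameter.
BEAN_RADIUS_M = 3.968e-4

#: Universal gas constant as used by the Arrhenius fits, J mol^-1 K^-1.
GAS_CONSTANT = 8.31446

#: Drying air temperatures evaluated, °C.
TEMPERATURES_C = (30.0, 40.0, 50.0, 60.0)

#: Published drying times (h) until the equilibrium moisture was reached.
DRYING_TIMES_H = {30.0: 52.0, 40.0: 34.0, 50.0: 30.0, 60.0: 20.0}

#: Linearized drying-line coefficients per temperature:
#: slope a (1/s) and intercept b (dimensionless) of ln(MR) = a t + b.
DRYING_LINE_COEFFS = {
    30.0: (-1.46982169e-5, -0.59745164),
    40.0: (-2.01117947e-5, -0.67151457),
    50.0: (-2.48775171e-5, -0.44401679),
    60.0: (-3.39803574e-5, -0.49186182),
}

#: Published mean-squared errors of the drying-line fits (not reproducible
#: without the raw series; treated as inputs).
DRYING_LINE_MSE = {30.0: 0.30508460, 40.0: 0.23127388,
                   50.0: 0.26330223, 60.0: 0.21446990}

#: Published transport parameters per temperature:
#: (mu, d_eff in 1e-13 m^2/s, biot, h_m in 1e-9 m/s).
TRANSPORT_TABLE = {
    30.0: (2.256442, 4.538592, 2.845864, 3.255095),
    40.0: (2.333156, 5.817569, 3.228052, 4.732716),
    50.0: (2.058683, 9.245937, 2.092496, 4.875778),
    60.0: (2.127121, 11.821655, 2.322733, 6.919997),
}

#: Published first six roots of 1 - mu*cot(mu) = Biot per Biot value.
EIGENVALUE_TABLE = {
    2.8459: (2.2564, 5.0621, 8.0786, 11.1595, 14.2659, 17.3845),
    3.2281: (2.3332, 5.1227, 8.1217, 11.1921, 14.2918, 17.4061),
    2.0925: (2.0587, 4.9304, 7.9899, 11.0937, 14.2139, 17.3417),
    2.3227: (2.1271, 4.9724, 8.0175, 11.1140, 14.2299, 17.3548),
}

#: Published Arrhenius summaries: slope, intercept, activation energy
#: (kJ/mol) and r^2 for ln(D_EFF) and ln(h_m) vs 1/(T+273.15).
ARRHENIUS_TABLE = {
    "d_eff": {"slope": -3369.5, "intercept": -17.343,
              "activation_energy_kJ_mol": 28.016, "r2": 0.983},
    "h_m": {"slope": -2317.9, "intercept": -11.869,
            "activation_energy_kJ_mol": 19.272, "r2": 0.923},
}

#: Published Arrhenius predictions: temperature °C -> (D_EFF m^2/s, h_m m/s).
ARRHENIUS_PREDICTIONS = {
    25.0: (3.652e-13, 2.957e-9),
    35.0: (5.268e-13, 3.804e-9),
    45.0: (7.426e-13, 4.818e-9),
    55.0: (1.025e-12, 6.014e-9),
    65.0: (1.389e-12, 7.410e-9),
    70.0: (1.605e-12, 8.188e-9),
}

#: Published cup-score summary per drying temperature: (mean, sd of 18
#: taster x replicate scores, n replicates cupped).
CUP_SCORE_TABLE = {
    30.0: (83.2, 1.66, 3),
    40.0: (83.5, 1.45, 3),
    50.0: (83.6, 0.88, 3),
    60.0: (83.26, 1.71, 3),
}

#: Range of observed cup scores across treatments.
CUP_SCORE_RANGE = (80.0, 88.0)
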