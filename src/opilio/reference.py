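"""Published reference values from the two-year snow crab ocean-acidification
experiment that this package reimplements the analysis of.

These tables are inputs: the best-fit survival parameters drive the synthetic
experiment generator at the study's design scale, and the water-tank
conditions feed the carbonate solver.  Treatment labels follow the study's
convention ("Ambient" ~ pH 8.1, "pH 7.8", "pH 7.5").
"""

from __future__ import annotations

from .survival import DEFAULT_LEVELS

#: Experimental design of each year's starvation-survival experiment:
#: 3 embryo x 3 larval pH treatments, 5 replicate inserts per cell,
#: 20 larvae per insert, censored at 7 weeks.
DESIGN_SCALE = {"inserts_per_cell": 5, "larvae_per_insert": 20, "max_day": 49}

_CELLS = [(e, l) for e in DEFAULT_LEVELS for l in DEFAULT_LEVELS]

# Best-fit full-interaction model parameters, per (embryo, larval) cell,
# embryo-major order Ambient, pH 7.8, pH 7.5.
_T50_YEAR1 = [6.20, 6.75, 6.69, 4.02, 5.86, 5.15, 4.90, 6.49, 5.36]
_S_YEAR1 = [-3.06, -2.92, -2.89, -2.92, -2.48, -3.21, -4.38, -3.69, -3.61]
_T50_YEAR2 = [7.75, 7.65, 7.81, 7.95, 9.27, 8.05, 7.82, 8.15, 9.03]
_S_YEAR2 = [-3.32, -3.92, -3.78, -3.92, -4.85, -3.98, -3.21, -3.74, -3.27]

#: ``SURVIVAL_PARAMS[year][(embryo, larval)] = (t50 days, slope s)``
SURVIVAL_PARAMS: dict[int, dict[tuple[str, str], tuple[float, float]]] = {
    1: {c: (t, s) for c, t, s in zip(_CELLS, _T50_YEAR1, _S_YEAR1)},
    2: {c: (t, s) for c, t, s in zip(_CELLS, _T50_YEAR2, _S_YEAR2)},
}

#: Mean measured conditions in the female holding tanks, per treatment:
#: temperature degC, pH (free scale), DIC mmol/kg, TA mmol/kg.  Salinity was
#: not reported; analyses assume 32 PSU.
FEMALE_TANK_CONDITIONS = {
    "Ambient": {"temperature": 2.09, "ph_free": 8.11, "dic": 2.01, "ta": 2.11},
    "pH 7.8": {"temperature": 1.97, "ph_free": 7.80, "dic": 2.09, "ta": 2.09},
    "pH 7.5": {"temperature": 2.05, "ph_free": 7.50, "dic": 2.15, "ta": 2.11},
}

#: Published derived chemistry for the same tanks (mean, SD) for
#: cross-checking the solver: pCO2 uatm, HCO3/CO3 mmol/kg, saturation states.
FEMALE_TANK_DERIVED = {
    "Ambient": {"pco2": (362.18, 68.33), "hco3": (1.90, 0.05), "co3": (0.09, 0.02),
                "omega_aragonite": (1.36, 0.23), "omega_calcite": (2.19, 0.37)},
    "pH 7.8": {"pco2": (760.98, 43.95), "hco3": (2.00, 0.04), "co3": (0.05, 0.005),
               "omega_aragonite": (0.69, 0.04), "omega_calcite": (1.11, 0.06)},
    "pH 7.5": {"pco2": (1548.29, 102.11), "hco3": (2.04, 0.06), "co3": (0.02, 0.005),
               "omega_aragonite": (0.36, 0.02), "omega_calcite": (0.57, 0.04)},
}

#: Larval-tank conditions for the two experiment years (same layout).
LARVAL_TANK_CONDITIONS = {
    2015: {
        "Ambient": {"temperature": 3.40, "ph_free": 8.16, "dic": 1.98, "ta": 2.12},
        "pH 7.8": {"temperature": 3.17, "ph_free": 7.80, "dic": 2.08, "ta": 2.12},
        "pH 7.5": {"temperature": 3.36, "ph_free": 7.50, "dic": 2.16, "ta": 2.12},
    },
    2016: {
        "Ambient": {"temperature": 2.77, "ph_free": 8.14, "dic": 1.98, "ta": 2.12},
        "pH 7.8": {"temperature": 2.59, "ph_free": 7.80, "dic": 2.08, "ta": 2.13},
        "pH 7.5": {"temperature": 2.75, "ph_free": 7.50, "dic": 2.14, "ta": 2.12},
    },
}

LARVAL_TANK_DERIVED = {
    2015: {
        "Ambient": {"pco2": (314.79, 31.00), "hco3": (1.86, 0.02)},
        "pH 7.8": {"pco2": (751.58, 24.49), "hco3": (1.99, 0.01)},
        "pH 7.5": {"pco2": (1526.01, 54.95), "hco3": (2.05, 0.01)},
    },
    2016: {
        "Ambient": {"pco2": (322.23, 32.83), "hco3": (1.86, 0.02)},
        "pH 7.8": {"pco2": (768.68, 24.26), "hco3": (1.99, 0.01)},
        "pH 7.5": {"pco2": (1556.47, 59.39), "hco3": (2.02, 0.02)},
    },
}

#: Year-1 larval morphometric treatment means (mm), per embryo treatment,
#: variables CW (carapace width), LSL (lateral spine), DSL (dorsal spine),
#: RDL (rostro-dorsal), RSL (rostral spine), PL (protopodite).
MORPHOMETRIC_VARS = ("CW", "LSL", "DSL", "RDL", "RSL", "PL")
MORPHOMETRIC_MEANS_YEAR1 = {
    "Ambient": {"CW": 2.89, "LSL": 0.965, "DSL": 2.25, "RDL": 5.24, "RSL": 1.67, "PL": 1.68},
    "pH 7.8": {"CW": 2.73, "LSL": 0.884, "DSL": 2.20, "RDL": 5.20, "RSL": 1.74, "PL": 1.83},
    "pH 7.5": {"CW": 2.68, "LSL": 0.84, "DSL": 2.14, "RDL": 5.07, "RSL": 1.67, "PL": 1.76},
}
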