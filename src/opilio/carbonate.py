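"""Seawater CO2-system solver.

Solves the marine carbonate system from a measured pair — (pH on the free
scale, DIC) for the daily probe records, or (TA, DIC) for the weekly bottle
samples — at a given temperature and salinity, and reports the derived
quantities an acidification experiment tracks: pCO2, carbonate speciation,
total alkalinity and the aragonite/calcite saturation states.

Formulations
------------
The dissociation constants follow the widely used "Lueker set":

* K1, K2 : Lueker, Dickson & Keeling (2000) refit of Mehrbach, total scale
* K0     : Weiss (1974) CO2 solubility, with the Weiss fugacity correction
* KB     : Dickson (1990b), total scale
* KW     : Millero (1995), total scale
* KS     : Dickson (1990a), free scale
* KF     : Perez & Fraga (1987)
* Ksp    : Mucci (1983) for aragonite and calcite
* B_T    : Lee et al. (2010); S_T Morris & Riley; F_T Riley (1965)
* [Ca2+] : Riley & Tongudai (1967), proportional to salinity

All concentrations are handled internally in mol/kg-solution; the public
interface uses mmol/kg for DIC/TA/speciation (the scale on which such data
are usually reported) and uatm for pCO2.  Pressure is fixed at the surface
and nutrient (phosphate/silicate) alkalinity is taken as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ConstantSet",
    "WaterSample",
    "CarbonateState",
    "equilibrium_constants",
    "solve_from_ph_dic",
    "solve_from_ta_dic",
    "omega",
    "ph_scale_convert",
]

PH_SCALES = ("free", "total", "seawater")

#: Default salinity (PSU) when a record does not carry one.  Coastal Gulf of
#: Alaska surface water sits near 32; every solver output records the value
#: actually used.
DEFAULT_SALINITY = 32.0

_T_RANGE = (-2.0, 40.0)
_S_RANGE = (0.0, 45.0)


@dataclass(frozen=True)
class ConstantSet:
    """Equilibrium constants and total concentrations at (T, S), surface pressure.

    K1/K2/KB/KW are on the total proton scale; KS is on the free scale.
    Units: K0 in mol/kg/atm; K1, K2, KB, KS, KF in mol/kg; KW in (mol/kg)^2;
    Ksp in (mol/kg)^2; totals in mol/kg.
    """

    temperature: float
    salinity: float
    K0: float
    K1: float
    K2: float
    KB: float
    KW: float
    KS: float
    KF: float
    Ksp_aragonite: float
    Ksp_calcite: float
    boron_total: float
    sulfate_total: float
    fluoride_total: float
    calcium: float
    fugacity_factor: float


@dataclass
class WaterSample:
    """One water-chemistry record: measured quantities only.

    DIC and TA are in mmol/kg; pH is on the free scale; either pH or TA
    may be absent (None) depending on which pair was measured.
    """

    temperature: float
    salinity: float = DEFAULT_SALINITY
    ph_free: float | None = None
    dic: float | None = None
    ta: float | None = None

    def __post_init__(self) -> None:
        if not (_S_RANGE[0] < self.salinity < _S_RANGE[1]):
            raise ValueError(f"salinity {self.salinity} outside (0, 45) PSU")
        if not (_T_RANGE[0] <= self.temperature <= _T_RANGE[1]):
            raise ValueError(f"temperature {self.temperature} outside [-2, 40] degC")
        for name in ("dic", "ta"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")


@dataclass
class CarbonateState:
    """Fully solved CO2 system for one sample.  Species in mmol/kg, pCO2 in uatm."""

    temperature: float
    salinity: float
    ph_free: float
    ph_total: float
    ph_seawater: float
    pco2: float
    fco2: float
    co2_star: float
    hco3: float
    co3: float
    dic: float
    ta: float
    omega_aragonite: float
    omega_calcite: float
    constants: ConstantSet = field(repr=False, default=None)


def equilibrium_constants(temperature: float, salinity: float) -> ConstantSet:
    """Evaluate the full constant set at ``temperature`` (degC) and ``salinity`` (PSU)."""
    T, S = float(temperature), float(salinity)
    if not (_T_RANGE[0] <= T <= _T_RANGE[1]):
        raise ValueError(f"temperature {T} outside [-2, 40] degC")
    if not (_S_RANGE[0] < S < _S_RANGE[1]):
        raise ValueError(f"salinity {S} outside (0, 45) PSU")

    Tk = T + 273.15
    lnTk = math.log(Tk)
    sqS = math.sqrt(S)

    # CO2 solubility, Weiss (1974), mol/kg/atm
    lnK0 = (
        -60.2409
        + 93.4517 * (100.0 / Tk)
        + 23.3585 * math.log(Tk / 100.0)
        + S * (0.023517 - 0.023656 * (Tk / 100.0) + 0.0047036 * (Tk / 100.0) ** 2)
    )
    K0 = math.exp(lnK0)

    # Fugacity factor (Weiss 1974 virial expression), 1 atm total pressure
    B_virial = -1636.75 + 12.0408 * Tk - 0.0327957 * Tk**2 + 3.16528e-5 * Tk**3
    delta = 57.7 - 0.118 * Tk
    R_bar = 83.14462618  # cm3 bar / (mol K)
    fugacity_factor = math.exp((B_virial + 2.0 * delta) * 1.01325 / (R_bar * Tk))

    # Carbonic acid, Lueker et al. (2000), total scale
    pK1 = 3633.86 / Tk - 61.2172 + 9.6777 * lnTk - 0.011555 * S + 0.0001152 * S**2
    pK2 = 471.78 / Tk + 25.929 - 3.16967 * lnTk - 0.01781 * S + 0.0001122 * S**2
    K1 = 10.0 ** (-pK1)
    K2 = 10.0 ** (-pK2)

    # Boric acid, Dickson (1990b), total scale
    lnKB = (
        (-8966.90 - 2890.53 * sqS - 77.942 * S + 1.728 * S * sqS - 0.0996 * S**2) / Tk
        + 148.0248
        + 137.1942 * sqS
        + 1.62142 * S
        + (-24.4344 - 25.085 * sqS - 0.2474 * S) * lnTk
        + 0.053105 * sqS * Tk
    )
    KB = math.exp(lnKB)

    # Water, Millero (1995), total scale
    lnKW = (
        148.9802
        - 13847.26 / Tk
        - 23.6521 * lnTk
        + (118.67 / Tk - 5.977 + 1.0495 * lnTk) * sqS
        - 0.01615 * S
    )
    KW = math.exp(lnKW)

    # Bisulfate, Dickson (1990a), free scale, ionic strength form
    IS = 19.924 * S / (1000.0 - 1.005 * S)
    sqIS = math.sqrt(IS)
    lnKS = (
        -4276.1 / Tk
        + 141.328
        - 23.093 * lnTk
        + (-13856.0 / Tk + 324.57 - 47.986 * lnTk) * sqIS
        + (35474.0 / Tk - 771.54 + 114.723 * lnTk) * IS
        - (2698.0 / Tk) * IS * sqIS
        + (1776.0 / Tk) * IS**2
        + math.log(1.0 - 0.001005 * S)
    )
    KS = math.exp(lnKS)

    # Hydrogen fluoride, Perez & Fraga (1987), total scale
    lnKF = 874.0 / Tk - 9.68 + 0.111 * sqS
    KF = math.exp(lnKF)

    # Solubility products, Mucci (1983)
    log10Tk = math.log10(Tk)
    logKsp_cal = (
        -171.9065
        - 0.077993 * Tk
        + 2839.319 / Tk
        + 71.595 * log10Tk
        + (-0.77712 + 0.0028426 * Tk + 178.34 / Tk) * sqS
        - 0.07711 * S
        + 0.0041249 * S * sqS
    )
    logKsp_ar = (
        -171.945
        - 0.077993 * Tk
        + 2903.293 / Tk
        + 71.595 * log10Tk
        + (-0.068393 + 0.0017276 * Tk + 88.135 / Tk) * sqS
        - 0.10018 * S
        + 0.0059415 * S * sqS
    )

    return ConstantSet(
        temperature=T,
        salinity=S,
        K0=K0,
        K1=K1,
        K2=K2,
        KB=KB,
        KW=KW,
        KS=KS,
        KF=KF,
        Ksp_aragonite=10.0**logKsp_ar,
        Ksp_calcite=10.0**logKsp_cal,
        boron_total=0.0004326 * S / 35.0,  # Lee et al. (2010)
        sulfate_total=(0.14 / 96.062) * (S / 1.80655),  # Morris & Riley (1966)
        fluoride_total=(0.000067 / 18.998) * (S / 1.80655),  # Riley (1965)
        calcium=(0.02128 / 40.087) * (S / 1.80655),  # Riley & Tongudai (1967)
        fugacity_factor=fugacity_factor,
    )


def ph_scale_convert(ph: float, from_scale: str, to_scale: str, constants: ConstantSet) -> float:
    """Convert a pH value between the free, total and seawater proton scales."""
    for scale in (from_scale, to_scale):
        if scale not in PH_SCALES:
            raise ValueError(f"unknown pH scale {scale!r}; expected one of {PH_SCALES}")
    st, ft = constants.sulfate_total, constants.fluoride_total
    free_to_total = math.log10(1.0 + st / constants.KS)
    free_to_sws = math.log10(1.0 + st / constants.KS + ft / constants.KF)
    # express input as free-scale pH first
    if from_scale == "total":
        ph_free = ph + free_to_total
    elif from_scale == "seawater":
        ph_free = ph + free_to_sws
    else:
        ph_free = ph
    if to_scale == "total":
        return ph_free - free_to_total
    if to_scale == "seawater":
        return ph_free - free_to_sws
    return ph_free


def _total_alkalinity(h_total: float, dic: float, k: ConstantSet) -> float:
    """TA (mol/kg) from [H+]_total and DIC (mol/kg): carbonate + borate + water
    + minor acid corrections (bisulfate, HF) and the free-proton term."""
    denom = h_total * h_total + k.K1 * h_total + k.K1 * k.K2
    hco3 = dic * k.K1 * h_total / denom
    co3 = dic * k.K1 * k.K2 / denom
    boh4 = k.boron_total * k.KB / (k.KB + h_total)
    oh = k.KW / h_total
    h_free = h_total / (1.0 + k.sulfate_total / k.KS)
    hso4 = k.sulfate_total / (1.0 + k.KS / h_free)
    hf = k.fluoride_total / (1.0 + k.KF / h_total)
    return hco3 + 2.0 * co3 + boh4 + oh - h_free - hso4 - hf


def omega(co3: float, salinity: float, constants: ConstantSet) -> tuple[float, float]:
    """Saturation states (aragonite, calcite) from [CO3^2-] in mmol/kg."""
    if co3 < 0:
        raise ValueError("CO3 concentration must be non-negative")
    ca = constants.calcium  # mol/kg, proportional to salinity
    co3_mol = co3 * 1e-3
    return (
        ca * co3_mol / constants.Ksp_aragonite,
        ca * co3_mol / constants.Ksp_calcite,
    )


def _state_from_h_total(h_total: float, dic_mmol: float, sample: WaterSample,
                        k: ConstantSet) -> CarbonateState:
    dic = dic_mmol * 1e-3
    denom = h_total * h_total + k.K1 * h_total + k.K1 * k.K2
    co2_star = dic * h_total * h_total / denom
    hco3 = dic * k.K1 * h_total / denom
    co3 = dic * k.K1 * k.K2 / denom
    fco2 = co2_star / k.K0  # atm
    pco2 = fco2 / k.fugacity_factor
    ta = _total_alkalinity(h_total, dic, k)
    ph_total = -math.log10(h_total)
    om_ar, om_ca = omega(co3 * 1e3, sample.salinity, k)
    return CarbonateState(
        temperature=sample.temperature,
        salinity=sample.salinity,
        ph_free=ph_scale_convert(ph_total, "total", "free", k),
        ph_total=ph_total,
        ph_seawater=ph_scale_convert(ph_total, "total", "seawater", k),
        pco2=pco2 * 1e6,
        fco2=fco2 * 1e6,
        co2_star=co2_star * 1e3,
        hco3=hco3 * 1e3,
        co3=co3 * 1e3,
        dic=dic_mmol,
        ta=ta * 1e3,
        omega_aragonite=om_ar,
        omega_calcite=om_ca,
        constants=k,
    )


def solve_from_ph_dic(sample: WaterSample) -> CarbonateState:
    """Closed-form speciation from the (pH_free, DIC) pair."""
    if sample.ph_free is None or sample.dic is None:
        raise ValueError("sample must carry both ph_free and dic")
    if not (4.0 <= sample.ph_free <= 10.0):
        raise ValueError(f"ph_free {sample.ph_free} outside [4, 10]")
    k = equilibrium_constants(sample.temperature, sample.salinity)
    ph_total = ph_scale_convert(sample.ph_free, "free", "total", k)
    return _state_from_h_total(10.0 ** (-ph_total), sample.dic, sample, k)


def solve_from_ta_dic(sample: WaterSample, ph_bracket: tuple[float, float] = (3.0, 11.0),
                      tol: float = 1e-12) -> CarbonateState:
    """Root-find pH from the (TA, DIC) pair, then speciate.

    The residual TA(pH; DIC) - TA_measured is monotone decreasing in [H+],
    so a bracketing solve on total-scale pH converges unconditionally when
    a root exists in the bracket.
    """
    if sample.ta is None or sample.dic is None:
        raise ValueError("sample must carry both ta and dic")
    k = equilibrium_constants(sample.temperature, sample.salinity)
    ta_target = sample.ta * 1e-3
    dic = sample.dic * 1e-3

    def residual(ph_total: float) -> float:
        return _total_alkalinity(10.0 ** (-ph_total), dic, k) - ta_target

    lo, hi = ph_bracket
    rlo, rhi = residual(lo), residual(hi)
    if rlo * rhi > 0:
        raise ValueError(
            f"no TA root in pH bracket {ph_bracket}: residuals ({rlo:.3e}, {rhi:.3e}) "
            f"for TA={sample.ta} mmol/kg, DIC={sample.dic} mmol/kg"
        )
    ph_total = brentq(residual, lo, hi, xtol=tol)
    return _state_from_h_total(10.0 ** (-ph_total), sample.dic, sample, k)


def solve_samples(samples, pair: str = "ph+dic") -> list[CarbonateState]:
    """Solve a sequence of :class:`WaterSample` with the chosen measured pair."""
    if pair == "ph+dic":
        return [solve_from_ph_dic(s) for s in samples]
    if pair == "ta+dic":
        return [solve_from_ta_dic(s) for s in samples]
    raise ValueError("pair must be 'ph+dic' or 'ta+dic'")
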