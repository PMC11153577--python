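"""Seawater carbonate-system solver and water-chemistry statistics.

Given pH on the total hydrogen-ion scale (pH_TS) and total alkalinity
(TA, umol kg-1) at in-situ temperature and salinity, the solver fixes
[H+] from the pH and resolves the total-alkalinity balance

    TA = [HCO3-] + 2[CO3--] + [B(OH)4-] + [OH-] - [H+]_F - [HSO4-] - [HF]

for DIC, from which CO2*, pCO2 and the calcite/aragonite saturation
states follow.  Equilibrium constants (all evaluated at sample T, S,
surface pressure, on the total scale):

- K0: Weiss (1974) CO2 solubility
- K1, K2: Lueker et al. (2000) refit of the Mehrbach constants
  (total scale)
- KB: Dickson (1990) boric acid; total boron from Uppstrom (1974)
- KW: Millero (1995), converted from the seawater to the total scale
- KS: Dickson (1990) bisulfate (free scale); KF: Dickson & Riley (1979)
- calcite/aragonite solubility: Mucci (1983); calcium from salinity

Nutrient alkalinity (phosphate, silicate) is taken as zero (not
measured) and pressure as surface.  pCO2 is reported as partial
pressure without the fugacity correction (~0.3% at these conditions).

The module also carries the TRIS-buffer electrode calibration and the
two summary-statistic tests used to compare treatment water chemistry:
a two-sided variance-ratio F test and a pooled-variance two-sample t
test, both computable from printed means/SDs alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "WaterSample",
    "CarbonateResult",
    "TrisCalibration",
    "equilibrium_constants",
    "solve_carbonate",
    "alkalinity_residual",
    "fit_tris_calibration",
    "variance_ratio_test",
    "pooled_t_test",
]


@dataclass
class WaterSample:
    """One water-chemistry observation."""

    ph_ts: float
    ta_umol_kg: float
    temperature_c: float
    salinity: float
    treatment: str = ""
    date: str = ""

    def __post_init__(self) -> None:
        if not (6.0 < self.ph_ts < 9.0):
            raise ValueError(f"pH_TS {self.ph_ts} outside plausible range (6, 9)")
        if self.ta_umol_kg <= 0:
            raise ValueError("total alkalinity must be positive")


@dataclass
class CarbonateResult:
    """Solved carbonate speciation for one sample."""

    pco2_uatm: float
    dic_umol_kg: float
    hco3_umol_kg: float
    co3_umol_kg: float
    co2_umol_kg: float
    omega_calcite: float
    omega_aragonite: float
    constants_set: str = "lueker2000"


@dataclass
class TrisCalibration:
    """Electrode-response -> pH_TS linear calibration from buffer readings."""

    slope: float
    intercept: float
    r2: float

    def ph(self, reading):
        return self.intercept + self.slope * np.asarray(reading, dtype=float)


# --- composition from salinity (mol kg-SW-1) ---------------------------------

def _totals(salinity: float) -> dict[str, float]:
    s = salinity
    return {
        "TB": 0.0004157 * s / 35.0,                 # Uppstrom 1974
        "TS": (0.14 / 96.062) * (s / 1.80655),      # Morris & Riley 1966
        "TF": (0.000067 / 18.998) * (s / 1.80655),  # Riley 1965
        "Ca": (0.02128 / 40.087) * (s / 1.80655),   # Riley & Tongudai 1967
    }


def equilibrium_constants(temperature_c: float, salinity: float) -> dict[str, float]:
    """All equilibrium constants at T, S; pH-dependent ones on the total scale."""
    T = temperature_c + 273.15
    S = salinity
    lnT = math.log(T)
    sqS = math.sqrt(S)

    # Weiss 1974 CO2 solubility, mol kg-1 atm-1
    ln_k0 = (
        -60.2409
        + 93.4517 * (100.0 / T)
        + 23.3585 * math.log(T / 100.0)
        + S * (0.023517 - 0.023656 * (T / 100.0) + 0.0047036 * (T / 100.0) ** 2)
    )
    k0 = math.exp(ln_k0)

    # Lueker et al. 2000, total scale
    pk1 = 3633.86 / T - 61.2172 + 9.67770 * lnT - 0.011555 * S + 0.0001152 * S * S
    pk2 = 471.78 / T + 25.9290 - 3.16967 * lnT - 0.01781 * S + 0.0001122 * S * S
    k1, k2 = 10.0 ** -pk1, 10.0 ** -pk2

    # Dickson 1990 bisulfate, free scale
    ion = 19.924 * S / (1000.0 - 1.005 * S)
    ln_ks = (
        -4276.1 / T
        + 141.328
        - 23.093 * lnT
        + (-13856.0 / T + 324.57 - 47.986 * lnT) * math.sqrt(ion)
        + (35474.0 / T - 771.54 + 114.723 * lnT) * ion
        - (2698.0 / T) * ion**1.5
        + (1776.0 / T) * ion**2
        + math.log(1.0 - 0.001005 * S)
    )
    ks = math.exp(ln_ks)

    # Dickson & Riley 1979 HF, free scale
    ln_kf = 1590.2 / T - 12.641 + 1.525 * math.sqrt(ion)
    kf = math.exp(ln_kf) * (1.0 - 0.001005 * S)

    tot = _totals(S)
    sws_to_tot = (1.0 + tot["TS"] / ks) / (1.0 + tot["TS"] / ks + tot["TF"] / kf)
    free_to_tot = 1.0 + tot["TS"] / ks

    # Dickson 1990 boric acid, total scale
    ln_kb = (
        (-8966.90 - 2890.53 * sqS - 77.942 * S + 1.728 * S * sqS - 0.0996 * S * S) / T
        + 148.0248
        + 137.1942 * sqS
        + 1.62142 * S
        + (-24.4344 - 25.085 * sqS - 0.2474 * S) * lnT
        + 0.053105 * sqS * T
    )
    kb = math.exp(ln_kb)

    # Millero 1995 water, seawater scale -> total
    ln_kw = (
        148.9802
        - 13847.26 / T
        - 23.6521 * lnT
        + (118.67 / T - 5.977 + 1.0495 * lnT) * sqS
        - 0.01615 * S
    )
    kw = math.exp(ln_kw) * sws_to_tot

    # Mucci 1983 solubility products (mol kg-1)^2
    log_kca = (
        -171.9065
        - 0.077993 * T
        + 2839.319 / T
        + 71.595 * math.log10(T)
        + (-0.77712 + 0.0028426 * T + 178.34 / T) * sqS
        - 0.07711 * S
        + 0.0041249 * S * sqS
    )
    log_kar = (
        -171.945
        - 0.077993 * T
        + 2903.293 / T
        + 71.595 * math.log10(T)
        + (-0.068393 + 0.0017276 * T + 88.135 / T) * sqS
        - 0.10018 * S
        + 0.0059415 * S * sqS
    )

    return {
        "K0": k0,
        "K1": k1,
        "K2": k2,
        "KB": kb,
        "KW": kw,
        "KS": ks,
        "KF": kf,
        "Ksp_calcite": 10.0 ** log_kca,
        "Ksp_aragonite": 10.0 ** log_kar,
        "free_to_tot": free_to_tot,
        **tot,
    }


def _speciation_from_h(h_tot: float, dic: float, k: dict[str, float]) -> dict[str, float]:
    """Carbonate species and minor TA terms at a given total-scale [H+]."""
    denom = h_tot * h_tot + k["K1"] * h_tot + k["K1"] * k["K2"]
    co2 = dic * h_tot * h_tot / denom
    hco3 = dic * k["K1"] * h_tot / denom
    co3 = dic * k["K1"] * k["K2"] / denom
    h_free = h_tot / k["free_to_tot"]
    return {
        "CO2": co2,
        "HCO3": hco3,
        "CO3": co3,
        "BOH4": k["TB"] * k["KB"] / (k["KB"] + h_tot),
        "OH": k["KW"] / h_tot,
        "Hfree": h_free,
        "HSO4": k["TS"] * h_free / (k["KS"] + h_free),
        "HF": k["TF"] * h_free / (k["KF"] + h_free),
    }


def alkalinity_residual(ph_ts: float, dic: float, ta: float, k: dict[str, float]) -> float:
    """TA implied by (pH, DIC) minus the target TA (mol kg-1)."""
    sp = _speciation_from_h(10.0 ** -ph_ts, dic, k)
    ta_calc = (
        sp["HCO3"] + 2.0 * sp["CO3"] + sp["BOH4"] + sp["OH"]
        - sp["Hfree"] - sp["HSO4"] - sp["HF"]
    )
    return ta_calc - ta


def solve_carbonate(sample: WaterSample, constants_set: str = "lueker2000") -> CarbonateResult:
    """Solve the carbonate system from pH_TS and TA.

    With [H+] fixed by the pH, the non-carbonate alkalinity terms are
    known, so carbonate alkalinity and DIC follow in closed form; no
    iteration is needed in this input pair.
    """
    if constants_set != "lueker2000":
        raise ValueError(f"unknown constants set: {constants_set!r}")
    k = equilibrium_constants(sample.temperature_c, sample.salinity)
    h = 10.0 ** -sample.ph_ts
    ta = sample.ta_umol_kg * 1e-6

    sp0 = _speciation_from_h(h, 0.0, k)  # DIC-independent terms
    carb_alk = ta - (sp0["BOH4"] + sp0["OH"] - sp0["Hfree"] - sp0["HSO4"] - sp0["HF"])
    if carb_alk <= 0:
        raise ValueError(
            f"non-carbonate alkalinity exceeds TA at pH {sample.ph_ts}; no solution"
        )
    denom = h * h + k["K1"] * h + k["K1"] * k["K2"]
    dic = carb_alk * denom / (k["K1"] * h + 2.0 * k["K1"] * k["K2"])
    sp = _speciation_from_h(h, dic, k)

    ca = k["Ca"]
    return CarbonateResult(
        pco2_uatm=sp["CO2"] / k["K0"] * 1e6,
        dic_umol_kg=dic * 1e6,
        hco3_umol_kg=sp["HCO3"] * 1e6,
        co3_umol_kg=sp["CO3"] * 1e6,
        co2_umol_kg=sp["CO2"] * 1e6,
        omega_calcite=ca * sp["CO3"] / k["Ksp_calcite"],
        omega_aragonite=ca * sp["CO3"] / k["Ksp_aragonite"],
        constants_set=constants_set,
    )


def ph_from_dic_ta(
    dic_umol_kg: float,
    ta_umol_kg: float,
    temperature_c: float,
    salinity: float,
) -> float:
    """Total-scale pH from (DIC, TA) by root-finding on the TA balance."""
    from scipy.optimize import brentq

    k = equilibrium_constants(temperature_c, salinity)
    dic = dic_umol_kg * 1e-6
    ta = ta_umol_kg * 1e-6
    return brentq(
        lambda ph: alkalinity_residual(ph, dic, ta, k), 3.0, 12.0, xtol=1e-12
    )


def fit_tris_calibration(readings, certified_ph) -> TrisCalibration:
    """Least-squares line mapping raw electrode reading -> certified pH_TS.

    Buffer solutions (TRIS and AMP at salinity 32) with certified
    total-scale pH anchor the electrode response.
    """
    x = np.asarray(readings, dtype=float)
    y = np.asarray(certified_ph, dtype=float)
    if len(x) < 2 or len(x) != len(y):
        raise ValueError("need >= 2 paired buffer readings")
    if np.ptp(x) == 0:
        raise ValueError("degenerate calibration: identical readings")
    res = stats.linregress(x, y)
    r2 = res.rvalue**2 if len(x) > 2 or np.ptp(y) > 0 else 1.0
    return TrisCalibration(slope=res.slope, intercept=res.intercept, r2=float(r2))


def variance_ratio_test(sd1: float, n1: int, sd2: float, n2: int) -> tuple[float, float]:
    """Two-sided variance-ratio F test from summary SDs.

    F = larger variance / smaller variance with (n_larger - 1,
    n_smaller - 1) degrees of freedom; the two-sided p doubles the
    upper-tail probability (capped at 1).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in both groups")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("zero or negative SD: variance ratio undefined")
    v1, v2 = sd1 * sd1, sd2 * sd2
    if v1 >= v2:
        f, dfn, dfd = v1 / v2, n1 - 1, n2 - 1
    else:
        f, dfn, dfd = v2 / v1, n2 - 1, n1 - 1
    p = min(1.0, 2.0 * stats.f.sf(f, dfn, dfd))
    return float(f), float(p)


def pooled_t_test(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Pooled-variance two-sample t test from summary statistics.

    Returns (t, df, two-sided p) with df = n1 + n2 - 2.
    """
    if n1 + n2 <= 2:
        raise ValueError("need n1 + n2 > 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("negative SD")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 * sd1 + (n2 - 1) * sd2 * sd2) / df
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        raise ValueError("zero pooled variance")
    t = (mean1 - mean2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)
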