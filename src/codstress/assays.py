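"""Liver antioxidant assay quantification from microplate kinetics.

Kinetic absorbance series (96-well plate reader) are reduced to rates,
converted to enzyme activities by Beer-Lambert, and normalized to
protein:

- GST: CDNB-GSH conjugation followed at 340 nm, extinction coefficient
  9600 M-1 cm-1 for the glutathione-DNB adduct.
- GR: DTNB reduction followed at 405 nm, extinction coefficient of TNB
  14151 M-1 cm-1.
- protein: Lowry with a BSA standard curve (endpoint, not kinetic).
- total glutathione (tGSH, sample diluted 80x) and GSSG (undiluted,
  after 2-vinylpyridine derivatization of GSH): DTNB recycling rates
  read against a GSH standard curve.

%GSSG is GSSG/GSH x 100.  The microplate optical path length depends on
fill volume and is configurable (default 1.0 cm); activities scale
inversely with it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from codstress.respirometry import estimate_slope

__all__ = [
    "AssaySpec",
    "GST_SPEC",
    "GR_SPEC",
    "TGSH_SPEC",
    "GSSG_SPEC",
    "kinetic_rate",
    "enzyme_activity",
    "lowry_protein",
    "glutathione_level",
    "pct_gssg",
]


@dataclass
class AssaySpec:
    """Optical and volumetric parameters of one assay."""

    name: str
    wavelength_nm: float
    extinction_m_cm: float | None  # None for standard-curve assays
    path_length_cm: float = 1.0
    reaction_volume_ul: float = 200.0
    sample_volume_ul: float = 20.0
    dilution_factor: float = 1.0
    direction: str = "increase"  # absorbance increases or decreases with activity
    linear_window_s: float = 180.0
    min_r2: float = 0.98

    def __post_init__(self) -> None:
        if self.extinction_m_cm is not None and self.extinction_m_cm <= 0:
            raise ValueError("extinction coefficient must be positive")
        if self.path_length_cm <= 0:
            raise ValueError("path length must be positive")
        if self.reaction_volume_ul <= 0 or self.sample_volume_ul <= 0:
            raise ValueError("volumes must be positive")
        if self.dilution_factor < 1:
            raise ValueError("dilution factor must be >= 1")
        if self.direction not in ("increase", "decrease"):
            raise ValueError("direction must be 'increase' or 'decrease'")


GST_SPEC = AssaySpec("GST", 340.0, 9600.0, direction="increase")
GR_SPEC = AssaySpec("GR", 405.0, 14151.0, direction="decrease")
TGSH_SPEC = AssaySpec("tGSH", 415.0, None, dilution_factor=80.0)
GSSG_SPEC = AssaySpec("GSSG", 415.0, None, dilution_factor=1.0)


def kinetic_rate(
    time_s: np.ndarray,
    absorbance: np.ndarray,
    spec: AssaySpec,
    blank_rate_au_min: float = 0.0,
) -> float:
    """Blank-corrected reaction rate (AU min-1, positive) for one well.

    OLS slope over the configured linear window; the sign is folded by
    the assay direction so product-accumulation and substrate-depletion
    assays both report positive rates.  Wells whose fit r2 falls below
    the spec gate are flagged with a warning rather than silently used.
    """
    t = np.asarray(time_s, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    if len(t) < 3:
        raise ValueError("need >= 3 kinetic time points")
    keep = t <= t[0] + spec.linear_window_s
    if keep.sum() >= 3:
        t, a = t[keep], a[keep]
    slope_per_s, r2 = estimate_slope(t, a, trim_s=0.0, min_samples=3)
    if np.ptp(a) > 0 and r2 < spec.min_r2:
        warnings.warn(
            f"{spec.name} well kinetics nonlinear (r2={r2:.3f} < {spec.min_r2})",
            stacklevel=2,
        )
    rate = slope_per_s * 60.0 - blank_rate_au_min
    if spec.direction == "decrease":
        rate = -rate
    return float(rate)


def enzyme_activity(
    rate_au_min: float, spec: AssaySpec, protein_mg_ml: float
) -> float:
    """Specific activity (nmol min-1 mg-protein-1) from a kinetic rate.

    Beer-Lambert inversion: rate / (epsilon * path) gives the molar
    concentration change per minute in the well; scaling by the
    reaction/sample volume ratio refers it back to the sample, and
    division by the sample protein concentration normalizes it.
    """
    if spec.extinction_m_cm is None:
        raise ValueError(f"{spec.name} is quantified by standard curve, not extinction")
    if protein_mg_ml <= 0:
        raise ValueError("protein concentration must be positive")
    conc_rate_m_min = rate_au_min / (spec.extinction_m_cm * spec.path_length_cm)
    # M min-1 in well -> nmol min-1 ml-sample-1: 1 M = 1e6 nmol/ml
    nmol_min_ml = conc_rate_m_min * 1e6 * (spec.reaction_volume_ul / spec.sample_volume_ul)
    return nmol_min_ml / protein_mg_ml


def lowry_protein(
    sample_absorbance,
    standard_absorbances,
    standard_concs_mg_ml,
    dilution_factor: float = 1.0,
) -> np.ndarray:
    """Protein concentration (mg ml-1) by linear standard-curve inversion.

    Requires >= 3 monotone BSA standards; samples outside the standard
    range are extrapolated with a warning.
    """
    a_std = np.asarray(standard_absorbances, dtype=float)
    c_std = np.asarray(standard_concs_mg_ml, dtype=float)
    if len(a_std) < 3 or len(a_std) != len(c_std):
        raise ValueError("need >= 3 paired standards")
    order = np.argsort(c_std)
    a_std, c_std = a_std[order], c_std[order]
    if np.any(np.diff(a_std) <= 0):
        raise ValueError("standard curve not monotone increasing")
    slope, intercept = np.polyfit(a_std, c_std, 1)
    a = np.atleast_1d(np.asarray(sample_absorbance, dtype=float))
    if np.any(a < a_std[0]) or np.any(a > a_std[-1]):
        warnings.warn("sample absorbance outside standard range; extrapolating", stacklevel=2)
    conc = (slope * a + intercept) * dilution_factor
    return conc if conc.size > 1 else float(conc[0])


def glutathione_level(
    rate_sample_au_min,
    standard_rates_au_min,
    standard_concs_um,
    spec: AssaySpec,
) -> np.ndarray:
    """Extract glutathione concentration (uM) from a DTNB-recycling rate.

    The recycling rate is linear in glutathione over the standard range;
    the sample rate is inverted through the GSH standard curve and
    multiplied by the assay dilution factor (80 for tGSH, 1 for GSSG).
    """
    r_std = np.asarray(standard_rates_au_min, dtype=float)
    c_std = np.asarray(standard_concs_um, dtype=float)
    if len(r_std) < 2 or len(r_std) != len(c_std):
        raise ValueError("need >= 2 paired standards")
    order = np.argsort(c_std)
    r_std, c_std = r_std[order], c_std[order]
    if np.any(np.diff(r_std) <= 0):
        raise ValueError("GSH standard curve not monotone increasing")
    slope, intercept = np.polyfit(r_std, c_std, 1)
    r = np.atleast_1d(np.asarray(rate_sample_au_min, dtype=float))
    if np.any(r < r_std[0]) or np.any(r > r_std[-1]):
        warnings.warn("sample rate outside standard range; extrapolating", stacklevel=2)
    conc = (slope * r + intercept) * spec.dilution_factor
    return conc if conc.size > 1 else float(conc[0])


def pct_gssg(gssg: float, gsh: float) -> float:
    """Percent oxidized glutathione, GSSG/GSH x 100."""
    if gsh <= 0:
        raise ValueError("GSH must be positive to form the ratio")
    if gssg < 0:
        raise ValueError("GSSG cannot be negative")
    return 100.0 * gssg / gsh
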