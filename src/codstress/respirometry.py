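"""Intermittent-flow respirometry: traces -> per-cycle MO2 -> SMR.

The respirometer alternates a flush phase (water renewal, 15 min by
default) with a sealed measurement phase (5 min) over a 20-h occupancy.
During each measurement window the oxygen saturation declines linearly
at a rate set by the fish's oxygen consumption plus microbial background
respiration.  Mass-specific oxygen consumption for one cycle is

    MO2 = [(Vr - Vf) * r_fish - Vr * r_bg] / m        (mg O2 kg-1 h-1)

where Vr is the respirometer volume (L), Vf the fish volume (L, from
mass at 1 g ml-1 tissue density), r_fish and r_bg the fish-phase and
background oxygen concentration decline rates (mg O2 L-1 h-1, obtained
from the %-saturation slopes via the solubility at the trial temperature
and salinity), and m the fish mass (kg).  Consumption is reported
positive although the measured slopes are negative.

Standard metabolic rate (SMR) is the mean of the lowest 10% of the
per-cycle MO2 values, after removing outliers more than 2 SD below the
mean of that lowest decile.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RespirometerSpec",
    "MeasureWindow",
    "SmrEstimate",
    "calibrate_trace",
    "segment_cycles",
    "estimate_slope",
    "o2_solubility",
    "background_model",
    "compute_mo2",
    "estimate_smr",
    "process_trace",
]

PHASE_PRE = "pre_background"
PHASE_FLUSH = "flush"
PHASE_MEASURE = "measure"
PHASE_POST = "post_background"


@dataclass
class RespirometerSpec:
    """Geometry, schedule and calibration of one respirometer.

    Parameters
    ----------
    volume_l : respirometer volume Vr in litres (3.0 or 3.9 in the
        experimental setup, depending on fish size).
    flush_s, measure_s : flush and sealed-measurement durations in
        seconds; their sum is the cycle period (default 15 min + 5 min).
    sampling_hz : optode sampling rate.
    cal_zero, cal_full : raw optode signal at 0% and 100% air
        saturation (two-point calibration anchors).
    trim_s : seconds discarded at the start of each measurement window
        (mixing transient) before the slope fit.
    background_s : duration of the fish-free background recordings
        before and after occupancy.
    """

    volume_l: float = 3.9
    flush_s: float = 900.0
    measure_s: float = 300.0
    sampling_hz: float = 1.0
    cal_zero: float = 0.0
    cal_full: float = 1.0
    trim_s: float = 30.0
    background_s: float = 3600.0

    def __post_init__(self) -> None:
        if self.volume_l <= 0:
            raise ValueError("respirometer volume must be positive")
        if self.flush_s <= 0 or self.measure_s <= 0:
            raise ValueError("flush and measure durations must be positive")
        if self.sampling_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.cal_zero == self.cal_full:
            raise ValueError("calibration anchors must be distinct")

    @property
    def cycle_s(self) -> float:
        return self.flush_s + self.measure_s


@dataclass
class MeasureWindow:
    """One sealed measurement window extracted from a trace."""

    cycle_index: int
    time_s: np.ndarray
    o2_percent_sat: np.ndarray


@dataclass
class SmrEstimate:
    """Lowest-decile SMR with outlier bookkeeping."""

    fish_id: str
    smr: float
    n_used: int
    n_outliers_removed: int
    decile_values: np.ndarray = field(repr=False)


def calibrate_trace(raw_signal: np.ndarray, spec: RespirometerSpec) -> np.ndarray:
    """Map raw optode signal to % air saturation by the two-point line.

    The line sends ``cal_zero`` to 0% and ``cal_full`` to 100%.  Values
    outside the anchors extrapolate (negative saturation is retained,
    not clipped) so that noise around the zero anchor is not biased.
    """
    raw = np.asarray(raw_signal, dtype=float)
    span = spec.cal_full - spec.cal_zero
    if span == 0:
        raise ValueError("calibration anchors must be distinct")
    sat = 100.0 * (raw - spec.cal_zero) / span
    if np.any(sat < 0):
        warnings.warn("calibrated saturation below 0% (extrapolated)", stacklevel=2)
    return sat


def segment_cycles(
    trace: pd.DataFrame, spec: RespirometerSpec
) -> tuple[list[MeasureWindow], pd.DataFrame, pd.DataFrame]:
    """Split a trace into measurement windows and background segments.

    ``trace`` needs columns ``time_s``, ``o2_percent_sat`` and ``phase``
    (labels ``pre_background`` / ``flush`` / ``measure`` /
    ``post_background``).  Returns the list of measurement windows in
    chronological order plus the pre- and post-background segments.

    A 20-h occupancy at the default 20-min cycle yields 60 windows;
    21 h yields 63.
    """
    required = {"time_s", "o2_percent_sat", "phase"}
    missing = required - set(trace.columns)
    if missing:
        raise ValueError(f"trace is missing columns: {sorted(missing)}")
    t = trace["time_s"].to_numpy(dtype=float)
    if len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("trace time must be strictly increasing")

    pre = trace[trace["phase"] == PHASE_PRE]
    post = trace[trace["phase"] == PHASE_POST]

    is_meas = (trace["phase"] == PHASE_MEASURE).to_numpy()
    if not is_meas.any():
        raise ValueError("trace contains no measurement phase; schedule inconsistent")
    # contiguous runs of the measure label are the sealed windows
    edges = np.flatnonzero(np.diff(np.concatenate(([0], is_meas.view(np.int8), [0]))))
    starts, stops = edges[::2], edges[1::2]
    windows: list[MeasureWindow] = []
    for k, (i, j) in enumerate(zip(starts, stops)):
        windows.append(
            MeasureWindow(
                cycle_index=k,
                time_s=t[i:j],
                o2_percent_sat=trace["o2_percent_sat"].to_numpy(dtype=float)[i:j],
            )
        )
    return windows, pre, post


def estimate_slope(
    time_s: np.ndarray,
    o2_percent_sat: np.ndarray,
    trim_s: float = 0.0,
    min_samples: int = 10,
) -> tuple[float, float]:
    """OLS slope (%sat s-1) and r2 of saturation vs time in one window.

    The first ``trim_s`` seconds are discarded as a mixing transient.
    Raises ``ValueError`` if fewer than ``min_samples`` points remain.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(o2_percent_sat, dtype=float)
    if trim_s > 0:
        keep = t >= t[0] + trim_s
        t, y = t[keep], y[keep]
    if len(t) < min_samples:
        raise ValueError(f"window has {len(t)} samples after trimming; need >= {min_samples}")
    tc = t - t.mean()
    yc = y - y.mean()
    sxx = float(tc @ tc)
    sxy = float(tc @ yc)
    syy = float(yc @ yc)
    slope = sxy / sxx
    r2 = 1.0 if syy == 0.0 else (sxy * sxy) / (sxx * syy)
    return slope, r2


# Garcia & Gordon (1992) refit of the Benson & Krause oxygen solubility
# data; "ml/L" coefficient set.  Valid for T in [-2, 40] degC, S in [0, 42].
_GG_A = (2.00907, 3.22014, 4.05010, 4.94457, -2.56847e-1, 3.88767)
_GG_B = (-6.24523e-3, -7.37614e-3, -1.03410e-2, -8.17083e-3)
_GG_C0 = -4.88682e-7
_ML_PER_MG = 1.42905  # mg O2 per mL O2 at STP


def o2_solubility(temperature_c: float, salinity: float) -> float:
    """Oxygen solubility (mg O2 L-1) at 100% air saturation, 1 atm.

    Garcia-Gordon polynomial (Benson-Krause refit) in scaled
    temperature; raises for inputs outside the fitted range.
    """
    T = np.asarray(temperature_c, dtype=float)
    S = np.asarray(salinity, dtype=float)
    if np.any(T < -2) or np.any(T > 40):
        raise ValueError("temperature outside [-2, 40] degC")
    if np.any(S < 0) or np.any(S > 42):
        raise ValueError("salinity outside [0, 42]")
    ts = np.log((298.15 - T) / (273.15 + T))
    a = sum(c * ts**i for i, c in enumerate(_GG_A))
    b = sum(c * ts**i for i, c in enumerate(_GG_B))
    ln_c = a + S * b + _GG_C0 * S**2
    ml_per_l = np.exp(ln_c)
    out = ml_per_l * _ML_PER_MG
    return float(out) if out.ndim == 0 else out


def background_model(
    pre_slope: float | None,
    post_slope: float | None,
    occupancy_span_s: tuple[float, float],
):
    """Background slope as a function of time over the occupancy span.

    Linear interpolation between the pre- and post-occupancy background
    slopes.  With only one available the model is constant at that value
    (with a warning); with neither it falls back to zero.
    """
    t0, t1 = occupancy_span_s
    if pre_slope is None and post_slope is None:
        warnings.warn("no background recordings; assuming zero background", stacklevel=2)
        return lambda t: np.zeros_like(np.asarray(t, dtype=float))
    if pre_slope is None or post_slope is None:
        warnings.warn("single background recording; assuming constant background", stacklevel=2)
        value = pre_slope if pre_slope is not None else post_slope
        return lambda t: np.full_like(np.asarray(t, dtype=float), value)

    def bg(t):
        t = np.asarray(t, dtype=float)
        frac = np.clip((t - t0) / (t1 - t0), 0.0, 1.0) if t1 > t0 else 0.0
        return pre_slope + frac * (post_slope - pre_slope)

    return bg


def _sat_slope_to_conc_rate(slope_sat_per_s: float, solubility_mg_l: float) -> float:
    """%sat s-1 decline -> mg O2 L-1 h-1 consumption rate (positive)."""
    return abs(slope_sat_per_s) * 3600.0 / 100.0 * solubility_mg_l


def compute_mo2(
    slope_fish: float,
    slope_bg: float,
    spec: RespirometerSpec,
    mass_g: float,
    temperature_c: float,
    salinity: float,
) -> float:
    """Background-corrected mass-specific MO2 (mg O2 kg-1 h-1) for one cycle.

    ``slope_fish`` and ``slope_bg`` are %sat s-1 (negative for a
    decline); both are converted to concentration rates through the
    solubility at the trial temperature and salinity, then combined as
    (Vr - Vf) * r_fish - Vr * r_bg and divided by the fish mass.
    """
    if mass_g <= 0:
        raise ValueError("fish mass must be positive")
    if not (math.isfinite(slope_fish) and math.isfinite(slope_bg)):
        raise ValueError("non-finite slope")
    v_f = mass_g / 1000.0  # 1 g tissue = 1 ml
    if v_f >= spec.volume_l:
        raise ValueError(
            f"fish volume {v_f:.3f} L not smaller than respirometer {spec.volume_l} L"
        )
    sol = o2_solubility(temperature_c, salinity)
    r_fish = _sat_slope_to_conc_rate(slope_fish, sol)
    r_bg = _sat_slope_to_conc_rate(slope_bg, sol)
    return ((spec.volume_l - v_f) * r_fish - spec.volume_l * r_bg) / (mass_g / 1000.0)


def estimate_smr(
    mo2_values: np.ndarray,
    fish_id: str = "",
    decile: float = 0.10,
    outlier_sd: float = 2.0,
) -> SmrEstimate:
    """Lowest-decile SMR with a low-side outlier filter.

    Takes the lowest ``decile`` fraction of the MO2 values (ceil rule,
    so 60 values -> 6), computes their mean and sample SD, removes
    values more than ``outlier_sd`` SD *below* that mean (spuriously low
    slopes, e.g. leaks), and returns the mean of the survivors.  The
    filter is a single pass; statistics are not re-estimated after
    removal.
    """
    values = np.sort(np.asarray(mo2_values, dtype=float))
    n = len(values)
    if n < 10:
        raise ValueError(f"need >= 10 MO2 values for an SMR estimate, got {n}")
    k = math.ceil(decile * n)
    lowest = values[:k]
    mean = float(lowest.mean())
    sd = float(lowest.std(ddof=1)) if k > 1 else 0.0
    cutoff = mean - outlier_sd * sd
    keep = lowest >= cutoff
    if not keep.any():
        raise ValueError("all lowest-decile values removed as outliers; pathological trace")
    survivors = lowest[keep]
    return SmrEstimate(
        fish_id=fish_id,
        smr=float(survivors.mean()),
        n_used=int(keep.sum()),
        n_outliers_removed=int(k - keep.sum()),
        decile_values=lowest,
    )


def process_trace(
    trace: pd.DataFrame,
    spec: RespirometerSpec,
    mass_g: float,
    temperature_c: float,
    salinity: float,
    fish_id: str = "",
    min_r2: float | None = None,
) -> pd.DataFrame:
    """Full per-fish pipeline: segment, fit slopes, background-correct.

    Returns a tidy frame with one row per retained measurement window
    (columns: fish_id, cycle, slope_fish, slope_bg, r2, mo2).  Windows
    failing the optional ``min_r2`` gate or with too few samples are
    dropped with a warning.
    """
    windows, pre, post = segment_cycles(trace, spec)

    def _bg_slope(seg: pd.DataFrame) -> float | None:
        if len(seg) < 10:
            return None
        s, _ = estimate_slope(
            seg["time_s"].to_numpy(), seg["o2_percent_sat"].to_numpy(), trim_s=0.0
        )
        return s

    pre_s, post_s = _bg_slope(pre), _bg_slope(post)
    t_occ0 = windows[0].time_s[0]
    t_occ1 = windows[-1].time_s[-1]
    bg = background_model(pre_s, post_s, (t_occ0, t_occ1))

    rows = []
    for w in windows:
        try:
            slope, r2 = estimate_slope(w.time_s, w.o2_percent_sat, trim_s=spec.trim_s)
        except ValueError as exc:
            warnings.warn(f"cycle {w.cycle_index} rejected: {exc}", stacklevel=2)
            continue
        if min_r2 is not None and r2 < min_r2:
            warnings.warn(
                f"cycle {w.cycle_index} rejected: r2 {r2:.3f} < {min_r2}", stacklevel=2
            )
            continue
        t_mid = 0.5 * (w.time_s[0] + w.time_s[-1])
        slope_bg = float(np.asarray(bg(t_mid)))
        mo2 = compute_mo2(slope, slope_bg, spec, mass_g, temperature_c, salinity)
        rows.append(
            {
                "fish_id": fish_id,
                "cycle": w.cycle_index,
                "slope_fish": slope,
                "slope_bg": slope_bg,
                "r2": r2,
                "mo2": mo2,
            }
        )
    return pd.DataFrame(rows)
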