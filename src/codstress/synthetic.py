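"""Seeded synthetic-data generators for the multi-stressor experiment.

The generators emulate the experimental design so that every downstream
stage is testable without the (undeposited) raw data: a cohort of
5 treatments x 4 tanks x 5 fish with ecotype-linked bimodal SMR in the
freshening and multi-stressor treatments, 20-h intermittent-flow
respirometry sessions (15-min flush + 5-min sealed measurement), weekly
carbonate-chemistry samples drawn from the per-treatment observed
distributions, and microplate kinetic plates built from a Beer-Lambert
forward model.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from codstress.respirometry import (
    PHASE_FLUSH,
    PHASE_MEASURE,
    PHASE_POST,
    PHASE_PRE,
    RespirometerSpec,
    o2_solubility,
)
from codstress.assays import AssaySpec

__all__ = [
    "CohortConfig",
    "FishRecord",
    "TREATMENTS",
    "WATER_PRESETS",
    "generate_cohort",
    "cohort_to_frame",
    "generate_o2_trace",
    "generate_water_samples",
    "generate_kinetic_plate",
]

TREATMENTS = ("control", "low_salinity", "high_temp", "low_pH", "multi_stressor")

# Per-treatment water conditions: (mean, SD) for pH_TS, TA (umol/kg),
# temperature (degC) and salinity, from the weekly monitoring of the
# four-week exposure.
WATER_PRESETS: dict[str, dict[str, tuple[float, float]]] = {
    "control": {"ph": (8.06, 0.08), "ta": (2308, 184), "t": (12.95, 0.35), "s": (32.62, 1.92)},
    "low_salinity": {"ph": (8.06, 0.08), "ta": (2308, 184), "t": (12.95, 0.35), "s": (26.39, 1.64)},
    "high_temp": {"ph": (8.06, 0.08), "ta": (2308, 184), "t": (16.90, 0.77), "s": (32.62, 1.92)},
    "low_pH": {"ph": (7.67, 0.30), "ta": (2235, 217), "t": (12.95, 0.35), "s": (32.62, 1.92)},
    "multi_stressor": {"ph": (7.67, 0.30), "ta": (2235, 217), "t": (16.90, 0.77), "s": (26.39, 1.64)},
}
# ambient alias used for single-parameter presets
WATER_PRESETS["ambient"] = WATER_PRESETS["control"]


@dataclass
class FishRecord:
    """One fish with its synthetic ground truth."""

    fish_id: str
    treatment: str
    tank_id: str
    ecotype: str  # offshore / coastal / unknown
    mass_g: float
    length_cm: float
    alive: bool
    true_smr: float  # mg O2 kg-1 h-1
    response_class: str  # heightened / reduced / none

    def __post_init__(self) -> None:
        if self.mass_g <= 0 or self.length_cm <= 0:
            raise ValueError("biometrics must be positive")


@dataclass
class CohortConfig:
    """Cohort design and effect parameters.

    Defaults reproduce the experimental design: 5 treatments x 4 tanks
    x 5 fish (100 fish); biometrics drawn from the cohort normal
    (159.4 +/- 72.6 g, 24.3 +/- 3.5 cm); death probabilities from the
    observed per-treatment deaths out of 20 (0, 4, 2, 2, 2); bimodal SMR
    in the freshening and multi-stressor treatments with the offshore
    ecotype heightened and the coastal ecotype reduced at the configured
    concordance.
    """

    n_treatments: int = 5
    tanks_per_treatment: int = 4
    fish_per_tank: int = 5
    treatment_names: tuple[str, ...] = TREATMENTS
    ecotype_fractions: dict = field(
        default_factory=lambda: {
            "control": 0.31, "low_salinity": 0.53, "high_temp": 0.42,
            "low_pH": 0.42, "multi_stressor": 0.41,
        }
    )
    mass_mean_g: float = 159.4
    mass_sd_g: float = 72.6
    length_mean_cm: float = 24.3
    length_sd_cm: float = 3.5
    smr_baseline: float = 60.0  # mg O2 kg-1 h-1, juvenile cod near 13 degC
    smr_effects: dict = field(
        default_factory=lambda: {
            "control": 0.0, "low_salinity": -4.0, "high_temp": 3.0,
            "low_pH": 1.0, "multi_stressor": 6.0,
        }
    )
    smr_sd: float = 4.0  # between-fish SD within a mode
    bimodal_treatments: dict = field(
        default_factory=lambda: {
            "low_salinity": {"heightened": 15.0, "reduced": -15.0},
            "multi_stressor": {"heightened": 15.0, "reduced": -15.0},
        }
    )
    concordance: float = 0.9  # P(response class matches ecotype expectation)
    mortality_probs: dict = field(
        default_factory=lambda: {
            "control": 0.0, "low_salinity": 0.2, "high_temp": 0.1,
            "low_pH": 0.1, "multi_stressor": 0.1,
        }
    )
    # endpoint growth multipliers on mass over the 4-week exposure,
    # (mean, sd); the reduced-SMR class in bimodal treatments grows more
    growth_mean: dict = field(
        default_factory=lambda: {
            "control": 1.10, "low_salinity": 1.15, "high_temp": 1.02,
            "low_pH": 1.08, "multi_stressor": 1.10,
        }
    )
    growth_sd: float = 0.04
    growth_class_shift: float = 0.08  # extra growth for reduced-SMR fish
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_treatments, self.tanks_per_treatment, self.fish_per_tank) <= 0:
            raise ValueError("design sizes must be positive")
        names = self.treatment_names[: self.n_treatments]
        if len(set(names)) != len(names):
            raise ValueError("treatment labels must be unique")
        for d in (self.ecotype_fractions, self.mortality_probs):
            for t in names:
                p = d.get(t, 0.0)
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability {p} for {t} outside [0, 1]")
        if not 0.0 <= self.concordance <= 1.0:
            raise ValueError("concordance must be in [0, 1]")
        if self.smr_baseline <= 0 or self.smr_sd < 0:
            raise ValueError("SMR parameters must be positive")


def generate_cohort(config: CohortConfig) -> list[FishRecord]:
    """Draw a full cohort of fish records; deterministic given config.seed."""
    rng = np.random.default_rng(config.seed)
    names = config.treatment_names[: config.n_treatments]
    records: list[FishRecord] = []
    for ti, treatment in enumerate(names):
        offsets = config.bimodal_treatments.get(treatment)
        for tank in range(config.tanks_per_treatment):
            tank_id = f"{treatment}_tank{tank + 1}"
            for f in range(config.fish_per_tank):
                fish_id = f"{treatment}_t{tank + 1}_f{f + 1}"
                mass = max(20.0, rng.normal(config.mass_mean_g, config.mass_sd_g))
                length = max(10.0, rng.normal(config.length_mean_cm, config.length_sd_cm))
                p_off = config.ecotype_fractions.get(treatment, 0.0)
                ecotype = "offshore" if rng.random() < p_off else "coastal"
                if offsets is not None:
                    expected = "heightened" if ecotype == "offshore" else "reduced"
                    if rng.random() < config.concordance:
                        response = expected
                    else:
                        response = "reduced" if expected == "heightened" else "heightened"
                    class_shift = offsets[response]
                else:
                    response = "none"
                    class_shift = 0.0
                smr = (
                    config.smr_baseline
                    + config.smr_effects.get(treatment, 0.0)
                    + class_shift
                    + rng.normal(0.0, config.smr_sd)
                )
                smr = max(smr, 5.0)
                alive = rng.random() >= config.mortality_probs.get(treatment, 0.0)
                records.append(
                    FishRecord(
                        fish_id=fish_id,
                        treatment=treatment,
                        tank_id=tank_id,
                        ecotype=ecotype,
                        mass_g=float(mass),
                        length_cm=float(length),
                        alive=bool(alive),
                        true_smr=float(smr),
                        response_class=response,
                    )
                )
    return records


def apply_growth(records: list[FishRecord], config: CohortConfig) -> list[FishRecord]:
    """Endpoint biometrics after the 4-week exposure.

    Growth is generated directly as an endpoint multiplier per treatment
    (and response class in the bimodal treatments, where the reduced-SMR
    fish grow more), not via a bioenergetic model.
    """
    rng = np.random.default_rng(config.seed + 1)
    grown = []
    for r in records:
        g = config.growth_mean.get(r.treatment, 1.0)
        if r.response_class == "reduced":
            g += config.growth_class_shift
        mult = max(0.8, rng.normal(g, config.growth_sd))
        grown.append(
            replace(r, mass_g=r.mass_g * mult, length_cm=r.length_cm * mult ** (1 / 3))
        )
    return grown


def cohort_to_frame(records: list[FishRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def generate_o2_trace(
    fish: FishRecord,
    spec: RespirometerSpec | None = None,
    background_rate: float = -0.2,  # %sat h-1 (negative = microbial consumption)
    noise_sd: float = 0.1,  # %sat, per-sample optode noise
    seed: int = 0,
    occupancy_h: float = 20.0,
    temperature_c: float = 13.0,
    salinity: float = 33.0,
    background_rate_post: float | None = None,
    activity_spike_prob: float = 0.0,
    activity_spike_mult: float = 2.0,
) -> pd.DataFrame:
    """Forward-model one respirometry session for a live fish.

    The trace spans a 1-h fish-free background, ``occupancy_h`` hours of
    flush/measure cycling, and a 1-h post background.  During sealed
    measurement windows the saturation declines at the rate implied by
    inverting the MO2 formula for the fish's true SMR plus background;
    flush phases relax exponentially back to 100% saturation (60-s time
    constant).  Background drift can be made linear by giving a
    different ``background_rate_post``.  Optional activity spikes
    multiply the fish's consumption in randomly chosen cycles, to stress
    the lowest-decile SMR estimator.

    Returns a frame with columns time_s, o2_percent_sat, phase.
    """
    if not fish.alive:
        raise ValueError("dead fish carry no respirometry data")
    spec = spec or RespirometerSpec()
    v_f = fish.mass_g / 1000.0
    if v_f >= spec.volume_l:
        raise ValueError("fish volume must be smaller than respirometer volume")
    rng = np.random.default_rng(seed)
    sol = o2_solubility(temperature_c, salinity)
    bg_pre = background_rate
    bg_post = background_rate if background_rate_post is None else background_rate_post

    dt = 1.0 / spec.sampling_hz
    n_cycles = int(round(occupancy_h * 3600.0 / spec.cycle_s))

    def fish_slope_sat_s(bg_sat_h: float, smr: float) -> float:
        # invert MO2 = [(Vr-Vf)*r_f - Vr*r_b]/m for the measured slope
        r_b = abs(bg_sat_h) / 100.0 * sol  # mg/L/h
        r_f = (smr * fish.mass_g / 1000.0 + spec.volume_l * r_b) / (spec.volume_l - v_f)
        return -(r_f * 100.0 / sol) / 3600.0

    times, sats, phases = [], [], []
    t = 0.0
    sat = 100.0

    def emit(n: int, slope_s, phase: str, relax_to_100: bool = False):
        nonlocal t, sat
        tt = t + dt * np.arange(n)
        if relax_to_100:
            vals = 100.0 + (sat - 100.0) * np.exp(-(tt - t) / 60.0)
        else:
            vals = sat + slope_s * (tt - t)
        times.append(tt)
        sats.append(vals)
        phases.extend([phase] * n)
        t = tt[-1] + dt
        sat = float(vals[-1]) if not relax_to_100 else float(vals[-1])

    n_bg = int(round(spec.background_s / dt))
    emit(n_bg, bg_pre / 3600.0, PHASE_PRE)

    n_flush = int(round(spec.flush_s / dt))
    n_meas = int(round(spec.measure_s / dt))
    span = n_cycles * spec.cycle_s
    for c in range(n_cycles):
        emit(n_flush, 0.0, PHASE_FLUSH, relax_to_100=True)
        frac = (t - spec.background_s) / span
        bg_now = bg_pre + frac * (bg_post - bg_pre)
        smr_now = fish.true_smr
        if activity_spike_prob > 0 and rng.random() < activity_spike_prob:
            smr_now *= activity_spike_mult
        emit(n_meas, fish_slope_sat_s(bg_now, smr_now), PHASE_MEASURE)
    sat = 100.0
    emit(n_bg, bg_post / 3600.0, PHASE_POST)

    time_s = np.concatenate(times)
    o2 = np.concatenate(sats)
    if noise_sd > 0:
        o2 = o2 + rng.normal(0.0, noise_sd, size=o2.shape)
    return pd.DataFrame({"time_s": time_s, "o2_percent_sat": o2, "phase": phases})


def generate_water_samples(
    treatment: str,
    n: int,
    seed: int = 0,
    params: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Independent normal draws of (pH_TS, TA, T, S) for one treatment.

    ``params`` overrides the built-in per-treatment presets; each entry
    is (mean, SD) keyed by ph / ta / t / s.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    p = params if params is not None else WATER_PRESETS.get(treatment)
    if p is None:
        raise ValueError(f"no water preset for treatment {treatment!r}")
    for key, (_, sd) in p.items():
        if sd < 0:
            raise ValueError(f"negative SD for {key}")
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "treatment": treatment,
            "ph_ts": rng.normal(*p["ph"], size=n),
            "ta_umol_kg": rng.normal(*p["ta"], size=n),
            "temperature_c": rng.normal(*p["t"], size=n),
            "salinity": rng.normal(*p["s"], size=n),
        }
    )


def generate_kinetic_plate(
    true_rates_um_min: dict[str, float],
    assay: AssaySpec,
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline_au: float = 0.1,
    n_timepoints: int = 13,
    interval_s: float = 15.0,
    standard_concs_um: list[float] | None = None,
    standard_rate_per_um: float = 0.0005,
) -> pd.DataFrame:
    """Beer-Lambert forward model of a kinetic microplate.

    Sample wells get absorbance(t) = A0 + slope*t + noise with
    slope (AU/min) = rate (uM/min) * 1e-6 * epsilon * path, signed by
    the assay direction.  For standard-curve assays
    (``standard_concs_um`` given) standard wells follow a perfect line
    of rate ``standard_rate_per_um`` * concentration.  A blank well
    (zero rate) is always included.

    Returns a long frame: well, role, standard_conc_um, time_s,
    absorbance.
    """
    for w, r in true_rates_um_min.items():
        if not np.isfinite(r):
            raise ValueError(f"non-finite rate for well {w}")
    rng = np.random.default_rng(seed)
    t = np.arange(n_timepoints) * interval_s
    sign = -1.0 if assay.direction == "decrease" else 1.0
    eps = assay.extinction_m_cm

    rows = []

    def add_well(well: str, role: str, slope_au_min: float, conc: float = np.nan):
        a = baseline_au + slope_au_min / 60.0 * t
        if noise_sd > 0:
            a = a + rng.normal(0.0, noise_sd, size=a.shape)
        for ti, ai in zip(t, a):
            rows.append(
                {"well": well, "role": role, "standard_conc_um": conc,
                 "time_s": ti, "absorbance": ai}
            )

    add_well("blank", "blank", 0.0)
    for well, rate in true_rates_um_min.items():
        if eps is not None:
            slope = sign * rate * 1e-6 * eps * assay.path_length_cm
        else:
            slope = sign * rate * standard_rate_per_um
        add_well(well, "sample", slope)
    if standard_concs_um is not None:
        for i, conc in enumerate(standard_concs_um):
            add_well(f"std{i}", "standard", sign * conc * standard_rate_per_um, conc)
    return pd.DataFrame(rows)
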