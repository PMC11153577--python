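"""Pipeline orchestration, configuration, CSV formats and validation.

Stages: simulate -> respirometry -> chem -> assays -> analyze.  Every
output CSV starts with a comment header recording the seed and a hash of
the resolved configuration, so a rerun with the same config is
byte-identical.

File formats (all CSV with a ``#``-comment header):

- cohort.csv: fish_id, treatment, tank_id, ecotype, mass_g, length_cm,
  alive, true_smr, response_class
- traces/<fish_id>.csv: time_s, o2_percent_sat, phase
- water_samples.csv: treatment, ph_ts, ta_umol_kg, temperature_c, salinity
- plates/<assay>.csv: well, role, standard_conc_um, time_s, absorbance
- mo2.csv: fish_id, cycle, slope_fish, slope_bg, r2, mo2
- smr.csv: fish_id, smr, n_used, n_outliers_removed
- chem_results.csv: per-sample carbonate speciation
- report.md: human-readable summary
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from codstress import synthetic
from codstress.assays import GST_SPEC, enzyme_activity, kinetic_rate
from codstress.carbonate import WaterSample, solve_carbonate
from codstress.cohort_stats import (
    ecotype_association,
    fulton_k,
    mortality_summary,
    split_within_treatment,
    treatment_tests,
)
from codstress.respirometry import RespirometerSpec, estimate_smr, process_trace
from codstress.synthetic import CohortConfig

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs", "write_csv", "read_csv"]


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    respirometer: RespirometerSpec = field(default_factory=RespirometerSpec)
    occupancy_h: float = 20.0
    noise_sd: float = 0.1
    background_rate: float = -0.2
    water_samples_per_treatment: int = 4
    plate_noise_sd: float = 0.001
    path_length_cm: float = 1.0
    constants_set: str = "lueker2000"
    split_strict: bool = False
    posthoc: str = "hsd"
    bimodal_endpoint_treatments: tuple[str, ...] = ("low_salinity", "multi_stressor")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        spec = RespirometerSpec(**raw.pop("respirometer", {}))
        return cls(cohort=cohort, respirometer=spec, **raw)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir", None)  # location, not configuration
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path: Path, seed: int, config_hash: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# seed={seed} config={config_hash}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def simulate_stage(cfg: PipelineConfig, out: Path) -> dict[str, Path]:
    """Generate cohort, traces and water samples; return the file map."""
    chash = cfg.config_hash()
    records = synthetic.generate_cohort(cfg.cohort)
    records = synthetic.apply_growth(records, cfg.cohort)
    cohort_df = synthetic.cohort_to_frame(records)
    paths = {"cohort": out / "cohort.csv"}
    write_csv(cohort_df, paths["cohort"], cfg.seed, chash)

    trace_dir = out / "traces"
    presets = synthetic.WATER_PRESETS
    for i, rec in enumerate(records):
        if not rec.alive:
            continue
        p = presets[rec.treatment]
        trace = synthetic.generate_o2_trace(
            rec,
            cfg.respirometer,
            background_rate=cfg.background_rate,
            noise_sd=cfg.noise_sd,
            seed=cfg.seed * 100003 + i,
            occupancy_h=cfg.occupancy_h,
            temperature_c=p["t"][0],
            salinity=p["s"][0],
        )
        write_csv(trace, trace_dir / f"{rec.fish_id}.csv", cfg.seed, chash)
    paths["traces"] = trace_dir

    frames = [
        synthetic.generate_water_samples(
            t, cfg.water_samples_per_treatment, seed=cfg.seed * 7919 + j
        )
        for j, t in enumerate(cfg.cohort.treatment_names[: cfg.cohort.n_treatments])
    ]
    paths["water"] = out / "water_samples.csv"
    write_csv(pd.concat(frames, ignore_index=True), paths["water"], cfg.seed, chash)

    # liver GST plate: one kinetic well per live fish, true activities
    # (uM/min in the well) and Lowry protein drawn around the cohort mean
    rng = np.random.default_rng(cfg.seed + 5)
    live = [r for r in records if r.alive]
    true_rates = {r.fish_id: float(rng.uniform(0.5, 3.0)) for r in live}
    plate = synthetic.generate_kinetic_plate(
        true_rates, GST_SPEC, noise_sd=cfg.plate_noise_sd, seed=cfg.seed + 6
    )
    paths["plate_gst"] = out / "plates" / "gst.csv"
    write_csv(plate, paths["plate_gst"], cfg.seed, chash)
    protein = pd.DataFrame(
        {
            "fish_id": [r.fish_id for r in live],
            "protein_mg_ml": np.clip(rng.normal(5.39, 1.0, len(live)), 1.0, None),
        }
    )
    paths["protein"] = out / "protein.csv"
    write_csv(protein, paths["protein"], cfg.seed, chash)
    return paths


def assays_stage(cfg: PipelineConfig, out: Path) -> pd.DataFrame:
    """Quantify the GST plate: rates -> specific activities per fish."""
    chash = cfg.config_hash()
    plate_path = out / "plates" / "gst.csv"
    if not plate_path.exists():
        raise FileNotFoundError(f"assays stage: missing plate file {plate_path}")
    plate = read_csv(plate_path)
    protein = read_csv(out / "protein.csv").set_index("fish_id")["protein_mg_ml"]
    spec = replace(GST_SPEC, path_length_cm=cfg.path_length_cm)
    blank = plate[plate["role"] == "blank"]
    blank_rate = kinetic_rate(
        blank["time_s"].to_numpy(), blank["absorbance"].to_numpy(), spec
    )
    rows = []
    for fish_id, g in plate[plate["role"] == "sample"].groupby("well"):
        rate = kinetic_rate(
            g["time_s"].to_numpy(), g["absorbance"].to_numpy(), spec,
            blank_rate_au_min=blank_rate,
        )
        rows.append(
            {
                "fish_id": fish_id,
                "protein_mg_ml": float(protein[fish_id]),
                "gst_rate_au_min": rate,
                "gst_nmol_min_mg": enzyme_activity(rate, spec, float(protein[fish_id])),
            }
        )
    results = pd.DataFrame(rows).sort_values("fish_id").reset_index(drop=True)
    write_csv(results, out / "assay_results.csv", cfg.seed, chash)
    return results


def respirometry_stage(cfg: PipelineConfig, out: Path) -> pd.DataFrame:
    """Process every trace to per-cycle MO2 and per-fish SMR."""
    chash = cfg.config_hash()
    cohort = read_csv(out / "cohort.csv")
    presets = synthetic.WATER_PRESETS
    mo2_frames, smr_rows = [], []
    for _, row in cohort.iterrows():
        if not row["alive"]:
            continue
        trace_path = out / "traces" / f"{row['fish_id']}.csv"
        if not trace_path.exists():
            raise FileNotFoundError(
                f"respirometry stage: missing trace file {trace_path}"
            )
        try:
            trace = read_csv(trace_path)
            p = presets[row["treatment"]]
            mo2 = process_trace(
                trace, cfg.respirometer, row["mass_g"], p["t"][0], p["s"][0],
                fish_id=row["fish_id"],
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"respirometry stage failed on {trace_path}: {exc}") from exc
        mo2_frames.append(mo2)
        est = estimate_smr(mo2["mo2"].to_numpy(), fish_id=row["fish_id"])
        smr_rows.append(
            {"fish_id": est.fish_id, "smr": est.smr, "n_used": est.n_used,
             "n_outliers_removed": est.n_outliers_removed}
        )
    mo2_all = pd.concat(mo2_frames, ignore_index=True)
    smr = pd.DataFrame(smr_rows)
    write_csv(mo2_all, out / "mo2.csv", cfg.seed, chash)
    write_csv(smr, out / "smr.csv", cfg.seed, chash)
    return smr


def chem_stage(cfg: PipelineConfig, out: Path) -> pd.DataFrame:
    """Solve the carbonate system for every water sample."""
    chash = cfg.config_hash()
    samples = read_csv(out / "water_samples.csv")
    rows = []
    for _, s in samples.iterrows():
        res = solve_carbonate(
            WaterSample(
                ph_ts=s["ph_ts"], ta_umol_kg=s["ta_umol_kg"],
                temperature_c=s["temperature_c"], salinity=s["salinity"],
                treatment=s["treatment"],
            ),
            constants_set=cfg.constants_set,
        )
        rows.append({"treatment": s["treatment"], **vars(res)})
    chem = pd.DataFrame(rows)
    write_csv(chem, out / "chem_results.csv", cfg.seed, chash)
    return chem


def analyze_stage(cfg: PipelineConfig, out: Path) -> dict:
    """Splits, treatment tests, mortality and ecotype association."""
    chash = cfg.config_hash()
    cohort = read_csv(out / "cohort.csv")
    smr = read_csv(out / "smr.csv")
    df = cohort.merge(smr, on="fish_id", how="inner")
    df["fulton_k"] = fulton_k(df["mass_g"].to_numpy(), df["length_cm"].to_numpy())

    splits, split_rows, response = {}, [], {}
    for t, g in df.groupby("treatment"):
        if len(g) < 4:
            continue
        res = split_within_treatment(
            dict(zip(g["fish_id"], g["smr"])), treatment=t, variable="smr",
            strict_two_each_side=cfg.split_strict,
        )
        splits[t] = res
        split_rows.append(
            {"treatment": t, "variable": "smr", "is_split": res.is_split,
             "median": res.median, "sem": res.sem,
             "gap_low": res.gap_low, "gap_high": res.gap_high}
        )
        if res.is_split and t in cfg.bimodal_endpoint_treatments:
            response.update(res.assignments)
    write_csv(pd.DataFrame(split_rows), out / "splits.csv", cfg.seed, chash)

    tests = treatment_tests(
        {t: g["smr"].to_numpy() for t, g in df.groupby("treatment")},
        posthoc=cfg.posthoc,
    )
    write_csv(tests.posthoc, out / "posthoc_smr.csv", cfg.seed, chash)

    mort = mortality_summary(cohort)
    assoc = None
    if response:
        ecotypes = dict(zip(cohort["fish_id"], cohort["ecotype"]))
        try:
            assoc = ecotype_association(response, ecotypes, endpoint="SMR")
        except ValueError as exc:
            warnings.warn(f"ecotype association skipped: {exc}", stacklevel=2)

    lines = [
        "# Pipeline report",
        f"seed: {cfg.seed}  config: {chash}",
        "",
        "## Mortality (dead / n per treatment)",
        mort["counts"].to_string(),
        "",
        f"## SMR omnibus: {tests.method} stat={tests.statistic:.3f} "
        f"p={tests.p_value:.4g} (transform: {tests.transform})",
        "",
        "## Within-treatment splits (SMR)",
    ]
    for t, res in splits.items():
        lines.append(
            f"- {t}: split={res.is_split} median={res.median:.2f} sem={res.sem:.3f}"
        )
    if assoc is not None:
        lines += [
            "",
            "## Ecotype association (SMR heightened/reduced vs ecotype)",
            f"chi2(1, N={assoc.n}) = {assoc.chi2:.3f}, p = {assoc.p_value:.4g}",
            f"table (rows offshore/coastal, cols B/A): {assoc.table.tolist()}",
        ]
    (out / "report.md").write_text("\n".join(lines) + "\n")
    return {"splits": splits, "tests": tests, "mortality": mort, "association": assoc}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute simulate -> respirometry -> chem -> analyze end to end."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    simulate_stage(cfg, out)
    respirometry_stage(cfg, out)
    chem_stage(cfg, out)
    assays_stage(cfg, out)
    return analyze_stage(cfg, out)


def validate_inputs(out_dir: str | Path) -> pd.DataFrame:
    """Schema and key-integrity checks over a pipeline directory.

    Returns a frame of (file, check, passed, detail); never raises for
    a failed check, only for an unreadable directory.
    """
    out = Path(out_dir)
    results = []

    def check(file: str, name: str, ok: bool, detail: str = ""):
        results.append({"file": file, "check": name, "passed": bool(ok), "detail": detail})

    cohort_path = out / "cohort.csv"
    cohort = None
    if cohort_path.exists():
        cohort = read_csv(cohort_path)
        needed = {"fish_id", "treatment", "tank_id", "mass_g", "length_cm", "alive"}
        check("cohort.csv", "columns", needed <= set(cohort.columns),
              f"missing {sorted(needed - set(cohort.columns))}")
        if {"mass_g", "length_cm"} <= set(cohort.columns):
            check("cohort.csv", "positive_biometrics",
                  bool((cohort["mass_g"] > 0).all() and (cohort["length_cm"] > 0).all()))
        check("cohort.csv", "unique_fish_id", cohort["fish_id"].is_unique)
    else:
        check("cohort.csv", "exists", False, "file not found")

    trace_dir = out / "traces"
    if trace_dir.is_dir():
        ids_with_traces = set()
        for tp in sorted(trace_dir.glob("*.csv")):
            tr = read_csv(tp)
            needed = {"time_s", "o2_percent_sat", "phase"}
            check(tp.name, "columns", needed <= set(tr.columns))
            if "time_s" in tr.columns:
                check(tp.name, "monotone_time",
                      bool(np.all(np.diff(tr["time_s"].to_numpy()) > 0)))
            ids_with_traces.add(tp.stem)
        if cohort is not None:
            alive_ids = set(cohort.loc[cohort["alive"].astype(bool), "fish_id"])
            orphans = ids_with_traces - set(cohort["fish_id"])
            check("traces/", "fish_id_cross_reference", not orphans,
                  f"traces without cohort entry: {sorted(orphans)[:5]}")
            missing = alive_ids - ids_with_traces
            check("traces/", "alive_fish_have_traces", not missing,
                  f"alive fish without trace: {sorted(missing)[:5]}")

    water_path = out / "water_samples.csv"
    if water_path.exists():
        w = read_csv(water_path)
        needed = {"treatment", "ph_ts", "ta_umol_kg", "temperature_c", "salinity"}
        check("water_samples.csv", "columns", needed <= set(w.columns))
        if "ph_ts" in w.columns:
            check("water_samples.csv", "ph_plausible",
                  bool(w["ph_ts"].between(6, 9).all()))
    return pd.DataFrame(results)
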