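"""Cohort-level statistics: condition factor, bimodality split rule,
treatment tests, tank checks, mortality, and ecotype association.

The central non-standard piece is the within-treatment split rule used
to detect a bimodal response inside a single treatment: if the nearest
observation above the median and the nearest observation below it each
lie one or more standard errors (SD/sqrt(n) of all treatment values)
from the median, the treatment is declared to contain two distinct
groups, split at the median (A = low, B = high).

Downstream, the pooled low/high classes from the split treatments are
cross-tabulated against genetic ecotype (coastal/offshore) and tested
with a Yates continuity-corrected chi-square.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SplitResult",
    "AssociationResult",
    "TreatmentTestResult",
    "fulton_k",
    "split_within_treatment",
    "treatment_tests",
    "nested_tank_check",
    "yates_chi_square",
    "mortality_summary",
    "ecotype_association",
]

ALPHA = 0.05


def fulton_k(weight_g, length_cm):
    """Fulton's condition factor K = 100 * W / L^3 (W in g, L in cm)."""
    w = np.asarray(weight_g, dtype=float)
    l = np.asarray(length_cm, dtype=float)
    if np.any(w <= 0) or np.any(l <= 0):
        raise ValueError("weight and length must be positive")
    k = 100.0 * w / l**3
    return float(k) if k.ndim == 0 else k


@dataclass
class SplitResult:
    """Outcome of the within-treatment median-gap split rule."""

    treatment: str
    variable: str
    is_split: bool
    assignments: dict = field(default_factory=dict)  # fish_id -> "A" | "B"
    median: float = float("nan")
    sem: float = float("nan")
    gap_low: float = float("nan")
    gap_high: float = float("nan")


def split_within_treatment(
    values: dict,
    treatment: str = "",
    variable: str = "",
    strict_two_each_side: bool = False,
) -> SplitResult:
    """Median-gap bimodality rule for one treatment's values.

    ``values`` maps fish id -> value.  The rule: with the nearest point
    above the median and the nearest below each >= 1 SEM from the
    median, the treatment holds two distinct groups split at the median
    (A below, B above).  SEM is SD/sqrt(n) over all treatment values,
    computed before any grouping.  ``strict_two_each_side`` requires the
    two nearest points on each side to clear the gap instead of one.
    """
    ids = list(values.keys())
    x = np.asarray([values[i] for i in ids], dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need >= 4 values for the split rule")
    med = float(np.median(x))
    sem = float(x.std(ddof=1) / np.sqrt(n))

    above = np.sort(x[x > med])
    below = np.sort(x[x < med])[::-1]
    at_median = np.isclose(x, med)
    if sem == 0 or len(above) == 0 or len(below) == 0:
        return SplitResult(treatment, variable, False, {}, med, sem)
    if at_median.any() and n % 2 == 1:
        warnings.warn(
            f"{treatment}/{variable}: value(s) exactly at the median; no split",
            stacklevel=2,
        )
        return SplitResult(treatment, variable, False, {}, med, sem)

    k = 2 if strict_two_each_side else 1
    if len(above) < k or len(below) < k:
        return SplitResult(treatment, variable, False, {}, med, sem)
    gap_high = float(above[0] - med)
    gap_low = float(med - below[0])
    # the k nearest points on each side must all clear one SEM; since
    # farther points clear whenever the nearest does, this reduces to
    # the nearest-point gaps plus the side-count requirement
    is_split = gap_high >= sem and gap_low >= sem
    assignments = (
        {i: ("A" if values[i] < med else "B") for i in ids} if is_split else {}
    )
    return SplitResult(treatment, variable, is_split, assignments, med, sem, gap_low, gap_high)


@dataclass
class TreatmentTestResult:
    """Omnibus treatment comparison with post-hoc table."""

    method: str  # "anova" or "kruskal"
    statistic: float
    p_value: float
    transform: str  # "none", "sqrt", "log", "log10p1"
    normality_p: dict
    levene_p: float
    posthoc: pd.DataFrame


_TRANSFORMS = {
    "none": lambda x: x,
    "sqrt": np.sqrt,
    "log": np.log,
    "log10p1": lambda x: np.log10(x + 1.0),
}


def _gates_pass(groups: list[np.ndarray]) -> tuple[bool, dict, float]:
    norm_p = {}
    ok = True
    for i, g in enumerate(groups):
        if len(g) >= 3 and np.ptp(g) > 0:
            p = stats.shapiro(g).pvalue
        else:
            p = 1.0
        norm_p[i] = p
        ok = ok and p >= ALPHA
    if all(np.ptp(g) == 0 for g in groups):
        lev_p = 1.0
    else:
        lev_p = stats.levene(*groups).pvalue
    return ok and lev_p >= ALPHA, norm_p, lev_p


def _tukey_unequal_n(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Tukey-Kramer (unequal-n HSD) pairwise comparisons."""
    labels = list(groups)
    all_x = np.concatenate([groups[g] for g in labels])
    all_g = np.concatenate([[g] * len(groups[g]) for g in labels])
    n_total, k = len(all_x), len(labels)
    mse = sum(
        ((groups[g] - groups[g].mean()) ** 2).sum() for g in labels
    ) / (n_total - k)
    rows = []
    for a, b in itertools.combinations(labels, 2):
        ga, gb = groups[a], groups[b]
        diff = ga.mean() - gb.mean()
        se = np.sqrt(mse / 2.0 * (1.0 / len(ga) + 1.0 / len(gb)))
        q = abs(diff) / se if se > 0 else 0.0
        p = stats.studentized_range.sf(q, k, n_total - k) if se > 0 else 1.0
        rows.append({"group1": a, "group2": b, "diff": diff, "p_adj": float(p)})
    return pd.DataFrame(rows)


def _dunn(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based multiple comparisons with tie correction."""
    labels = list(groups)
    all_x = np.concatenate([groups[g] for g in labels])
    ranks = stats.rankdata(all_x)
    n = len(all_x)
    idx = 0
    mean_rank = {}
    for g in labels:
        m = len(groups[g])
        mean_rank[g] = ranks[idx: idx + m].mean()
        idx += m
    _, tie_counts = np.unique(all_x, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    m_comp = len(labels) * (len(labels) - 1) // 2
    rows = []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)) * m_comp)  # Bonferroni-adjusted
        rows.append({"group1": a, "group2": b, "z": float(z), "p_adj": float(p)})
    return pd.DataFrame(rows)


def treatment_tests(
    values_by_treatment: dict[str, np.ndarray],
    posthoc: str = "hsd",
) -> TreatmentTestResult:
    """Omnibus comparison across treatments with assumption gates.

    Shapiro-Wilk normality per group and Levene homoscedasticity gate a
    one-way ANOVA.  If the raw data fail, the transform ladder (sqrt,
    log, log10(x+1)) is tried in order; if no transform passes, a
    Kruskal-Wallis test with Dunn post-hoc comparisons is used instead.
    Post-hoc after ANOVA: Tukey-Kramer unequal-n HSD (default) or Fisher
    LSD (unadjusted pairwise t).
    """
    groups = {
        k: np.asarray(v, dtype=float)
        for k, v in values_by_treatment.items()
        if len(v) >= 2
    }
    dropped = set(values_by_treatment) - set(groups)
    if dropped:
        warnings.warn(f"groups with < 2 observations excluded: {sorted(dropped)}", stacklevel=2)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 observations")

    arrays = list(groups.values())
    chosen = None
    for name, fn in _TRANSFORMS.items():
        if name in ("sqrt",) and any(np.any(a < 0) for a in arrays):
            continue
        if name == "log" and any(np.any(a <= 0) for a in arrays):
            continue
        if name == "log10p1" and any(np.any(a <= -1) for a in arrays):
            continue
        tx = [fn(a) for a in arrays]
        ok, norm_p, lev_p = _gates_pass(tx)
        if ok:
            chosen = (name, dict(zip(groups, tx)), norm_p, lev_p)
            break

    if chosen is not None:
        name, tgroups, norm_p, lev_p = chosen
        if all(np.ptp(g) == 0 for g in tgroups.values()):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.f_oneway(*tgroups.values())
        if posthoc == "hsd":
            ph = _tukey_unequal_n(tgroups)
        elif posthoc == "lsd":
            rows = []
            for a, b in itertools.combinations(tgroups, 2):
                t, pv = stats.ttest_ind(tgroups[a], tgroups[b])
                rows.append({"group1": a, "group2": b, "t": float(t), "p_adj": float(pv)})
            ph = pd.DataFrame(rows)
        else:
            raise ValueError(f"unknown post-hoc method {posthoc!r}")
        return TreatmentTestResult("anova", float(stat), float(p), name, norm_p, lev_p, ph)

    _, norm_p, lev_p = _gates_pass(arrays)
    if all(np.ptp(g) == 0 for g in arrays) and len({a[0] for a in arrays}) == 1:
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.kruskal(*arrays)
    return TreatmentTestResult(
        "kruskal", float(stat), float(p), "none", norm_p, lev_p, _dunn(groups)
    )


def nested_tank_check(
    values: np.ndarray, tank: np.ndarray, treatment: np.ndarray
) -> dict:
    """Nested ANOVA testing tank-within-treatment effects.

    Fits value ~ treatment + tank(treatment) and tests the nested tank
    term against the residual.  Returns the ANOVA table plus a flag
    raised when the tank term is significant at alpha = 0.05.
    Treatments with fewer than 2 tanks are excluded.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "tank": np.asarray(tank).astype(str),
        "treatment": np.asarray(treatment).astype(str),
    })
    n_tanks = df.groupby("treatment")["tank"].nunique()
    keep = n_tanks[n_tanks >= 2].index
    excluded = sorted(set(df["treatment"]) - set(keep))
    if excluded:
        warnings.warn(f"treatments with a single tank excluded: {excluded}", stacklevel=2)
    df = df[df["treatment"].isin(keep)].copy()
    if df.empty or df["treatment"].nunique() < 1:
        raise ValueError("no treatment has >= 2 tanks; nested ANOVA undefined")

    # recode tanks within treatment so the nested term has k*(m-1) df
    # instead of one column per (treatment, global-tank) combination
    df["tank"] = df.groupby("treatment")["tank"].transform(
        lambda s: pd.factorize(s)[0]
    ).astype(str)
    model = ols("value ~ C(treatment) + C(treatment):C(tank)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    tank_row = table.loc["C(treatment):C(tank)"]
    p_tank = float(tank_row["PR(>F)"])
    return {
        "anova_table": table,
        "tank_F": float(tank_row["F"]),
        "tank_p": p_tank,
        "tank_effect_flagged": p_tank < ALPHA,
        "excluded_treatments": excluded,
    }


@dataclass
class AssociationResult:
    """Yates-corrected chi-square on a 2x2 contingency table."""

    table: np.ndarray
    chi2: float
    df: int
    p_value: float
    n: int


def yates_chi_square(table) -> AssociationResult:
    """Continuity-corrected chi-square for a 2x2 table.

    chi2 = sum over cells of (max(|O - E| - 0.5, 0))^2 / E, with the
    correction clamped so it never overshoots |O - E|; df = 1.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("cell counts must be nonnegative integers")
    n = obs.sum()
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero marginal total: chi-square undefined")
    expected = row @ col / n
    adj = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    chi2 = float((adj**2 / expected).sum())
    p = float(stats.chi2.sf(chi2, 1))
    return AssociationResult(obs.astype(int), chi2, 1, p, int(n))


def mortality_summary(cohort: pd.DataFrame) -> dict:
    """Per-treatment mortality counts plus a rank test on tank ratios.

    ``cohort`` needs columns treatment, tank_id, alive.  Returns the
    dead/alive counts per treatment, and a Kruskal-Wallis omnibus on the
    per-tank mortality proportions with Dunn post-hoc comparisons; when
    every tank has the same proportion the omnibus is reported as
    degenerate (no variation).
    """
    counts = (
        cohort.groupby("treatment")["alive"]
        .agg(n="size", survivors="sum")
        .assign(dead=lambda d: d["n"] - d["survivors"])
    )
    tank_props = (
        cohort.groupby(["treatment", "tank_id"])["alive"]
        .apply(lambda s: 1.0 - s.mean())
        .rename("mortality")
        .reset_index()
    )
    groups = {
        t: g["mortality"].to_numpy() for t, g in tank_props.groupby("treatment")
    }
    all_props = np.concatenate(list(groups.values()))
    if np.ptp(all_props) == 0:
        return {"counts": counts, "omnibus": None, "posthoc": None,
                "note": "no variation in tank mortality"}
    h, p = stats.kruskal(*groups.values())
    return {
        "counts": counts,
        "omnibus": {"H": float(h), "p": float(p)},
        "posthoc": _dunn(groups),
        "note": "",
    }


def ecotype_association(
    response_class: dict,
    ecotypes: dict,
    endpoint: str = "SMR",
    min_known_fraction: float = 0.8,
) -> AssociationResult:
    """Ecotype x response-class association across the split treatments.

    ``response_class`` maps fish id -> "A" (reduced) or "B"
    (heightened), pooled across the treatments where the split rule
    fired; ``ecotypes`` maps fish id -> "coastal" / "offshore" /
    "unknown".  Fish with unknown ecotype are excluded; the test
    requires ecotype known for at least ``min_known_fraction`` of split
    fish.  Returns the Yates-corrected chi-square on the 2x2 table.
    """
    split_ids = list(response_class)
    known = [i for i in split_ids if ecotypes.get(i, "unknown") in ("coastal", "offshore")]
    if not split_ids:
        raise ValueError("no split fish supplied")
    if len(known) / len(split_ids) < min_known_fraction:
        raise ValueError(
            f"ecotype known for {len(known)}/{len(split_ids)} split fish; "
            f"need >= {min_known_fraction:.0%}"
        )
    table = np.zeros((2, 2))
    for i in known:
        r = 0 if ecotypes[i] == "offshore" else 1
        c = 0 if response_class[i] == "B" else 1
        table[r, c] += 1
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(f"empty pooled class for endpoint {endpoint}")
    return yates_chi_square(table)
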