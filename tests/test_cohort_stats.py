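"""Cohort statistics: condition factor, split rule, treatment tests,
nested tank ANOVA, Yates chi-square, mortality, ecotype association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from codstress.cohort_stats import (
    ecotype_association,
    fulton_k,
    mortality_summary,
    nested_tank_check,
    split_within_treatment,
    treatment_tests,
    yates_chi_square,
)


class TestFultonK:
    def test_unit_case(self):
        assert fulton_k(10.0, 10.0) == pytest.approx(1.0)

    def test_cohort_means(self):
        assert fulton_k(159.4, 24.3) == pytest.approx(100 * 159.4 / 24.3**3, rel=1e-12)
        assert fulton_k(159.4, 24.3) == pytest.approx(1.111, abs=0.001)

    def test_homogeneity(self):
        assert fulton_k(20.0, 10.0) == pytest.approx(2 * fulton_k(10.0, 10.0))
        assert fulton_k(10.0, 20.0) == pytest.approx(fulton_k(10.0, 10.0) / 8)

    def test_domain(self):
        with pytest.raises(ValueError):
            fulton_k(-1.0, 10.0)


class TestSplitRule:
    def test_clear_gap_splits(self):
        values = dict(zip("abcdef", [1.0, 2, 3, 10, 11, 12]))
        res = split_within_treatment(values)
        assert res.is_split
        assert res.median == pytest.approx(6.5)
        assert res.sem == pytest.approx(np.std([1, 2, 3, 10, 11, 12], ddof=1) / np.sqrt(6))
        assert {k for k, v in res.assignments.items() if v == "A"} == {"a", "b", "c"}
        assert {k for k, v in res.assignments.items() if v == "B"} == {"d", "e", "f"}

    def test_continuum_no_split(self):
        values = dict(zip("abcdef", [1.0, 2, 3, 4, 5, 6]))
        res = split_within_treatment(values)
        assert not res.is_split
        assert res.assignments == {}

    def test_constant_vector_no_split(self):
        res = split_within_treatment(dict(zip("abcd", [5.0, 5, 5, 5])))
        assert not res.is_split

    def test_value_at_median_odd_n_no_split(self):
        values = dict(zip("abcde", [1.0, 2, 6, 10, 11]))
        with pytest.warns(UserWarning, match="median"):
            res = split_within_treatment(values)
        assert not res.is_split

    def test_a_below_b_above_median(self):
        values = dict(zip("abcdefgh", [0.0, 1, 2, 3, 20, 21, 22, 23]))
        res = split_within_treatment(values)
        assert res.is_split
        for k, v in values.items():
            assert res.assignments[k] == ("A" if v < res.median else "B")

    def test_affine_equivariance(self, rng):
        """Scaling/shifting values never changes the decision or groups."""
        for _ in range(25):
            vals = rng.normal(0, 1, 12)
            base = split_within_treatment(dict(enumerate(vals)))
            a, b = rng.uniform(0.1, 10), rng.uniform(-100, 100)
            tx = split_within_treatment(dict(enumerate(a * vals + b)))
            assert base.is_split == tx.is_split
            assert base.assignments == tx.assignments

    def test_strict_variant_more_conservative(self, rng):
        for _ in range(50):
            vals = rng.normal(0, 1, 10)
            loose = split_within_treatment(dict(enumerate(vals)))
            strict = split_within_treatment(dict(enumerate(vals)), strict_two_each_side=True)
            if strict.is_split:
                assert loose.is_split

    def test_minimum_n(self):
        with pytest.raises(ValueError, match=">= 4"):
            split_within_treatment({"a": 1.0, "b": 2.0, "c": 3.0})


class TestTreatmentTests:
    def test_identical_groups_high_p(self, rng):
        g = rng.normal(10, 1, 20)
        res = treatment_tests({"a": g, "b": g.copy(), "c": g.copy()})
        assert res.p_value > 0.9
        assert not (res.posthoc["p_adj"] < 0.05).any()

    def test_large_shift_detected(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(5, 1, 20)
        res = treatment_tests({"a": a, "b": b})
        assert res.p_value < 0.001
        assert (res.posthoc["p_adj"] < 0.001).all()

    def test_kruskal_branch_hand_ranked_oracle(self):
        """Groups engineered to fail every gate: H must equal the
        hand-ranked Kruskal-Wallis value 7.2 for [1-3],[4-6],[7-9]."""
        groups = {
            "a": np.array([1.0, 2, 3]),
            "b": np.array([4.0, 5, 6]),
            "c": np.array([7.0, 8, 9]),
        }
        h = 12 / (9 * 10) * (3 * (2 - 5) ** 2 + 3 * (5 - 5) ** 2 + 3 * (8 - 5) ** 2)
        got, _ = stats.kruskal(*groups.values())
        assert got == pytest.approx(h)

    def test_transform_ladder_rescues_lognormal(self):
        """Log-normal groups with equal log-variance should pass the
        gates after a transform rather than falling through to ranks.
        Built from exponentiated normal scores so the log branch is
        gate-clean by construction while the raw data are skewed."""
        scores = stats.norm.ppf((np.arange(25) + 0.5) / 25)
        groups = {k: np.exp(m + 1.0 * scores) for k, m in
                  [("a", 0.0), ("b", 0.1), ("c", 0.2)]}
        raw_shapiro = min(stats.shapiro(g).pvalue for g in groups.values())
        assert raw_shapiro < 0.05  # raw data genuinely fail the gate
        res = treatment_tests(groups)
        assert res.method == "anova"
        assert res.transform in ("log", "sqrt", "log10p1")

    def test_heteroscedastic_falls_to_kruskal(self, rng):
        # bimodal + wildly unequal spread defeats the ladder
        a = np.concatenate([rng.normal(0, 0.01, 15), rng.normal(10, 0.01, 15)])
        b = rng.normal(5, 20, 30)
        c = np.concatenate([rng.normal(-5, 0.01, 15), rng.normal(20, 0.01, 15)])
        res = treatment_tests({"a": a, "b": b, "c": c})
        assert res.method == "kruskal"

    def test_small_group_excluded(self, rng):
        with pytest.warns(UserWarning, match="excluded"):
            res = treatment_tests({"a": rng.normal(0, 1, 10), "b": rng.normal(0, 1, 10), "c": [1.0]})
        assert set(res.normality_p) == {0, 1}

    def test_lsd_posthoc_available(self, rng):
        res = treatment_tests(
            {"a": rng.normal(0, 1, 10), "b": rng.normal(3, 1, 10)}, posthoc="lsd"
        )
        assert "t" in res.posthoc.columns


class TestNestedTank:
    @staticmethod
    def _design(rng, tank_sd=0.0, n_treat=3, n_tank=4, n_fish=5):
        rows = []
        for t in range(n_treat):
            for k in range(n_tank):
                tank_eff = rng.normal(0, tank_sd)
                for f in range(n_fish):
                    rows.append((rng.normal(t, 1) + tank_eff, f"t{t}_k{k}", f"t{t}"))
        v, tank, treat = zip(*rows)
        return np.array(v), np.array(tank), np.array(treat)

    def test_null_flag_rate_near_alpha(self):
        rng = np.random.default_rng(7)
        flags = sum(
            nested_tank_check(*self._design(rng))["tank_effect_flagged"]
            for _ in range(200)
        )
        assert 0.01 <= flags / 200 <= 0.10  # nominal 0.05 with binomial slack

    def test_large_tank_effect_flagged(self):
        rng = np.random.default_rng(8)
        res = nested_tank_check(*self._design(rng, tank_sd=3.0))
        assert res["tank_effect_flagged"]

    def test_single_tank_per_treatment_error(self, rng):
        v = rng.normal(0, 1, 10)
        tank = np.array(["k1"] * 10)
        treat = np.array(["t1"] * 10)
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            nested_tank_check(v, tank, treat)


class TestYatesChiSquare:
    def test_balanced_table_zero(self):
        res = yates_chi_square([[5, 5], [5, 5]])
        assert res.chi2 == 0.0 and res.p_value == 1.0 and res.n == 20

    def test_hand_oracle(self):
        """E = 7.5 everywhere; chi2 = 4 * (2.5 - 0.5)^2 / 7.5."""
        res = yates_chi_square([[10, 5], [5, 10]])
        assert res.chi2 == pytest.approx(4 * 2.0**2 / 7.5)
        assert res.chi2 == pytest.approx(2.133, abs=0.001)

    def test_equivalence_with_scipy_on_random_tables(self, rng):
        checked = 0
        while checked < 100:
            table = rng.integers(1, 40, size=(2, 2))
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            if np.abs(table - expected).min() < 0.5:
                continue  # scipy does not clamp the correction below |O-E|
            ref = stats.chi2_contingency(table, correction=True)
            res = yates_chi_square(table)
            assert res.chi2 == pytest.approx(ref.statistic, rel=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)
            checked += 1

    def test_correction_never_exceeds_uncorrected(self, rng):
        for _ in range(50):
            table = rng.integers(0, 30, size=(2, 2))
            if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
                continue
            yates = yates_chi_square(table).chi2
            plain = stats.chi2_contingency(table, correction=False).statistic
            assert yates <= plain + 1e-12

    def test_zero_marginal_error(self):
        with pytest.raises(ValueError, match="marginal"):
            yates_chi_square([[0, 0], [5, 5]])


class TestMortality:
    @staticmethod
    def _cohort(deaths_per_treatment):
        rows = []
        for t, deaths in deaths_per_treatment.items():
            fish = 0
            for tank in range(4):
                for f in range(5):
                    rows.append(
                        {"fish_id": f"{t}{tank}{f}", "treatment": t,
                         "tank_id": f"{t}_k{tank}", "alive": fish >= deaths}
                    )
                    fish += 1
        return pd.DataFrame(rows)

    def test_observed_death_pattern(self):
        deaths = {"control": 0, "low_salinity": 4, "high_temp": 2, "low_pH": 2,
                  "multi_stressor": 2}
        res = mortality_summary(self._cohort(deaths))
        assert dict(res["counts"]["survivors"]) == {
            "control": 20, "low_salinity": 16, "high_temp": 18,
            "low_pH": 18, "multi_stressor": 18,
        }

    def test_all_alive_degenerate(self):
        res = mortality_summary(self._cohort({"a": 0, "b": 0}))
        assert res["omnibus"] is None
        assert "no variation" in res["note"]

    def test_extreme_contrast_flagged(self):
        res = mortality_summary(self._cohort({"all_dead": 20, "none_dead": 0}))
        assert res["omnibus"]["p"] < 0.05
        pair = res["posthoc"].iloc[0]
        assert pair["p_adj"] < 0.05


class TestEcotypeAssociation:
    def test_perfect_concordance_rejects(self):
        """16 offshore all heightened, 15 coastal all reduced (n = 31)."""
        response = {f"o{i}": "B" for i in range(16)} | {f"c{i}": "A" for i in range(15)}
        ecotypes = {f"o{i}": "offshore" for i in range(16)} | {
            f"c{i}": "coastal" for i in range(15)
        }
        res = ecotype_association(response, ecotypes)
        assert res.n == 31
        assert res.p_value < 0.01

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(11)
        rejections = 0
        for _ in range(500):
            ids = [f"f{i}" for i in range(31)]
            response = {i: ("B" if rng.random() < 0.5 else "A") for i in ids}
            ecotypes = {i: ("offshore" if rng.random() < 0.45 else "coastal") for i in ids}
            try:
                res = ecotype_association(response, ecotypes)
            except ValueError:
                continue
            rejections += res.p_value < 0.05
        # Yates correction makes the test conservative at this n
        assert 0.0 < rejections / 500 <= 0.08

    def test_all_one_ecotype_error(self):
        response = {"a": "A", "b": "B", "c": "A", "d": "B"}
        ecotypes = {k: "coastal" for k in response}
        with pytest.raises(ValueError, match="empty pooled|marginal"):
            ecotype_association(response, ecotypes)

    def test_unknown_fraction_gate(self):
        response = {f"f{i}": "A" for i in range(10)}
        ecotypes = {f"f{i}": "unknown" for i in range(10)}
        with pytest.raises(ValueError, match="known"):
            ecotype_association(response, ecotypes)
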