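"""RLRS computation, selection-effect regressions, subgroup scans and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selgen.scan import (
    aflb_control_contrast,
    birth_year_trend,
    completed_fertility_filter,
    compute_rlrs,
    cross_generation_compare,
    estimate_selection,
    median_pct_difference,
    meta_human_capital,
    risk_attitude_robustness,
    scan_all,
    standardize_scores,
    subgroup_scan,
    SelectionEffect,
)
from selgen.simulate import GeneratorConfig, generate_cohort

from conftest import clean_config


class TestComputeRlrs:
    def test_equal_fertility_gives_unit_rlrs(self, single_year_table):
        tab = single_year_table([0.0, 0.1, -0.1, 0.2], [2, 2, 2, 2])
        assert np.allclose(compute_rlrs(tab), 1.0)

    def test_simple_example(self, single_year_table):
        tab = single_year_table([0.0, 0.1, -0.1], [1, 2, 3])
        assert np.allclose(compute_rlrs(tab), [0.5, 1.0, 1.5])

    def test_within_year_mean_is_one(self, small_cohort):
        rlrs = compute_rlrs(small_cohort)
        means = rlrs.groupby(small_cohort["birth_year"]).mean()
        assert np.allclose(means, 1.0, atol=1e-12)

    def test_parents_generation_uses_sibship(self, single_year_table):
        tab = single_year_table([0.0, 0.0], [0, 0])
        tab["n_siblings"] = [0, 2]  # parental families of 1 and 3 children
        assert np.allclose(compute_rlrs(tab, "parents"), [0.5, 1.5])

    def test_zero_fertility_year_flagged_not_dropped(self, single_year_table):
        tab = single_year_table([0.0, 0.1, 0.2, -0.1], [1, 2, 0, 0])
        tab["birth_year"] = [1950, 1950, 1951, 1951]
        rlrs = compute_rlrs(tab)
        assert rlrs.notna().sum() == 2 and rlrs.isna().sum() == 2

    def test_unknown_generation_rejected(self, single_year_table):
        with pytest.raises(ValueError):
            compute_rlrs(single_year_table([0.0], [1]), "grandparents")

    @settings(derandomize=True, max_examples=25)
    @given(counts=st.lists(st.integers(0, 8), min_size=3, max_size=30))
    def test_mean_one_property(self, counts):
        if sum(counts) == 0:
            return
        tab = pd.DataFrame(
            {"birth_year": 1950, "n_children": counts, "n_siblings": 0}
        )
        rlrs = compute_rlrs(tab)
        assert rlrs.mean() == pytest.approx(1.0, abs=1e-12)


class TestCompletedFertilityFilter:
    @pytest.mark.parametrize(
        "sex, birth_year, kept",
        [
            ("M", 1959, True),   # age 51
            ("M", 1960, False),  # age 50: not over 50
            ("F", 1964, True),   # age 46
            ("F", 1965, False),  # age 45: not over 45
        ],
    )
    def test_age_boundaries(self, single_year_table, sex, birth_year, kept):
        tab = single_year_table([0.0], [1])
        tab["sex"], tab["birth_year"] = sex, birth_year
        out, counts = completed_fertility_filter(tab, reference_year=2010)
        assert (len(out) == 1) is kept
        assert counts["retained"] + counts["excluded"] == 1

    def test_empty_input(self, single_year_table):
        tab = single_year_table([0.0], [1]).iloc[0:0]
        out, counts = completed_fertility_filter(tab)
        assert len(out) == 0 and counts["retained"] == 0


class TestSelectionIdentity:
    def test_worked_robertson_price_instance(self, single_year_table):
        z = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0 / 3.0)
        tab = single_year_table(z, [1, 2, 3])
        tab["rlrs"] = compute_rlrs(tab)
        eff = estimate_selection(tab, "pgs_1")
        assert eff.beta == pytest.approx(1.0 / np.sqrt(6.0), abs=1e-10)

    def test_slope_equals_child_weighted_mean_score(self, single_year_table):
        rng = np.random.default_rng(9)
        z_raw = rng.standard_normal(40)
        n = rng.poisson(2.0, 40)
        tab = standardize_scores(single_year_table(z_raw, n))
        tab["rlrs"] = compute_rlrs(tab)
        eff = estimate_selection(tab, "pgs_1")
        z = tab["pgs_1"].to_numpy()
        assert eff.beta == pytest.approx((n * z).sum() / n.sum(), abs=1e-10)

    def test_equal_weights_match_unweighted(self, single_year_table):
        rng = np.random.default_rng(2)
        tab = single_year_table(rng.standard_normal(30), rng.poisson(2, 30))
        tab["rlrs"] = compute_rlrs(tab)
        unw = estimate_selection(tab, "pgs_1", weights=False)
        wtd = estimate_selection(tab, "pgs_1", weights=True)
        assert wtd.beta == pytest.approx(unw.beta, abs=1e-12)

    def test_degenerate_regressor_rejected(self, single_year_table):
        tab = single_year_table([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        tab["rlrs"] = compute_rlrs(tab)
        with pytest.raises(ValueError, match="zero variance"):
            estimate_selection(tab, "pgs_1")

    def test_insufficient_data_rejected(self, single_year_table):
        tab = single_year_table([0.0, 1.0], [1, 2])
        tab["rlrs"] = compute_rlrs(tab)
        with pytest.raises(ValueError, match="insufficient"):
            estimate_selection(tab, "pgs_1")


class TestScanAll:
    def test_bonferroni_threshold(self, small_cohort):
        rep = scan_all(small_cohort)
        assert rep.threshold == pytest.approx(0.05 / 4)

    def test_weighted_and_unweighted_per_score(self, small_cohort):
        rep = scan_all(small_cohort)
        assert len(rep.effects) == 8
        assert {e.weighted for e in rep.effects} == {False, True}

    def test_failing_score_reported_others_computed(self, small_cohort):
        broken = small_cohort.copy()
        broken["pgs_1"] = 0.0
        rep = scan_all(broken)
        assert "pgs_1" in rep.exclusions
        assert {e.score_id for e in rep.effects} == {"pgs_2", "pgs_3", "pgs_4"}

    def test_summary_recomputable_from_effects(self, small_cohort):
        rep = scan_all(small_cohort)
        unw = {e.score_id: e.beta for e in rep.effects if not e.weighted}
        wtd = {e.score_id: e.beta for e in rep.effects if e.weighted}
        pct = np.mean(
            [100 * (abs(wtd[s]) - abs(unw[s])) / abs(unw[s]) for s in unw]
        )
        assert rep.summary["mean_pct_change_from_weighting"] == pytest.approx(pct)


class TestSubgroupScan:
    def test_partner_split_at_median(self):
        t = generate_cohort(GeneratorConfig(n=8_000, n_scores=1, seed=33))
        rep = subgroup_scan(t, "partners")
        med = t["n_sex_partners"].median()
        labels = {e.subgroup for e in rep.effects}
        assert labels == {f"partners<={med:g}", f"partners>{med:g}"}

    def test_heterogeneous_truth_recovered(self):
        cfg = clean_config(
            n=120_000,
            birth_year_range=(1945, 1955),
            subgroup_multipliers={"income_band": (2.0, 1.5, 1.25, 1.0, 1.0)},
            seed=41,
        )
        t = generate_cohort(cfg)
        rep = subgroup_scan(t, "income")
        by = {e.subgroup: e for e in rep.effects}
        lo, hi = by["income_band=1"], by["income_band=5"]
        assert abs(lo.beta) > abs(hi.beta)
        sep = abs(lo.beta - hi.beta) / np.hypot(lo.se, hi.se)
        assert sep > 3

    def test_homogeneous_truth_no_spurious_contrast(self):
        cfg = clean_config(n=60_000, birth_year_range=(1945, 1955), seed=42)
        t = generate_cohort(cfg)
        rep = subgroup_scan(t, "income")
        by = {e.subgroup: e for e in rep.effects}
        lo, hi = by["income_band=1"], by["income_band=5"]
        assert abs(lo.beta - hi.beta) < 3 * np.hypot(lo.se, hi.se)

    def test_aflb_terciles_women_only(self, small_cohort):
        rep = subgroup_scan(small_cohort, "aflb-terciles")
        n_women_aflb = (
            (small_cohort.sex == "F") & small_cohort.aflb.notna()
        ).sum()
        assert sum(e.n for e in rep.effects if e.score_id == "pgs_1") <= n_women_aflb

    def test_tiny_stratum_reported_not_estimable(self, single_year_table):
        tab = single_year_table(
            np.r_[np.random.default_rng(0).standard_normal(9), 0.5],
            [1, 2, 1, 3, 2, 1, 2, 2, 1, 2],
        )
        tab["lives_with_partner"] = [1] * 9 + [0]
        rep = subgroup_scan(tab, "cohabiting")
        assert any("not_cohabiting" in key for key in rep.exclusions)


class TestMedianPctDifference:
    @staticmethod
    def _eff(score, beta, p=1e-6, group="A"):
        return SelectionEffect(score, group, False, (), beta, 0.01, p, 100)

    def test_double_effect_is_100pct(self):
        a = [self._eff(f"pgs_{i}", 0.2) for i in range(3)]
        b = [self._eff(f"pgs_{i}", 0.1, group="B") for i in range(3)]
        assert median_pct_difference(a, b, 0.05) == pytest.approx(100.0)

    def test_equal_effects_zero(self):
        a = [self._eff("pgs_1", 0.2)]
        b = [self._eff("pgs_1", 0.2, group="B")]
        assert median_pct_difference(a, b, 0.05) == pytest.approx(0.0)

    def test_median_of_ratios(self):
        ratios = [1.5, 2.5, 6.95]
        a = [self._eff(f"pgs_{i}", 0.1 * r) for i, r in enumerate(ratios)]
        b = [self._eff(f"pgs_{i}", 0.1, group="B") for i in range(3)]
        assert median_pct_difference(a, b, 0.05) == pytest.approx(150.0)

    def test_sign_flipped_scores_excluded(self):
        a = [self._eff("pgs_1", 0.2), self._eff("pgs_2", 0.2)]
        b = [self._eff("pgs_1", 0.1, group="B"), self._eff("pgs_2", -0.1, group="B")]
        assert median_pct_difference(a, b, 0.05) == pytest.approx(100.0)

    def test_empty_qualifying_set_is_nan(self):
        a = [self._eff("pgs_1", 0.2, p=0.9)]  # not significant
        b = [self._eff("pgs_1", 0.1, group="B")]
        assert np.isnan(median_pct_difference(a, b, 0.05))


class TestAflbContrast:
    @staticmethod
    def _two_channel_table(n=40_000, seed=6, opposing=True):
        # score raises AFLB; conditional on AFLB the score raises fertility.
        # the AFLB channel dominates marginally, so controlling flips the sign.
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(n)
        aflb = 25 + 3 * z + 2 * rng.standard_normal(n)
        direct = 0.08 * z if opposing else 0.0
        mean = np.clip(2.0 - 0.12 * (aflb - 25) / 3 + direct, 0.05, None)
        tab = pd.DataFrame(
            {
                "id": np.arange(1, n + 1),
                "sex": "F",
                "birth_year": 1950,
                "n_children": rng.poisson(mean),
                "n_siblings": 1,
                "income_band": 1,
                "edu_age_band": 1,
                "aflb": np.clip(aflb, 14, 45),
                "n_sex_partners": 2,
                "lives_with_partner": 1,
                "risk_attitude": 0,
                "weight": 1.0,
                "pgs_1": z,
            }
        )
        tab.loc[tab.n_children == 0, "aflb"] = np.nan
        return tab

    def test_opposing_channels_flip_sign(self):
        out = aflb_control_contrast(self._two_channel_table(opposing=True))
        row = out.iloc[0]
        assert row["beta_raw"] < 0 < row["beta_controlled"]
        assert row["sign_changed"]

    def test_full_mediation_by_control(self):
        out = aflb_control_contrast(self._two_channel_table(opposing=False))
        row = out.iloc[0]
        assert abs(row["beta_controlled"]) < 3 * row["se_controlled"]

    def test_independent_aflb_leaves_effect(self):
        tab = self._two_channel_table(opposing=False)
        rng = np.random.default_rng(1)
        tab["aflb"] = np.where(
            tab["aflb"].notna(), rng.uniform(18, 35, len(tab)), np.nan
        )
        tab["n_children"] = rng.poisson(np.clip(2.0 - 0.1 * tab["pgs_1"], 0.05, None))
        out = aflb_control_contrast(tab)
        row = out.iloc[0]
        assert row["beta_controlled"] == pytest.approx(
            row["beta_raw"], abs=3 * row["se_controlled"]
        )


class TestBirthYearTrend:
    def test_drift_detected(self):
        cfg = clean_config(n=50_000, birth_year_range=(1940, 1970), seed=51)
        t = generate_cohort(cfg)
        # inject a +0.05 SD drift over the 30-year span into one score
        drift = 0.05 * (t["birth_year"] - 1940) / 30
        t["pgs_1"] = t["pgs_1"] + drift
        out = birth_year_trend(t)
        row = out.iloc[0]
        assert row["slope_per_year"] > 0 and row["significant"]

    def test_null_scores_rarely_significant(self):
        cfg = clean_config(
            n=30_000, n_scores=3, score_hc_corr=(0.0,) * 3,
            gamma=(0.0,) * 3, birth_year_range=(1940, 1970), seed=52,
        )
        out = birth_year_trend(generate_cohort(cfg))
        assert out["significant"].sum() == 0

    def test_slope_invariant_to_recentred_years(self):
        cfg = clean_config(n=5_000, birth_year_range=(1940, 1960), seed=53)
        t = generate_cohort(cfg)
        s1 = birth_year_trend(t)["slope_per_year"].iloc[0]
        t2 = t.assign(birth_year=t["birth_year"] - 1950)
        s2 = birth_year_trend(t2)["slope_per_year"].iloc[0]
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_single_year_not_estimable(self, single_year_table):
        with pytest.raises(ValueError, match="2 distinct"):
            birth_year_trend(single_year_table([0.1, 0.2, 0.3], [1, 2, 3]))


class TestCrossGeneration:
    def test_shared_truth_gives_high_effect_correlation(self):
        cfg = clean_config(
            n=80_000, n_scores=4, score_hc_corr=(0.0,) * 4,
            gamma=(-0.06, -0.02, 0.02, 0.06),
            parent_gamma_scale=1.0, birth_year_range=(1945, 1955), seed=61,
        )
        out = cross_generation_compare(generate_cohort(cfg))
        assert out["effect_correlation"] > 0.9

    def test_independent_parental_fertility_decorrelates_rlrs(self):
        cfg = clean_config(n=40_000, birth_year_range=(1945, 1955), seed=62)
        out = cross_generation_compare(generate_cohort(cfg))
        assert abs(out["rlrs_correlation"]) < 0.02

    def test_heritable_fertility_gives_positive_rlrs_correlation(self):
        cfg = clean_config(
            n=40_000, parent_fertility_noise_sd=0.25, fertility_heritability=1.0,
            parent_gamma_scale=1.0, birth_year_range=(1945, 1955), seed=63,
        )
        out = cross_generation_compare(generate_cohort(cfg))
        assert out["rlrs_correlation"] > 0.05

    def test_size_bias_diagnostic_emitted(self, small_cohort):
        out = cross_generation_compare(small_cohort)
        assert out["mean_parental_children"] > 0


class TestMetaHumanCapital:
    def test_mechanism_gives_strong_negative_correlation(self):
        rho = (0.5, 0.35, 0.2, 0.05, -0.2)
        cfg = GeneratorConfig(
            n=60_000, n_scores=5, score_hc_corr=rho,
            gamma=tuple(-0.15 * r for r in rho),
            subgroup_multipliers={}, ascertainment_strength=0.0,
            mediation_frac=0.25, seed=71,
        )
        t = generate_cohort(cfg)
        rep = scan_all(t)
        eff = [e for e in rep.effects if not e.weighted]
        out = meta_human_capital(eff, t)
        assert out.attrs["cross_score_correlation"] < -0.8

    def test_unrelated_gamma_gives_weak_correlation(self):
        # fertility coefficients orthogonal to the scores' human-capital
        # loadings; income (an HC measure untouched by the fertility channel)
        # then carries no cross-score relation with selection effects
        cfg = GeneratorConfig(
            n=60_000, n_scores=6, score_hc_corr=(0.4, -0.4, 0.3, -0.3, 0.2, -0.2),
            gamma=(0.03,) * 6, income_hc_weight=0.6,
            subgroup_multipliers={}, ascertainment_strength=0.0, seed=72,
        )
        t = generate_cohort(cfg)
        rep = scan_all(t)
        eff = [e for e in rep.effects if not e.weighted]
        out = meta_human_capital(eff, t, hc_col="income_band")
        assert abs(out.attrs["cross_score_correlation"]) < 0.6

    def test_fewer_than_three_scores_rejected(self, small_cohort):
        rep = scan_all(small_cohort)
        eff = [e for e in rep.effects if not e.weighted][:2]
        with pytest.raises(ValueError, match=">= 3"):
            meta_human_capital(eff, small_cohort[
                ["pgs_1", "pgs_2", "edu_age_band"]
            ])


class TestRiskAttitude:
    def test_independent_risk_ratio_near_one(self):
        cfg = clean_config(n=60_000, risk_fertility_coef=0.05, seed=81)
        out = risk_attitude_robustness(generate_cohort(cfg))
        assert out.attrs["median_ratio"] == pytest.approx(1.0, abs=0.05)
        assert out.attrs["risk_predicts_rlrs_p"] < 1e-6

    def test_fully_confounded_score_ratio_near_zero(self, single_year_table):
        rng = np.random.default_rng(82)
        n = 60_000
        risk = (rng.random(n) < 0.3).astype(int)
        z = (risk - 0.3) / np.sqrt(0.21) * 0.9 + 0.44 * rng.standard_normal(n)
        children = rng.poisson(2.0 * (1 + 0.15 * (risk - 0.3)))
        tab = single_year_table(z, children)
        tab["risk_attitude"] = risk
        out = risk_attitude_robustness(tab)
        assert abs(out["ratio"].iloc[0]) < 0.25

    def test_constant_risk_column_dropped(self, single_year_table):
        rng = np.random.default_rng(83)
        tab = single_year_table(rng.standard_normal(500), rng.poisson(2, 500))
        tab["risk_attitude"] = 1
        out = risk_attitude_robustness(tab)
        assert out["beta_controlled"].iloc[0] == out["beta_raw"].iloc[0]
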