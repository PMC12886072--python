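import numpy as np
import pandas as pd
import pytest

from nichedose import (
    CohortSimConfig,
    CoxModelSpec,
    MODEL_REGISTRY,
    adjusted_vif,
    correlate_dose_burden,
    fit_cox,
    generate_cohort_table,
    km_by_group,
    sensitivity_filters,
)
from nichedose.survival_models import RankDeficientDesignError, complete_cases


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort_table(CohortSimConfig(n_patients=400), seed=11)


class TestModelRegistry:
    def test_specs_are_strictly_nested(self):
        for interest in ("svz_dose", "hpc_dose", "svz_contact", "hpc_contact"):
            tiers = [set(MODEL_REGISTRY[f"{interest}_m{k}"].covariates) for k in range(4)]
            for small, big in zip(tiers, tiers[1:]):
                assert small < big

    def test_interest_variable_present_once(self):
        for spec in MODEL_REGISTRY.values():
            assert spec.covariates.count(spec.variable_of_interest) == 1

    def test_full_models_adjust_for_burden_and_gtv(self):
        covs = MODEL_REGISTRY["svz_dose_m3"].covariates
        assert "gtv_volume_cm3" in covs and "n_bm" in covs and "svz_volume_cm3" in covs
        assert "sgz_volume_cm3" in MODEL_REGISTRY["hpc_dose_m3"].covariates

    def test_duplicate_interest_rejected(self):
        with pytest.raises(ValueError):
            CoxModelSpec("bad", ("age", "age"), "age")


class TestKaplanMeier:
    def toy_table(self, times, events, group):
        return pd.DataFrame({"os_months": times, "event": events, "grp": group})

    def test_product_limit_matches_hand_computation(self):
        # one group: times 1,2,3,4 all events -> S = .75, .5, .25, 0; median 2
        t = self.toy_table([1, 2, 3, 4, 1, 2, 3, 4], [1] * 8, ["a"] * 4 + ["b"] * 4)
        res = km_by_group(t, "grp")
        g = res.groups["a"]
        np.testing.assert_allclose(
            g.survival[np.isin(g.times, [1, 2, 3, 4])], [0.75, 0.5, 0.25, 0.0]
        )
        assert g.median_months == 2

    def test_censoring_reduces_risk_set(self):
        # times 1+,2,3 with censoring at 1: S(2)=2/3*1/2... hand table:
        # t=2: at risk 2, 1 event -> S=0.5 ; t=3: at risk 1, 1 event -> S=0
        t = self.toy_table([1, 2, 3, 1, 2, 3], [0, 1, 1, 0, 1, 1], list("aaabbb"))
        g = km_by_group(t, "grp").groups["a"]
        assert g.survival[g.times == 2][0] == pytest.approx(0.5)
        assert g.survival[g.times == 3][0] == pytest.approx(0.0)

    def test_all_censored_medians_not_reached(self):
        t = self.toy_table([5, 6, 7, 8], [0, 0, 0, 0], ["a", "a", "b", "b"])
        res = km_by_group(t, "grp")
        assert all(g.median_not_reached for g in res.groups.values())
        assert all(g.median_display == "NR" for g in res.groups.values())

    def test_separated_groups_detected(self, rng):
        n = 300
        t = self.toy_table(
            np.concatenate([rng.exponential(6, n), rng.exponential(9, n)]),
            [1] * (2 * n),
            ["hi"] * n + ["lo"] * n,
        )
        res = km_by_group(t, "grp")
        assert res.logrank_p < 1e-3
        assert res.hr_cox < 1  # "lo" hazard lower than "hi"
        # the O/E ratio is a coarser estimate but must agree in size and sign
        assert res.hr_logrank < 1
        assert res.hr_logrank == pytest.approx(res.hr_cox, rel=0.35)

    def test_empty_group_and_bad_levels_rejected(self):
        t = self.toy_table([1, 2], [1, 1], ["a", "a"])
        with pytest.raises(ValueError):
            km_by_group(t, "grp")


class TestCoxFit:
    def test_null_covariate_has_unit_hazard_ratio(self, rng):
        n = 2000
        table = pd.DataFrame(
            {
                "svz_mean_dose_gy": rng.uniform(0, 5, n),
                "os_months": rng.exponential(8, n),
                "event": 1,
            }
        )
        res = fit_cox(table, MODEL_REGISTRY["svz_dose_m0"])
        row = res.interest_row
        assert row["hr"] == pytest.approx(1.0, abs=0.05)
        assert row["ci_lower"] < 1.0 < row["ci_upper"]

    def test_known_effect_recovered_within_fitted_ci(self, cohort):
        from nichedose import recovery_config

        table = generate_cohort_table(recovery_config("svz", n_patients=3000), seed=3)
        res = fit_cox(table, MODEL_REGISTRY["svz_dose_m3"])
        row = res.interest_row
        assert row["ci_lower"] < 1.306 < row["ci_upper"]

    def test_row_duplication_leaves_point_estimates_unchanged(self, cohort):
        """Doubling every row changes SEs but not point estimates.

        Duplication turns every event time into a tie, so with the Efron tie
        correction equality holds up to the (small) tie-approximation error
        rather than exactly.
        """
        res1 = fit_cox(cohort, MODEL_REGISTRY["svz_dose_m1"])
        doubled = pd.concat([cohort, cohort], ignore_index=True)
        res2 = fit_cox(doubled, MODEL_REGISTRY["svz_dose_m1"])
        np.testing.assert_allclose(res1.table["coef"], res2.table["coef"], atol=0.01)
        assert res2.n_used == 2 * res1.n_used
        # standard errors shrink by ~sqrt(2) while estimates stay put
        width1 = np.log(res1.table["ci_upper"] / res1.table["ci_lower"])
        width2 = np.log(res2.table["ci_upper"] / res2.table["ci_lower"])
        np.testing.assert_allclose(width2, width1 / np.sqrt(2.0), rtol=0.05)

    def test_complete_case_n_reported(self, cohort):
        res0 = fit_cox(cohort, MODEL_REGISTRY["svz_dose_m0"])
        res3 = fit_cox(cohort, MODEL_REGISTRY["svz_dose_m3"])
        assert res0.n_used == len(cohort)
        expected = len(complete_cases(cohort, MODEL_REGISTRY["svz_dose_m3"].covariates))
        assert res3.n_used == expected < res0.n_used

    def test_zero_events_rejected(self):
        table = pd.DataFrame(
            {"svz_mean_dose_gy": [1.0, 2.0, 3.0], "os_months": [1, 2, 3], "event": 0}
        )
        with pytest.raises(ValueError, match="events"):
            fit_cox(table, MODEL_REGISTRY["svz_dose_m0"])


class TestAdjustedVIF:
    def test_independent_covariates_near_one(self, rng):
        n = 5000
        table = pd.DataFrame(
            {
                "age": rng.normal(67, 10, n),
                "gtv_volume_cm3": rng.lognormal(1.8, 1.0, n),
                "sex": rng.choice(["female", "male"], n),
                "svz_mean_dose_gy": rng.uniform(0, 5, n),
                "os_months": rng.exponential(8, n),
                "event": 1,
            }
        )
        spec = CoxModelSpec("t", ("svz_mean_dose_gy", "age", "gtv_volume_cm3", "sex"),
                            "svz_mean_dose_gy")
        vif = adjusted_vif(table, spec)
        assert (vif >= 1.0 - 1e-12).all()
        assert np.allclose(vif, 1.0, atol=0.05)

    def test_correlated_pair_matches_closed_form(self, rng):
        n = 4000
        x = rng.normal(size=n)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=n)
        table = pd.DataFrame(
            {"age": x, "gtv_volume_cm3": y, "os_months": rng.exponential(8, n), "event": 1}
        )
        spec = CoxModelSpec("t", ("age", "gtv_volume_cm3"), "age")
        vif = adjusted_vif(table, spec)
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert vif["age"] == pytest.approx(1.0 / (1.0 - r2), rel=1e-6)
        assert vif["gtv_volume_cm3"] == pytest.approx(1.0 / (1.0 - r2), rel=1e-6)

    def test_balanced_orthogonal_categorical_is_one(self):
        # full factorial 2x3 design, perfectly balanced -> adjusted VIF = 1
        table = pd.DataFrame(
            {
                "sex": ["female", "male"] * 30,
                "n_bm": ["1", "1", "2-4", "2-4", ">4", ">4"] * 10,
                "os_months": np.arange(60) + 1.0,
                "event": 1,
            }
        )
        spec = CoxModelSpec("t", ("sex", "n_bm"), "sex")
        vif = adjusted_vif(table, spec)
        assert vif["sex"] == pytest.approx(1.0, abs=1e-10)
        assert vif["n_bm"] == pytest.approx(1.0, abs=1e-10)

    def test_duplicate_covariate_raises_rank_error(self, rng):
        n = 200
        x = rng.normal(size=n)
        table = pd.DataFrame(
            {"age": x, "gtv_volume_cm3": 2.0 * x, "os_months": np.ones(n), "event": 1}
        )
        spec = CoxModelSpec("t", ("age", "gtv_volume_cm3"), "age")
        with pytest.raises(RankDeficientDesignError) as err:
            adjusted_vif(table, spec)
        assert set(err.value.columns) & {"age", "gtv_volume_cm3"}


class TestSensitivityFilters:
    def test_drop_largest_ptv_removes_ceil_ten_percent(self, cohort):
        out = sensitivity_filters(cohort.head(140), "drop-largest-ptv-10pct")
        assert len(out) == 126
        dropped = set(cohort.head(140).index) - set(out.index)
        thresh = cohort.head(140)["ptv_volume_cm3"].nlargest(14).min()
        assert all(cohort.loc[i, "ptv_volume_cm3"] >= thresh for i in dropped)

    def test_single_bm_filter_keeps_only_single(self, cohort):
        out = sensitivity_filters(cohort, "single-bm")
        assert (out["n_bm"] == "1").all()
        assert len(out) == (cohort["n_bm"] == "1").sum()

    def test_single_bm_is_identity_on_single_bm_cohort(self, cohort):
        single = cohort[cohort["n_bm"] == "1"]
        out = sensitivity_filters(single, "single-bm")
        pd.testing.assert_frame_equal(out, single)
        # and idempotent
        pd.testing.assert_frame_equal(sensitivity_filters(out, "single-bm"), out)

    def test_central_decile_removes_smallest_distances(self):
        table = pd.DataFrame(
            {
                "n_bm": ["1"] * 10,
                "centrality_cm": np.arange(10, 0, -1, dtype=float),
                "ptv_volume_cm3": np.ones(10),
            }
        )
        out = sensitivity_filters(table, "exclude-central-decile")
        assert len(out) == 9
        assert out["centrality_cm"].min() == 2.0  # only the 1.0 row removed

    def test_filters_are_deterministic_and_order_stable(self, cohort):
        for which in ("drop-largest-ptv-10pct", "single-bm", "exclude-central-decile"):
            a = sensitivity_filters(cohort, which)
            b = sensitivity_filters(cohort, which)
            pd.testing.assert_frame_equal(a, b)
            assert list(a.index) == sorted(a.index)  # original order preserved

    def test_small_subset_flagged(self):
        table = pd.DataFrame(
            {
                "n_bm": ["1"] * 5 + ["2-4"] * 30,
                "centrality_cm": [1.0, 2, 3, 4, 5] + [np.nan] * 30,
                "ptv_volume_cm3": np.ones(35),
            }
        )
        out = sensitivity_filters(table, "exclude-central-decile")
        assert out.attrs["small_subset"]

    def test_unknown_filter_rejected(self, cohort):
        with pytest.raises(ValueError, match="unknown sensitivity filter"):
            sensitivity_filters(cohort, "bogus")


class TestDoseBurdenCorrelation:
    def test_perfect_monotone_relationships(self, rng):
        n = 50
        g = rng.uniform(1, 10, n)
        table = pd.DataFrame(
            {
                "gtv_volume_cm3": g,
                "ptv_volume_cm3": g**3,          # monotone nonlinear
                "n_bm": ["1"] * n,
                "centrality_cm": rng.uniform(2, 10, n),
                "svz_mean_dose_gy": g,            # identical ranks
                "hpc_mean_dose_gy": g**2,
            }
        )
        res = correlate_dose_burden(table).set_index(["burden", "dose"])
        assert res.loc[("gtv_volume_cm3", "svz_mean_dose_gy"), "rho"] == pytest.approx(1.0)
        assert res.loc[("ptv_volume_cm3", "hpc_mean_dose_gy"), "rho"] == pytest.approx(1.0)

    def test_independent_pairs_near_zero(self, rng):
        n = 1000
        table = pd.DataFrame(
            {
                "gtv_volume_cm3": rng.uniform(1, 10, n),
                "ptv_volume_cm3": rng.uniform(1, 10, n),
                "n_bm": rng.choice(["1", "2-4", ">4"], n),
                "centrality_cm": rng.uniform(2, 10, n),
                "svz_mean_dose_gy": rng.uniform(0, 5, n),
                "hpc_mean_dose_gy": rng.uniform(0, 5, n),
            }
        )
        res = correlate_dose_burden(table)
        assert np.all(np.abs(res["rho"]) < 0.12)

    def test_constant_column_flagged_not_raised(self):
        table = pd.DataFrame(
            {
                "gtv_volume_cm3": [1.0, 2.0, 3.0, 4.0],
                "ptv_volume_cm3": [1.0, 1.0, 1.0, 1.0],
                "n_bm": ["1"] * 4,
                "centrality_cm": [1.0, 2.0, 3.0, 4.0],
                "svz_mean_dose_gy": [0.5, 1.0, 1.5, 2.0],
                "hpc_mean_dose_gy": [0.2, 0.4, 0.6, 0.8],
            }
        )
        res = correlate_dose_burden(table).set_index(["burden", "dose"])
        assert res.loc[("ptv_volume_cm3", "svz_mean_dose_gy"), "undefined"]
        assert np.isnan(res.loc[("ptv_volume_cm3", "svz_mean_dose_gy"), "rho"])

    def test_synthetic_cohort_shows_burden_dose_association(self, cohort):
        res = correlate_dose_burden(cohort).set_index(["burden", "dose"])
        assert res.loc[("gtv_volume_cm3", "svz_mean_dose_gy"), "rho"] > 0.15
        assert res.loc[("n_bm", "hpc_mean_dose_gy"), "rho"] > 0.15
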