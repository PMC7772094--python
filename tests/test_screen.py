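"""Age decomposition, change scores, baseline and longitudinal screens."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sca1vol import SimConfig, simulate_cohort
from sca1vol.screen import (ModelSpec, baseline_screen, bonferroni,
                            change_from_baseline, decompose_age,
                            fit_baseline_model, fit_lme, screen_all)


def three_visit_frame(values, ages=(50.0, 51.5, 53.0)):
    return pd.DataFrame({
        "subject": ["a"] * 3, "group": ["affected"] * 3, "gender": ["F"] * 3,
        "visit": [1, 2, 3], "age": list(ages),
        "time_years": [a - ages[0] for a in ages],
        "icv": [1.5e6] * 3, "voi_pons": list(values),
    })


class TestDecomposeAge:
    def test_three_visit_example(self):
        out = decompose_age(three_visit_frame([1, 2, 3]))
        assert (out["baseline_age"] == 50.0).all()
        np.testing.assert_allclose(out["delta_age"], [0.0, 1.5, 3.0])

    def test_single_visit_subject_has_zero_delta(self):
        df = three_visit_frame([1, 2, 3]).iloc[:1]
        out = decompose_age(df)
        assert out["delta_age"].iloc[0] == 0.0

    def test_reconstruction_identity_on_random_cohort(self, cohort_default):
        cohort, _ = cohort_default
        out = decompose_age(cohort)
        np.testing.assert_allclose(out["baseline_age"] + out["delta_age"],
                                   out["age"], rtol=1e-14)

    def test_missing_baseline_rejected(self):
        df = three_visit_frame([1, 2, 3])
        df = df[df["visit"] > 1]
        with pytest.raises(ValueError, match="baseline"):
            decompose_age(df)


class TestChangeFromBaseline:
    def test_declining_series(self):
        out = change_from_baseline(three_visit_frame([100.0, 98.0, 95.0]),
                                   ["voi_pons"])
        np.testing.assert_allclose(out["delta_voi_pons"], [0.0, -2.0, -5.0])

    def test_constant_series_gives_zero_change(self):
        out = change_from_baseline(three_visit_frame([7.0, 7.0, 7.0]),
                                   ["voi_pons"])
        assert (out["delta_voi_pons"] == 0.0).all()

    def test_differencing_is_idempotent(self):
        once = change_from_baseline(three_visit_frame([100.0, 98.0, 95.0]),
                                    ["voi_pons"])
        twice = change_from_baseline(once, ["delta_voi_pons"])
        np.testing.assert_array_equal(twice["delta_delta_voi_pons"],
                                      once["delta_voi_pons"])

    def test_unknown_column_rejected(self):
        with pytest.raises(ValueError, match="no column"):
            change_from_baseline(three_visit_frame([1, 2, 3]), ["nope"])


class TestBonferroni:
    def test_reference_row_arithmetic(self):
        # Corrected p printed for the strongest screen row: 5.91e-12 * 34.
        assert bonferroni([5.91e-12], 34)[0] == pytest.approx(2.0094e-10)
        assert bonferroni([0.000321], 34)[0] == pytest.approx(0.0109, rel=2e-3)

    def test_capped_at_one(self):
        assert bonferroni([0.5], 34)[0] == 1.0

    @given(st.lists(st.floats(1e-300, 1.0), min_size=1, max_size=20),
           st.integers(1, 100))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_elementwise_min_one_m_p(self, ps, m):
        out = bonferroni(ps, m)
        np.testing.assert_allclose(out, np.minimum(1.0, m * np.asarray(ps)))

    def test_invalid_family_size(self):
        with pytest.raises(ValueError):
            bonferroni([0.1], 0)


class TestBaselineModel:
    def baseline_frame(self, affected, unaffected, ages=None):
        n1, n2 = len(affected), len(unaffected)
        if ages is None:
            rng = np.random.default_rng(0)
            ages = rng.uniform(45, 60, n1 + n2)
        return pd.DataFrame({
            "subject": [f"s{i}" for i in range(n1 + n2)],
            "group": ["affected"] * n1 + ["unaffected"] * n2,
            "gender": (["F", "M"] * (n1 + n2))[: n1 + n2],
            "visit": 1, "age": ages,
            "time_years": 0.0, "icv": 1.5e6,
            "voi_pons": np.concatenate([affected, unaffected]),
        })

    def test_identical_groups_give_zero_standardized_beta(self):
        # identical response AND covariate patterns in both groups: the
        # group contrast must vanish exactly
        vals = np.array([10.0, 11.0, 12.0, 13.0])
        ages = np.tile([46.0, 50.0, 54.0, 58.0], 2)
        df = self.baseline_frame(vals, vals, ages=ages)
        res = fit_baseline_model("pons", df)
        assert res.std_beta == pytest.approx(0.0, abs=1e-10)

    def test_matches_ols_oracle_on_zscored_response(self, cohort_default):
        cohort, _ = cohort_default
        res = fit_baseline_model("pons", cohort)
        base = cohort[cohort["visit"] == 1]
        z = ((base["voi_pons"] - base["voi_pons"].mean())
             / base["voi_pons"].std(ddof=1))
        X = np.column_stack([np.ones(len(base)),
                             (base["group"] == "affected").astype(float),
                             base["age"],
                             (base["gender"] == "F").astype(float)])
        beta_hat = np.linalg.lstsq(X, z.to_numpy(), rcond=None)[0]
        assert res.std_beta == pytest.approx(beta_hat[1], rel=1e-10)
        assert res.ci95[0] < res.std_beta < res.ci95[1]

    def test_group_gap_coverage_at_cohort_scale(self):
        # -1.7 SD gap, n=33; the 95% CI should cover truth in >= 90% of
        # replicates (CI calibration under the generating model).
        rng = np.random.default_rng(99)
        cover = 0
        n_rep = 500
        for _ in range(n_rep):
            aff = rng.normal(-1.7, 1.0, 13)
            una = rng.normal(0.0, 1.0, 20)
            df = self.baseline_frame(aff, una)
            sd = np.concatenate([aff, una]).std(ddof=1)
            res = fit_baseline_model("pons", df)
            if res.ci95[0] <= -1.7 / sd <= res.ci95[1]:
                cover += 1
        assert cover / n_rep >= 0.90

    def test_too_few_per_group_rejected(self):
        df = self.baseline_frame(np.array([1.0]), np.array([2.0, 3.0, 4.0]))
        with pytest.raises(ValueError, match="affected"):
            fit_baseline_model("pons", df)


class TestFitLme:
    def test_t_is_beta_over_se_exactly(self, cohort_default):
        cohort, _ = cohort_default
        res = fit_lme(ModelSpec(voi="pons"), cohort)
        assert res.t == res.beta / res.se

    def test_invariant_to_subject_relabeling(self, cohort_default):
        cohort, _ = cohort_default
        res1 = fit_lme(ModelSpec(voi="putamen"), cohort)
        relabeled = cohort.copy()
        subjects = sorted(cohort["subject"].unique(), reverse=True)
        mapping = {s: f"Z{i:03d}" for i, s in enumerate(subjects)}
        relabeled["subject"] = relabeled["subject"].map(mapping)
        res2 = fit_lme(ModelSpec(voi="putamen"), relabeled)
        # identical up to accumulation order and optimizer tolerance
        assert res2.beta == pytest.approx(res1.beta, rel=1e-6)
        assert res2.se == pytest.approx(res1.se, rel=1e-6)

    def test_affected_only_slope_consistent_with_group_model_sum(self):
        # With identical group slopes the affected-only time coefficient
        # should sit within one SE of the group model's time + interaction.
        cfg = SimConfig(seed=31)
        cfg.slope_by_group["unaffected"] = dict(cfg.slope_by_group["affected"])
        cohort, _ = simulate_cohort(cfg)
        grp = fit_lme(ModelSpec(voi="pons", subset="all"), cohort)
        aff = fit_lme(ModelSpec(voi="pons", subset="affected-only"), cohort)
        i_t = grp.fixed_names.index("time_years")
        i_gt = grp.fixed_names.index("group_affected:time_years")
        combined = grp.fixed_beta[i_t] + grp.fixed_beta[i_gt]
        assert abs(aff.beta - combined) < 2 * aff.se

    def test_constant_response_rejected(self, cohort_default):
        cohort, _ = cohort_default
        flat = cohort.copy()
        flat["voi_pons"] = 12345.0
        with pytest.raises(ValueError, match="constant"):
            fit_lme(ModelSpec(voi="pons"), flat)


class TestScreenAll:
    def test_full_family_has_34_rows_and_m_34(self, cohort_default):
        cohort, _ = cohort_default
        table, results = screen_all(cohort, "group-by-time")
        assert len(table) == 34
        assert len(results) == 34
        for voi, res in results.items():
            assert res.p_bonferroni == pytest.approx(min(1.0, 34 * res.p))

    def test_focal_regions_flagged_under_default_conditions(self, cohort_default):
        cohort, _ = cohort_default
        table, _ = screen_all(cohort, "group-by-time")
        sig = set(table.loc[table["p_bonferroni"] < 0.05, "voi"])
        assert {"pons", "pallidum"} <= sig

    def test_per_region_failure_flagged_and_rest_completed(self, cohort_default):
        cohort, _ = cohort_default
        broken = cohort.copy()
        broken["voi_scp"] = 5.0
        table, results = screen_all(broken, "affected-only")
        row = table[table["voi"] == "scp"].iloc[0]
        assert row["failed"] != ""
        assert np.isnan(row["p"])
        assert "pons" in results

    def test_baseline_screen_reports_all_regions(self, cohort_default):
        cohort, _ = cohort_default
        table, _ = baseline_screen(cohort)
        assert len(table) == 34
        assert table["ci95_lo"].lt(table["ci95_hi"]).all()
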