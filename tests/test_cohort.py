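"""Cohort generator calibration and the statistical stages."""

import numpy as np
import pandas as pd
import pytest

from sandilite.cohort import (
    CohortConfig,
    LESION_COLUMNS,
    SUBJECT_COLUMNS,
    delta_fsoma,
    generate_cohort,
    lesionwise_model,
    pearson_corr,
    snfl_model,
    welch_test,
)


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(CohortConfig(seed=11))


class TestGenerator:
    def test_schemas(self, cohort):
        subjects, lesions = cohort
        assert list(subjects.columns) == SUBJECT_COLUMNS
        assert list(lesions.columns) == LESION_COLUMNS

    def test_seed_determinism(self):
        a = generate_cohort(CohortConfig(seed=3))
        b = generate_cohort(CohortConfig(seed=3))
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_group_sizes(self, cohort):
        counts = cohort[0]["group"].value_counts()
        assert counts["HC"] == 80 and counts["RRMS"] == 98 and counts["PMS"] == 57

    def test_hc_mean_matches_calibration(self, cohort):
        hc = cohort[0].query("group == 'HC'")["cortex_fsoma_mean"]
        # 0.34 ± 0.01 population: sample mean within 3·SD/√n
        assert abs(hc.mean() - 0.34) < 3 * 0.01 / np.sqrt(len(hc))

    def test_hc_has_no_lesion_fields(self, cohort):
        subjects, lesions = cohort
        hc_ids = set(subjects.query("group == 'HC'")["subject_id"])
        assert not (set(lesions["subject_id"]) & hc_ids)
        assert subjects.query("group == 'HC'")["snfl_z"].isna().all()
        assert subjects.query("group == 'HC'")["wm_lesion_volume"].isna().all()

    def test_fractions_within_unit_interval(self, cohort):
        subjects, lesions = cohort
        for col in ("cortex_fsoma_mean", "inner_fsoma_mean", "outer_fsoma_mean"):
            assert subjects[col].between(0, 1).all()
        assert lesions["lesion_fsoma_mean"].between(0, 1).all()


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # m̄₁−m̄₂ = 0.03, s² = 1e-4 each, n = 3 → t = 3.674, df = 4
        t, df, p = welch_test([0.34, 0.35, 0.33], [0.30, 0.31, 0.32])
        assert t == pytest.approx(3.674, abs=1e-3)
        assert df == pytest.approx(4.0, abs=1e-9)
        assert 0 < p < 0.05

    def test_antisymmetry(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 2, 14)
        t1, _, p1 = welch_test(a, b)
        t2, _, p2 = welch_test(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            welch_test([1.0], [1.0, 2.0])


class TestDeltaFsoma:
    def test_arithmetic(self):
        rec = {"lesion_fsoma_mean": 0.36, "perilesion_fsoma_mean": 0.33}
        assert delta_fsoma(rec) == pytest.approx(0.03)

    def test_equal_means_zero(self):
        assert delta_fsoma({"lesion_fsoma_mean": 0.3,
                            "perilesion_fsoma_mean": 0.3}) == 0.0

    def test_translation_invariance_and_antisymmetry(self):
        rec = {"lesion_fsoma_mean": 0.36, "perilesion_fsoma_mean": 0.33}
        shifted = {k: v + 0.1 for k, v in rec.items()}
        assert delta_fsoma(shifted) == pytest.approx(delta_fsoma(rec))
        swapped = {"lesion_fsoma_mean": 0.33, "perilesion_fsoma_mean": 0.36}
        assert delta_fsoma(swapped) == pytest.approx(-delta_fsoma(rec))

    def test_missing_flagged_nan(self):
        assert np.isnan(delta_fsoma({"lesion_fsoma_mean": np.nan,
                                     "perilesion_fsoma_mean": 0.3}))


class TestLesionwiseModel:
    def test_zero_random_effect_matches_ols(self):
        import statsmodels.formula.api as smf

        # independent lesions (no per-patient shift): boundary case
        cfg = CohortConfig(seed=5, lesion_patient_sd=1e-12, n_hc=0)
        subjects, lesions = generate_cohort(cfg)
        fe = lesionwise_model(lesions, subjects)
        df = lesions.merge(subjects[["subject_id", "age", "sex", "treatment"]],
                           on="subject_id")
        df["delta"] = df["lesion_fsoma_mean"] - df["perilesion_fsoma_mean"]
        df["lesion_type"] = pd.Categorical(
            df["lesion_type"], categories=["leukocortical", "subpial"])
        ols = smf.ols("delta ~ age + C(sex) + C(treatment) + C(lesion_type)",
                      df).fit()
        contrast = fe.filter(like="lesion_type", axis=0)["estimate"].iloc[0]
        assert contrast == pytest.approx(
            ols.params["C(lesion_type)[T.subpial]"], abs=1e-4)

    def test_recovers_subpial_effect_in_rrms(self):
        cfg = CohortConfig(seed=21)
        subjects, lesions = generate_cohort(cfg)
        rrms_ids = subjects.query("group == 'RRMS'")["subject_id"]
        fe = lesionwise_model(lesions[lesions["subject_id"].isin(rrms_ids)],
                              subjects)
        row = fe.filter(like="lesion_type", axis=0).iloc[0]
        assert row["estimate"] == pytest.approx(0.03, abs=3 * row["se"])
        assert row["p"] < 0.05

    def test_sign_flip_negates_contrast(self):
        cfg = CohortConfig(seed=8, n_hc=0)
        subjects, lesions = generate_cohort(cfg)
        fe = lesionwise_model(lesions, subjects)
        flipped = lesions.copy()
        flipped["lesion_fsoma_mean"], flipped["perilesion_fsoma_mean"] = (
            lesions["perilesion_fsoma_mean"], lesions["lesion_fsoma_mean"])
        fe2 = lesionwise_model(flipped, subjects)
        c1 = fe.filter(like="lesion_type", axis=0)["estimate"].iloc[0]
        c2 = fe2.filter(like="lesion_type", axis=0)["estimate"].iloc[0]
        assert c2 == pytest.approx(-c1, abs=1e-6)


class TestPearson:
    def test_perfect_linear_relations(self, rng):
        x = rng.normal(size=30)
        assert pearson_corr(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_corr(x, -x)[0] == pytest.approx(-1.0)

    def test_generator_qt1_correlation_in_band(self):
        hits = 0
        for seed in range(30):
            _, lesions = generate_cohort(CohortConfig(seed=seed))
            r, _ = pearson_corr(lesions["lesion_fsoma_mean"], lesions["qt1"])
            hits += -0.7 < r < -0.3
        assert hits >= 27  # ≥90 % of replicates near the configured −0.5

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSnflModel:
    def test_noiseless_recovery_is_exact(self):
        cfg = CohortConfig(seed=13, snfl_noise_sd=1e-300)
        subjects, _ = generate_cohort(cfg)
        res = snfl_model(subjects)
        assert res["coefficients"].loc["fsoma_per5", "estimate"] == pytest.approx(
            0.738, abs=1e-6)
        assert res["coefficients"].loc["wm_per10", "estimate"] == pytest.approx(
            0.334, abs=1e-6)

    def test_volume_rescaling_rescales_coefficient_exactly(self):
        cfg = CohortConfig(seed=14)
        subjects, _ = generate_cohort(cfg)
        res = snfl_model(subjects)
        scaled = subjects.copy()
        scaled["wm_lesion_volume"] = scaled["wm_lesion_volume"] * 10
        res10 = snfl_model(scaled)
        assert res10["coefficients"].loc["wm_per10", "estimate"] == pytest.approx(
            res["coefficients"].loc["wm_per10", "estimate"] / 10, rel=1e-9)

    def test_constant_fsoma_reduces_to_null_model(self):
        cfg = CohortConfig(seed=15)
        subjects, _ = generate_cohort(cfg)
        subjects["cortex_fsoma_mean"] = 0.33
        res = snfl_model(subjects)
        assert res["adj_r2_difference"] == pytest.approx(0.0, abs=0.01)
        assert res["lr_p"] > 0.5

    def test_reports_nested_comparison(self):
        subjects, _ = generate_cohort(CohortConfig(seed=16))
        res = snfl_model(subjects)
        assert set(res) >= {"adj_r2_full", "adj_r2_reduced",
                            "adj_r2_difference", "lr_statistic", "lr_p", "n"}
        assert res["adj_r2_full"] >= res["adj_r2_reduced"] - 1e-9
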