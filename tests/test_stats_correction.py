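import numpy as np
import pandas as pd
import pytest

from anklemorph.stats_correction import (
    RegressionModel,
    compare_2d_3d,
    correct_2d,
    fit_regressions,
    icc_3k,
    reliability_band,
    residual_error_table,
    standard_pose_measurements,
)

# fixed 3x3 repeatability matrix with a hand-computed two-way ANOVA:
# row means 2, 6, 10; grand mean 6; SS_rows = 96, SS_cols = 86/3,
# SS_total = 132 => SS_err = 22/3; BMS = 48, EMS = 11/6;
# ICC(3,k) = (48 - 11/6)/48 = 277/288
ORACLE_MATRIX = np.array([[1.0, 2.0, 3.0], [4.0, 6.0, 8.0], [7.0, 9.0, 14.0]])
ORACLE_ICC = 277.0 / 288.0


class TestICC:
    def test_matches_manual_anova_oracle(self):
        r = icc_3k(ORACLE_MATRIX)
        assert r.icc == pytest.approx(ORACLE_ICC, abs=1e-12)
        assert r.between_ms == pytest.approx(48.0)
        assert r.residual_ms == pytest.approx(11.0 / 6.0)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        m = rng.normal(size=(8, 5)) + rng.normal(size=(8, 1)) * 3
        long = pd.DataFrame({
            "target": np.repeat(np.arange(8), 5),
            "rater": np.tile(np.arange(5), 8),
            "score": m.ravel(),
        })
        ref = pg.intraclass_corr(long, targets="target", raters="rater",
                                 ratings="score")
        # the consistency / average-of-k row (labels vary across versions)
        labels = ref["Type"].astype(str).str.replace(r"[(),]", "", regex=True).str.upper()
        ref = ref[labels.isin(["ICC3K", "ICCCK"])]
        ref_icc3k = float(ref["ICC"].iloc[0])
        assert icc_3k(m).icc == pytest.approx(ref_icc3k, abs=1e-9)

    def test_duplicated_columns_give_one(self):
        col = np.array([1.0, 5.0, 9.0, 2.0])
        m = np.column_stack([col, col, col])
        assert icc_3k(m).icc == pytest.approx(1.0, abs=1e-12)

    def test_shift_invariance(self):
        r0 = icc_3k(ORACLE_MATRIX)
        r1 = icc_3k(ORACLE_MATRIX + 100.0)
        assert r1.icc == pytest.approx(r0.icc, abs=1e-12)

    def test_constant_matrix_undefined(self):
        with pytest.raises(ValueError, match="undefined|variance"):
            icc_3k(np.full((4, 3), 2.5))

    def test_variance_ratio_expectation(self):
        """Specimen variance 100x the pose noise at n=58, k=10 must give
        ICC(3,k) > 0.95 (expectation ~ 1 - EMS/BMS with BMS ~ k*100 + 1)."""
        rng = np.random.default_rng(8)
        m = rng.normal(0, 10.0, size=(58, 1)) + rng.normal(0, 1.0, size=(58, 10))
        assert icc_3k(m).icc > 0.95

    def test_incomplete_rows_dropped_and_counted(self):
        m = ORACLE_MATRIX.astype(float).copy()
        m = np.vstack([m, [np.nan, 1.0, 2.0]])
        r = icc_3k(m)
        assert r.n == 3 and r.n_dropped == 1

    def test_reliability_bands(self):
        assert reliability_band(0.95) == "very good"
        assert reliability_band(0.7) == "good"
        assert reliability_band(0.5) == "moderate"
        assert reliability_band(0.3) == "fair"
        assert reliability_band(0.1) == "poor"


class TestComparison:
    def test_identical_arms(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame({"TiAL": rng.normal(28, 2, 20)})
        table = compare_2d_3d(x, x.copy())
        row = table.loc["TiAL"]
        assert row.pct_error == 0.0
        assert row.paired_t_p == 1.0
        assert row.a == pytest.approx(1.0, abs=1e-9)
        assert row.b == pytest.approx(0.0, abs=1e-7)

    def test_printed_mean_arithmetic(self):
        # percent error between cohort means 29.35 and 28.41
        assert 100 * (29.35 - 28.41) / 28.41 == pytest.approx(3.31, abs=0.005)

    def test_regression_direction_is_3d_from_2d(self):
        rng = np.random.default_rng(1)
        x2 = pd.DataFrame({"MalW": rng.normal(63.73, 3.8, 58)})
        x3 = pd.DataFrame({"MalW": 0.97 * x2["MalW"] + 0.95 + rng.normal(0, 0.2, 58)})
        table = compare_2d_3d(x3, x2)
        row = table.loc["MalW"]
        # predicting the 3D mean from the 2D mean through (a, b)
        assert row.a * 63.73 + row.b == pytest.approx(0.97 * 63.73 + 0.95, abs=0.5)

    def test_regression_recovery_within_ci(self):
        """Data built as 3D = a*2D + b + noise recovers (a, b) within the
        standard-error confidence interval at n = 58."""
        rng = np.random.default_rng(2)
        a_true, b_true = 0.95, 0.39
        x2 = rng.normal(29.35, 2.75, 58)
        x3 = a_true * x2 + b_true + rng.normal(0, 0.3, 58)
        table = compare_2d_3d(pd.DataFrame({"TiAL": x3}), pd.DataFrame({"TiAL": x2}))
        row = table.loc["TiAL"]
        resid = x3 - (row.a * x2 + row.b)
        sxx = ((x2 - x2.mean()) ** 2).sum()
        se_a = np.sqrt((resid**2).sum() / 56 / sxx)
        se_b = se_a * np.sqrt((x2**2).mean())
        assert abs(row.a - a_true) < 2.5 * se_a
        assert abs(row.b - b_true) < 2.5 * se_b

    def test_shapiro_reported(self):
        rng = np.random.default_rng(3)
        x2 = pd.DataFrame({"TaR": rng.normal(21, 3, 30)})
        x3 = pd.DataFrame({"TaR": rng.normal(20.5, 2.8, 30)})
        t = compare_2d_3d(x3, x2)
        assert 0 <= t.loc["TaR", "shapiro_p_3d"] <= 1

    def test_unpaired_lengths_rejected(self):
        a = pd.DataFrame({"TiAL": [1.0, 2.0, 3.0]})
        b = pd.DataFrame({"TiAL": [1.0, 2.0]})
        with pytest.raises(ValueError, match="paired"):
            compare_2d_3d(a, b)


class TestCorrection:
    def test_identity_model(self):
        m = RegressionModel(1.0, 0.0, 1.0, 58)
        assert correct_2d(29.35, m) == 29.35

    def test_printed_equation_applied(self):
        # slope 0.95, intercept 0.39 applied to a 2D mean of 29.35
        m = RegressionModel(0.95, 0.39, 1.0, 58)
        assert correct_2d(29.35, m) == pytest.approx(28.27, abs=0.005)

    def test_exact_affine_relation_closes(self):
        rng = np.random.default_rng(6)
        x2 = rng.normal(30, 3, 58)
        x3 = 0.9 * x2 + 2.0
        table = compare_2d_3d(pd.DataFrame({"p": x3}), pd.DataFrame({"p": x2}))
        model = fit_regressions(table)["p"]
        assert np.allclose(correct_2d(x2, model), x3, atol=1e-9)

    def test_model_needs_three_points(self):
        with pytest.raises(ValueError):
            RegressionModel(1.0, 0.0, 1.0, 2)


class TestResidualErrorTable:
    @pytest.fixture(scope="class")
    def cohort_and_models(self, cohort20):
        cohort = cohort20[:6]
        prof3, prof2 = standard_pose_measurements(cohort)
        models = fit_regressions(compare_2d_3d(prof3, prof2))
        return cohort, models

    def test_correction_reduces_error_for_insensitive_parameters(self, cohort_and_models):
        """At 3-degree perturbations the standard-pose regressions must cut
        the mean absolute error of the pose-insensitive length parameters."""
        cohort, models = cohort_and_models
        table = residual_error_table(cohort, models, pose_bounds=(3.0,),
                                     n_poses=5, seed=0)
        t = table.set_index("parameter")
        for p in ("TiAL", "TiSR", "MTiTh", "TaR", "TiW", "MalW", "TaW"):
            assert t.loc[p, "corrected_error_abs_pct"] < t.loc[p, "error_abs_pct"], p

    def test_sensitive_small_angle_resists_correction(self, cohort_and_models):
        """The near-zero-baseline frontal talar tilt stays poorly corrected
        at 6-degree perturbations (the in-plane rotation swamps it)."""
        cohort, models = cohort_and_models
        table = residual_error_table(cohort, models, pose_bounds=(6.0,),
                                     n_poses=5, seed=0)
        t = table.set_index("parameter")
        assert t.loc["MLATa", "corrected_error_abs_pct"] > 10.0
        assert t.loc["MLATa", "corrected_error_abs_pct"] > \
            t.loc["TiAL", "corrected_error_abs_pct"]

    def test_zero_perturbation_leaves_regression_residual_only(self, cohort_and_models):
        cohort, models = cohort_and_models
        table = residual_error_table(cohort, models, pose_bounds=(1e-9,),
                                     n_poses=2, seed=0)
        t = table.set_index("parameter")
        # corrected errors collapse to the standard-pose regression residual
        assert t.loc["TiAL", "corrected_error_abs_pct"] < 1.0
        assert t.loc["MalW", "corrected_error_abs_pct"] < 1.0
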