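"""Validation-statistics tests against frozen bench values and brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qnmr import reference_data as ref
from qnmr.validation import (
    ValidationReport,
    fit_calibration,
    lod_loq,
    precision_study,
    recovery,
    recovery_stats,
    specificity_check,
    stability_series,
    two_sample_t,
    variance_ratio_f,
)


# ----------------------------------------------------------- brute-force oracles

def ols_normal_equations(x, y):
    """Independent OLS by explicit summation formulas (no library calls)."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    b = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    a = (sy - b * sx) / n
    residuals = [yi - (a + b * xi) for xi, yi in zip(x, y)]
    sse = sum(r * r for r in residuals)
    sy_x = math.sqrt(sse / (n - 2))
    sxx_c = sxx - sx * sx / n
    sb = sy_x / math.sqrt(sxx_c)
    sa = sy_x * math.sqrt(sxx / (n * sxx_c))
    syy = sum(v * v for v in y) - sy * sy / n
    r = (sxy - sx * sy / n) / math.sqrt(sxx_c * syy)
    return a, b, r, sy_x, sa, sb


def summation_stats(values):
    n = len(values)
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    return mean, sd


def pooled_t(values1, values2):
    m1, s1 = summation_stats(values1)
    m2, s2 = summation_stats(values2)
    n1, n2 = len(values1), len(values2)
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    return (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))


# ----------------------------------------------------------------- calibration

class TestFitCalibration:
    def test_exact_line_recovers_published_coefficients(self):
        concs = [0.25, 0.5, 1.0, 2.5, 5.0, 10.0, 15.0, 20.0]
        points = [(c, 64e-4 + 0.02 * c) for c in concs]
        model = fit_calibration(points)
        assert model.slope == pytest.approx(0.02, rel=1e-12)
        assert model.intercept == pytest.approx(64e-4, rel=1e-10)
        assert model.r == pytest.approx(1.0, abs=1e-12)
        assert model.sy_x == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(0.2, 20.0, size=9)
        y = 0.003 + 0.021 * x + rng.normal(0, 0.002, size=9)
        model = fit_calibration(list(zip(x, y)))
        a, b, r, sy_x, sa, sb = ols_normal_equations(list(x), list(y))
        assert model.intercept == pytest.approx(a, abs=1e-10)
        assert model.slope == pytest.approx(b, abs=1e-10)
        assert model.r == pytest.approx(r, abs=1e-10)
        assert model.sy_x == pytest.approx(sy_x, abs=1e-10)
        assert model.sa == pytest.approx(sa, abs=1e-10)
        assert model.sb == pytest.approx(sb, abs=1e-10)

    def test_matches_statsmodels_cross_check(self, rng):
        import statsmodels.api as sm

        x = rng.uniform(0.2, 20.0, size=8)
        y = 0.006 + 0.02 * x + rng.normal(0, 0.001, size=8)
        model = fit_calibration(list(zip(x, y)))
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert model.intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert model.slope == pytest.approx(fit.params[1], abs=1e-10)
        assert model.sa == pytest.approx(fit.bse[0], abs=1e-10)
        assert model.sb == pytest.approx(fit.bse[1], abs=1e-10)

    def test_duplicating_points_shrinks_coefficient_sds(self, rng):
        x = [1.0, 2.0, 5.0, 10.0]
        y = [0.02, 0.043, 0.1, 0.21]
        single = fit_calibration(list(zip(x, y)))
        double = fit_calibration(list(zip(x + x, y + y)))
        assert double.slope == pytest.approx(single.slope, rel=1e-12)
        assert double.intercept == pytest.approx(single.intercept, abs=1e-12)
        assert double.sa < single.sa
        assert double.sb < single.sb

    def test_identical_concentrations_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            fit_calibration([(1.0, 0.1), (1.0, 0.2), (1.0, 0.3)])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_calibration([(1.0, 0.1), (2.0, 0.2)])


class TestLodLoq:
    def test_zero_intercept_sd_gives_zero_limits(self):
        model = fit_calibration([(c, 0.02 * c) for c in (1.0, 2.0, 4.0, 8.0)])
        assert lod_loq(model) == (0.0, 0.0)

    def test_direct_arithmetic_on_published_inputs(self):
        # 3.3 * 21e-5 / 0.02 and 10 * 21e-5 / 0.02
        from qnmr.validation import CalibrationModel

        model = CalibrationModel(
            slope=0.02, intercept=64e-4, r=0.9999, sy_x=43e-5, sa=21e-5,
            sb=2e-5, n_points=8, conc_range=(0.25, 20.0),
        )
        lod, loq = lod_loq(model)
        assert lod == pytest.approx(0.03465, rel=1e-10)
        assert loq == pytest.approx(0.105, rel=1e-10)

    @given(sa=st.floats(1e-6, 1e-2), b=st.floats(1e-3, 1.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_loq_over_lod_is_ten_thirds(self, sa, b):
        from qnmr.validation import CalibrationModel

        model = CalibrationModel(
            slope=b, intercept=0.0, r=1.0, sy_x=0.0, sa=sa, sb=0.0,
            n_points=5, conc_range=(0.0, 1.0),
        )
        lod, loq = lod_loq(model)
        assert loq / lod == pytest.approx(10.0 / 3.3, rel=1e-12)


# ------------------------------------------------------------------ recoveries

class TestRecovery:
    @pytest.mark.parametrize(
        "found, taken, expected",
        [(5.0, 5.0, 100.0), (0.0, 5.0, 0.0), (4.98, 5.0, 99.60)],
    )
    def test_arithmetic(self, found, taken, expected):
        assert recovery(found, taken) == pytest.approx(expected, abs=1e-10)

    def test_nonpositive_taken_rejected(self):
        with pytest.raises(ValueError):
            recovery(1.0, 0.0)


class TestRecoveryStats:
    def test_pure_form_qnmr_recovery_summaries(self):
        flp = recovery_stats(ref.FLP_PURE_RECOVERIES_QNMR)
        assert flp.mean == pytest.approx(100.14, abs=0.005)
        assert flp.sd == pytest.approx(0.91, abs=0.005)
        assert flp.error_percent == pytest.approx(0.32, abs=0.005)
        azh = recovery_stats(ref.AZH_PURE_RECOVERIES_QNMR)
        assert azh.mean == pytest.approx(99.67, abs=0.005)
        assert azh.sd == pytest.approx(1.04, abs=0.005)

    def test_constant_values_have_zero_spread(self):
        st_ = recovery_stats([99.5, 99.5, 99.5])
        assert st_.sd == 0.0 and st_.rsd_percent == 0.0

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            recovery_stats([100.0])

    @given(
        values=st.lists(st.floats(90.0, 110.0), min_size=2, max_size=12)
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_matches_summation_oracle(self, values):
        st_ = recovery_stats(values)
        mean, sd = summation_stats(values)
        assert st_.mean == pytest.approx(mean, abs=1e-10)
        assert st_.sd == pytest.approx(sd, abs=1e-10)
        assert st_.error_percent == pytest.approx(
            100.0 * sd / mean / math.sqrt(len(values)), abs=1e-10
        )


# ---------------------------------------------------------- method comparison

class TestTwoSampleT:
    def test_identical_groups_give_zero(self):
        g = recovery_stats([99.0, 100.0, 101.0])
        res = two_sample_t(g, g)
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert not res.significant

    def test_flp_method_comparison(self):
        qnmr = recovery_stats(ref.FLP_PURE_RECOVERIES_QNMR)
        hplc = recovery_stats(ref.FLP_PURE_RECOVERIES_HPLC)
        res = two_sample_t(qnmr, hplc)
        assert res.df_t == 10
        assert abs(res.t_statistic) == pytest.approx(0.1, abs=0.05)
        assert res.critical_t == pytest.approx(2.23, abs=0.005)
        assert not res.significant

    def test_matches_pooled_oracle_on_small_groups(self):
        v1, v2 = [99.1, 100.4, 101.0], [98.8, 100.0, 99.4]
        res = two_sample_t(recovery_stats(v1), recovery_stats(v2))
        assert res.t_statistic == pytest.approx(pooled_t(v1, v2), abs=1e-12)

    def test_degenerate_variances_rejected(self):
        g = recovery_stats([100.0, 100.0])
        with pytest.raises(ValueError):
            two_sample_t(g, g)


class TestVarianceRatioF:
    def test_equal_variances_give_unity(self):
        g1 = recovery_stats([99.0, 101.0])
        g2 = recovery_stats([89.0, 91.0])
        assert variance_ratio_f(g1, g2).f_statistic == pytest.approx(1.0)

    def test_flp_and_azh_method_comparisons(self):
        flp = variance_ratio_f(
            recovery_stats(ref.FLP_PURE_RECOVERIES_QNMR),
            recovery_stats(ref.FLP_PURE_RECOVERIES_HPLC),
        )
        assert flp.f_statistic == pytest.approx(1.39, abs=0.005)
        assert not flp.significant
        azh = variance_ratio_f(
            recovery_stats(ref.AZH_PURE_RECOVERIES_QNMR),
            recovery_stats(ref.AZH_PURE_RECOVERIES_HPLC),
        )
        assert azh.f_statistic == pytest.approx(1.11, abs=0.005)
        # the larger variance sits in the 8-replicate qNMR group here, so
        # the critical value is the F(7, 3) upper 5 % quantile
        assert azh.df_f == (7, 3)
        assert azh.critical_f == pytest.approx(8.89, abs=0.005)

    def test_larger_variance_always_in_numerator(self, rng):
        for _ in range(5):
            v1 = list(rng.normal(100, rng.uniform(0.2, 2.0), size=5))
            v2 = list(rng.normal(100, rng.uniform(0.2, 2.0), size=7))
            res = variance_ratio_f(recovery_stats(v1), recovery_stats(v2))
            assert res.f_statistic >= 1.0

    def test_zero_variance_rejected(self):
        g1 = recovery_stats([100.0, 100.0])
        g2 = recovery_stats([99.0, 101.0])
        with pytest.raises(ValueError):
            variance_ratio_f(g1, g2)


# ------------------------------------------------------- precision & stability

class TestPrecisionStudy:
    def test_intra_day_bench_values(self):
        table = precision_study(ref.PRECISION_INTRA_DAY["FLP"], "intra")
        row = table[table["concentration_mg_ml"] == 1.0].iloc[0]
        assert row["mean"] == pytest.approx(100.85, abs=0.005)
        assert row["sd"] == pytest.approx(0.68, abs=0.005)
        assert row["error_percent"] == pytest.approx(0.39, abs=0.005)

    def test_constant_replicates_have_zero_rsd(self):
        table = precision_study({5.0: [100.0, 100.0, 100.0]}, "intra")
        assert table.iloc[0]["rsd_percent"] == 0.0

    def test_random_cell_matches_direct_formulas(self, rng):
        reps = list(rng.normal(100, 0.8, size=3))
        table = precision_study({2.0: reps}, "inter")
        mean, sd = summation_stats(reps)
        row = table.iloc[0]
        assert row["mean"] == pytest.approx(mean, abs=1e-10)
        assert row["sd"] == pytest.approx(sd, abs=1e-10)

    def test_missing_cell_reported_absent(self):
        table = precision_study({1.0: [100.1, 99.9], 5.0: []}, "intra")
        absent = table[table["concentration_mg_ml"] == 5.0].iloc[0]
        assert absent["n"] == 0 and math.isnan(absent["mean"])

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            precision_study({1.0: [100.0, 100.1]}, "weekly")


class TestStabilitySeries:
    def test_bench_stability_summaries(self):
        mean_flp, rsd_flp = stability_series(ref.STABILITY_SERIES["FLP"])
        assert mean_flp == pytest.approx(100.29, abs=0.006)
        assert rsd_flp == pytest.approx(0.16, abs=0.005)
        mean_azh, rsd_azh = stability_series(ref.STABILITY_SERIES["AZH"])
        assert mean_azh == pytest.approx(99.83, abs=0.005)
        assert rsd_azh == pytest.approx(0.18, abs=0.005)

    def test_constant_series_has_zero_rsd(self):
        assert stability_series([(0, 100.0), (6, 100.0)])[1] == 0.0


# -------------------------------------------------------------- specificity

@pytest.fixture(scope="module")
def specificity_inputs():
    from qnmr.config import default_config
    from qnmr.pipeline import process_fid, simulate_sample

    cfg = default_config(
        acquisition={"data_points": 8192},
        simulation={"amplitude_noise_frac": 0.0},
        samples=[],
    )

    def spec_for(concs, include_standard):
        return process_fid(
            cfg,
            simulate_sample(
                cfg, concs, seed=1, include_standard=include_standard
            ),
        )

    blank = spec_for({}, include_standard=False)
    comps = {
        "FLP": spec_for({"FLP": 7.3}, include_standard=False),
        "AZH": spec_for({"AZH": 20.0}, include_standard=False),
        "inositol": spec_for({}, include_standard=True),
    }
    mixture = spec_for({"FLP": 7.3, "AZH": 20.0}, include_standard=True)
    return cfg, blank, comps, mixture


class TestSpecificity:

    def test_blank_contributes_nothing(self, specificity_inputs):
        cfg, blank, comps, mixture = specificity_inputs
        table = specificity_check(blank, comps, mixture, cfg.regions)
        assert (table["blank_percent"].abs() < 0.1).all()

    def test_full_mixture_cross_contribution_below_one_percent(
        self, specificity_inputs
    ):
        cfg, blank, comps, mixture = specificity_inputs
        table = specificity_check(blank, comps, mixture, cfg.regions)
        assert table["passes"].all()
        assert (table["max_foreign_percent"] < 1.0).all()

    def test_overlapping_impurity_is_flagged(self, specificity_inputs):
        from qnmr.pipeline import process_fid, simulate_sample
        from qnmr.signal_model import AnalyteSpec, Line

        cfg, blank, comps, mixture = specificity_inputs
        impurity = AnalyteSpec(
            "impurity", 200.0, 100.0, 1, 1.5, (Line(8.30, 1.0, 0.5),)
        )
        cfg2 = cfg
        cfg2.analytes = cfg.analytes + [impurity]
        contaminated = dict(comps)
        contaminated["impurity"] = process_fid(
            cfg2,
            simulate_sample(
                cfg2, {"impurity": 5.0}, seed=2, include_standard=False
            ),
        )
        table = specificity_check(blank, contaminated, mixture, cfg.regions)
        azh_row = table[table["owner"] == "AZH"].iloc[0]
        assert azh_row["from_impurity_percent"] > 1.0
        assert not azh_row["passes"]


class TestValidationReport:
    def test_csv_round_trip_preserves_values(self, tmp_path):
        report = ValidationReport(
            calibration=pd.DataFrame(
                {"analyte": ["FLP"], "slope": [0.0213577], "r": [0.99991]}
            ),
            accuracy=pd.DataFrame(
                {"analyte": ["FLP", "AZH"], "recovery_percent": [99.52, 100.18]}
            ),
            stability=pd.DataFrame({"time_h": [0, 6], "assay": [100.36, 100.42]}),
        )
        report.to_csv(tmp_path)
        back = ValidationReport.from_csv(tmp_path)
        pd.testing.assert_frame_equal(report.calibration, back.calibration)
        pd.testing.assert_frame_equal(report.accuracy, back.accuracy)
        pd.testing.assert_frame_equal(
            report.stability, back.stability, check_dtype=False
        )
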