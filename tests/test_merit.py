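"""Figures of merit against published benchmark arithmetic and oracles."""

import numpy as np
import pytest
from scipy import stats

from specal import refdata
from specal.merit import (
    build_merit_report,
    compare_methods,
    lod_loq,
    pred_actual_regression,
    recovery_percent,
    rmsep,
    sep,
    standard_addition,
    summarize_recoveries,
)


class TestRecovery:
    def test_tabulated_example(self):
        assert recovery_percent(11.286, 11.0) == pytest.approx(102.6, abs=0.05)

    def test_identity_and_zero(self):
        assert recovery_percent(7.0, 7.0) == 100.0
        assert recovery_percent(0.0, 5.0) == 0.0

    def test_nonpositive_actual_rejected(self):
        with pytest.raises(ValueError):
            recovery_percent(1.0, 0.0)

    @pytest.mark.parametrize(
        "key", [("NZ", "PLS"), ("NZ", "ANN"), ("PN", "PLS"), ("PN", "ANN")]
    )
    def test_reported_summary_cells_reproduce(self, key):
        mean, sd = summarize_recoveries(refdata.VALIDATION_RECOVERIES[key])
        exp_mean, exp_sd = refdata.VALIDATION_SUMMARY[key]
        assert round(mean, 1) == exp_mean
        assert round(sd, 1) == exp_sd

    def test_constant_list_has_zero_sd(self):
        mean, sd = summarize_recoveries([100.0] * 5)
        assert (mean, sd) == (100.0, 0.0)

    def test_summary_needs_two_values(self):
        with pytest.raises(ValueError):
            summarize_recoveries([100.0])


class TestErrorMetrics:
    def test_rmsep_basics(self):
        assert rmsep([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert rmsep([1.1, 1.9], [1.0, 2.0]) == pytest.approx(0.1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            rmsep([1.0], [1.0, 2.0])

    @pytest.mark.parametrize(
        "key",
        [("NZ", "PLS"), ("PN", "PLS"), ("PN_impB", "PLS"), ("NZ", "ANN"),
         ("PN", "ANN"), ("NZ_impB", "ANN"), ("PN_impA", "PLS"), ("PN_impB", "ANN")],
    )
    def test_sep_rmsep_ratio_matches_published_pairs(self, key):
        """SEP/RMSEP = sqrt(10/8) reproduces every published pair at n=10."""
        params = refdata.REGRESSION_PARAMS[key]
        derived_sep = params["rmsep"] * np.sqrt(10.0 / 8.0)
        assert derived_sep == pytest.approx(params["sep"], abs=5e-6)

    def test_sep_on_residuals_and_conventions(self):
        actual = np.arange(1.0, 11.0)
        predicted = actual + np.array([0.1, -0.1] * 5)
        assert sep(predicted, actual) == pytest.approx(0.1 * np.sqrt(10 / 8))
        assert sep(predicted, actual) / rmsep(predicted, actual) == pytest.approx(
            np.sqrt(10 / 8)
        )
        # bias-corrected alternative uses centered residuals over n-1
        assert sep(predicted, actual, convention="biased-n1") == pytest.approx(
            np.std([0.1, -0.1] * 5, ddof=1)
        )

    def test_sep_needs_three_points(self):
        with pytest.raises(ValueError):
            sep([1.0, 2.0], [1.0, 2.0])

    def test_zero_residuals_give_zero_sep(self):
        assert sep([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0


class TestRegression:
    def test_perfect_line(self):
        slope, intercept, r, s = pred_actual_regression(
            [1.0, 2.0, 3.0], [1.0, 2.0, 3.0]
        )
        assert (slope, intercept, r) == pytest.approx((1.0, 0.0, 1.0))
        assert s == pytest.approx(0.0, abs=1e-12)

    def test_exact_two_to_one_line(self):
        slope, intercept, _, _ = pred_actual_regression(
            [2.0, 4.0, 6.0], [1.0, 2.0, 3.0]
        )
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_against_scipy_linregress_oracle(self):
        rng = np.random.default_rng(1)
        actual = np.linspace(1, 10, 12)
        predicted = actual + rng.normal(0, 0.2, 12)
        slope, intercept, r, s = pred_actual_regression(predicted, actual)
        ref = stats.linregress(actual, predicted)
        assert slope == pytest.approx(ref.slope, abs=1e-10)
        assert intercept == pytest.approx(ref.intercept, abs=1e-10)
        assert r == pytest.approx(ref.rvalue, abs=1e-10)

    def test_degenerate_actual_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pred_actual_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestLodLoq:
    @pytest.mark.parametrize(
        "lod, loq", [(1.750, 5.303), (0.494, 1.497), (0.277, 0.839)]
    )
    def test_published_lod_loq_ratio(self, lod, loq):
        """LOQ = LOD x 10/3.3 reproduces the published pairs at 3 d.p."""
        _, derived_loq = lod_loq(lod / 3.3, 1.0)
        assert derived_loq == pytest.approx(loq, abs=5e-4)

    def test_three_sigma_rule(self):
        lod, loq = lod_loq(0.1, 2.0)
        assert lod == pytest.approx(3.3 * 0.1 / 2.0)
        assert loq == pytest.approx(10.0 * 0.1 / 2.0)
        assert loq / lod == pytest.approx(10.0 / 3.3)

    def test_zero_spread_zero_limits(self):
        assert lod_loq(0.0, 1.0) == (0.0, 0.0)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            lod_loq(0.1, 0.0)


class TestStandardAddition:
    @pytest.mark.parametrize(
        "key", [("NZ", "PLS"), ("PN", "PLS"), ("NZ", "ANN"), ("PN", "ANN")]
    )
    def test_published_triplets_summarize_correctly(self, key):
        entry = refdata.STANDARD_ADDITION[key]
        mean, sd = summarize_recoveries(entry["recoveries"])
        assert round(mean, 1) == entry["mean"]
        assert round(sd, 1) == entry["sd"]

    def test_recovery_computed_on_added_amount_only(self):
        res = standard_addition(4.0, [6.0, 8.0, 12.0], [2.0, 4.0, 8.0])
        assert np.allclose(res.recoveries, 100.0)
        assert res.mean == pytest.approx(100.0)

    def test_roundtrip_from_predictions(self):
        entry = refdata.STANDARD_ADDITION[("NZ", "PLS")]
        added = np.array(entry["added"])
        spiked = entry["taken"] + added * np.array(entry["recoveries"]) / 100.0
        res = standard_addition(entry["taken"], spiked, added)
        assert round(res.mean, 1) == entry["mean"]
        assert round(res.sd, 1) == entry["sd"]

    def test_nonpositive_additions_rejected(self):
        with pytest.raises(ValueError):
            standard_addition(4.0, [5.0], [0.0])


class TestMethodComparison:
    def test_reported_t_statistic_and_critical(self):
        pls = refdata.METHOD_SUMMARIES[("NZ", "PLS")]
        ref = refdata.METHOD_SUMMARIES[("NZ", "reference")]
        c = compare_methods(pls["mean"], pls["sd"], pls["n"],
                            ref["mean"], ref["sd"], ref["n"])
        assert round(c.t_statistic, 2) == refdata.REPORTED_T[("NZ", "PLS")]
        assert round(c.t_critical, 2) == 2.16
        assert c.t_df == 13

    def test_identical_groups_give_zero_t_unit_f(self):
        c = compare_methods(100.0, 1.0, 8, 100.0, 1.0, 8)
        assert c.t_statistic == 0.0
        assert c.f_statistic == 1.0

    def test_f_puts_larger_variance_in_numerator(self):
        c = compare_methods(10.0, 1.0, 5, 10.0, 2.0, 10)
        assert c.f_statistic == pytest.approx(4.0)
        assert c.f_df == (9, 4)
        assert c.f_statistic >= 1.0

    def test_f_critical_is_one_tailed_upper(self):
        c = compare_methods(10.0, 2.0, 10, 10.0, 1.0, 5)
        assert c.f_critical == pytest.approx(stats.f.ppf(0.95, 9, 4))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compare_methods(1.0, 1.0, 1, 1.0, 1.0, 5)
        with pytest.raises(ValueError):
            compare_methods(1.0, 0.0, 5, 1.0, 1.0, 5)


class TestReport:
    def test_report_internal_identities(self, clean_calval):
        from specal.pls import fit_pls, predict_pls

        X, Y, X_val, Y_val = clean_calval
        pred = predict_pls(fit_pls(X, Y, 5), X_val)
        # perturb slightly so residuals are non-trivial
        rng = np.random.default_rng(0)
        pred = pred + rng.normal(0, 0.01, pred.shape)
        report = build_merit_report(pred, Y_val, ["NZ", "PN", "NZ_impB",
                                                  "PN_impA", "PN_impB"])
        n = Y_val.shape[0]
        for comp in report.components:
            assert comp.loq == pytest.approx(comp.lod * 10.0 / 3.3, rel=1e-12)
            assert comp.sep == pytest.approx(
                comp.rmsep * np.sqrt(n / (n - 2)), rel=1e-12
            )
            assert np.all(comp.recoveries > 0)

    def test_report_lookup_and_shape_validation(self, clean_calval):
        X, Y, _, _ = clean_calval
        with pytest.raises(ValueError):
            build_merit_report(Y, Y[:, :4], ["a"] * 5)
        report = build_merit_report(Y + 0.01, Y, list("abcde"))
        assert report["a"].name == "a"
        with pytest.raises(KeyError):
            report["zz"]
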