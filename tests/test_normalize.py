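import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.base import clone

import refchip as rc
from conftest import matrix_from_xy, pair_sheet


class TestRPM:
    def test_scales_to_per_million(self):
        m = rc.CountsMatrix(pd.DataFrame({"s1": [200, 2_000_000 - 200]}, index=["a", "b"]))
        out = rc.normalize_rpm(m, mode="reads_in_peaks")
        assert out.counts.loc["a", "s1"] == pytest.approx(100.0)

    def test_equal_totals_preserve_relative_values(self):
        m = rc.CountsMatrix(pd.DataFrame({"s1": [10, 90], "s2": [30, 70]}, index=["a", "b"]))
        out = rc.normalize_rpm(m, mode="reads_in_peaks")
        ratio = out.counts / m.counts
        assert np.allclose(ratio.loc["a"], ratio.loc["b"])

    def test_missing_library_totals_errors(self):
        m = rc.CountsMatrix(pd.DataFrame({"s1": [1]}, index=["a"]))
        with pytest.raises(ValueError, match="library_totals"):
            rc.normalize_rpm(m, mode="total_reads")

    def test_zero_total_errors(self):
        m = rc.CountsMatrix(pd.DataFrame({"s1": [0]}, index=["a"]))
        with pytest.raises(ValueError, match="totals"):
            rc.normalize_rpm(m, mode="reads_in_peaks")


class TestControlSizeFactors:
    def test_sum_method_forced_by_geometric_mean(self):
        m = rc.CountsMatrix(pd.DataFrame({"s1": [40, 60], "s2": [90, 110]}, index=["a", "b"]))
        sf = rc.control_size_factors(m, ["a", "b"], method="sum")
        assert sf.factors["s1"] == pytest.approx(1 / np.sqrt(2))
        assert sf.factors["s2"] == pytest.approx(np.sqrt(2))

    def test_identical_columns_give_unit_factors(self):
        m = rc.CountsMatrix(pd.DataFrame({"s1": [5, 9], "s2": [5, 9]}, index=["a", "b"]))
        for method in ("sum", "median_ratio"):
            sf = rc.control_size_factors(m, ["a", "b"], method=method)
            assert np.allclose(sf.factors, 1.0)

    def test_median_ratio_hand_computed(self):
        # rows [[10,20],[20,40],[40,80]]: per-row geometric means are
        # sqrt(200), sqrt(800), sqrt(3200); every ratio column is
        # (1/sqrt 2, sqrt 2), so the medians already have geometric mean 1.
        m = rc.CountsMatrix(
            pd.DataFrame({"s1": [10, 20, 40], "s2": [20, 40, 80]}, index=["a", "b", "c"])
        )
        sf = rc.control_size_factors(m, ["a", "b", "c"], method="median_ratio")
        assert sf.factors["s1"] == pytest.approx(1 / np.sqrt(2))
        assert sf.factors["s2"] == pytest.approx(np.sqrt(2))

    def test_factors_use_only_the_control_submatrix(self):
        m = rc.CountsMatrix(
            pd.DataFrame({"s1": [10, 1000], "s2": [20, 1]}, index=["ctrl", "target"])
        )
        sf = rc.control_size_factors(m, ["ctrl"], method="sum")
        assert sf.factors["s2"] / sf.factors["s1"] == pytest.approx(2.0)

    def test_zero_control_counts_error(self):
        m = rc.CountsMatrix(pd.DataFrame({"s1": [0], "s2": [5]}, index=["a"]))
        with pytest.raises(ValueError, match="zero control"):
            rc.control_size_factors(m, ["a"], method="sum")

    def test_all_zero_rows_error_for_median_ratio(self):
        m = rc.CountsMatrix(pd.DataFrame({"s1": [0, 3], "s2": [4, 0]}, index=["a", "b"]))
        with pytest.raises(ValueError, match="all-positive"):
            rc.control_size_factors(m, ["a", "b"], method="median_ratio")

    def test_sum_equals_ratio_of_column_sums_oracle(self):
        rng = np.random.default_rng(5)
        vals = rng.integers(1, 500, size=(30, 4))
        m = rc.CountsMatrix.from_array(vals, [f"p{i}" for i in range(30)], list("abcd"))
        sf = rc.control_size_factors(m, m.peak_names, method="sum")
        sums = vals.sum(axis=0).astype(float)
        expected = sums / np.exp(np.mean(np.log(sums)))
        assert np.allclose(sf.factors, expected)


class TestNormalizationCoefficient:
    def test_exact_proportionality(self):
        m = matrix_from_xy([10, 20, 30], [5, 10, 15])
        res = rc.normalization_coefficient(m, m.peak_names, pair_sheet(), ("control", "treated"))
        assert res.slope == pytest.approx(0.5)
        assert res.coefficient == pytest.approx(2.0)
        assert res.residual_se == pytest.approx(0.0, abs=1e-12)

    def test_identical_conditions_give_unity(self):
        m = matrix_from_xy([10, 20, 30], [10, 20, 30])
        res = rc.normalization_coefficient(m, m.peak_names, pair_sheet(), ("control", "treated"))
        assert res.coefficient == pytest.approx(1.0)

    def test_matches_brute_force_closed_form(self, small_experiment):
        exp = small_experiment
        res = rc.normalization_coefficient(
            exp.counts, exp.control_peak_names, exp.sheet, ("control", "treated")
        )
        ctrl = exp.counts.subset_peaks(exp.control_peak_names).counts
        num = den = 0.0
        for _, row in ctrl.iterrows():  # independent per-peak loop
            x = (row["ctrl_rep1"] + row["ctrl_rep2"] + row["ctrl_rep3"]) / 3
            y = (row["trt_rep1"] + row["trt_rep2"] + row["trt_rep3"]) / 3
            num += x * y
            den += x * x
        assert res.slope == pytest.approx(num / den, rel=1e-12)

    def test_recovers_known_efficiency_bias(self):
        # deep-coverage reference peaks: the Poisson component of the
        # errors-in-variables attenuation is negligible there
        cfg = rc.SimulationConfig(
            n_target_peaks=10,
            n_control_peaks=5_000,
            n_spikein_peaks=10,
            fraction_changed=0.0,
            true_treated_scaling=0.8,
            mean_median=1_000.0,
            dispersion=0.05,
            seed=17,
        )
        exp = rc.generate_experiment(cfg)
        res = rc.normalization_coefficient(
            exp.counts, exp.control_peak_names, exp.sheet, ("control", "treated")
        )
        assert abs(res.coefficient * 0.8 - 1.0) < 0.02

    def test_too_few_control_peaks(self):
        m = matrix_from_xy([10], [5])
        with pytest.raises(ValueError, match=">= 2"):
            rc.normalization_coefficient(m, ["p0"], pair_sheet(), ("control", "treated"))

    def test_all_zero_x_errors(self):
        m = matrix_from_xy([0, 0], [1, 2])
        with pytest.raises(ValueError, match="zero"):
            rc.normalization_coefficient(m, m.peak_names, pair_sheet(), ("control", "treated"))

    @given(st.integers(0, 10_000))
    def test_gradient_restoration_property(self, seed):
        """Rescaling treated columns by c always restores slope 1 exactly."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 30))
        x = rng.integers(1, 1000, n).astype(float)
        y = rng.integers(0, 1000, n).astype(float)
        if np.dot(x, y) == 0:
            y[0] = 1.0
        m = matrix_from_xy(x, y)
        sheet = pair_sheet()
        res = rc.normalization_coefficient(m, m.peak_names, sheet, ("control", "treated"))
        corrected = rc.apply_coefficient(m, res, ["t1"], rounding="none")
        refit = rc.normalization_coefficient(
            corrected, m.peak_names, sheet, ("control", "treated")
        )
        assert abs(refit.slope - 1.0) <= 1e-9

    @given(st.integers(0, 10_000), st.floats(0.1, 10.0))
    def test_scale_equivariance(self, seed, k):
        rng = np.random.default_rng(seed)
        x = rng.integers(1, 500, 10).astype(float)
        y = rng.integers(1, 500, 10).astype(float)
        sheet = pair_sheet()
        base = rc.normalization_coefficient(
            matrix_from_xy(x, y), [f"p{i}" for i in range(10)], sheet, ("control", "treated")
        )
        scaled = rc.normalization_coefficient(
            matrix_from_xy(x, k * y), [f"p{i}" for i in range(10)], sheet, ("control", "treated")
        )
        assert scaled.slope == pytest.approx(k * base.slope)
        assert scaled.coefficient == pytest.approx(base.coefficient / k)


class TestApplyCoefficient:
    def res(self, c):
        return rc.NormalizationResult(
            coefficient=c, slope=1.0 / c, n_control_peaks=2, residual_se=0.0
        )

    def test_scales_only_treated_columns(self):
        m = matrix_from_xy([7], [7])
        out = rc.apply_coefficient(m, self.res(2.0), ["t1"])
        assert out.counts.loc["p0", "t1"] == pytest.approx(14.0)
        assert out.counts.loc["p0", "c1"] == pytest.approx(7.0)

    def test_unity_coefficient_is_identity(self):
        m = matrix_from_xy([3, 4], [5, 6])
        out = rc.apply_coefficient(m, self.res(1.0), ["t1"])
        assert out.counts.equals(m.counts.astype(float))

    def test_nearest_int_rounds_half_away_from_zero(self):
        m = matrix_from_xy([1], [3.7])
        out = rc.apply_coefficient(m, self.res(2.0), ["t1"], rounding="nearest_int")
        assert out.counts.loc["p0", "t1"] == 7  # 7.4 -> 7
        m2 = matrix_from_xy([1], [3.75])
        out2 = rc.apply_coefficient(m2, self.res(2.0), ["t1"], rounding="nearest_int")
        assert out2.counts.loc["p0", "t1"] == 8  # 7.5 -> 8


class TestMATransform:
    def test_hand_computed_m_and_a(self):
        m = matrix_from_xy([16], [4])
        sf = rc.SizeFactors.identity(["c1", "t1"])
        tab = rc.ma_transform(m, sf, pair_sheet(), ("control", "treated"), pseudocount=1e-12)
        assert tab.loc["p0", "M"] == pytest.approx(-2.0, abs=1e-9)
        assert tab.loc["p0", "A"] == pytest.approx(np.log2(10.0), abs=1e-9)

    def test_equal_means_give_zero_m(self):
        m = matrix_from_xy([10, 50], [10, 50])
        sf = rc.SizeFactors.identity(["c1", "t1"])
        tab = rc.ma_transform(m, sf, pair_sheet(), ("control", "treated"))
        assert np.allclose(tab["M"], 0.0)

    def test_all_zero_peak_defined_by_pseudocount(self):
        m = matrix_from_xy([0], [0])
        sf = rc.SizeFactors.identity(["c1", "t1"])
        tab = rc.ma_transform(m, sf, pair_sheet(), ("control", "treated"), pseudocount=0.5)
        assert tab.loc["p0", "M"] == 0.0
        assert tab.loc["p0", "A"] == pytest.approx(np.log2(0.5))

    def test_size_factors_divide_counts(self):
        m = matrix_from_xy([10], [40])
        sf = rc.SizeFactors.from_raw(pd.Series({"c1": 1.0, "t1": 4.0}), method="sum")
        tab = rc.ma_transform(m, sf, pair_sheet(), ("control", "treated"), pseudocount=1e-12)
        assert tab.loc["p0", "M"] == pytest.approx(0.0, abs=1e-6)

    def test_control_peaks_center_on_zero_after_normalization(self):
        """Monte-Carlo: unchanged reference peaks have mean M ~ 0 once
        control-derived size factors are applied."""
        cfg = rc.SimulationConfig(
            n_target_peaks=200,
            n_control_peaks=2_000,
            n_spikein_peaks=50,
            fraction_changed=0.8,
            seed=23,
        )
        exp = rc.generate_experiment(cfg)
        sf = rc.control_size_factors(exp.counts, exp.control_peak_names)
        tab = rc.ma_transform(
            exp.counts, sf, exp.sheet, ("control", "treated"), peak_channels=exp.channels()
        )
        m_ctrl = tab.loc[tab["channel"] == "control", "M"]
        se = m_ctrl.std(ddof=1) / np.sqrt(len(m_ctrl))
        assert abs(m_ctrl.mean()) < 3 * se


class TestLfcFitCorrection:
    def table(self, a_ctrl, m_ctrl, a_tgt=(1.0, 5.0), m_tgt=(2.0, -1.0)):
        return pd.DataFrame(
            {
                "A": list(a_ctrl) + list(a_tgt),
                "M": list(m_ctrl) + list(m_tgt),
                "channel": ["control"] * len(a_ctrl) + ["target"] * len(a_tgt),
            },
            index=[f"r{i}" for i in range(len(a_ctrl) + len(a_tgt))],
        )

    def test_constant_offset_removed_everywhere(self):
        tab = self.table([2.0, 4.0, 6.0], [1.0, 1.0, 1.0])
        out = rc.lfc_fit_correction(tab)
        assert np.allclose(out["M"], tab["M"] - 1.0)

    def test_zero_control_m_is_identity(self):
        tab = self.table([2.0, 4.0], [0.0, 0.0])
        out = rc.lfc_fit_correction(tab)
        assert np.allclose(out["M"], tab["M"])

    def test_linear_trend_removed_exactly(self):
        a = np.array([1.0, 3.0, 5.0, 8.0])
        tab = self.table(a, 0.1 * a)
        out = rc.lfc_fit_correction(tab)
        expected = tab["M"] - 0.1 * tab["A"]
        assert np.allclose(out["M"], expected)

    def test_control_rows_centered_after_correction(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(1, 10, 50)
        tab = self.table(a, 0.3 * a - 1 + rng.normal(0, 0.2, 50))
        out = rc.lfc_fit_correction(tab)
        assert abs(out.loc[out["channel"] == "control", "M"].mean()) < 1e-9

    def test_constant_only_fit_option(self):
        tab = self.table([2.0, 4.0], [1.0, 3.0])
        out = rc.lfc_fit_correction(tab, fit="constant")
        assert np.allclose(
            out.loc[out["channel"] == "control", "M"], np.array([1.0, 3.0]) - 2.0
        )

    def test_errors_on_degenerate_control(self):
        with pytest.raises(ValueError, match=">= 2"):
            rc.lfc_fit_correction(self.table([2.0], [1.0]))
        with pytest.raises(ValueError, match="variance"):
            rc.lfc_fit_correction(self.table([2.0, 2.0], [1.0, 2.0]))


class TestEstimators:
    def test_regression_normalizer_fit_attributes(self, small_experiment):
        exp = small_experiment
        est = rc.RegressionNormalizer(
            control_peaks=exp.control_peak_names,
            sample_sheet=exp.sheet,
            contrast=("control", "treated"),
        )
        est.fit(exp.counts)
        assert est.coefficient_ == pytest.approx(1.0 / est.slope_)
        assert est.n_control_peaks_ == len(exp.control_peak_names)
        refit = rc.normalization_coefficient(
            est.transform(exp.counts), exp.control_peak_names, exp.sheet, ("control", "treated")
        )
        assert abs(refit.slope - 1.0) <= 1e-9

    def test_estimators_clone_and_get_params(self, small_experiment):
        exp = small_experiment
        for est in (
            rc.RPMScaler(mode="reads_in_peaks"),
            rc.ControlSizeFactorNormalizer(control_peaks=exp.control_peak_names),
            rc.RegressionNormalizer(
                control_peaks=exp.control_peak_names, sample_sheet=exp.sheet
            ),
        ):
            cloned = clone(est)
            assert cloned.get_params() == est.get_params()

    def test_size_factor_normalizer_transform_divides(self, small_experiment):
        exp = small_experiment
        est = rc.ControlSizeFactorNormalizer(control_peaks=exp.control_peak_names).fit(exp.counts)
        out = est.transform(exp.counts)
        sid = exp.counts.sample_ids[0]
        assert np.allclose(
            out.counts[sid], exp.counts.counts[sid] / est.size_factors_[sid]
        )
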