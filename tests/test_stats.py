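"""Epiallele-expression statistics: indicator means, paired tests, correlations."""

import math

import numpy as np
import pandas as pd
import pytest

from panepi.stats import (
    duplicate_proportion_test,
    mean_tpm_per_epiallele,
    methylation_expression_correlation,
    paired_difference_tests,
)


def frames(dt_rows, de_rows):
    idx = [f"p{i}" for i in range(len(dt_rows))]
    cols = [f"G{j}" for j in range(len(dt_rows[0]))]
    return (
        pd.DataFrame(dt_rows, index=idx, columns=cols, dtype=float),
        pd.DataFrame(de_rows, index=idx, columns=cols),
    )


class TestMeanTpmPerEpiallele:
    def test_arithmetic_mean_per_type(self):
        dt, de = frames([[10, 12, 9, 9, 9]], [["gbM", "gbM", "UM", "UM", "UM"]])
        assert mean_tpm_per_epiallele(dt, de, "gbM").iloc[0] == pytest.approx(11)
        assert mean_tpm_per_epiallele(dt, de, "UM").iloc[0] == pytest.approx(9)

    def test_absent_type_is_undefined(self):
        dt, de = frames([[10, 12]], [["gbM", "gbM"]])
        assert math.isnan(mean_tpm_per_epiallele(dt, de, "teM").iloc[0])

    def test_shape_mismatch_is_error(self):
        dt, de = frames([[1, 2]], [["UM", "UM"]])
        with pytest.raises(ValueError, match="shape"):
            mean_tpm_per_epiallele(dt, de.iloc[:, :1], "UM")

    def test_matches_double_loop_oracle(self, rng):
        types = np.array(["UM", "gbM", "teM", None], dtype=object)
        for _ in range(300):
            n_i, n_j = int(rng.integers(1, 8)), int(rng.integers(1, 8))
            dt = pd.DataFrame(rng.random((n_i, n_j)) * 100)
            dt[rng.random((n_i, n_j)) < 0.1] = np.nan
            de = pd.DataFrame(
                types[rng.integers(0, 4, (n_i, n_j))], index=dt.index,
                columns=dt.columns,
            )
            for e in ("UM", "gbM", "teM"):
                got = mean_tpm_per_epiallele(dt, de, e)
                for i in range(n_i):
                    vals = [
                        dt.iat[i, j]
                        for j in range(n_j)
                        if de.iat[i, j] == e and not np.isnan(dt.iat[i, j])
                    ]
                    if not vals:
                        assert math.isnan(got.iloc[i])
                    else:
                        assert got.iloc[i] == pytest.approx(sum(vals) / len(vals))


class TestPairedDifferences:
    def test_all_positive_exact_p(self):
        r = paired_difference_tests(pd.Series([1.0] * 10))
        assert r.sign_test_p == pytest.approx(2 * 0.5**10)
        assert r.sign_test_p == pytest.approx(0.001953125)

    def test_balanced_signs_p_one(self):
        r = paired_difference_tests(pd.Series([1, 1, 1, 1, 1, -1, -1, -1, -1, -1.0]))
        assert r.sign_test_p == pytest.approx(1.0)

    def test_sign_p_matches_binomial_cdf_summation(self, rng):
        from math import comb

        for _ in range(50):
            d = pd.Series(rng.normal(0.2, 1.0, int(rng.integers(2, 40))))
            r = paired_difference_tests(d)
            n = r.n_pos + r.n_neg
            if n == 0:
                continue
            pmf = [comb(n, k) * 0.5**n for k in range(n + 1)]
            p_obs = pmf[r.n_pos]
            expect = sum(p for p in pmf if p <= p_obs * (1 + 1e-9))
            assert r.sign_test_p == pytest.approx(min(expect, 1.0))

    def test_ties_excluded_from_default_n(self):
        r = paired_difference_tests(pd.Series([1.0, 1.0, 1.0, 0.0]))
        assert (r.n_pos, r.n_neg, r.n_tie) == (3, 0, 1)
        assert r.sign_test_p == pytest.approx(2 * 0.5**3)
        # tie-inclusive variant (3 of 4 successes) reported alongside
        assert r.sign_test_p_with_ties == pytest.approx(2 * 5 / 16)

    def test_label_swap_negates_differences(self, rng):
        from panepi.stats import gbm_um_analysis

        dt = pd.DataFrame(rng.random((30, 8)) * 50)
        de = pd.DataFrame(
            np.array(["UM", "gbM"])[rng.integers(0, 2, (30, 8))],
            index=dt.index, columns=dt.columns,
        )
        fwd = gbm_um_analysis({"t": dt}, de)["t"]
        rev = gbm_um_analysis({"t": dt}, de, type_a="UM", type_b="gbM")["t"]
        np.testing.assert_allclose(fwd.differences, -rev.differences.loc[fwd.differences.index])
        assert fwd.median_d == pytest.approx(-rev.median_d)

    def test_normalized_median_uses_mean_um(self):
        d = pd.Series([2.0, 4.0, 6.0])
        r = paired_difference_tests(d, mean_um=pd.Series([100.0, 100.0, 100.0]))
        assert r.normalized_median_pct == pytest.approx(4.0)

    def test_empty_input_undefined(self):
        r = paired_difference_tests(pd.Series([], dtype=float))
        assert r.n == 0 and math.isnan(r.sign_test_p)


class TestChiSquare:
    def test_homogeneous_table(self):
        chi2, p, dof = duplicate_proportion_test([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert dof == 1

    def test_pearson_formula_hand_oracle(self):
        obs = np.array([[50, 10], [30, 30]], dtype=float)
        # Pearson 2x2 shortcut: N (ad - bc)^2 / (r1 r2 c1 c2)
        n = obs.sum()
        a, b, c, d = obs.ravel()
        expect = n * (a * d - b * c) ** 2 / (
            obs[0].sum() * obs[1].sum() * obs[:, 0].sum() * obs[:, 1].sum()
        )
        chi2, _, dof = duplicate_proportion_test(obs)
        assert chi2 == pytest.approx(expect) == pytest.approx(15.0)
        assert dof == 1

    def test_scaling_property(self):
        chi2a, _, _ = duplicate_proportion_test([[50, 10], [30, 30]])
        chi2b, _, _ = duplicate_proportion_test([[200, 40], [120, 120]])
        assert chi2b == pytest.approx(4 * chi2a)

    def test_zero_expected_cell_is_error(self):
        with pytest.raises(ValueError, match="expected"):
            duplicate_proportion_test([[0, 10], [0, 20]])


class TestCorrelation:
    def test_perfect_linearity(self):
        meth = pd.DataFrame([[0.0, 0.3, 0.6]], index=["p0"])
        tpm = pd.DataFrame([[1.0, 2.0, 3.0]], index=["p0"])
        cs = methylation_expression_correlation(meth, tpm)
        assert cs.r_values.loc["p0"] == pytest.approx(1.0)
        assert cs.n_pangenes == 1 and cs.n_pos == 1

    def test_range_below_threshold_excluded(self):
        meth = pd.DataFrame([[0.0, 0.05, 0.15]], index=["p0"])
        tpm = pd.DataFrame([[1.0, 2.0, 3.0]], index=["p0"])
        cs = methylation_expression_correlation(meth, tpm)
        assert math.isnan(cs.r_values.loc["p0"]) and cs.n_pangenes == 0

    def test_constant_tpm_undefined(self):
        meth = pd.DataFrame([[0.0, 0.3, 0.6]], index=["p0"])
        tpm = pd.DataFrame([[2.0, 2.0, 2.0]], index=["p0"])
        cs = methylation_expression_correlation(meth, tpm)
        assert math.isnan(cs.r_values.loc["p0"])

    def test_fewer_than_three_genes_undefined(self):
        meth = pd.DataFrame([[0.0, 0.4, np.nan]], index=["p0"])
        tpm = pd.DataFrame([[1.0, 2.0, 3.0]], index=["p0"])
        cs = methylation_expression_correlation(meth, tpm)
        assert cs.n_pangenes == 0

    def test_empty_summary_when_all_excluded(self):
        meth = pd.DataFrame([[0.0, 0.01, 0.02]], index=["p0"])
        tpm = pd.DataFrame([[1.0, 2.0, 3.0]], index=["p0"])
        cs = methylation_expression_correlation(meth, tpm)
        assert cs.n_pangenes == 0 and math.isnan(cs.median_r)

    def test_null_model_median_near_zero(self, rng):
        """Zero-slope methylation-expression model gives median r near 0."""
        n = 400
        meth = pd.DataFrame(rng.uniform(0, 0.8, (n, 10)))
        tpm = pd.DataFrame(rng.lognormal(3, 0.4, (n, 10)))
        cs = methylation_expression_correlation(meth, tpm)
        se_median = 1.2533 * cs.r_values.dropna().std() / np.sqrt(cs.n_pangenes)
        assert abs(cs.median_r) < 2 * se_median + 1e-12
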