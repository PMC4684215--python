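"""Unit and property tests for the seven equal-variance tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from methvar import (
    FDistHyperparams,
    MethylationMatrix,
    TEST_NAMES,
    anova_f_on_deviations,
    bartlett_test,
    center_deviations,
    f_test,
    fit_fdist,
    moderated_t_table,
    po_test,
    run_test,
    squeeze_var,
    trimmed_mean,
)
from methvar.data import InvalidInputError


class TestFTest:
    def test_hand_computed_ratio(self):
        r = f_test((2, 4, 6, 8), (1, 2, 3, 4))
        assert r.statistic == pytest.approx(4.0)
        assert (r.df1, r.df2) == (3.0, 3.0)

    def test_identical_groups_give_unit_ratio(self):
        r = f_test((1.0, 2.0, 5.0), (1.0, 2.0, 5.0))
        assert r.statistic == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1.0)

    def test_short_group_rejected(self):
        with pytest.raises(InvalidInputError):
            f_test((1.0,), (1.0, 2.0))

    def test_both_groups_constant_is_degenerate(self):
        r = f_test((3.0, 3.0, 3.0), (1.0, 1.0))
        assert r.degenerate and r.p_value == 1.0 and r.statistic == 0.0

    def test_null_calibration(self):
        """Rejection rate on i.i.d. normal nulls stays near the level."""
        rng = np.random.default_rng(11)
        n_rep = 10_000
        x = rng.standard_normal((n_rep, 20))
        y = rng.standard_normal((n_rep, 20))
        m = MethylationMatrix.from_arrays(
            np.hstack([y, x]), np.repeat([0, 1], 20)
        )
        rate = (run_test(m, "F")["p_value"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < 3 * se


class TestBartlett:
    def test_equal_variances_give_zero(self):
        r = bartlett_test([(1.0, 2.0, 3.0), (4.0, 5.0, 6.0)])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)
        assert r.df1 == 1.0  # k - 1 with two groups

    def test_matches_scipy_on_three_groups(self, rng):
        groups = [rng.normal(0, s, size=n) for s, n in ((1, 8), (2, 12), (0.5, 9))]
        r = bartlett_test(groups)
        ref_stat, ref_p = stats.bartlett(*groups)
        assert r.statistic == pytest.approx(ref_stat, abs=1e-10)
        assert r.p_value == pytest.approx(ref_p, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(InvalidInputError):
            bartlett_test([(1.0, 2.0)])


class TestDeviations:
    def test_mean_centred_abs(self):
        m = MethylationMatrix.from_arrays(
            np.array([[1.0, 2.0, 3.0, 0.0, 0.0]]),
            np.array([1, 1, 1, 0, 0]),
        )
        z = center_deviations(m, "abs", "group_mean")
        np.testing.assert_allclose(z.z_values[0, :3], [1.0, 0.0, 1.0])

    def test_median_is_robust(self):
        m = MethylationMatrix.from_arrays(
            np.array([[1.0, 2.0, 100.0, 0.0, 0.0]]),
            np.array([1, 1, 1, 0, 0]),
        )
        z = center_deviations(m, "abs", "group_median")
        np.testing.assert_allclose(z.z_values[0, :3], [1.0, 0.0, 98.0])

    def test_square_is_elementwise_square_of_abs(self, small_matrix):
        za = center_deviations(small_matrix, "abs", "group_mean")
        zs = center_deviations(small_matrix, "square", "group_mean")
        np.testing.assert_allclose(zs.z_values, za.z_values**2)

    @pytest.mark.parametrize(
        "values, frac, expected",
        [
            (range(1, 11), 0.1, 5.5),  # drops 1 and 10, mean of 2..9
            ((3.0, 1.0, 2.0), 0.0, 2.0),
            ((-2.0, -1.0, 0.0, 1.0, 2.0), 0.2, 0.0),  # symmetric
        ],
    )
    def test_trimmed_mean(self, values, frac, expected):
        assert trimmed_mean(values, frac) == pytest.approx(expected)

    def test_trimmed_mean_bad_fraction(self):
        with pytest.raises(InvalidInputError):
            trimmed_mean((1.0, 2.0), 0.5)


class TestAnovaOnDeviations:
    def test_identical_deviations_give_zero_f(self):
        m = MethylationMatrix.from_arrays(
            np.array([[1.0, -1.0, 1.0, -1.0]]), np.array([0, 0, 1, 1])
        )
        z = center_deviations(m, "abs", "group_mean")
        table = anova_f_on_deviations(z)
        assert table["statistic"].iloc[0] == pytest.approx(0.0)
        assert table["p_value"].iloc[0] == pytest.approx(1.0)

    def test_f_equals_t_squared(self, small_matrix):
        """Two-group ANOVA F on z is the square of the pooled t on z."""
        z = center_deviations(small_matrix, "abs", "group_mean")
        table = anova_f_on_deviations(z, small_matrix.site_ids)
        z_d = z.z_values[:, z.labels == 1]
        z_n = z.z_values[:, z.labels == 0]
        t = stats.ttest_ind(z_d, z_n, axis=1).statistic
        np.testing.assert_allclose(table["statistic"], t**2, atol=1e-10)

    @pytest.mark.parametrize(
        "test_name, scipy_center",
        [("Levene", "mean"), ("BF", "median")],
    )
    def test_matches_scipy_levene(self, small_matrix, test_name, scipy_center):
        table = run_test(small_matrix, test_name)
        x_d = small_matrix.group_values(1)
        x_n = small_matrix.group_values(0)
        for i in range(0, 100, 7):
            ref_stat, ref_p = stats.levene(x_n[i], x_d[i], center=scipy_center)
            assert table["statistic"].iloc[i] == pytest.approx(ref_stat, abs=1e-10)
            assert table["p_value"].iloc[i] == pytest.approx(ref_p, abs=1e-10)

    def test_trimmed_levene_against_direct_formula(self, small_matrix):
        """L.trim centres all observations at the 10% trimmed group mean."""
        table = run_test(small_matrix, "L.trim", trim_fraction=0.10)
        x_d = small_matrix.group_values(1)
        x_n = small_matrix.group_values(0)
        for i in (0, 13, 55, 99):
            z_d = np.abs(x_d[i] - stats.trim_mean(x_d[i], 0.10))
            z_n = np.abs(x_n[i] - stats.trim_mean(x_n[i], 0.10))
            ref = stats.f_oneway(z_n, z_d)
            assert table["statistic"].iloc[i] == pytest.approx(ref.statistic, abs=1e-10)
            assert table["p_value"].iloc[i] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_brown_forsythe_power_against_strong_effect(self):
        """Variance doubled at n = 200/group: power should be high."""
        rng = np.random.default_rng(3)
        n_sites = 1000
        x_n = rng.normal(0, 1, (n_sites, 200))
        x_d = rng.normal(0, np.sqrt(2), (n_sites, 200))
        m = MethylationMatrix.from_arrays(
            np.hstack([x_n, x_d]), np.repeat([0, 1], 200)
        )
        rate = (run_test(m, "BF")["p_value"] < 0.05).mean()
        assert rate > 0.8


class TestModeratedT:
    def test_fit_fdist_zero_dispersion(self):
        """Equal variances clamp d0 to infinity; s0^2 is the common value
        after the log-scale bias correction exp(log(d/2) - psi(d/2))."""
        from scipy.special import digamma

        hyper = fit_fdist(np.full(50, 0.7), residual_df=10)
        assert np.isinf(hyper.d0)
        correction = np.exp(np.log(5.0) - digamma(5.0))
        assert hyper.s0_sq == pytest.approx(0.7 * correction)
        # correction vanishes for large residual df
        hyper_big = fit_fdist(np.full(50, 0.7), residual_df=4000)
        assert hyper_big.s0_sq == pytest.approx(0.7, rel=1e-3)

    def test_fit_fdist_parameter_recovery(self):
        """Moment matching recovers (d0, s0^2) of the scaled-F model."""
        rng = np.random.default_rng(99)
        d0_true, s0_true, d = 20.0, 0.64, 38.0
        s2 = s0_true * (d0_true / rng.chisquare(d0_true, 10_000)) * (
            rng.chisquare(d, 10_000) / d
        )
        hyper = fit_fdist(s2, d)
        assert abs(hyper.d0 - d0_true) / d0_true < 0.20
        assert abs(hyper.s0_sq - s0_true) / s0_true < 0.05

    def test_fit_fdist_agrees_with_numeric_mle(self):
        """Independent maximum-likelihood fit of s^2 ~ s0^2 F(d, d0)."""
        from scipy.optimize import minimize

        rng = np.random.default_rng(7)
        d0_true, s0_true, d = 20.0, 0.64, 38.0
        s2 = s0_true * (d0_true / rng.chisquare(d0_true, 10_000)) * (
            rng.chisquare(d, 10_000) / d
        )

        def nll(theta):
            log_d0, log_s0 = theta
            return -stats.f.logpdf(
                s2 / np.exp(log_s0), d, np.exp(log_d0)
            ).sum() + len(s2) * log_s0

        fit = minimize(nll, x0=(np.log(10.0), np.log(1.0)), method="Nelder-Mead")
        d0_mle, s0_mle = np.exp(fit.x)
        hyper = fit_fdist(s2, d)
        assert abs(hyper.d0 - d0_mle) / d0_mle < 0.10
        assert abs(hyper.s0_sq - s0_mle) / s0_mle < 0.02

    def test_fit_fdist_rejects_nonpositive_variances(self):
        with pytest.raises(InvalidInputError):
            fit_fdist([0.5, 0.0, 1.0], 10)

    @pytest.mark.parametrize(
        "d0, s0, s_g, d_g, expected",
        [
            (0.0, 1.0, 3.0, 10.0, 3.0),  # no shrinkage
            (np.inf, 2.5, 3.0, 10.0, 2.5),  # full shrinkage
            (10.0, 1.0, 3.0, 10.0, 2.0),  # midpoint
        ],
    )
    def test_squeeze_var(self, d0, s0, s_g, d_g, expected):
        assert squeeze_var(s_g, d_g, FDistHyperparams(d0, s0)) == pytest.approx(expected)

    def test_zero_numerator_site(self, rng):
        z_vals = np.abs(rng.standard_normal((20, 10)))
        z_vals[0] = np.tile([0.5, 1.5], 5)  # equal group means at site 0
        from methvar.data import DeviationMatrix

        labels = np.repeat([0, 1], 5)
        z_vals[0, labels == 1] = z_vals[0, labels == 0]
        z = DeviationMatrix(z_vals, labels, "abs", "group_mean")
        table = moderated_t_table(z)
        assert table["statistic"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert table["p_value"].iloc[0] == pytest.approx(1.0)

    def test_d0_zero_recovers_ordinary_t(self, small_matrix):
        z = center_deviations(small_matrix, "abs", "group_mean")
        table = moderated_t_table(z, hyper=FDistHyperparams(0.0, 1.0))
        z_d = z.z_values[:, z.labels == 1]
        z_n = z.z_values[:, z.labels == 0]
        ref = stats.ttest_ind(z_d, z_n, axis=1)
        np.testing.assert_allclose(table["statistic"], ref.statistic, atol=1e-8)
        np.testing.assert_allclose(table["p_value"], ref.pvalue, atol=1e-8)

    def test_single_site_rejected(self):
        from methvar.data import DeviationMatrix

        z = DeviationMatrix(np.ones((1, 8)), np.repeat([0, 1], 4), "abs", "group_mean")
        with pytest.raises(InvalidInputError):
            moderated_t_table(z)

    def test_matches_limma_reference(self, tmp_path):
        """Full moderated-t table agrees with the limma implementation."""
        import shutil
        import subprocess

        rng = np.random.default_rng(500)
        n_sites, n = 500, 15
        z_vals = np.abs(rng.standard_normal((n_sites, 2 * n)) + 1.0)
        labels = np.repeat([0, 1], n)
        from methvar.data import DeviationMatrix

        z = DeviationMatrix(z_vals, labels, "abs", "group_mean")
        table = moderated_t_table(z)

        z_path = tmp_path / "z.tsv"
        np.savetxt(z_path, z_vals, delimiter="\t")
        r_script = tmp_path / "modt.R"
        r_script.write_text(
            f"""
suppressMessages(library(limma))
z <- as.matrix(read.table("{z_path}", sep="\\t"))
design <- cbind(1, rep(c(0, 1), each = {n}))
fit <- eBayes(lmFit(z, design))
out <- cbind(fit$t[, 2], fit$p.value[, 2], fit$df.prior, fit$s2.prior)
write.table(out, "{tmp_path}/ref.tsv", sep="\\t", row.names=FALSE, col.names=FALSE)
"""
        )
        subprocess.run(
            [shutil.which("Rscript") or "Rscript", str(r_script)],
            check=True,
            capture_output=True,
        )
        ref = np.loadtxt(tmp_path / "ref.tsv")
        np.testing.assert_allclose(table["statistic"], ref[:, 0], atol=1e-6)
        np.testing.assert_allclose(table["p_value"], ref[:, 1], atol=1e-6)


class TestPOTests:
    def test_no_variability_difference_gives_large_p(self, rng):
        x = rng.standard_normal((50, 12))
        values = np.hstack([x, x])  # diseased group duplicates control
        m = MethylationMatrix.from_arrays(values, np.repeat([0, 1], 12))
        for mode in ("AD", "SQ"):
            table = po_test(m, mode)
            assert (table["p_value"] > 0.99).all()

    def test_po_names(self, small_matrix):
        assert (po_test(small_matrix, "AD")["test"] == "PO.AD").all()
        assert (po_test(small_matrix, "SQ")["test"] == "PO.SQ").all()


class TestDispatch:
    def test_bf_is_median_centred_composition(self, small_matrix):
        direct = run_test(small_matrix, "BF")
        z = center_deviations(small_matrix, "abs", "group_median")
        composed = anova_f_on_deviations(z, small_matrix.site_ids)
        np.testing.assert_allclose(direct["statistic"], composed["statistic"])
        np.testing.assert_allclose(direct["p_value"], composed["p_value"])

    def test_unknown_test_rejected(self, small_matrix):
        with pytest.raises(InvalidInputError):
            run_test(small_matrix, "Welch")

    def test_f_and_bartlett_p_ranks_agree(self, small_matrix):
        """With equal group sizes the two tests order sites identically."""
        p_f = run_test(small_matrix, "F")["p_value"]
        p_b = run_test(small_matrix, "Bartlett")["p_value"]
        assert stats.spearmanr(p_f, p_b).statistic > 0.999

    @pytest.mark.parametrize("test_name", TEST_NAMES)
    def test_p_values_in_unit_interval(self, unbalanced_matrix, test_name):
        p = run_test(unbalanced_matrix, test_name)["p_value"]
        assert ((p >= 0) & (p <= 1)).all()

    @pytest.mark.parametrize("test_name", ["F", "Bartlett", "Levene", "L.trim", "BF"])
    def test_scale_equivariance(self, small_matrix, test_name):
        """Multiplying everything by a positive constant changes nothing."""
        base = run_test(small_matrix, test_name)
        scaled_matrix = MethylationMatrix(
            small_matrix.values * 3.7,
            small_matrix.site_ids,
            small_matrix.subject_ids,
            small_matrix.labels,
        )
        scaled = run_test(scaled_matrix, test_name)
        np.testing.assert_allclose(base["statistic"], scaled["statistic"], atol=1e-10)
        np.testing.assert_allclose(base["p_value"], scaled["p_value"], atol=1e-10)

    @pytest.mark.parametrize("test_name", ["Levene", "L.trim", "BF", "PO.AD", "PO.SQ"])
    def test_location_invariance(self, small_matrix, test_name):
        """Shifting one group's location leaves deviation tests unchanged."""
        base = run_test(small_matrix, test_name)
        shifted_values = small_matrix.values.copy()
        shifted_values[:, small_matrix.labels == 1] += 5.0
        shifted = run_test(
            MethylationMatrix(
                shifted_values,
                small_matrix.site_ids,
                small_matrix.subject_ids,
                small_matrix.labels,
            ),
            test_name,
        )
        np.testing.assert_allclose(base["statistic"], shifted["statistic"], atol=1e-10)
        np.testing.assert_allclose(base["p_value"], shifted["p_value"], atol=1e-10)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    scale=st.floats(0.1, 10.0),
    seed=st.integers(0, 2**20),
)
def test_f_statistic_orientation_property(scale, seed):
    """Swapping the groups inverts the statistic but keeps the p-value."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0, scale, 10)
    b = rng.normal(0, 1, 10)
    fwd = f_test(a, b)
    rev = f_test(b, a)
    if fwd.statistic > 0:
        assert rev.statistic == pytest.approx(1.0 / fwd.statistic)
    assert rev.p_value == pytest.approx(fwd.p_value, abs=1e-12)
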