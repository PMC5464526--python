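"""SEM engine: closed-form oracles, FIML, multigroup, indices, scores."""

import numpy as np
import pandas as pd
import pytest

from deltamed.sem import (
    SemModelSpec,
    factor_determinacy,
    factor_score_weights,
    fit_indices,
    fit_sem,
)
from deltamed.sem.model import Term, parse_model


# ---------------------------------------------------------------------------
# model specification and syntax
# ---------------------------------------------------------------------------
class TestSpec:
    def test_parse_loadings_regressions_covariances(self):
        terms = parse_model(
            """
            # measurement
            f =~ x1 + 0.5*x2 + x3 [lam3]
            y ~ x1 [b1] + x2
            x1 ~~ x2
            """
        )
        assert Term("f", "=~", "x1") in terms
        assert Term("f", "=~", "x2", value=0.5) in terms
        assert Term("f", "=~", "x3", tag="lam3") in terms
        assert Term("y", "~", "x1", tag="b1") in terms
        assert Term("x1", "~~", "x2") in terms

    def test_json_round_trip(self):
        spec = SemModelSpec.from_syntax("f =~ a + b + c\nd ~ a [p]")
        again = SemModelSpec.from_json(spec.to_json())
        assert again.terms == spec.terms
        assert again.latents == spec.latents

    def test_cyclic_graph_rejected(self):
        spec = SemModelSpec.from_syntax("a ~ b\nb ~ c\nc ~ a")
        with pytest.raises(ValueError, match="cyclic"):
            spec.validate()

    def test_unknown_operator_rejected(self):
        with pytest.raises(ValueError):
            Term("a", "<~", "b")

    def test_missing_column_raises(self, triad_data):
        spec = SemModelSpec.from_syntax("f =~ x1 + x2 + nope")
        with pytest.raises(KeyError):
            fit_sem(spec, triad_data)


# ---------------------------------------------------------------------------
# ML fitting against closed forms
# ---------------------------------------------------------------------------
class TestCompleteDataML:
    def test_triad_closed_form(self, triad_data):
        """One factor, three indicators: lambda_i = sqrt(r_ij r_ik / r_jk)."""
        fit = fit_sem(SemModelSpec.from_syntax("f =~ x1 + x2 + x3"), triad_data)
        assert fit.converged
        est = fit.estimates
        assert est["lambda_x1_f"] == pytest.approx(0.8, abs=1e-4)
        assert est["lambda_x2_f"] == pytest.approx(0.7, abs=1e-4)
        assert est["lambda_x3_f"] == pytest.approx(0.6, abs=1e-4)
        assert est["var_x1"] == pytest.approx(0.36, abs=1e-4)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-8)
        assert fit.df == 0

    def test_saturated_model_chi2_zero_and_gaussian_loglik(self, triad_data):
        spec = SemModelSpec.from_syntax(
            "x1 ~~ x1\nx2 ~~ x2\nx3 ~~ x3\nx1 ~~ x2\nx1 ~~ x3\nx2 ~~ x3"
        )
        fit = fit_sem(spec, triad_data, missing="fiml")
        assert fit.chi2 == pytest.approx(0.0, abs=1e-6)
        # casewise -2 loglik at the optimum equals the unrestricted
        # Gaussian value n (p ln 2pi + ln|S_ml| + p)
        X = triad_data.to_numpy()
        n, p = X.shape
        S_ml = np.cov(X, rowvar=False, ddof=0)
        expected = n * (p * np.log(2 * np.pi) + np.linalg.slogdet(S_ml)[1] + p)
        assert fit.minus2ll == pytest.approx(expected, rel=1e-8)

    def test_chi2_invariant_to_indicator_order(self, triad_data):
        f1 = fit_sem(SemModelSpec.from_syntax("f =~ x1 + x2 + x3"), triad_data)
        f2 = fit_sem(SemModelSpec.from_syntax("f =~ x3 + x1 + x2"), triad_data)
        assert f1.chi2 == pytest.approx(f2.chi2, abs=1e-8)
        assert f1.estimates["lambda_x2_f"] == pytest.approx(
            f2.estimates["lambda_x2_f"], abs=1e-6
        )

    def test_multistart_reaches_same_optimum(self, triad_data):
        base = fit_sem(SemModelSpec.from_syntax("f =~ x1 + x2 + x3"), triad_data)
        multi = fit_sem(
            SemModelSpec.from_syntax("f =~ x1 + x2 + x3"),
            triad_data,
            restarts=3,
            seed=99,
        )
        for k in base.estimates:
            assert abs(abs(base.estimates[k]) - abs(multi.estimates[k])) < 1e-6

    def test_loading_recovery_bifactor(self):
        """5-indicator delta/g' data from known loadings: estimates within 3 SEs."""
        from deltamed import DeltaModel, SimConfig, simulate_cohort

        coh = simulate_cohort(SimConfig(n_subjects=20000, seed=2, n_proteins=1))
        frame = coh.truth.indicators_raw  # pre-discretization indicators
        dm = DeltaModel(missing="listwise").fit(frame)
        fit = dm.sem_fit_
        lam = coh.truth.loadings
        for ind in lam.index:
            est = fit.estimates[f"lambda_{ind}_delta"]
            se = fit.se[f"lambda_{ind}_delta"]
            # the fitted factor's global sign is arbitrary
            assert min(abs(est - lam.loc[ind, "delta"]), abs(-est - lam.loc[ind, "delta"])) <= 3 * se

    def test_nonconvergence_is_flagged_not_silent(self):
        rng = np.random.default_rng(0)
        # two indicators for one factor: under-identified
        df = pd.DataFrame(rng.normal(size=(100, 2)), columns=["x1", "x2"])
        with pytest.raises(ValueError):
            fit_sem(SemModelSpec.from_syntax("f =~ x1 + x2"), df)

    def test_non_pd_sample_covariance_rejected(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        df = pd.DataFrame({"x1": x, "x2": x, "x3": rng.normal(size=200)})
        with pytest.raises(np.linalg.LinAlgError, match="positive definite"):
            fit_sem(SemModelSpec.from_syntax("f =~ x1 + x2 + x3"), df)


class TestPathModelOLS:
    def test_ml_equals_equationwise_ols(self, path_model_data):
        """Recursive observed-variable system: ML = per-equation least squares."""
        import statsmodels.api as sm

        spec = SemModelSpec.from_syntax(
            """
            protein_x ~ gds_z [c] + z1
            deq_w2 ~ gds_z [a] + protein_x [b] + z1 + z2
            """
        )
        fit = fit_sem(spec, path_model_data)
        d = path_model_data
        o1 = sm.OLS(d["protein_x"], sm.add_constant(d[["gds_z", "z1"]])).fit()
        o2 = sm.OLS(d["deq_w2"], sm.add_constant(d[["gds_z", "protein_x", "z1", "z2"]])).fit()
        assert fit.estimates["c"] == pytest.approx(o1.params["gds_z"], abs=1e-6)
        assert fit.estimates["a"] == pytest.approx(o2.params["gds_z"], abs=1e-6)
        assert fit.estimates["b"] == pytest.approx(o2.params["protein_x"], abs=1e-6)
        # ML standard errors agree with OLS up to the n/(n-k) variance convention
        assert fit.se["b"] == pytest.approx(o2.bse["protein_x"], rel=5e-3)

    def test_listwise_normal_likelihood_matches_fiml(self, path_model_data):
        """With no missingness the N-divisor complete-data ML and FIML
        maximize the same likelihood, so estimates coincide."""
        spec = SemModelSpec.from_syntax("deq_w2 ~ gds_z [a] + protein_x [b]")
        f_norm = fit_sem(spec, path_model_data, likelihood="normal")
        f_fiml = fit_sem(spec, path_model_data, missing="fiml")
        for k in ("a", "b"):
            assert f_norm.estimates[k] == pytest.approx(f_fiml.estimates[k], abs=1e-6)

    def test_fiml_uses_partially_observed_rows(self, path_model_data):
        spec = SemModelSpec.from_syntax("deq_w2 ~ gds_z [a] + protein_x [b]")
        d = path_model_data.copy()
        d.loc[d.index[:500], "protein_x"] = np.nan
        f_listwise = fit_sem(spec, d)
        f_fiml = fit_sem(spec, d, missing="fiml")
        assert f_fiml.n == len(d)
        assert f_listwise.n == len(d) - 500
        assert f_fiml.converged
        assert f_fiml.estimates["b"] == pytest.approx(-0.3, abs=0.05)


class TestMultigroup:
    def test_shared_tags_are_constrained(self, path_model_data):
        d = path_model_data.copy()
        d["grp"] = (np.arange(len(d)) % 2).astype(int)
        spec = SemModelSpec.from_syntax("deq_w2 ~ gds_z [a] + protein_x [b]")
        fit_c = fit_sem(spec, d, groups="grp", share_tags=True)
        fit_u = fit_sem(spec, d, groups="grp", share_tags=False)
        assert fit_c.df - fit_u.df == 2  # a and b shared
        assert fit_c.chi2 >= fit_u.chi2 - 1e-8
        assert "a" in fit_c.estimates and "a_g0" in fit_u.estimates


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------
class TestFitIndices:
    def test_reported_base_model_rmsea(self):
        """chi2=84.42, df=11, N=3385 -> RMSEA 0.044."""
        fi = fit_indices(84.42, 11, 3385)
        assert fi.rmsea == pytest.approx(0.0444, abs=1e-3)
        assert fi.cmin_df == pytest.approx(84.42 / 11, rel=1e-12)

    def test_exact_fit_gives_cfi_one_rmsea_zero(self):
        fi = fit_indices(10.0, 10, 500, baseline_chi_square=900.0, baseline_df=15)
        assert fi.cfi == 1.0
        assert fi.rmsea == 0.0

    def test_arithmetic_example(self):
        fi = fit_indices(40.0, 10, 401, baseline_chi_square=1000.0, baseline_df=15)
        assert fi.cfi == pytest.approx(1 - 30 / 985, abs=1e-6)
        assert fi.rmsea == pytest.approx(np.sqrt(30 / 4000), abs=1e-6)

    def test_zero_df_reported_not_applicable(self):
        fi = fit_indices(0.0, 0, 100)
        assert np.isnan(fi.cmin_df) and np.isnan(fi.rmsea)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fit_indices(1.0, -1, 100)
        with pytest.raises(ValueError):
            fit_indices(1.0, 1, 1)


# ---------------------------------------------------------------------------
# factor scores and determinacy
# ---------------------------------------------------------------------------
class TestScores:
    def test_weights_match_linear_solve_oracle(self, triad_data):
        fit = fit_sem(SemModelSpec.from_syntax("f =~ x1 + x2 + x3"), triad_data)
        W = factor_score_weights(fit)
        lam = np.array([0.8, 0.7, 0.6])
        Sigma = np.outer(lam, lam) + np.diag(1 - lam**2)
        oracle = np.linalg.solve(Sigma, lam)
        np.testing.assert_allclose(W.loc["f"].to_numpy(), oracle, atol=1e-4)

    def test_determinacy_woodbury_oracle(self, triad_data):
        """rho = sqrt(t/(1+t)) with t = sum(lambda_i^2 / theta_i)."""
        fit = fit_sem(SemModelSpec.from_syntax("f =~ x1 + x2 + x3"), triad_data)
        rho = factor_determinacy(fit)["f"]
        t = (0.64 / 0.36) + (0.49 / 0.51) + (0.36 / 0.64)
        assert rho == pytest.approx(np.sqrt(t / (1 + t)), abs=1e-3)
        assert rho == pytest.approx(0.876, abs=1e-3)

    def test_error_free_single_indicator_determinacy_one(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x1": rng.normal(size=300), "x2": rng.normal(size=300)})
        df["x2"] += 0.5 * df["x1"]
        spec = SemModelSpec(
            terms=[
                Term("f", "=~", "x1", value=1.0),
                Term("f", "=~", "x2"),
                Term("x1", "~~", "x1", value=0.0),
            ],
            latents=["f"],
            identification="unit_loading",
        )
        fit = fit_sem(spec, df)
        assert factor_determinacy(fit)["f"] == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("lam,lo,hi", [(0.25, 0.0, 0.6), (0.9, 0.9, 1.0)])
    def test_determinacy_tracks_loading_strength(self, lam, lo, hi):
        """Weak loadings give poorly determined scores; strong loadings
        give determinacy near 1 (Grice's criterion)."""
        rng = np.random.default_rng(4)
        n = 3000
        f = rng.normal(size=n)
        df = pd.DataFrame(
            {f"x{i}": lam * f + np.sqrt(1 - lam**2) * rng.normal(size=n) for i in range(4)}
        )
        fit = fit_sem(SemModelSpec.from_syntax("g =~ x0 + x1 + x2 + x3"), df)
        assert lo < factor_determinacy(fit)["g"] < hi
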