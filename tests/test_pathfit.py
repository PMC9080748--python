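"""ML covariance path-model fitting, RMSEA, likelihood-ratio tests and the
model-menu comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sidewinderkin import (PathModelSpec, build_model_menu,
                           default_speed_path_model, fit_path_model,
                           lrt_path, model_menu_search, pearson_matrix,
                           residualize, rmsea, variance_explained_percent)
from sidewinderkin.pathfit import simulate_from_model


def two_var_corr(r=0.5):
    return np.array([[1.0, r], [r, 1.0]])


class TestSpecValidation:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="acyclic"):
            PathModelSpec(("a", "b"), (("a", "b"), ("b", "a")))

    def test_too_many_variables(self):
        with pytest.raises(ValueError, match="7"):
            PathModelSpec(tuple("abcdefgh"))

    def test_unknown_variable(self):
        with pytest.raises(ValueError):
            PathModelSpec(("a", "b"), (("a", "zz"),))

    def test_df_arithmetic(self):
        spec = default_speed_path_model()
        p = len(spec.variables)
        assert spec.df + spec.n_free == p * (p + 1) // 2
        assert spec.df == 2

    @given(st.integers(0, 15))
    @settings(max_examples=16, deadline=None)
    def test_menu_df_accounting(self, i):
        menu = build_model_menu()
        spec = menu[i]
        p = len(spec.variables)
        assert p == 7
        assert spec.df + spec.n_free == p * (p + 1) // 2
        assert spec.df >= 0


class TestFitting:
    def test_saturated_model_zero_chi_square(self):
        spec = PathModelSpec(("x", "y"), (), (("x", "y"),))
        fit = fit_path_model(spec, two_var_corr(0.37), n=50, restarts=2)
        assert fit.chi_square == pytest.approx(0.0, abs=1e-8)
        assert fit.df == 0
        np.testing.assert_allclose(fit.sigma_hat, two_var_corr(0.37),
                                   atol=1e-6)

    def test_single_path_equals_pearson_r(self):
        spec = PathModelSpec(("x", "y"), (("x", "y"),))
        fit = fit_path_model(spec, two_var_corr(0.62), n=100, restarts=2)
        assert fit.path("x", "y") == pytest.approx(0.62, abs=1e-6)

    def test_just_identified_reproduces_sample_matrix(self, rng):
        # x -> y -> z with x~~... saturated-df structure
        spec = PathModelSpec(("x", "y", "z"),
                             (("x", "y"), ("y", "z"), ("x", "z")))
        X = rng.normal(size=(300, 3)) @ rng.normal(size=(3, 3))
        S = np.corrcoef(X, rowvar=False)
        fit = fit_path_model(spec, S, n=300, restarts=3)
        assert fit.df == 0
        np.testing.assert_allclose(fit.sigma_hat, S, atol=1e-6)
        assert fit.chi_square < 1e-6

    def test_negative_df_rejected(self):
        spec = PathModelSpec(("x", "y"), (("x", "y"),), (("x", "y"),))
        with pytest.raises(ValueError, match="degrees of freedom"):
            fit_path_model(spec, two_var_corr(), n=30)

    def test_non_pd_matrix_rejected(self):
        spec = PathModelSpec(("x", "y"), (("x", "y"),))
        with pytest.raises(ValueError, match="positive definite"):
            fit_path_model(spec, two_var_corr(1.0), n=30)

    def test_scale_equivariance_correlation_vs_standardized_cov(self, rng):
        spec = default_speed_path_model()
        params = _paperlike_params(spec)
        df = simulate_from_model(spec, params, 500, seed=8)
        Z = (df - df.mean()) / df.std(ddof=1)
        S_corr = np.corrcoef(df.to_numpy(), rowvar=False)
        S_cov = np.cov(Z.to_numpy(), rowvar=False)
        f1 = fit_path_model(spec, S_corr, 500, restarts=3, compute_se=False)
        f2 = fit_path_model(spec, S_cov, 500, restarts=3, compute_se=False)
        for key in f1.estimates:
            if key[0] == "path":
                assert f1.estimates[key] == pytest.approx(
                    f2.estimates[key], abs=1e-4)


def _paperlike_params(spec):
    params = {}
    path_vals = {("frequency", "speed"): 0.9,
                 ("wavelength", "speed"): 0.15,
                 ("amplitude", "speed"): -0.15,
                 ("skew", "speed"): -0.05,
                 ("width50", "wavelength"): 0.55}
    for a, b in spec.paths:
        params[("path", a, b)] = path_vals.get((a, b), 0.3)
    for v in spec.variables:
        if v == "speed":
            params[("var", v, v)] = 0.15
        elif v == "wavelength":
            params[("var", v, v)] = 0.6
        else:
            params[("var", v, v)] = 1.0
    for a, b in spec.covariances:
        params[("cov", a, b)] = 0.05 if "wavelength" in (a, b) else 0.15
    return params


class TestRmsea:
    def test_zero_when_chi_square_below_df(self):
        assert rmsea(2.0, 2, 26) == 0.0
        assert rmsea(1.148, 2, 26) == 0.0

    def test_closed_form(self):
        assert rmsea(6.0, 2, 26) == pytest.approx(np.sqrt(4 / 50.0))

    def test_df_zero_flagged(self):
        with pytest.raises(ValueError):
            rmsea(1.0, 0, 26)


class TestLrt:
    def test_null_path_no_improvement(self):
        spec = PathModelSpec(("x", "y"), (("x", "y"),))
        chi2, p = lrt_path(spec, ("x", "y"), two_var_corr(0.0), n=80,
                           restarts=2)
        assert chi2 == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-3)

    def test_strong_path_decisive(self):
        spec = default_speed_path_model()
        df = simulate_from_model(spec, _paperlike_params(spec), 500, seed=2)
        S = np.corrcoef(df.to_numpy(), rowvar=False)
        chi2, p = lrt_path(spec, ("frequency", "speed"), S, 500, restarts=3)
        assert chi2 > 0.0
        assert p < 1e-6

    def test_never_negative(self, rng):
        spec = PathModelSpec(("x", "y", "z"),
                             (("x", "y"), ("y", "z")), (("x", "z"),))
        X = rng.normal(size=(120, 3))
        S = np.corrcoef(X, rowvar=False)
        chi2, _ = lrt_path(spec, ("x", "y"), S, 120, restarts=3)
        assert chi2 >= 0.0


class TestResidualize:
    @staticmethod
    def _frame(rng, n=100):
        log_svl = rng.normal(1.6, 0.1, n)
        return pd.DataFrame({
            "svl_cm": 10.0 ** log_svl,
            "double": 10.0 ** (2 * log_svl),
            "indep": rng.normal(5, 1, n),
            "allom": 10.0 ** (1.2 * log_svl + rng.normal(0, 0.05, n)),
        })

    def test_exact_dependence_gives_zero_residuals(self, rng):
        df = self._frame(rng)
        res = residualize(df, config={"double": {"log": True}})
        np.testing.assert_allclose(res["double"], 0.0, atol=1e-10)

    def test_independent_variable_residuals_centered(self, rng):
        df = self._frame(rng)
        res = residualize(df, config={"indep": {"log": False}})
        centered = df["indep"] - df["indep"].mean()
        assert np.corrcoef(res["indep"], centered)[0, 1] > 0.99
        assert abs(res["indep"].mean()) < 1e-10

    def test_residuals_orthogonal_to_log_svl(self, rng):
        df = self._frame(rng)
        res = residualize(df, config={"allom": {"log": True}})
        r = np.corrcoef(res["allom"], np.log10(df["svl_cm"]))[0, 1]
        assert abs(r) < 1e-10

    def test_constant_variable_rejected(self, rng):
        df = self._frame(rng)
        df["flat"] = 3.0
        with pytest.raises(ValueError, match="constant"):
            residualize(df, config={"flat": {"log": False}})


class TestPearson:
    def test_self_and_negation(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"x": x, "y": x, "z": -x})
        r, p = pearson_matrix(df)
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert r.loc["x", "z"] == pytest.approx(-1.0)

    def test_bivariate_normal_estimate(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=5000)
        y = 0.6 * x + np.sqrt(1 - 0.36) * rng.normal(size=5000)
        r, _ = pearson_matrix(pd.DataFrame({"x": x, "y": y}))
        assert abs(r.loc["x", "y"] - 0.6) < 0.03


class TestMenu:
    def test_menu_is_sixteen_seven_variable_models(self):
        menu = build_model_menu()
        assert len(menu) == 16
        assert all(len(m.variables) == 7 for m in menu)
        # mass and width50 never co-occur (redundant stoutness measures)
        assert not any({"mass", "width50"} <= set(m.variables) for m in menu)

    def test_true_model_selected_over_misspecified(self):
        spec = default_speed_path_model()
        df = simulate_from_model(spec, _paperlike_params(spec), 500, seed=4)
        # a rival model omitting the strong frequency->speed path
        rival = PathModelSpec(
            spec.variables,
            tuple(p for p in spec.paths if p != ("frequency", "speed")),
            spec.covariances)
        report = model_menu_search([spec, rival], df, restarts=3)
        assert report.selected == 0
        assert bool(report.table.loc[1, "rejected"])

    def test_equal_rmsea_tie_broken_by_aicc(self):
        spec = default_speed_path_model()
        df = simulate_from_model(spec, _paperlike_params(spec), 800, seed=6)
        # saturate the rival by freeing one more covariance: same fit class
        extra = ("height", "speed")
        richer = PathModelSpec(spec.variables, spec.paths,
                               spec.covariances + (extra,))
        report = model_menu_search([richer, spec], df, restarts=3)
        tab = report.table
        if (tab["rmsea"] == 0).all():
            sel = report.selected
            assert tab.loc[sel, "aicc"] == tab["aicc"].min()


class TestSimulation:
    def test_simulation_matches_implied_covariance(self):
        spec = default_speed_path_model()
        params = _paperlike_params(spec)
        df = simulate_from_model(spec, params, 20000, seed=9)
        fit = fit_path_model(spec, np.cov(df.to_numpy(), rowvar=False),
                             n=20000, restarts=3, compute_se=False)
        for a, b in spec.paths:
            assert fit.path(a, b) == pytest.approx(
                params[("path", a, b)], abs=0.05)


class TestParseModelSpec:
    def test_round_trip_of_default_structure(self):
        from sidewinderkin import parse_model_spec
        text = """
        variables: x y z   # three observed variables
        paths:
          x -> y
          y -> z
        covariances:
          x ~~ z
        """
        spec = parse_model_spec(text)
        assert spec.variables == ("x", "y", "z")
        assert spec.paths == (("x", "y"), ("y", "z"))
        assert spec.covariances == (("x", "z"),)

    def test_garbage_line_rejected(self):
        from sidewinderkin import parse_model_spec
        with pytest.raises(ValueError, match="unparseable"):
            parse_model_spec("variables: a b\na => b\n")
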