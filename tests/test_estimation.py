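"""Penalized fitting: starts, convergence, smoothing selection, inference."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import ndtr

from recprobit import (
    EquationSpec,
    GeneratorConfig,
    ModelSpec,
    RecursiveBivariateProbit,
    RecursiveBivariateProbitResults,
    SmoothSpec,
    generate,
)


class TestInitialize:
    def test_intercept_start_at_probit_quantile(self):
        frame = pd.DataFrame(
            {"y1": [0.0, 1.0] * 20, "y2": [0.0, 0.0, 1.0, 1.0] * 10}
        )
        spec = ModelSpec("y1", "y2", EquationSpec(), EquationSpec())
        m = RecursiveBivariateProbit(frame, spec)
        theta = m.initialize()
        assert theta[m.design.sl_delta1][0] == pytest.approx(0.0, abs=1e-6)
        assert theta[m.design.idx_rho] == 0.0

    def test_start_near_joint_optimum_when_independent(self, nospline_spec):
        ds = generate(GeneratorConfig(n=3000, rho=0.0, gamma=-1.0, seed=17))
        m = RecursiveBivariateProbit(ds.frame, nospline_spec)
        start = m.initialize()
        res = m.fit()
        moved = np.abs(res.params - start)
        # rho_z moves freely; every regression coefficient stays close
        assert moved[: m.design.idx_rho].max() < 0.1


class TestFit:
    def test_null_truth_recovered(self, nospline_spec):
        ds = generate(GeneratorConfig(n=4000, rho=0.0, gamma=0.0, seed=4))
        res = RecursiveBivariateProbit(ds.frame, nospline_spec).fit()
        d = res.design
        g, g_se = res.theta.gamma, res.bse[d.idx_gamma]
        assert abs(g) < 3 * g_se
        assert abs(res.rho) < 3 * res.rho_se

    def test_rho_zero_fit_equals_univariate_probits(self, nospline_spec, ds_confounded):
        frame = ds_confounded.frame
        res = RecursiveBivariateProbit(frame, nospline_spec).fit(fix_rho_at=0.0)
        X1 = np.column_stack([np.ones(len(frame)), frame["access"], frame["age"]])
        p1 = sm.Probit(frame["STres"], X1).fit(disp=0, tol=1e-12)
        X2 = np.column_stack(
            [np.ones(len(frame)), frame["killip"], frame["EF"], frame["STres"]]
        )
        p2 = sm.Probit(frame["mortality"], X2).fit(disp=0, tol=1e-12)
        tv = res.theta
        np.testing.assert_allclose(tv.delta1, p1.params, atol=1e-6)
        np.testing.assert_allclose(np.r_[tv.delta2, tv.gamma], p2.params, atol=1e-6)

    def test_monotone_inner_ascent(self, fitted_confounded):
        trace = fitted_confounded.trace
        assert np.all(np.diff(trace) >= -1e-10)

    def test_converged_flag_means_small_gradient(self, fitted_confounded):
        m = fitted_confounded.model
        S = m.design.penalty_matrix(fitted_confounded.lambdas)
        f, g = m._penalized_value_and_score(fitted_confounded.params, S)
        assert fitted_confounded.converged
        assert np.abs(g).max() <= 1e-6 * (1 + abs(f))

    def test_linear_truth_shrinks_to_linear(self, case_spec):
        """When the true ischaemic-time effect is linear, UBRE drives the
        smooth's edf toward its 1-dimensional linear null space."""
        hits = 0
        for seed in range(6):
            ds = generate(
                GeneratorConfig(n=3000, gamma=-1.0, rho=0.4, seed=600 + seed, smooth_shape="linear")
            )
            res = RecursiveBivariateProbit(ds.frame, case_spec).fit()
            hits += list(res.edf_smooth.values())[0] <= 1.5
        assert hits >= 4

    def test_single_dataset_truth_in_intervals(self, fitted_confounded, ds_confounded):
        d = fitted_confounded.design
        g, g_se = fitted_confounded.theta.gamma, fitted_confounded.bse[d.idx_gamma]
        assert abs(g - (-1.0)) < 3 * g_se
        assert abs(fitted_confounded.rho - 0.4) < 3 * fitted_confounded.rho_se


class TestPosteriorCovariance:
    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(12)
        n = 2000
        frame = pd.DataFrame(
            {
                "y1": (rng.random(n) < 0.7).astype(float),
                "y2": (rng.random(n) < 0.3).astype(float),
            }
        )
        spec = ModelSpec("y1", "y2", EquationSpec(), EquationSpec(), include_treatment_in_eq2=False)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = RecursiveBivariateProbit(frame, spec).fit(fix_rho_at=0.0)
        x = res.params[res.design.sl_delta1][0]
        phi = np.exp(-x * x / 2) / np.sqrt(2 * np.pi)
        closed = ndtr(x) * (1 - ndtr(x)) / (n * phi**2)
        assert res.V_theta[0, 0] == pytest.approx(closed, rel=0.01)

    def test_matches_unpenalized_information_without_smooths(self, nospline_spec, ds_confounded):
        frame = ds_confounded.frame
        res = RecursiveBivariateProbit(frame, nospline_spec).fit(fix_rho_at=0.0)
        X1 = np.column_stack([np.ones(len(frame)), frame["access"], frame["age"]])
        p1 = sm.Probit(frame["STres"], X1).fit(disp=0, tol=1e-12)
        sl = res.design.sl_delta1
        np.testing.assert_allclose(
            res.V_theta[sl, sl], np.asarray(p1.cov_params()), rtol=1e-4
        )

    def test_variances_shrink_with_lambda(self, toy_model):
        traces = []
        for lam in [1e-2, 1e1, 1e4, 1e7]:
            res = toy_model.fit(lambdas=[lam])
            gsl = res.design.smooth_slices[0][2]
            traces.append(np.trace(res.V_theta[gsl, gsl]))
        assert all(a > b for a, b in zip(traces, traces[1:]))


@pytest.fixture(scope="module")
def unit_scale_model():
    ds = generate(GeneratorConfig(n=1500, gamma=-1.0, rho=0.3, seed=9))
    spec = ModelSpec(
        "STres",
        "mortality",
        EquationSpec(parametric=("access", "age"), smooths=(SmoothSpec("O2B", 8),)),
        EquationSpec(parametric=("killip", "EF")),
    )
    return RecursiveBivariateProbit(ds.frame, spec)


class TestEdf:
    def test_zero_lambda_full_dimension(self, unit_scale_model):
        res = unit_scale_model.fit(lambdas=[0.0])
        assert list(res.edf_smooth.values())[0] == pytest.approx(7, abs=1e-4)

    def test_huge_lambda_linear_null_space(self, unit_scale_model):
        res = unit_scale_model.fit(lambdas=[1e8])
        assert list(res.edf_smooth.values())[0] == pytest.approx(1.0, abs=0.05)

    def test_intermediate_matches_dense_assembly(self, unit_scale_model):
        res = unit_scale_model.fit(lambdas=[50.0])
        m = unit_scale_model
        S = m.design.penalty_matrix(res.lambdas)
        H_pen = m._fd_hessian(res.params, S)
        I_unpen = -H_pen - S
        F = np.linalg.solve(-H_pen, I_unpen)  # V I_unpen by direct solve
        gsl = m.design.smooth_slices[0][2]
        assert list(res.edf_smooth.values())[0] == pytest.approx(
            np.trace(F[gsl, gsl]), abs=1e-6
        )
        assert res.edf_total == pytest.approx(np.trace(F), abs=1e-6)


class TestSummary:
    def test_zero_estimate_unit_pvalue(self, fitted_confounded):
        res = fitted_confounded
        doctored = RecursiveBivariateProbitResults(
            model=res.model,
            params=res.params.copy(),
            V_theta=res.V_theta,
            lambdas=res.lambdas,
            edf_smooth=res.edf_smooth,
            edf_total=res.edf_total,
            loglik=res.loglik,
            penalized_loglik=res.penalized_loglik,
            converged=res.converged,
            trace=res.trace,
            options=res.options,
        )
        doctored.params[doctored.design.idx_gamma] = 0.0
        tab = doctored.params_table(2)
        row = tab[tab["term"] == "STres"].iloc[0]
        assert row["P val."] == pytest.approx(1.0)

    def test_rho_row_format(self, fitted_confounded):
        text = fitted_confounded.summary()
        import re

        m = re.search(r"rho (-?\d\.\d{3}) \((-?\d\.\d{4}), (-?\d\.\d{4})\)", text)
        assert m, text
        lo, hi = float(m.group(2)), float(m.group(3))
        assert lo < float(m.group(1)) < hi

    def test_smooth_table_layout(self, fitted_confounded):
        tab = fitted_confounded.smooth_table()
        assert list(tab.columns) == ["Smooth term", "Edf", "Est. rank", "P val."]
        assert tab["Est. rank"].dtype.kind == "i"
        assert ((tab["Edf"] > 0) & (tab["Edf"] <= 9)).all()

    def test_equation_tables_order(self, fitted_confounded):
        t1 = fitted_confounded.params_table(1)
        t2 = fitted_confounded.params_table(2)
        assert list(t1["term"]) == ["intercept", "access", "age"]
        assert list(t2["term"]) == ["intercept", "STres", "killip", "EF"]
        assert (t1["Std. err."] > 0).all() and (t2["Std. err."] > 0).all()


def test_v_theta_symmetric_psd(fitted_confounded):
    V = fitted_confounded.V_theta
    assert np.abs(V - V.T).max() < 1e-8
    assert np.linalg.eigvalsh(V).min() > -1e-10
    for label, edf in fitted_confounded.edf_smooth.items():
        assert 0 < edf <= 9
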