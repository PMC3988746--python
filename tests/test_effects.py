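"""Treatment-effect estimators and the tetrachoric correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr, ndtri

from recprobit import (
    EquationSpec,
    GeneratorConfig,
    ModelSpec,
    RecursiveBivariateProbit,
    ate_ap,
    ate_sbp,
    ate_unadjusted,
    bvn_cdf,
    generate,
    tetrachoric,
)
from recprobit.model import RecursiveBivariateProbitResults


def _clone_with_params(res, params):
    return RecursiveBivariateProbitResults(
        model=res.model,
        params=params,
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


class TestAteSbp:
    def test_factorizes_at_rho_zero(self, nospline_spec, ds_confounded):
        """With rho fixed at 0 the conditional contrast equals the
        potential-outcome average exactly."""
        res = RecursiveBivariateProbit(ds_confounded.frame, nospline_spec).fit(
            fix_rho_at=0.0
        )
        r = ate_sbp(res)
        d = res.design
        _, b, c = (
            d.linear_predictors(res.params)[0],
            d.linear_predictors(res.params, y1=np.ones(d.n))[1],
            d.linear_predictors(res.params, y1=np.zeros(d.n))[1],
        )
        direct = float(np.mean(ndtr(b) - ndtr(c)))
        assert r.estimate == pytest.approx(direct, abs=1e-10)
        assert r.estimate == pytest.approx(r.extra["potential_outcome"], abs=1e-10)

    def test_zero_gamma(self, fitted_confounded):
        """gamma=0: the potential-outcome effect is exactly 0; the
        conditional contrast is not (selection on correlated errors)."""
        params = fitted_confounded.params.copy()
        params[fitted_confounded.design.idx_gamma] = 0.0
        r = ate_sbp(_clone_with_params(fitted_confounded, params))
        assert r.extra["potential_outcome"] == 0.0
        assert abs(r.estimate) > 1e-4  # rho_hat != 0 here

    def test_recovers_truth_potential_outcome(self, fitted_confounded, ds_confounded):
        r = ate_sbp(fitted_confounded)
        po = r.extra["potential_outcome"]
        se = r.extra["potential_outcome_se"]
        assert abs(po - ds_confounded.true_ate) < 3 * se

    def test_conditional_contrast_matches_empirical(self, fitted_confounded, ds_confounded):
        """The printed estimand is the model-implied conditional contrast:
        it should track the raw P(y2|y1) difference, not the causal ATE."""
        r = ate_sbp(fitted_confounded)
        emp = ate_unadjusted(ds_confounded.y1, ds_confounded.y2)
        assert abs(r.estimate - emp.estimate) < 3 * emp.se

    def test_delta_gradient_matches_finite_differences(self, fitted_confounded):
        res = fitted_confounded
        r = ate_sbp(res)
        for key, grad in (
            ("estimate", r.extra["gradient"]),
            ("potential_outcome", r.extra["potential_outcome_gradient"]),
        ):
            fd = np.empty_like(res.params)
            for j in range(res.params.size):
                h = 1e-5 * (1 + abs(res.params[j]))
                up, dn = res.params.copy(), res.params.copy()
                up[j] += h
                dn[j] -= h
                r_up = ate_sbp(_clone_with_params(res, up))
                r_dn = ate_sbp(_clone_with_params(res, dn))
                v_up = r_up.estimate if key == "estimate" else r_up.extra[key]
                v_dn = r_dn.estimate if key == "estimate" else r_dn.extra[key]
                fd[j] = (v_up - v_dn) / (2 * h)
            np.testing.assert_allclose(grad, fd, atol=1e-7)

    def test_interval_brackets_estimate(self, fitted_confounded):
        r = ate_sbp(fitted_confounded)
        assert r.ci_low <= r.estimate <= r.ci_high
        assert abs(r.estimate) <= 1.0
        est100, lo100, hi100 = r.display()
        assert est100 == pytest.approx(100 * r.estimate)


class TestAteAp:
    def test_null_effect_recovered(self, nospline_spec):
        ds = generate(GeneratorConfig(n=3000, gamma=0.0, rho=0.0, seed=77))
        r = ate_ap(ds.frame, nospline_spec)
        assert abs(r.estimate) < 3 * r.se

    def test_collapses_to_unadjusted_without_covariates(self, ds_confounded):
        spec = ModelSpec("STres", "mortality", EquationSpec(), EquationSpec())
        r_ap = ate_ap(ds_confounded.frame, spec)
        r_un = ate_unadjusted(ds_confounded.y1, ds_confounded.y2)
        assert r_ap.estimate == pytest.approx(r_un.estimate, abs=1e-8)

    def test_biased_under_unobserved_confounding(self):
        """rho=0.7, gamma=0: ignoring the error correlation leaves a
        selection effect that AP attributes to the treatment."""
        ds = generate(GeneratorConfig(n=3000, gamma=0.0, rho=0.7, seed=55))
        spec = ModelSpec(
            "STres",
            "mortality",
            EquationSpec(parametric=("access", "age")),
            EquationSpec(parametric=("killip", "EF")),
        )
        r = ate_ap(ds.frame, spec)
        assert abs(r.estimate) > 3 * r.se


class TestAteUnadjusted:
    def test_equal_proportions_zero(self):
        y1 = np.repeat([0.0, 1.0], 50)
        y2 = np.tile([0.0, 1.0], 50)
        assert ate_unadjusted(y1, y2).estimate == 0.0

    def test_arithmetic(self):
        y1 = np.repeat([1.0, 0.0], 100)
        y2 = np.r_[np.repeat([1.0, 0.0], [30, 70]), np.repeat([1.0, 0.0], [40, 60])]
        r = ate_unadjusted(y1, y2)
        assert r.estimate == pytest.approx(-0.10, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            ate_unadjusted(np.ones(10), np.zeros(10))


class TestTetrachoric:
    def test_independence_product_table(self):
        # cells proportional to the product of the margins: rho = 0
        tab = np.outer([60, 40], [70, 30]) / 10  # counts, margins 0.4/0.3
        rho, _ = tetrachoric(tab)
        assert rho == pytest.approx(0.0, abs=1e-6)

    def test_matches_grid_search_oracle(self):
        tab = np.array([[40, 10], [10, 40]], dtype=float)
        n = tab.sum()
        h, k = ndtri(tab[1].sum() / n), ndtri(tab[:, 1].sum() / n)
        grid = np.linspace(-0.999, 0.999, 4001)
        ll = np.empty_like(grid)
        for i, r in enumerate(grid):
            p11 = bvn_cdf(h, k, r)
            p10 = ndtr(h) - p11
            p01 = ndtr(k) - p11
            p00 = 1 - ndtr(h) - ndtr(k) + p11
            cells = np.clip([p00, p01, p10, p11], 1e-12, 1)
            counts = [tab[0, 0], tab[0, 1], tab[1, 0], tab[1, 1]]
            ll[i] = np.dot(counts, np.log(cells))
        rho_grid = grid[np.argmax(ll)]
        rho, ci = tetrachoric(tab)
        assert rho == pytest.approx(rho_grid, abs=1e-3)  # grid resolution 5e-4
        assert ci[0] < rho < ci[1]

    def test_label_swap_symmetries(self):
        tab = np.array([[50, 15], [20, 35]], dtype=float)
        rho, _ = tetrachoric(tab)
        both = tab[::-1, ::-1]
        assert tetrachoric(both)[0] == pytest.approx(rho, abs=1e-10)
        one = tab[::-1, :]
        assert tetrachoric(one)[0] == pytest.approx(-rho, abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            tetrachoric([[0, 0], [10, 20]])

    def test_equals_nonrecursive_intercept_only_fit(self):
        tab = np.array([[40, 10], [10, 40]], dtype=float)
        rho_tc, _ = tetrachoric(tab)
        rows = []
        for i in (0, 1):
            for j in (0, 1):
                rows += [[float(i), float(j)]] * int(tab[i, j])
        frame = pd.DataFrame(rows, columns=["y1", "y2"])
        spec = ModelSpec(
            "y1", "y2", EquationSpec(), EquationSpec(), include_treatment_in_eq2=False
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = RecursiveBivariateProbit(frame, spec).fit()
        assert res.rho == pytest.approx(rho_tc, abs=1e-4)
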