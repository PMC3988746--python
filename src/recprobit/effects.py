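"""Average treatment effects and the tetrachoric correlation utility.

Three estimators of the effect of the binary treatment on the outcome
probability, mirroring the usual confounding ladder:

* ``ate_sbp`` — from the fitted recursive bivariate probit, which
  adjusts for observed covariates *and* (through rho) unobserved
  confounders.  Two estimands are computed: the conditional-probability
  contrast

      (1/n) sum_i [ Phi2(eta2_i(1), eta1_i; rho)/Phi(eta1_i)
                    - Phi2(eta2_i(0), -eta1_i; -rho)/(1 - Phi(eta1_i)) ]

  (the difference of the model-implied P(y2=1 | y1=1, x) and
  P(y2=1 | y1=0, x), reported as the primary estimate) and the
  potential-outcome average (1/n) sum_i [Phi(eta2_i(1)) - Phi(eta2_i(0))],
  exposed alongside it.  With rho = 0 the two coincide.
* ``ate_ap`` — from an additive (univariate) probit of the outcome on
  treatment and the outcome-equation covariates: observed confounders
  only.
* ``ate_unadjusted`` — the raw risk difference between treated and
  untreated.

Confidence intervals are delta-method intervals through the posterior
covariance of the fitted parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from .bvn import bvn_cdf, bvn_pdf
from .design import EquationSpec, ModelSpec
from .model import (
    EPS_P,
    AdditiveProbit,
    RecursiveBivariateProbitResults,
    _fd_hessian,
    _npdf,
)

__all__ = ["ATEResult", "ate_sbp", "ate_ap", "ate_unadjusted", "tetrachoric"]


@dataclass
class ATEResult:
    """A treatment-effect estimate with its interval.

    ``estimate`` is on the probability-difference scale; ``display``
    multiplies by 100 for percentage-point reporting.
    """

    estimate: float
    ci_low: float
    ci_high: float
    se: float
    method: str  # one of {"SBP", "AP", "unadjusted"}
    scale: str = "probability difference"
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("interval must bracket the estimate")

    def display(self, factor: float = 100.0):
        """(estimate, lo, hi) scaled for reporting, e.g. percentage points."""
        return (
            factor * self.estimate,
            factor * self.ci_low,
            factor * self.ci_high,
        )


def _counterfactual_etas(results: RecursiveBivariateProbitResults):
    d = results.design
    n = d.n
    eta1, _ = d.linear_predictors(results.params)
    eta2_1 = d.linear_predictors(results.params, y1=np.ones(n))[1]
    eta2_0 = d.linear_predictors(results.params, y1=np.zeros(n))[1]
    return eta1, eta2_1, eta2_0


def ate_sbp(results: RecursiveBivariateProbitResults, level: float = 0.95) -> ATEResult:
    """Average treatment effect from the recursive bivariate probit fit.

    Primary estimate: the conditional-probability contrast averaged over
    subjects; ``extra`` carries the potential-outcome average
    (``"potential_outcome"``) with its own delta-method interval.
    """
    d = results.design
    if not d.has_gamma:
        raise ValueError("ate_sbp requires a recursive fit (treatment in equation 2)")
    n = d.n
    rho = results.rho
    a, b, c = _counterfactual_etas(results)

    P1 = ndtr(a)
    floor_hit = (P1 < EPS_P) | (P1 > 1.0 - EPS_P)
    if np.any(floor_hit):
        import warnings

        warnings.warn(
            f"{int(floor_hit.sum())} treatment propensities were numerically 0 or 1; "
            "floored for the conditional contrast",
            stacklevel=2,
        )
        P1 = np.clip(P1, EPS_P, 1.0 - EPS_P)
    Q1 = 1.0 - P1

    num1 = bvn_cdf(b, a, rho)
    num2 = bvn_cdf(c, -a, -rho)
    t1 = num1 / P1
    t2 = num2 / Q1
    estimate = float(np.mean(t1 - t2))

    # delta-method gradient through (a, b, c, rho)
    s = np.sqrt(max(1.0 - rho * rho, 1e-16))
    phi_a = _npdf(a)
    dT1_db = _npdf(b) * ndtr((a - rho * b) / s) / P1
    dT1_da = phi_a * ndtr((b - rho * a) / s) / P1 - num1 * phi_a / P1**2
    dT1_dr = bvn_pdf(b, a, rho) / P1
    dT2_dc = _npdf(c) * ndtr((rho * c - a) / s) / Q1
    dT2_da = -phi_a * ndtr((c - rho * a) / s) / Q1 + num2 * phi_a / Q1**2
    dT2_dr = -bvn_pdf(c, -a, -rho) / Q1

    u_a = (dT1_da - dT2_da) / n
    u_b = dT1_db / n
    u_c = -dT2_dc / n

    grad = np.zeros(d.n_params)
    grad[d.sl_delta1] = d.eq1.X.T @ u_a
    if d.eq1.n_beta:
        grad[d.sl_beta1] = d.eq1.B.T @ u_a
    grad[d.idx_gamma] = float(u_b.sum())
    grad[d.sl_delta2] = d.eq2.X.T @ (u_b + u_c)
    if d.eq2.n_beta:
        grad[d.sl_beta2] = d.eq2.B.T @ (u_b + u_c)
    if d.free_rho:
        grad[d.idx_rho] = float(np.sum(dT1_dr - dT2_dr)) / n * (1.0 - rho * rho)

    se = float(np.sqrt(max(grad @ results.V_theta @ grad, 0.0)))
    q = norm.ppf(0.5 + level / 2.0)

    # potential-outcome average and its interval
    po = float(np.mean(ndtr(b) - ndtr(c)))
    grad_po = np.zeros(d.n_params)
    v_b = _npdf(b) / n
    v_c = -_npdf(c) / n
    grad_po[d.idx_gamma] = float(v_b.sum())
    grad_po[d.sl_delta2] = d.eq2.X.T @ (v_b + v_c)
    if d.eq2.n_beta:
        grad_po[d.sl_beta2] = d.eq2.B.T @ (v_b + v_c)
    se_po = float(np.sqrt(max(grad_po @ results.V_theta @ grad_po, 0.0)))

    return ATEResult(
        estimate=estimate,
        ci_low=estimate - q * se,
        ci_high=estimate + q * se,
        se=se,
        method="SBP",
        extra={
            "potential_outcome": po,
            "potential_outcome_ci": (po - q * se_po, po + q * se_po),
            "potential_outcome_se": se_po,
            "gradient": grad,
            "potential_outcome_gradient": grad_po,
        },
    )


def ate_ap(data, spec: ModelSpec, level: float = 0.95, **fit_kwargs) -> ATEResult:
    """Additive-probit ATE: outcome on treatment plus equation-2 terms.

    Adjusts for the observed outcome-equation covariates (including any
    smooths) but not for unobserved confounding.
    """
    eq = EquationSpec(
        parametric=(spec.treatment,) + tuple(spec.eq2.parametric),
        smooths=spec.eq2.smooths,
        intercept=spec.eq2.intercept,
    )
    ap = AdditiveProbit(data, spec.outcome, eq)
    res = ap.fit(**fit_kwargs)

    n = ap.n
    treat_idx = 1 if spec.eq2.intercept else 0  # treatment column position in X
    X1 = ap.eq.X.copy()
    X1[:, treat_idx] = 1.0
    X0 = ap.eq.X.copy()
    X0[:, treat_idx] = 0.0
    eta1 = ap.linear_predictor(res.params, X=X1)
    eta0 = ap.linear_predictor(res.params, X=X0)
    estimate = float(np.mean(ndtr(eta1) - ndtr(eta0)))

    u1 = _npdf(eta1) / n
    u0 = _npdf(eta0) / n
    grad = np.zeros(ap.n_params)
    grad[ap.sl_delta] = X1.T @ u1 - X0.T @ u0
    if ap.eq.n_beta:
        grad[ap.sl_beta] = ap.eq.B.T @ (u1 - u0)
    se = float(np.sqrt(max(grad @ res.V_theta @ grad, 0.0)))
    q = norm.ppf(0.5 + level / 2.0)
    return ATEResult(
        estimate=estimate,
        ci_low=estimate - q * se,
        ci_high=estimate + q * se,
        se=se,
        method="AP",
        extra={"fit": res},
    )


def ate_unadjusted(y1, y2, level: float = 0.95) -> ATEResult:
    """Raw risk difference mean(y2 | y1=1) - mean(y2 | y1=0), Wald interval."""
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    n1 = int((y1 == 1).sum())
    n0 = int((y1 == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both treatment groups must be nonempty")
    p1 = float(y2[y1 == 1].mean())
    p0 = float(y2[y1 == 0].mean())
    estimate = p1 - p0
    se = float(np.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0))
    q = norm.ppf(0.5 + level / 2.0)
    return ATEResult(
        estimate=estimate,
        ci_low=estimate - q * se,
        ci_high=estimate + q * se,
        se=se,
        method="unadjusted",
    )


def tetrachoric(table_2x2, level: float = 0.95):
    """Tetrachoric correlation of a 2x2 table, by maximum likelihood.

    The table counts n[i, j] = #(y1 = i, y2 = j) for i, j in {0, 1} are
    modeled as dichotomized bivariate normal; the thresholds are the
    normal quantiles of the margins (their ML estimates) and rho solves
    the moment condition Phi2(h, k; rho) = p11.  Returns
    ``(rho_hat, (ci_low, ci_high))``; the interval comes from the
    observed information of the three-parameter multinomial likelihood,
    delta-method-transformed from the arctanh scale.
    """
    tab = np.asarray(table_2x2, dtype=float)
    if tab.shape != (2, 2) or np.any(tab < 0):
        raise ValueError("table_2x2 must be a 2x2 array of nonnegative counts")
    n = tab.sum()
    row1 = tab[1].sum()  # y1 = 1 margin
    col1 = tab[:, 1].sum()  # y2 = 1 margin
    if row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        raise ValueError("tetrachoric correlation undefined: a margin is zero")
    p1 = row1 / n
    p2 = col1 / n
    h = ndtri(p1)  # P(y1=1) = Phi(h)
    k = ndtri(p2)
    p11_obs = tab[1, 1] / n

    def moment(r):
        return bvn_cdf(h, k, r) - p11_obs

    lo, hi = -1.0 + 1e-10, 1.0 - 1e-10
    f_lo, f_hi = moment(lo), moment(hi)
    if f_lo >= 0:
        rho_hat = -1.0 + 1e-10
    elif f_hi <= 0:
        rho_hat = 1.0 - 1e-10
    else:
        rho_hat = brentq(moment, lo, hi, xtol=1e-12)

    # observed information of (h, k, z) at the ML point
    def nll(par):
        hh, kk, zz = par
        r = np.tanh(zz)
        q11 = bvn_cdf(hh, kk, r)
        P1, P2 = ndtr(hh), ndtr(kk)
        cells = np.clip(
            np.array(
                [1.0 - P1 - P2 + q11, P2 - q11, P1 - q11, q11]
            ),  # (00, 01, 10, 11)
            EPS_P,
            1.0,
        )
        counts = np.array([tab[0, 0], tab[0, 1], tab[1, 0], tab[1, 1]])
        return -float(counts @ np.log(cells))

    z_hat = float(np.arctanh(np.clip(rho_hat, -1 + 1e-12, 1 - 1e-12)))
    x0 = np.array([h, k, z_hat])

    def grad(par):
        eps = 1e-6
        g = np.zeros(3)
        for j in range(3):
            e = np.zeros(3)
            e[j] = eps * (1.0 + abs(par[j]))
            g[j] = (nll(par + e) - nll(par - e)) / (2 * e[j])
        return g

    H = _fd_hessian(grad, x0, rel_step=1e-4)
    try:
        cov = np.linalg.inv(H)
        var_z = max(float(cov[2, 2]), 0.0)
    except np.linalg.LinAlgError:
        var_z = np.inf
    q = norm.ppf(0.5 + level / 2.0)
    se_z = np.sqrt(var_z)
    ci = (float(np.tanh(z_hat - q * se_z)), float(np.tanh(z_hat + q * se_z)))
    return float(rho_hat), ci
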