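"""Recursive bivariate probit with penalized regression-spline smooths.

Model: two latent-Gaussian equations

    y1* = x1' delta1 + sum_k s_1k(x1k) + e1        (treatment)
    y2* = gamma y1 + x2' delta2 + sum_k s_2k(x2k) + e2   (outcome)

with y_v = 1{y_v* > 0} and (e1, e2) standard bivariate normal with
correlation rho.  The observed treatment y1 appears on the right of the
outcome equation; rho carries the correlation of the unobserved
confounders shared by the two equations.  Smooth terms are penalized
cubic regression splines; the penalized log-likelihood

    lp(theta) = l(theta) - (1/2) beta' S_lambda beta

is maximized by a quasi-Newton inner loop with Newton polishing, and the
smoothing parameters lambda are chosen by minimizing a deviance-based
approximate unbiased risk estimator (UBRE) over the converged inner
fits.  Interval inference uses the Bayesian posterior approximation
theta | y ~ N(theta_hat, V_theta) with V_theta the inverse penalized
observed information at convergence.
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from .bvn import bvn_cdf, bvn_pdf
from .design import ModelDesign, ModelSpec, ThetaVector

__all__ = [
    "RecursiveBivariateProbit",
    "RecursiveBivariateProbitResults",
    "FitOptions",
    "JointProbabilities",
    "EPS_P",
]

# floor applied to the four cell probabilities before taking logs;
# binds only at pathological linear predictors
EPS_P = 1e-10

JointProbabilities = namedtuple("JointProbabilities", ["p11", "p10", "p01", "p00"])

_SQRT_TWOPI = np.sqrt(2.0 * np.pi)


def _npdf(x):
    return np.exp(-0.5 * x * x) / _SQRT_TWOPI


def _fd_hessian(grad_fn, theta, rel_step=1e-5):
    """Central finite differences of an exact gradient, symmetrized."""
    theta = np.asarray(theta, dtype=float)
    p = theta.size
    H = np.empty((p, p))
    for j in range(p):
        h = rel_step * (1.0 + abs(theta[j]))
        tp = theta.copy()
        tp[j] += h
        tm = theta.copy()
        tm[j] -= h
        H[:, j] = (grad_fn(tp) - grad_fn(tm)) / (2.0 * h)
    return (H + H.T) / 2.0


def _newton_direction(H_pen, g):
    """Ascent direction from a (possibly indefinite) penalized Hessian."""
    p = g.size
    ridge = 0.0
    for _ in range(8):
        try:
            step = np.linalg.solve(-(H_pen - ridge * np.eye(p)), g)
        except np.linalg.LinAlgError:
            step = None
        if step is not None and step @ g > 0:
            return step
        ridge = 10.0 * ridge if ridge else 1e-4 * (1.0 + np.abs(np.diag(H_pen)).max())
    return g.copy()


def _maximize_inner(vs_fn, theta0, S, opts, H_ll0=None):
    """Newton ascent of a penalized objective at fixed penalty, with step-halving.

    ``vs_fn(theta)`` returns (penalized value, penalized gradient).  The
    expensive part of the Hessian (the unpenalized block H_ll) is re-used
    across steps and across smoothing-parameter candidates: only the
    analytic penalty part -S changes with lambda.  H_ll is refreshed by
    finite differences of the exact gradient whenever stale steps stop
    making progress, and once more at convergence so the returned
    penalized Hessian is exact at theta_hat.

    Returns (theta, H_pen, f, converged, trace, H_ll); trace holds the
    accepted penalized objective values (non-decreasing).
    """
    theta = np.asarray(theta0, dtype=float).copy()
    f, g = vs_fn(theta)
    trace = [f]
    grad_fn = lambda th: vs_fn(th)[1]

    def _converged(f, g):
        return np.max(np.abs(g)) <= opts.inner_tol * (1.0 + abs(f))

    H_ll = None if H_ll0 is None else np.asarray(H_ll0, dtype=float)
    if H_ll is None:
        # cold start: a few gradient-ascent steps tame bad initials cheaply
        for _ in range(3):
            if _converged(f, g):
                break
            t = 1.0 / (1.0 + np.linalg.norm(g))
            accepted = False
            for _half in range(opts.max_step_halvings):
                cand = theta + t * g
                fc, gc = vs_fn(cand)
                if np.isfinite(fc) and fc > f:
                    accepted = True
                    break
                t /= 2.0
            if not accepted:
                break
            theta, f, g = cand, fc, gc
            trace.append(f)
        H_ll = _fd_hessian(grad_fn, theta) + S

    converged = False
    fresh_at = None  # theta at which H_ll was last refreshed
    for _ in range(opts.max_inner_iter):
        if _converged(f, g):
            converged = True
            break
        step = _newton_direction(H_ll - S, g)
        t = 1.0
        accepted = False
        for _half in range(opts.max_step_halvings):
            cand = theta + t * step
            fc, gc = vs_fn(cand)
            if np.isfinite(fc) and fc >= f:
                accepted = True
                break
            t /= 2.0
        made_progress = accepted and (fc > f or np.max(np.abs(gc)) < np.max(np.abs(g)))
        if accepted:
            theta, f, g = cand, fc, gc
            trace.append(f)
        if not made_progress or (accepted and t < 1.0):
            # stale Hessian is limiting: refresh at the current point
            if fresh_at is not None and np.array_equal(fresh_at, theta):
                break  # fresh Hessian and still stuck
            H_ll = _fd_hessian(grad_fn, theta) + S
            fresh_at = theta.copy()

    if fresh_at is None or not np.array_equal(fresh_at, theta):
        H_ll = _fd_hessian(grad_fn, theta) + S
    converged = converged or _converged(f, g)
    return theta, H_ll - S, f, converged, trace, H_ll


def _lambda_search(ubre_at, n_smooth, opts):
    """Cycled grid plus golden-section search of the UBRE surface.

    ``ubre_at(lams)`` returns the criterion value at converged inner fits
    (cached by the caller).  Returns the selected smoothing parameters.
    """
    lams = np.ones(n_smooth)
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    grid = opts.lambda_grid
    for _cycle in range(opts.max_outer_iter):
        prev = lams.copy()
        for k in range(n_smooth):
            best = None
            for cand in grid:
                lt = lams.copy()
                lt[k] = cand
                crit = ubre_at(lt)
                if best is None or crit < best[0]:
                    best = (crit, cand)
            i = int(np.argmin(np.abs(np.log10(grid) - np.log10(best[1]))))
            a = np.log10(grid[max(i - 1, 0)])
            b = np.log10(grid[min(i + 1, grid.size - 1)])
            c1 = b - gr * (b - a)
            c2 = a + gr * (b - a)
            lt = lams.copy()
            lt[k] = 10.0**c1
            f1 = ubre_at(lt)
            lt[k] = 10.0**c2
            f2 = ubre_at(lt)
            for _ in range(opts.golden_iter):
                if f1 <= f2:
                    b, c2, f2 = c2, c1, f1
                    c1 = b - gr * (b - a)
                    lt = lams.copy()
                    lt[k] = 10.0**c1
                    f1 = ubre_at(lt)
                else:
                    a, c1, f1 = c1, c2, f2
                    c2 = a + gr * (b - a)
                    lt = lams.copy()
                    lt[k] = 10.0**c2
                    f2 = ubre_at(lt)
            cand_set = [(f1, c1), (f2, c2), (best[0], np.log10(best[1]))]
            _, log_best = min(cand_set, key=lambda t: t[0])
            lams[k] = 10.0**log_best
        if np.max(np.abs(np.log10(lams) - np.log10(prev))) < 0.05:
            break
    return lams


def joint_probs(eta1, eta2, rho) -> JointProbabilities:
    """Cell probabilities of the four (y1, y2) outcomes, floored and renormalized."""
    eta1 = np.asarray(eta1, dtype=float)
    eta2 = np.asarray(eta2, dtype=float)
    p11 = bvn_cdf(eta1, eta2, rho)
    P1 = ndtr(eta1)
    P2 = ndtr(eta2)
    p10 = P1 - p11
    p01 = P2 - p11
    p00 = 1.0 - P1 - P2 + p11
    cells = [np.clip(p, EPS_P, 1.0) for p in (p11, p10, p01, p00)]
    total = cells[0] + cells[1] + cells[2] + cells[3]
    return JointProbabilities(*(p / total for p in cells))


@dataclass
class FitOptions:
    """Tuning knobs of the nested fitting scheme.

    ``inner_tol`` is the relative gradient infinity-norm tolerance of
    the inner penalized maximization; ``lambda_grid`` holds the coarse
    log-spaced candidates searched per smoothing parameter before a
    golden-section refinement; ``fix_rho_at`` constrains the error
    correlation (e.g. 0 for the no-endogeneity fit).
    """

    max_outer_iter: int = 3
    max_inner_iter: int = 200
    bfgs_iter: int = 40  # quasi-Newton burn-in before Newton polishing
    inner_tol: float = 1e-6
    lambda_grid: np.ndarray = field(default_factory=lambda: np.logspace(-4.0, 8.0, 7))
    golden_iter: int = 8
    max_step_halvings: int = 30
    seed: int = 0
    fix_rho_at: float = None
    lambdas: np.ndarray = None  # fixed smoothing parameters; skips UBRE selection

    def __post_init__(self):
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        if self.inner_tol <= 0:
            raise ValueError("inner_tol must be positive")
        if self.lambda_grid.size == 0:
            raise ValueError("lambda_grid must be nonempty")


class RecursiveBivariateProbit:
    """Recursive (endogenous-treatment) bivariate probit model.

    Parameters
    ----------
    data : DataFrame
        One row per subject, containing the binary treatment and outcome
        columns plus all covariates named in ``spec``.
    spec : ModelSpec
        Per-equation parametric and smooth terms.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        self.data = data
        self.spec = spec
        self.design = ModelDesign(data, spec)
        self._rho_fixed = None

    @classmethod
    def from_dataframe(cls, data, treatment, outcome, eq1, eq2, include_treatment_in_eq2=True):
        spec = ModelSpec(
            treatment=treatment,
            outcome=outcome,
            eq1=eq1,
            eq2=eq2,
            include_treatment_in_eq2=include_treatment_in_eq2,
        )
        return cls(data, spec)

    # ------------------------------------------------------------------
    # likelihood machinery
    # ------------------------------------------------------------------
    def _rho_of(self, tv: ThetaVector):
        if self.design.free_rho:
            return np.tanh(tv.rho_z)
        return self._rho_fixed if self._rho_fixed is not None else 0.0

    def joint_probabilities(self, theta) -> JointProbabilities:
        tv = self.design.unpack(theta)
        eta1, eta2 = self.design.linear_predictors(theta)
        return joint_probs(eta1, eta2, self._rho_of(tv))

    def loglike(self, theta) -> float:
        """Joint log-likelihood over the four outcome cells."""
        d = self.design
        p = self.joint_probabilities(theta)
        y1, y2 = d.y1, d.y2
        ll = (
            y1 * y2 * np.log(p.p11)
            + y1 * (1 - y2) * np.log(p.p10)
            + (1 - y1) * y2 * np.log(p.p01)
            + (1 - y1) * (1 - y2) * np.log(p.p00)
        )
        return float(ll.sum())

    def _value_and_score(self, theta):
        """Unpenalized log-likelihood and its exact gradient."""
        d = self.design
        tv = d.unpack(theta)
        rho = self._rho_of(tv)
        eta1, eta2 = d.linear_predictors(theta)
        y1, y2 = d.y1, d.y2

        p11 = bvn_cdf(eta1, eta2, rho)
        P1 = ndtr(eta1)
        P2 = ndtr(eta2)
        p10 = np.clip(P1 - p11, EPS_P, 1.0)
        p01 = np.clip(P2 - p11, EPS_P, 1.0)
        p00 = np.clip(1.0 - P1 - P2 + p11, EPS_P, 1.0)
        p11 = np.clip(p11, EPS_P, 1.0)

        ll = (
            y1 * y2 * np.log(p11)
            + y1 * (1 - y2) * np.log(p10)
            + (1 - y1) * y2 * np.log(p01)
            + (1 - y1) * (1 - y2) * np.log(p00)
        ).sum()

        s = np.sqrt(max(1.0 - rho * rho, 1e-16))
        phi1 = _npdf(eta1)
        phi2 = _npdf(eta2)
        g1 = phi1 * ndtr((eta2 - rho * eta1) / s)  # d p11 / d eta1
        g2 = phi2 * ndtr((eta1 - rho * eta2) / s)  # d p11 / d eta2
        d2 = bvn_pdf(eta1, eta2, rho)  # d p11 / d rho

        c11 = y1 * y2 / p11
        c10 = y1 * (1 - y2) / p10
        c01 = (1 - y1) * y2 / p01
        c00 = (1 - y1) * (1 - y2) / p00

        u1 = c11 * g1 + c10 * (phi1 - g1) - c01 * g1 + c00 * (g1 - phi1)
        u2 = c11 * g2 - c10 * g2 + c01 * (phi2 - g2) + c00 * (g2 - phi2)
        ur = d2 * (c11 - c10 - c01 + c00)

        grad = np.empty(d.n_params)
        grad[d.sl_delta1] = d.eq1.X.T @ u1
        if d.eq1.n_beta:
            grad[d.sl_beta1] = d.eq1.B.T @ u1
        if d.has_gamma:
            grad[d.idx_gamma] = float(u2 @ y1)
        grad[d.sl_delta2] = d.eq2.X.T @ u2
        if d.eq2.n_beta:
            grad[d.sl_beta2] = d.eq2.B.T @ u2
        if d.free_rho:
            grad[d.idx_rho] = float(ur.sum()) * (1.0 - rho * rho)
        return float(ll), grad

    def score(self, theta) -> np.ndarray:
        """Exact gradient of the (unpenalized) log-likelihood in packed theta."""
        return self._value_and_score(theta)[1]

    def penalized_loglike(self, theta, lambdas) -> float:
        S = self.design.penalty_matrix(lambdas)
        theta = np.asarray(theta, dtype=float)
        return self.loglike(theta) - 0.5 * float(theta @ S @ theta)

    def penalized_score(self, theta, lambdas) -> np.ndarray:
        S = self.design.penalty_matrix(lambdas)
        theta = np.asarray(theta, dtype=float)
        return self.score(theta) - S @ theta

    # soft barrier keeping the optimizer off the rho = +-1 boundary; inert
    # for |rho_z| <= 8 (|rho| <= 0.99999977), i.e. for any interior optimum
    _Z_BARRIER = 8.0
    _Z_BARRIER_W = 10.0

    def _penalized_value_and_score(self, theta, S):
        """Internal optimizer objective: lp(theta) plus the rho_z barrier."""
        ll, g = self._value_and_score(theta)
        f = ll - 0.5 * float(theta @ S @ theta)
        g = g - S @ theta
        if self.design.free_rho:
            z = theta[self.design.idx_rho]
            excess = abs(z) - self._Z_BARRIER
            if excess > 0:
                f -= 0.5 * self._Z_BARRIER_W * excess**2
                g[self.design.idx_rho] -= self._Z_BARRIER_W * excess * np.sign(z)
        return f, g

    # ------------------------------------------------------------------
    # starting values
    # ------------------------------------------------------------------
    def initialize(self) -> np.ndarray:
        """Starting theta from two separately fitted univariate probits."""
        import statsmodels.api as sm

        d = self.design
        theta = np.zeros(d.n_params)

        def _probit_start(y, X, ridge_msg):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.Probit(y, X).fit(disp=0, maxiter=200)
                    coefs = np.asarray(res.params, dtype=float)
                if not np.all(np.isfinite(coefs)) or np.abs(coefs).max() > 1e3:
                    raise ValueError("diverged")
                return coefs
            except Exception:
                warnings.warn(
                    f"{ridge_msg}: separation or divergence in the starting probit; "
                    "using a ridge-stabilized start",
                    stacklevel=2,
                )
                # one ridge-stabilized Fisher-scoring step from eta = 0
                XtX = X.T @ X + 1e-2 * len(y) * np.eye(X.shape[1])
                coefs = np.linalg.solve(XtX, X.T @ ((y - 0.5) / norm.pdf(0.0)))
                p_bar = np.clip(y.mean(), 1e-3, 1 - 1e-3)
                coefs[0] = ndtri(p_bar)
                return coefs

        X1 = np.column_stack([d.eq1.X, d.eq1.B]) if d.eq1.n_beta else d.eq1.X
        c1 = _probit_start(d.y1, X1, "equation 1")
        theta[d.sl_delta1] = c1[: d.eq1.n_par]
        if d.eq1.n_beta:
            theta[d.sl_beta1] = c1[d.eq1.n_par :]

        cols2 = [d.eq2.X]
        if d.eq2.n_beta:
            cols2.append(d.eq2.B)
        if d.has_gamma:
            cols2.append(d.y1[:, None])
        X2 = np.column_stack(cols2)
        c2 = _probit_start(d.y2, X2, "equation 2")
        theta[d.sl_delta2] = c2[: d.eq2.n_par]
        if d.eq2.n_beta:
            theta[d.sl_beta2] = c2[d.eq2.n_par : d.eq2.n_par + d.eq2.n_beta]
        if d.has_gamma:
            theta[d.idx_gamma] = c2[-1]
        if d.free_rho:
            theta[d.idx_rho] = 0.0
        return theta

    # ------------------------------------------------------------------
    # optimization
    # ------------------------------------------------------------------
    def _fd_hessian(self, theta, S, rel_step=1e-5):
        """Central finite differences of the exact penalized gradient."""
        return _fd_hessian(lambda th: self._penalized_value_and_score(th, S)[1], theta, rel_step)

    def _inner_maximize(self, theta0, S, opts: FitOptions, H_ll0=None):
        return _maximize_inner(
            lambda th: self._penalized_value_and_score(th, S), theta0, S, opts, H_ll0
        )

    def _edf(self, H_pen, S):
        """Total and per-smooth effective degrees of freedom.

        F = V_theta I_unpen with I_unpen = -H_pen - S; per-smooth edf is
        the trace of F restricted to that smooth's coefficients.
        """
        d = self.design
        I_pen = -H_pen
        try:
            V = np.linalg.inv(I_pen)
        except np.linalg.LinAlgError:
            # flat directions (e.g. rho_z drifting) at a candidate lambda
            V = np.linalg.pinv(I_pen, hermitian=True)
        F = np.eye(d.n_params) - V @ S
        edf_total = float(np.trace(F))
        per_smooth = [float(np.trace(F[gsl, gsl])) for _, _, gsl in d.smooth_slices]
        return edf_total, per_smooth, V

    def _ubre(self, theta_hat, H_pen, S):
        """Deviance-based approximate unbiased risk estimator at a converged fit."""
        n = self.design.n
        dev = -2.0 * self.loglike(theta_hat)
        edf_total = self._edf(H_pen, S)[0]
        return dev / n - 1.0 + 2.0 * edf_total / n

    def fit(self, **kwargs) -> "RecursiveBivariateProbitResults":
        """Penalized maximum likelihood fit with UBRE smoothing selection.

        Keyword arguments are the fields of :class:`FitOptions`.
        """
        opts = kwargs.pop("options", None) or FitOptions(**kwargs)
        d = self.design
        self._rho_fixed = opts.fix_rho_at
        d._layout(fix_rho=opts.fix_rho_at is not None)
        n_smooth = len(d.smooth_slices)

        theta = self.initialize()
        warm = {"H_ll": None}

        def _fit_at(lams, theta_start):
            S = d.penalty_matrix(lams)
            th, H, f, conv, trace, H_ll = self._inner_maximize(
                theta_start, S, opts, H_ll0=warm["H_ll"]
            )
            warm["H_ll"] = H_ll
            return th, H, f, conv, trace, S

        if n_smooth == 0 or opts.lambdas is not None:
            lams = (
                np.asarray(opts.lambdas, dtype=float)
                if opts.lambdas is not None
                else np.zeros(0)
            )
            theta, H, f, conv, trace, S = _fit_at(lams, theta)
        else:
            cache = {}
            state = {"theta": theta}

            def _ubre_at(lams_try):
                key = tuple(np.round(np.log10(np.maximum(lams_try, 1e-300)), 10))
                if key not in cache:
                    th, H, f, conv, trace, S = _fit_at(lams_try, state["theta"])
                    crit = self._ubre(th, H, S)
                    cache[key] = (crit, th, H, f, conv, trace, S)
                    state["theta"] = th
                return cache[key]

            lams = _lambda_search(lambda lt: _ubre_at(lt)[0], n_smooth, opts)
            crit, theta, H, f, conv, trace, S = _ubre_at(lams)

        edf_total, edf_smooth, V = self._edf(H, S)
        V = (V + V.T) / 2.0
        ev, U = np.linalg.eigh(V)
        if ev.min() < 0:
            warnings.warn(
                "posterior covariance had negative eigenvalues "
                f"(min {ev.min():.2e}); clipped at zero",
                stacklevel=2,
            )
            V = U @ np.diag(np.clip(ev, 0.0, None)) @ U.T
        if not conv:
            warnings.warn("inner maximization did not reach the gradient tolerance", stacklevel=2)
        return RecursiveBivariateProbitResults(
            model=self,
            params=theta,
            V_theta=V,
            lambdas=np.asarray(lams, dtype=float),
            edf_smooth=dict(zip(d.smooth_labels, edf_smooth)),
            edf_total=edf_total,
            loglik=self.loglike(theta),
            penalized_loglik=f,
            converged=bool(conv),
            trace=np.asarray(trace),
            options=opts,
        )

    def posterior_covariance(self, theta, lambdas) -> np.ndarray:
        """Inverse penalized observed information at theta (symmetrized, PSD-clipped)."""
        S = self.design.penalty_matrix(lambdas)
        H = self._fd_hessian(np.asarray(theta, dtype=float), S)
        I_pen = -(H + H.T) / 2.0
        try:
            V = np.linalg.inv(I_pen)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "singular penalized information; consider a stronger penalty or a "
                "simpler specification"
            ) from err
        V = (V + V.T) / 2.0
        ev, U = np.linalg.eigh(V)
        if ev.min() < 0:
            warnings.warn("posterior covariance clipped to PSD", stacklevel=2)
            V = U @ np.diag(np.clip(ev, 0.0, None)) @ U.T
        return V


class AdditiveProbit:
    """Univariate probit with penalized spline smooths.

    The single-equation analogue of the bivariate model: same spline
    bases, same UBRE smoothing selection, same Bayesian posterior
    covariance — but no second equation, so unobserved confounders
    correlated with the regressors are not accounted for.
    """

    def __init__(self, data: pd.DataFrame, outcome: str, eq):
        from .design import EquationSpec, _build_equation, _check_binary

        if not isinstance(eq, EquationSpec):
            raise TypeError("eq must be an EquationSpec")
        self.data = data
        self.outcome = outcome
        self.y = np.asarray(data[outcome], dtype=float)
        _check_binary(self.y, outcome)
        self.eq = _build_equation(data, eq, "equation")
        self.n = len(data)
        self.n_params = self.eq.n_par + self.eq.n_beta
        self.sl_delta = slice(0, self.eq.n_par)
        self.sl_beta = slice(self.eq.n_par, self.n_params)
        self.smooth_slices = [
            (basis, slice(self.eq.n_par + sl.start, self.eq.n_par + sl.stop))
            for basis, sl in zip(self.eq.bases, self.eq.beta_slices)
        ]

    def linear_predictor(self, theta, X=None, B=None):
        X = self.eq.X if X is None else X
        B = self.eq.B if B is None else B
        eta = X @ theta[self.sl_delta]
        if self.eq.n_beta:
            eta = eta + B @ theta[self.sl_beta]
        return eta

    def penalty_matrix(self, lambdas):
        lambdas = np.asarray(lambdas, dtype=float)
        if np.any(lambdas < 0):
            raise ValueError("smoothing parameters must be nonnegative")
        S = np.zeros((self.n_params, self.n_params))
        for lam, (basis, gsl) in zip(lambdas, self.smooth_slices):
            S[gsl, gsl] += lam * basis.penalty / np.linalg.norm(basis.penalty)
        return S

    def _value_and_score(self, theta):
        eta = self.linear_predictor(theta)
        P = np.clip(ndtr(eta), EPS_P, 1.0 - EPS_P)
        y = self.y
        ll = float((y * np.log(P) + (1.0 - y) * np.log(1.0 - P)).sum())
        u = _npdf(eta) * (y / P - (1.0 - y) / (1.0 - P))
        grad = np.empty(self.n_params)
        grad[self.sl_delta] = self.eq.X.T @ u
        if self.eq.n_beta:
            grad[self.sl_beta] = self.eq.B.T @ u
        return ll, grad

    def fit(self, **kwargs):
        opts = kwargs.pop("options", None) or FitOptions(**kwargs)
        import statsmodels.api as sm

        Xfull = (
            np.column_stack([self.eq.X, self.eq.B]) if self.eq.n_beta else self.eq.X
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                theta = np.asarray(
                    sm.Probit(self.y, Xfull).fit(disp=0, maxiter=200).params, dtype=float
                )
            if not np.all(np.isfinite(theta)) or np.abs(theta).max() > 1e3:
                raise ValueError("diverged")
        except Exception:
            theta = np.zeros(self.n_params)
            theta[0] = ndtri(np.clip(self.y.mean(), 1e-3, 1 - 1e-3))

        n_smooth = len(self.smooth_slices)

        def _vs(S):
            def vs(th):
                ll, g = self._value_and_score(th)
                return ll - 0.5 * float(th @ S @ th), g - S @ th

            return vs

        warm = {"H_ll": None}

        def _fit_at(lams, theta_start):
            S = self.penalty_matrix(lams)
            vs = _vs(S)
            th, H, f, conv, trace, H_ll = _maximize_inner(
                vs, theta_start, S, opts, H_ll0=warm["H_ll"]
            )
            warm["H_ll"] = H_ll
            return th, H, f, conv, trace, S

        if n_smooth == 0 or opts.lambdas is not None:
            lams = (
                np.asarray(opts.lambdas, dtype=float)
                if opts.lambdas is not None
                else np.zeros(0)
            )
            theta, H, f, conv, trace, S = _fit_at(lams, theta)
        else:
            cache = {}
            state = {"theta": theta}

            def _ubre_at(lams_try):
                key = tuple(np.round(np.log10(np.maximum(lams_try, 1e-300)), 10))
                if key not in cache:
                    th, H, f, conv, trace, S = _fit_at(lams_try, state["theta"])
                    try:
                        V = np.linalg.inv(-H)
                    except np.linalg.LinAlgError:
                        V = np.linalg.pinv(-H, hermitian=True)
                    edf_total = float(np.trace(np.eye(self.n_params) - V @ S))
                    ll = self._value_and_score(th)[0]
                    crit = -2.0 * ll / self.n - 1.0 + 2.0 * edf_total / self.n
                    cache[key] = (crit, th, H, f, conv, trace, S)
                    state["theta"] = th
                return cache[key]

            lams = _lambda_search(lambda lt: _ubre_at(lt)[0], n_smooth, opts)
            crit, theta, H, f, conv, trace, S = _ubre_at(lams)

        I_pen = -H
        try:
            V = np.linalg.inv(I_pen)
        except np.linalg.LinAlgError:
            V = np.linalg.pinv(I_pen, hermitian=True)
        V = (V + V.T) / 2.0
        ev, U = np.linalg.eigh(V)
        if ev.min() < 0:
            V = U @ np.diag(np.clip(ev, 0.0, None)) @ U.T
        F = np.eye(self.n_params) - V @ S
        edf_total = float(np.trace(F))
        return AdditiveProbitResults(
            model=self,
            params=theta,
            V_theta=V,
            lambdas=np.asarray(lams, dtype=float),
            edf_total=edf_total,
            edf_smooth={
                f"s({b.covariate_name})": float(np.trace(F[gsl, gsl]))
                for b, gsl in self.smooth_slices
            },
            loglik=self._value_and_score(theta)[0],
            converged=bool(conv),
        )


@dataclass
class AdditiveProbitResults:
    """Fit results of the univariate penalized probit."""

    model: AdditiveProbit
    params: np.ndarray
    V_theta: np.ndarray
    lambdas: np.ndarray
    edf_total: float
    edf_smooth: dict
    loglik: float
    converged: bool

    @property
    def bse(self):
        return np.sqrt(np.clip(np.diag(self.V_theta), 0.0, None))


class RecursiveBivariateProbitResults:
    """Fit results: estimates, posterior covariance, edf and report tables."""

    def __init__(
        self,
        model,
        params,
        V_theta,
        lambdas,
        edf_smooth,
        edf_total,
        loglik,
        penalized_loglik,
        converged,
        trace,
        options,
    ):
        self.model = model
        self.design = model.design
        self.params = np.asarray(params, dtype=float)
        self.V_theta = np.asarray(V_theta, dtype=float)
        self.lambdas = np.asarray(lambdas, dtype=float)
        self.edf_smooth = dict(edf_smooth)
        self.edf_total = float(edf_total)
        self.loglik = float(loglik)
        self.penalized_loglik = float(penalized_loglik)
        self.converged = bool(converged)
        self.trace = trace
        self.options = options
        self.n_obs = model.design.n
        self.rho_fixed = options.fix_rho_at

    # -- parameter views ------------------------------------------------
    @property
    def theta(self) -> ThetaVector:
        return self.design.unpack(self.params, rho_fixed=self.rho_fixed)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.V_theta), 0.0, None))

    @property
    def rho(self) -> float:
        if self.design.free_rho:
            return float(np.tanh(self.params[self.design.idx_rho]))
        return float(self.rho_fixed)

    def rho_ci(self, level=0.95):
        """Delta-method interval for rho, built on the arctanh scale."""
        if not self.design.free_rho:
            return (self.rho, self.rho)
        z = self.params[self.design.idx_rho]
        se_z = self.bse[self.design.idx_rho]
        q = norm.ppf(0.5 + level / 2.0)
        return (float(np.tanh(z - q * se_z)), float(np.tanh(z + q * se_z)))

    @property
    def rho_se(self) -> float:
        """Standard error of rho by the delta method through rho = tanh(z)."""
        if not self.design.free_rho:
            return 0.0
        se_z = self.bse[self.design.idx_rho]
        return float((1.0 - self.rho**2) * se_z)

    # -- report tables ---------------------------------------------------
    def _param_frame(self, eq: int) -> pd.DataFrame:
        d = self.design
        if eq == 1:
            names = list(d.eq1.names)
            sl = d.sl_delta1
            rows = [(nm, self.params[sl][i], self.bse[sl][i]) for i, nm in enumerate(names)]
        else:
            names = list(d.eq2.names)
            sl = d.sl_delta2
            rows = [(nm, self.params[sl][i], self.bse[sl][i]) for i, nm in enumerate(names)]
            if d.has_gamma:
                rows.insert(
                    1,
                    (
                        self.design.spec.treatment,
                        self.params[d.idx_gamma],
                        self.bse[d.idx_gamma],
                    ),
                )
        out = []
        for nm, est, se in rows:
            zval = est / se if se > 0 else np.inf * np.sign(est) if est else 0.0
            pval = 2.0 * norm.sf(abs(zval)) if np.isfinite(zval) else 0.0
            out.append((nm, est, se, pval))
        return pd.DataFrame(out, columns=["term", "Estimate", "Std. err.", "P val."])

    def params_table(self, eq: int) -> pd.DataFrame:
        """Parametric coefficient table for equation ``eq`` (1 or 2)."""
        if eq not in (1, 2):
            raise ValueError("eq must be 1 or 2")
        return self._param_frame(eq)

    def smooth_table(self) -> pd.DataFrame:
        """Per-smooth edf, estimated rank and Wald-type p-value."""
        rows = []
        for (eq_i, basis, gsl), label in zip(
            self.design.smooth_slices, self.design.smooth_labels
        ):
            beta = self.params[gsl]
            Vk = self.V_theta[gsl, gsl]
            ev, U = np.linalg.eigh((Vk + Vk.T) / 2.0)
            tol = 1e-7 * max(ev.max(), 0.0)
            keep = ev > tol
            rank = int(keep.sum())
            if rank:
                Vinv = (U[:, keep] / ev[keep]) @ U[:, keep].T
                stat = float(beta @ Vinv @ beta)
                pval = float(chi2_dist.sf(stat, rank))
            else:
                stat, pval = 0.0, 1.0
            rows.append((label, self.edf_smooth[label], rank, pval))
        return pd.DataFrame(rows, columns=["Smooth term", "Edf", "Est. rank", "P val."])

    def summary(self, level=0.95) -> str:
        """Human-readable fit report in the two-equation table layout."""
        lines = []
        lines.append("Recursive bivariate probit (penalized ML)")
        lines.append(f"n = {self.n_obs}   log-likelihood = {self.loglik:.4f}")
        lines.append(
            f"converged = {self.converged}   total edf = {self.edf_total:.3f}"
        )
        for eq, title in ((1, "Equation 1 (treatment)"), (2, "Equation 2 (outcome)")):
            lines.append("")
            lines.append(title)
            frame = self.params_table(eq)
            lines.append(
                frame.to_string(
                    index=False,
                    formatters={
                        "Estimate": "{:.4f}".format,
                        "Std. err.": "{:.4f}".format,
                        "P val.": "{:.4f}".format,
                    },
                )
            )
            st = self.smooth_table()
            st_eq = st[[lbl.startswith(f"s{eq}(") for lbl in st["Smooth term"]]]
            if len(st_eq):
                lines.append(
                    st_eq.to_string(
                        index=False,
                        formatters={
                            "Edf": "{:.3f}".format,
                            "P val.": "{:.4f}".format,
                        },
                    )
                )
        lines.append("")
        if self.design.free_rho:
            lo, hi = self.rho_ci(level)
            lines.append(f"rho {self.rho:.3f} ({lo:.4f}, {hi:.4f})")
        else:
            lines.append(f"rho fixed at {self.rho:.3f}")
        if self.lambdas.size:
            lam_txt = ", ".join(
                f"{lbl}: {lam:.4g} (edf {self.edf_smooth[lbl]:.3f})"
                for lbl, lam in zip(self.design.smooth_labels, self.lambdas)
            )
            lines.append(f"smoothing parameters: {lam_txt}")
        return "\n".join(lines)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        spec = self.design.spec
        return {
            "spec": {
                "treatment": spec.treatment,
                "outcome": spec.outcome,
                "eq1": {
                    "parametric": list(spec.eq1.parametric),
                    "smooths": [
                        {"name": s.name, "basis_dim": s.basis_dim, "knot_rule": s.knot_rule}
                        for s in spec.eq1.smooths
                    ],
                    "intercept": spec.eq1.intercept,
                },
                "eq2": {
                    "parametric": list(spec.eq2.parametric),
                    "smooths": [
                        {"name": s.name, "basis_dim": s.basis_dim, "knot_rule": s.knot_rule}
                        for s in spec.eq2.smooths
                    ],
                    "intercept": spec.eq2.intercept,
                },
                "include_treatment_in_eq2": spec.include_treatment_in_eq2,
            },
            "params": self.params.tolist(),
            "V_theta": self.V_theta.tolist(),
            "lambdas": self.lambdas.tolist(),
            "edf_smooth": self.edf_smooth,
            "edf_total": self.edf_total,
            "loglik": self.loglik,
            "penalized_loglik": self.penalized_loglik,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "fix_rho_at": self.rho_fixed,
            "knots": {
                lbl: (basis.knots.tolist())
                for (e, basis, _), lbl in zip(
                    self.design.smooth_slices, self.design.smooth_labels
                )
            },
        }

    @classmethod
    def from_dict(cls, payload: dict, data: pd.DataFrame) -> "RecursiveBivariateProbitResults":
        """Rebuild results from a serialized payload plus the original data."""
        from .design import EquationSpec, SmoothSpec

        sp = payload["spec"]

        def _eq(d):
            return EquationSpec(
                parametric=tuple(d["parametric"]),
                smooths=tuple(SmoothSpec(**s) for s in d["smooths"]),
                intercept=d["intercept"],
            )

        spec = ModelSpec(
            treatment=sp["treatment"],
            outcome=sp["outcome"],
            eq1=_eq(sp["eq1"]),
            eq2=_eq(sp["eq2"]),
            include_treatment_in_eq2=sp["include_treatment_in_eq2"],
        )
        model = RecursiveBivariateProbit(data, spec)
        opts = FitOptions(fix_rho_at=payload.get("fix_rho_at"))
        model._rho_fixed = opts.fix_rho_at
        model.design._layout(fix_rho=opts.fix_rho_at is not None)
        return cls(
            model=model,
            params=np.asarray(payload["params"], dtype=float),
            V_theta=np.asarray(payload["V_theta"], dtype=float),
            lambdas=np.asarray(payload["lambdas"], dtype=float),
            edf_smooth=payload["edf_smooth"],
            edf_total=payload["edf_total"],
            loglik=payload["loglik"],
            penalized_loglik=payload["penalized_loglik"],
            converged=payload["converged"],
            trace=None,
            options=opts,
        )
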