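"""Model specification and design-matrix assembly.

A :class:`ModelSpec` names, per equation, the binary treatment and
outcome columns, the parametric terms and the smooth terms.  From a
DataFrame it is turned into per-equation designs (parametric matrix plus
concatenated centered spline blocks) and a fixed packing of the joint
parameter vector

    theta = (delta1, beta1, gamma, delta2, beta2, rho_z)

where delta_v are the parametric coefficients of equation v (intercept
first), beta_v stack the spline coefficients of equation v smooth by
smooth, gamma is the coefficient of the endogenous treatment in the
outcome equation, and rho_z is the unconstrained error correlation on
the arctanh scale (rho = tanh(rho_z)).  gamma is absent for
non-recursive fits and rho_z is absent when the correlation is fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .splines import SmoothBasis, build_basis

__all__ = ["SmoothSpec", "EquationSpec", "ModelSpec", "ModelDesign", "ThetaVector"]


@dataclass(frozen=True)
class SmoothSpec:
    """Request for one spline smooth: covariate name and basis size."""

    name: str
    basis_dim: int = 10
    knot_rule: str = "quantile"


@dataclass(frozen=True)
class EquationSpec:
    """Terms of one equation: parametric column names and smooth terms."""

    parametric: tuple = ()
    smooths: tuple = ()
    intercept: bool = True

    def __post_init__(self):
        object.__setattr__(self, "parametric", tuple(self.parametric))
        smooths = tuple(
            s if isinstance(s, SmoothSpec) else SmoothSpec(s) for s in self.smooths
        )
        object.__setattr__(self, "smooths", smooths)

    @property
    def columns(self):
        return tuple(self.parametric) + tuple(s.name for s in self.smooths)


@dataclass(frozen=True)
class ModelSpec:
    """Full specification of the recursive system.

    Equation 1 models the binary treatment, equation 2 the binary
    outcome; the treatment enters equation 2 as the endogenous regressor
    unless ``include_treatment_in_eq2`` is switched off (the
    non-recursive, seemingly-unrelated form used e.g. for tetrachoric
    fits).
    """

    treatment: str
    outcome: str
    eq1: EquationSpec = EquationSpec()
    eq2: EquationSpec = EquationSpec()
    include_treatment_in_eq2: bool = True

    def used_columns(self):
        cols = [self.treatment, self.outcome]
        for c in self.eq1.columns + self.eq2.columns:
            if c not in cols:
                cols.append(c)
        return cols


def _check_binary(values: np.ndarray, name: str):
    bad = np.setdiff1d(np.unique(values), [0.0, 1.0])
    if bad.size:
        raise ValueError(
            f"column '{name}' must be coded 0/1; found values {bad.tolist()}"
        )


@dataclass
class EquationDesign:
    X: np.ndarray  # n x Q parametric block (intercept first)
    names: list  # parametric coefficient names
    bases: list  # SmoothBasis per smooth term
    B: np.ndarray  # n x sum(basis cols) concatenated smooth blocks
    beta_slices: list  # slice into B per smooth

    @property
    def n_par(self):
        return self.X.shape[1]

    @property
    def n_beta(self):
        return self.B.shape[1]


def _build_equation(data: pd.DataFrame, eq: EquationSpec, label: str) -> EquationDesign:
    n = len(data)
    cols = [np.ones(n)] if eq.intercept else []
    names = ["intercept"] if eq.intercept else []
    for c in eq.parametric:
        cols.append(np.asarray(data[c], dtype=float))
        names.append(c)
    X = np.column_stack(cols) if cols else np.empty((n, 0))
    bases, blocks, slices = [], [], []
    start = 0
    for s in eq.smooths:
        basis = build_basis(
            np.asarray(data[s.name], dtype=float),
            basis_dim=s.basis_dim,
            knot_rule=s.knot_rule,
            name=s.name,
        )
        bases.append(basis)
        blocks.append(basis.design_block)
        slices.append(slice(start, start + basis.n_coef))
        start += basis.n_coef
    B = np.column_stack(blocks) if blocks else np.empty((n, 0))
    full = np.column_stack([X, B]) if X.size or B.size else X
    if full.shape[1]:
        rank = np.linalg.matrix_rank(full)
        if rank < full.shape[1]:
            raise ValueError(
                f"{label}: design matrix is rank deficient "
                f"(rank {rank} < {full.shape[1]} columns); check terms "
                f"{names + [s.name for s in eq.smooths]} for collinearity"
            )
    return EquationDesign(X=X, names=names, bases=bases, B=B, beta_slices=slices)


@dataclass
class ThetaVector:
    """Unpacked view of the joint parameter vector."""

    delta1: np.ndarray
    beta1: np.ndarray
    gamma: float  # None when the treatment is excluded from equation 2
    delta2: np.ndarray
    beta2: np.ndarray
    rho_z: float  # None when rho is fixed

    @property
    def rho(self):
        return None if self.rho_z is None else float(np.tanh(self.rho_z))


class ModelDesign:
    """Design matrices, parameter packing and penalty assembly."""

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        missing = [c for c in spec.used_columns() if c not in data.columns]
        if missing:
            raise ValueError(f"columns missing from data: {missing}")
        self.spec = spec
        self.n = len(data)
        self.y1 = np.asarray(data[spec.treatment], dtype=float)
        self.y2 = np.asarray(data[spec.outcome], dtype=float)
        _check_binary(self.y1, spec.treatment)
        _check_binary(self.y2, spec.outcome)
        self.eq1 = _build_equation(data, spec.eq1, "equation 1")
        self.eq2 = _build_equation(data, spec.eq2, "equation 2")
        if spec.include_treatment_in_eq2 and not (
            set(spec.eq1.columns) - set(spec.eq2.columns)
        ):
            warnings.warn(
                "equation 1 contains no covariate absent from equation 2; "
                "identification rests on functional form alone (no exclusion "
                "restriction)",
                stacklevel=2,
            )
        self._layout(fix_rho=False)

    def _layout(self, fix_rho: bool):
        """(Re)compute packing slices; gamma presence follows the spec."""
        self.has_gamma = bool(self.spec.include_treatment_in_eq2)
        self.free_rho = not fix_rho
        p = 0
        self.sl_delta1 = slice(p, p + self.eq1.n_par)
        p += self.eq1.n_par
        self.sl_beta1 = slice(p, p + self.eq1.n_beta)
        p += self.eq1.n_beta
        if self.has_gamma:
            self.idx_gamma = p
            p += 1
        else:
            self.idx_gamma = None
        self.sl_delta2 = slice(p, p + self.eq2.n_par)
        p += self.eq2.n_par
        self.sl_beta2 = slice(p, p + self.eq2.n_beta)
        p += self.eq2.n_beta
        if self.free_rho:
            self.idx_rho = p
            p += 1
        else:
            self.idx_rho = None
        self.n_params = p
        # global slices per smooth term, equation order then term order
        self.smooth_slices = []
        for eq_i, (eqd, base_sl) in enumerate(
            [(self.eq1, self.sl_beta1), (self.eq2, self.sl_beta2)], start=1
        ):
            for basis, sl in zip(eqd.bases, eqd.beta_slices):
                gsl = slice(base_sl.start + sl.start, base_sl.start + sl.stop)
                self.smooth_slices.append((eq_i, basis, gsl))

    @property
    def smooth_labels(self):
        return [f"s{eq}({b.covariate_name})" for eq, b, _ in self.smooth_slices]

    def unpack(self, theta: np.ndarray, rho_fixed=None) -> ThetaVector:
        theta = np.asarray(theta, dtype=float)
        return ThetaVector(
            delta1=theta[self.sl_delta1],
            beta1=theta[self.sl_beta1],
            gamma=float(theta[self.idx_gamma]) if self.has_gamma else None,
            delta2=theta[self.sl_delta2],
            beta2=theta[self.sl_beta2],
            rho_z=float(theta[self.idx_rho]) if self.free_rho else rho_fixed,
        )

    def pack(self, tv: ThetaVector) -> np.ndarray:
        theta = np.empty(self.n_params)
        theta[self.sl_delta1] = tv.delta1
        theta[self.sl_beta1] = tv.beta1
        if self.has_gamma:
            theta[self.idx_gamma] = tv.gamma
        theta[self.sl_delta2] = tv.delta2
        theta[self.sl_beta2] = tv.beta2
        if self.free_rho:
            theta[self.idx_rho] = tv.rho_z
        return theta

    def linear_predictors(self, theta: np.ndarray, y1=None):
        """eta1 and eta2; y1 defaults to the observed treatment."""
        tv = self.unpack(theta)
        eta1 = self.eq1.X @ tv.delta1
        if self.eq1.n_beta:
            eta1 = eta1 + self.eq1.B @ tv.beta1
        eta2 = self.eq2.X @ tv.delta2
        if self.eq2.n_beta:
            eta2 = eta2 + self.eq2.B @ tv.beta2
        if self.has_gamma:
            eta2 = eta2 + tv.gamma * (self.y1 if y1 is None else y1)
        return eta1, eta2

    def penalty_matrix(self, lambdas, normalize: bool = True) -> np.ndarray:
        """S_lambda embedded in the full parameter space.

        With ``normalize`` each smooth's curvature penalty is divided by
        its Frobenius norm, so the smoothing parameters live on a scale
        that is invariant to the units of the covariate (the exact
        integrated-squared-second-derivative form stays available on the
        basis object itself).
        """
        lambdas = np.asarray(lambdas, dtype=float)
        if lambdas.size != len(self.smooth_slices):
            raise ValueError(
                f"expected {len(self.smooth_slices)} smoothing parameters, "
                f"got {lambdas.size}"
            )
        if np.any(lambdas < 0):
            raise ValueError("smoothing parameters must be nonnegative")
        S = np.zeros((self.n_params, self.n_params))
        for lam, (_, basis, gsl) in zip(lambdas, self.smooth_slices):
            Sk = basis.penalty
            if normalize:
                Sk = Sk / np.linalg.norm(Sk)
            S[gsl, gsl] += lam * Sk
        return S
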