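"""Cubic regression spline bases with exact curvature penalties.

A smooth term s(x) is represented by a natural cubic spline interpolating
values beta_1..beta_q at q knots (the "cr" parameterization): the basis
functions are the cardinal natural splines of the knot sequence, and the
roughness penalty beta' S beta equals the integrated squared second
derivative of the represented function exactly, via the banded relation
between knot values and knot second derivatives.

Identifiability: each basis is centered by absorbing the single
sum-to-zero constraint (the fitted smooth averages to zero over the
construction sample) into a (q-1)-column reparameterization, so the
penalty stays an exact quadratic form in the reduced coefficients.
Outside the knot range the spline continues linearly, the natural-spline
extension with zero curvature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SmoothBasis", "build_basis", "evaluate_smooth"]


def _knot_matrices(knots: np.ndarray):
    """Banded matrices linking knot values to knot second derivatives.

    For a natural cubic spline with values beta at knots, the interior
    second derivatives are F beta with F = B^{-1} D, and
    int f''(x)^2 dx = beta' D' B^{-1} D beta over the knot range.
    """
    q = knots.size
    h = np.diff(knots)
    D = np.zeros((q - 2, q))
    B = np.zeros((q - 2, q - 2))
    for i in range(q - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i < q - 3:
            B[i, i + 1] = h[i + 1] / 6.0
            B[i + 1, i] = h[i + 1] / 6.0
    Binv_D = np.linalg.solve(B, D)
    S = D.T @ Binv_D
    S = (S + S.T) / 2.0
    F = np.zeros((q, q))
    F[1:-1] = Binv_D  # natural spline: zero curvature at the end knots
    return F, S


def _design_rows(x: np.ndarray, knots: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Evaluate the q cardinal basis functions at each x (linear beyond the knots)."""
    q = knots.size
    h = np.diff(knots)
    x = np.asarray(x, dtype=float)
    xc = np.clip(x, knots[0], knots[-1])
    j = np.clip(np.searchsorted(knots, xc, side="right") - 1, 0, q - 2)
    hj = h[j]
    dl = xc - knots[j]
    dr = knots[j + 1] - xc
    am = dr / hj
    ap = dl / hj
    cm = (dr**3 / hj - hj * dr) / 6.0
    cp = (dl**3 / hj - hj * dl) / 6.0
    rows = np.zeros((x.size, q))
    idx = np.arange(x.size)
    rows[idx, j] += am
    rows[idx, j + 1] += ap
    rows += cm[:, None] * F[j] + cp[:, None] * F[j + 1]

    out = x != xc  # beyond the boundary knots: linear continuation
    if np.any(out):
        # derivative of the basis row at the clamped boundary point
        dam = -1.0 / hj
        dap = 1.0 / hj
        dcm = (-3.0 * dr**2 / hj + hj) / 6.0
        dcp = (3.0 * dl**2 / hj - hj) / 6.0
        drow = np.zeros((x.size, q))
        drow[idx, j] += dam
        drow[idx, j + 1] += dap
        drow += dcm[:, None] * F[j] + dcp[:, None] * F[j + 1]
        rows[out] += (x[out] - xc[out])[:, None] * drow[out]
    return rows


@dataclass
class SmoothBasis:
    """A centered cubic regression spline basis for one covariate.

    Attributes
    ----------
    covariate_name : str
        Label of the covariate the smooth applies to.
    knots : ndarray
        Ordered knot vector of length ``basis_dim``.
    basis_dim : int
        Number of knots q; the centered basis has q - 1 columns.
    design_block : ndarray, shape (n, q - 1)
        Centered basis evaluated at the construction sample; every column
        sums to zero.
    penalty : ndarray, shape (q - 1, q - 1)
        Curvature penalty in the centered parameterization (PSD,
        rank q - 2; the surviving null direction is the linear trend).
    """

    covariate_name: str
    knots: np.ndarray
    basis_dim: int
    design_block: np.ndarray
    penalty: np.ndarray
    constraint: np.ndarray  # q x (q-1) centering reparameterization Z
    _F: np.ndarray = field(repr=False, default=None)

    @property
    def n_coef(self) -> int:
        return self.basis_dim - 1

    def rows(self, x_new) -> np.ndarray:
        """Centered basis rows at new covariate values."""
        x_new = np.atleast_1d(np.asarray(x_new, dtype=float))
        return _design_rows(x_new, self.knots, self._F) @ self.constraint


def build_basis(x, basis_dim: int = 10, knot_rule: str = "quantile", name: str = "x") -> SmoothBasis:
    """Construct a centered cubic regression spline basis for covariate ``x``.

    Parameters
    ----------
    x : array_like
        Covariate values the smooth is built (and centered) over.
    basis_dim : int
        Number of knots (>= 4); the centered basis has ``basis_dim - 1``
        free coefficients.
    knot_rule : {"quantile", "even"}
        Knots at sample quantiles (default) or evenly spaced over the range.
    name : str
        Covariate label used in error messages and reports.
    """
    x = np.asarray(x, dtype=float).ravel()
    if basis_dim < 4:
        raise ValueError(f"smooth '{name}': basis_dim must be >= 4, got {basis_dim}")
    n_distinct = np.unique(x).size
    if n_distinct < basis_dim:
        raise ValueError(
            f"smooth '{name}': needs at least {basis_dim} distinct covariate values, "
            f"found {n_distinct}"
        )
    if knot_rule == "quantile":
        knots = np.unique(np.quantile(x, np.linspace(0.0, 1.0, basis_dim)))
        if knots.size < basis_dim:  # heavy ties: fall back to even spacing
            knots = np.linspace(x.min(), x.max(), basis_dim)
    elif knot_rule == "even":
        knots = np.linspace(x.min(), x.max(), basis_dim)
    else:
        raise ValueError(f"unknown knot_rule {knot_rule!r}")

    F, S_raw = _knot_matrices(knots)
    raw = _design_rows(x, knots, F)
    m = raw.mean(axis=0)
    # Z spans the null space of the constraint m' beta = 0
    Q = np.linalg.qr(m.reshape(-1, 1), mode="complete")[0]
    Z = Q[:, 1:]
    design = raw @ Z
    S = Z.T @ S_raw @ Z
    S = (S + S.T) / 2.0
    return SmoothBasis(
        covariate_name=name,
        knots=knots,
        basis_dim=knots.size,
        design_block=design,
        penalty=S,
        constraint=Z,
        _F=F,
    )


def evaluate_smooth(basis: SmoothBasis, beta, x_new) -> np.ndarray:
    """Fitted smooth values at ``x_new`` for centered coefficients ``beta``."""
    beta = np.asarray(beta, dtype=float).ravel()
    if beta.size != basis.n_coef:
        raise ValueError(
            f"smooth '{basis.covariate_name}': expected {basis.n_coef} coefficients, "
            f"got {beta.size}"
        )
    return basis.rows(x_new) @ beta
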