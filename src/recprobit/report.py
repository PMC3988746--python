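"""Plain-text report rendering for fits and treatment effects.

Tables mirror the two-part layout of the case-study report: per-equation
parametric coefficient tables (Estimate, Std. err., P val.), a smooth
table (Edf, Est. rank, P val.), the error-correlation row with its
interval, and a three-row ATE table (SBP, AP, Unadjusted) on the
percentage-point scale.
"""

from __future__ import annotations

import numpy as np

__all__ = ["render_fit_report", "render_ate_table", "format_pvalue"]


def format_pvalue(p: float) -> str:
    return "<0.0001" if p < 1e-4 else f"{p:.4f}"


def _param_lines(frame) -> list:
    w = max([len(str(t)) for t in frame["term"]] + [10])
    head = f"{'':{w}}  {'Estimate':>9}  {'Std. err.':>9}  {'P val.':>8}"
    lines = [head]
    for _, row in frame.iterrows():
        lines.append(
            f"{row['term']:{w}}  {row['Estimate']:>9.4f}  {row['Std. err.']:>9.4f}  "
            f"{format_pvalue(row['P val.']):>8}"
        )
    return lines


def _smooth_lines(frame) -> list:
    if not len(frame):
        return []
    w = max([len(str(t)) for t in frame["Smooth term"]] + [10])
    head = f"{'':{w}}  {'Edf':>7}  {'Est. rank':>9}  {'P val.':>8}"
    lines = [head]
    for _, row in frame.iterrows():
        lines.append(
            f"{row['Smooth term']:{w}}  {row['Edf']:>7.3f}  {row['Est. rank']:>9d}  "
            f"{format_pvalue(row['P val.']):>8}"
        )
    return lines


def render_fit_report(results, level: float = 0.95) -> str:
    """Coefficient and smooth-term tables for both equations plus the rho row."""
    lines = []
    lines.append("Recursive bivariate probit fit")
    lines.append(f"n = {results.n_obs}")
    lines.append(f"log-likelihood = {results.loglik:.4f}")
    lines.append(f"total edf = {results.edf_total:.3f}")
    lines.append(f"converged = {results.converged}")
    smooths = results.smooth_table()
    for eq, title in ((1, "Equation 1 (treatment)"), (2, "Equation 2 (outcome)")):
        lines.append("")
        lines.append(title)
        lines.extend(_param_lines(results.params_table(eq)))
        st_eq = smooths[[lbl.startswith(f"s{eq}(") for lbl in smooths["Smooth term"]]]
        if len(st_eq):
            lines.append("")
            lines.extend(_smooth_lines(st_eq))
    lines.append("")
    if results.design.free_rho:
        lo, hi = results.rho_ci(level)
        lines.append(f"rho {results.rho:.3f} ({lo:.4f}, {hi:.4f})")
    else:
        lines.append(f"rho fixed at {results.rho:.3f}")
    if results.lambdas.size:
        for lbl, lam in zip(results.design.smooth_labels, results.lambdas):
            lines.append(
                f"smoothing parameter {lbl}: {lam:.6g}  "
                f"(edf {results.edf_smooth[lbl]:.3f})"
            )
        for (eq_i, basis, _), lbl in zip(
            results.design.smooth_slices, results.design.smooth_labels
        ):
            knots = ", ".join(f"{k:.4g}" for k in basis.knots)
            lines.append(f"knots {lbl}: [{knots}]")
    return "\n".join(lines) + "\n"


def render_ate_table(ate_results, scale: float = 100.0) -> str:
    """Three-row treatment-effect table (percentage points by default)."""
    lines = []
    unit = "percentage points" if scale == 100.0 else "probability difference"
    lines.append(f"Average treatment effect of the treatment indicator ({unit})")
    lines.append(f"{'ATE of':<12}  {'Estimate':>9}  {'CI':>18}")
    for r in ate_results:
        est, lo, hi = r.display(scale)
        lines.append(f"{r.method:<12}  {est:>9.2f}  ({lo:>7.2f}, {hi:>7.2f})")
        if r.method == "SBP" and "potential_outcome" in r.extra:
            po = scale * r.extra["potential_outcome"]
            plo, phi = (scale * v for v in r.extra["potential_outcome_ci"])
            lines.append(
                f"{'  (potential-outcome form)':<12}  {po:>9.2f}  ({plo:>7.2f}, {phi:>7.2f})"
            )
    return "\n".join(lines) + "\n"
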