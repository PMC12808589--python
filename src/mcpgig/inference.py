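"""Hypothesis tests and model comparison for MCPGIGR fits.

Simultaneous significance uses the likelihood-ratio statistic

    G^2 = 2 (lnL(full) - lnL(intercepts-only)),

referred to a chi-square with p*m degrees of freedom (one per tested slope;
intercepts and the dispersion pair remain free under both hypotheses, so no
boundary correction is needed).  Coefficient-wise significance uses Wald
Z = estimate / SE against the standard normal.  Model comparison uses the
small-sample corrected AICc with P equal to the TOTAL free-parameter count,
so that MPR (P = m(p+1)) and MCPGIGR (P = m(p+1)+2) carry different
penalties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .regression import (
    CoefficientSet,
    ConvergenceError,
    CountPanel,
    FitResult,
    bhhh_fit,
    fit_mcpgigr,
    initialize,
)


@dataclass
class TestReport:
    """MLRT and Wald results in one container."""

    g2: float
    df: int
    p_value: float
    critical_value: float
    alpha: float
    reject: bool
    wald: list = field(default_factory=list)  # dicts: name, estimate, se, z, p, reject


def chi2_critical(df: int, alpha: float) -> float:
    """(1 - alpha) quantile of the chi-square distribution."""
    if df < 1 or int(df) != df:
        raise ValueError("df must be a positive integer")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie strictly between 0 and 1")
    return float(stats.chi2.ppf(1.0 - alpha, int(df)))


def fit_null(panel: CountPanel, gamma: float = -0.5, tol: float = 1e-7,
             max_iter: int = 500) -> FitResult:
    """Intercepts-only MCPGIGR fit (all slopes pinned at 0; tau, xi free)."""
    mask = np.zeros((panel.m, panel.p + 1), dtype=bool)
    mask[:, 0] = True
    return fit_mcpgigr(panel, gamma=gamma, tol=tol, max_iter=max_iter, slope_mask=mask)


def mlrt(full: FitResult, null: FitResult, alpha: float = 0.05) -> TestReport:
    """Simultaneous likelihood-ratio test of all slope coefficients."""
    if full.model != null.model:
        raise ValueError("full and null fits must come from the same model family")
    df = int(full.slope_mask.sum() - null.slope_mask.sum())
    if df < 1:
        raise ValueError("null model does not restrict any slope")
    g2 = 2.0 * (full.loglik - null.loglik)
    if g2 < -1e-6:
        raise ConvergenceError(
            f"negative likelihood-ratio statistic ({g2:.3e}): optimizer failure"
        )
    if g2 < 0.0:
        import warnings

        warnings.warn("small negative G^2 clipped to 0", RuntimeWarning)
        g2 = 0.0
    crit = chi2_critical(df, alpha)
    p = float(stats.chi2.sf(g2, df))
    return TestReport(
        g2=float(g2), df=df, p_value=p, critical_value=crit,
        alpha=alpha, reject=bool(g2 > crit),
    )


def wald_tests(fit: FitResult, alpha: float = 0.05) -> list:
    """Per-coefficient Wald Z statistics with two-sided normal p-values."""
    if not fit.converged:
        raise ConvergenceError("Wald tests require a converged fit")
    rows = []
    for name, est, se in zip(
        fit.param_names, _flat_estimates(fit), fit.se
    ):
        if not name.startswith("beta_"):
            continue
        if not np.isfinite(se) or se <= 0.0:
            raise ConvergenceError(f"invalid standard error for coefficient '{name}'")
        z = est / se
        p = 2.0 * float(stats.norm.sf(abs(z)))
        rows.append(
            {"name": name, "estimate": float(est), "se": float(se),
             "z": float(z), "p": p, "reject": bool(abs(z) > stats.norm.ppf(1 - alpha / 2))}
        )
    return rows


def _flat_estimates(fit: FitResult) -> np.ndarray:
    est = fit.estimates
    vals = list(est.betas[fit.slope_mask])
    if est.gig is not None:
        vals += [est.gig.tau, est.gig.xi]
    return np.asarray(vals)


def test_coefficients(panel: CountPanel, gamma: float = -0.5, alpha: float = 0.05,
                      tol: float = 1e-7, max_iter: int = 500,
                      full: Optional[FitResult] = None) -> TestReport:
    """Convenience wrapper: full fit, null fit, MLRT and Wald tests."""
    if full is None:
        full = fit_mcpgigr(panel, gamma=gamma, tol=tol, max_iter=max_iter)
    null = fit_null(panel, gamma=gamma, tol=tol, max_iter=max_iter)
    report = mlrt(full, null, alpha=alpha)
    report.wald = wald_tests(full, alpha=alpha)
    return report


def aicc(fit: FitResult, n: Optional[int] = None) -> float:
    """Small-sample corrected Akaike criterion -2 lnL + 2P + 2P(P+1)/(n-P-1).

    P is the total number of freely estimated parameters; lower is better.
    """
    if n is None:
        n = fit.n_obs
    P = fit.n_params
    if n <= P + 1:
        raise ValueError(f"AICc undefined: need n > P+1 (n={n}, P={P})")
    return float(-2.0 * fit.loglik + 2.0 * P + 2.0 * P * (P + 1) / (n - P - 1))
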