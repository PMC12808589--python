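"""Common-shock multivariate Poisson counts and their GIG mixture (MCPGIG).

Construction: with independent Poisson variables Z_1, ..., Z_m of rates
lambda_1, ..., lambda_m, the responses are

    Y_1 = Z_1,   Y_j = Z_1 + Z_j   (j = 2, ..., m),

so the shared shock Z_1 induces positive cross-component correlation and the
support obeys y_j >= y_1 for all j >= 2.  Mixing every rate with a single
GIG frailty nu (Y | nu ~ common-shock Poisson with rates lambda*nu,
nu ~ GIG(tau, xi, gamma)) yields the MCPGIG distribution whose pmf is
available in closed form:

    P(y) = xi^{-gamma} / K_gamma(w)
           * lambda_1^{y_1}/y_1! * prod_{j>=2} lambda_j^{y_j-y_1}/(y_j-y_1)!
           * (w xi^2 / psi)^{(Y+gamma)/2} * K_{Y+gamma}(sqrt(psi w)),

with total count Y = y_1 + sum_{j>=2}(y_j - y_1), w the derived GIG argument
and psi = 2 xi (sum_j lambda_j) + w.  The slow quadrature mixture
``mcpgig_pmf_oracle`` is kept as an independent reference implementation; the
closed form is required to agree with it and with the GIG Laplace transform
at y = 0.

All pmf work is done in the log domain; ``exp`` is applied only at the
boundary of each public ``*_pmf`` function.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, special

from .gig import GIGParams, InvalidParameterError, gig_logpdf, gig_mean, gig_variance, gig_sample, log_kv


class NumericalError(RuntimeError):
    """Raised when a reference quadrature fails to converge."""


def _check_rates(rates: np.ndarray) -> np.ndarray:
    rates = np.asarray(rates, dtype=float)
    if rates.ndim != 1 or rates.size < 2:
        raise InvalidParameterError("rates must be a 1-D vector of length m >= 2")
    if np.any(rates < 0.0):
        raise InvalidParameterError("rates must be non-negative")
    if rates[0] <= 0.0:
        raise InvalidParameterError(
            "shock rate lambda_1 must be strictly positive (it carries the correlation)"
        )
    return rates


def _check_counts(y, m: int) -> np.ndarray:
    y = np.asarray(y)
    if np.any(y < 0) or not np.issubdtype(y.dtype, np.integer) and np.any(y != np.floor(y)):
        raise InvalidParameterError("counts must be non-negative integers")
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[-1] != m:
        raise InvalidParameterError(f"count vectors must have length m={m}")
    return y


def _shock_differences(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row count exponents c = (y_1, y_2-y_1, ..., y_m-y_1) and support mask."""
    c = y.copy()
    c[:, 1:] -= y[:, [0]]
    ok = np.all(c[:, 1:] >= 0.0, axis=1)
    return c, ok


def mp_logpmf(y, rates) -> np.ndarray:
    """Log pmf of the common-shock multivariate Poisson; -inf off support."""
    rates = _check_rates(rates)
    y2 = _check_counts(y, rates.size)
    c, ok = _shock_differences(y2)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = special.xlogy(c, rates[np.newaxis, :])
    out = np.where(
        ok,
        -rates.sum() + logs.sum(axis=1) - special.gammaln(c + 1.0).sum(axis=1),
        -np.inf,
    )
    return out if np.asarray(y).ndim > 1 else float(out[0])


def mp_pmf(y, rates):
    """Joint pmf of the common-shock multivariate Poisson distribution."""
    return np.exp(mp_logpmf(y, rates))


def mp_sample(n: int, rates, seed=None) -> np.ndarray:
    """Draw ``n`` count vectors via the variate-reduction construction."""
    rates = _check_rates(rates)
    if n < 1:
        raise InvalidParameterError("sample size must be >= 1")
    rng = np.random.default_rng(seed)
    z = rng.poisson(rates[np.newaxis, :], size=(int(n), rates.size))
    y = z.copy()
    y[:, 1:] += z[:, [0]]
    return y


def mcpgig_logpmf(y, rates, params: GIGParams) -> np.ndarray:
    """Log pmf of the MCPGIG distribution (closed-form GIG mixture)."""
    rates = _check_rates(rates)
    y2 = _check_counts(y, rates.size)
    c, ok = _shock_differences(y2)
    g, xi, w = params.gamma_shape, params.xi, params.omega
    total = c.sum(axis=1)  # Y = y_1 + sum_{j>=2}(y_j - y_1)
    order = total + g
    psi = 2.0 * xi * rates.sum() + w
    u = np.sqrt(psi * w)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = special.xlogy(c, rates[np.newaxis, :])
    ll = (
        -g * np.log(xi)
        - log_kv(g, w)
        + logs.sum(axis=1)
        - special.gammaln(c + 1.0).sum(axis=1)
        + 0.5 * order * (np.log(w) + 2.0 * np.log(xi) - np.log(psi))
        + log_kv(order, u)
    )
    out = np.where(ok, ll, -np.inf)
    return out if np.asarray(y).ndim > 1 else float(out[0])


def mcpgig_pmf(y, rates, params: GIGParams):
    """Pmf of the MCPGIG distribution."""
    return np.exp(mcpgig_logpmf(y, rates, params))


def mcpgig_pmf_oracle(y, rates, params: GIGParams, tol: float = 1e-12) -> float:
    """Reference pmf by adaptive quadrature of the Poisson-GIG mixture.

    Computes ``int_0^inf MP(y | rates * nu) g(nu) dnu`` directly.  Slow and
    single-point; used only to pin down the closed-form algebra.
    """
    rates = _check_rates(rates)
    y1 = np.asarray(y, dtype=float).ravel()
    c, ok = _shock_differences(np.atleast_2d(y1))
    if not ok[0]:
        return 0.0

    def integrand(nu):
        return np.exp(mp_logpmf(y1[np.newaxis, :], rates * nu) + gig_logpdf(nu, params))[0]

    mode_guess = max(params.xi, 1e-3)
    val, err = integrate.quad(
        integrand, 0.0, np.inf, epsabs=0.0, epsrel=tol,
        points=None, limit=400,
    )
    # quad over (0, inf) can miss a sharp interior peak; refine with a split.
    val2, err2 = 0.0, 0.0
    for lo, hi in ((0.0, mode_guess), (mode_guess, np.inf)):
        v, e = integrate.quad(integrand, lo, hi, epsabs=0.0, epsrel=tol, limit=400)
        val2 += v
        err2 += e
    if val2 > 0 and abs(val - val2) > 1e-6 * max(val, val2):
        val, err = val2, err2
    if val > 0 and err > 1e-6 * val:
        raise NumericalError(
            f"mixture quadrature did not converge (value {val:g}, abserr {err:g})"
        )
    return val


def mcpgig_moments(rates, params: GIGParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-component mean and variance of the MCPGIG distribution.

    The effective Poisson rate of component j is Lambda_j = lambda_1 + lambda_j
    (j >= 2) and Lambda_1 = lambda_1, so by the mixed-Poisson law of total
    variance

        E(Y_j)   = E(nu) * Lambda_j = xi R_gamma(w) Lambda_j,
        Var(Y_j) = E(Y_j) + Lambda_j^2 * Var(nu).
    """
    rates = _check_rates(rates)
    lam_eff = rates.copy()
    lam_eff[1:] += rates[0]
    mean = gig_mean(params) * lam_eff
    var = mean + lam_eff**2 * gig_variance(params)
    return mean, var


def mcpgig_sample(n: int, rates, params: GIGParams, seed=None) -> np.ndarray:
    """Draw ``n`` MCPGIG count vectors (one shared frailty per unit)."""
    rates = _check_rates(rates)
    if n < 1:
        raise InvalidParameterError("sample size must be >= 1")
    rng = np.random.default_rng(seed)
    nu = gig_sample(int(n), params, seed=rng)
    z = rng.poisson(rates[np.newaxis, :] * nu[:, np.newaxis])
    y = z.copy()
    y[:, 1:] += z[:, [0]]
    return y
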