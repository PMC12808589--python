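"""Generalized inverse Gaussian (GIG) mixing distribution and Bessel-ratio numerics.

The mixing law used throughout the package is the three-parameter GIG with
density

    g(nu; tau, xi, gamma) = xi^{-gamma} / (2 K_gamma(w)) * nu^{gamma-1}
                            * exp(-(w/2) * (nu/xi + xi/nu)),   nu > 0,

where ``w = sqrt(tau^2 + xi^2) - xi`` is the derived Bessel argument and
``K_gamma`` is the modified Bessel function of the third kind.  In the standard
two-argument GIG parametrization this is GIG(p=gamma, a=w/xi, b=w*xi), so the
normalizer, moments and sampler all follow from classical identities:

    E(nu^k) = xi^k * K_{gamma+k}(w) / K_gamma(w)

``tau`` controls the dispersion of the random effect, ``xi`` its scale, and
``gamma`` the tail behaviour (half-integers such as -1/2, -3/2, -5/2 give
tractable closed forms and are the only values the regression model uses,
though everything here accepts arbitrary real ``gamma``).

All Bessel evaluation is done in the log domain via exponentially scaled
functions plus a stable upward order recurrence, so ratios such as
``R_gamma(w) = K_{gamma+1}(w)/K_gamma(w)`` stay accurate for arguments from
1e-6 up to 1e4 and for large orders where a naive ratio would overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats


class InvalidParameterError(ValueError):
    """Raised when a distribution parameter violates its domain."""


def gig_omega(tau: float, xi: float) -> float:
    """Derived GIG Bessel argument ``sqrt(tau^2 + xi^2) - xi``.

    Evaluated as ``tau^2 / (sqrt(tau^2 + xi^2) + xi)`` — algebraically
    identical but free of the catastrophic cancellation that would silently
    return 0.0 for tiny ``tau`` (e.g. tau=1e-8, xi=1 gives ~5e-17, not 0).
    """
    tau = float(tau)
    xi = float(xi)
    if not (tau > 0.0):
        raise InvalidParameterError(f"tau must be positive, got {tau!r}")
    if not (xi > 0.0):
        raise InvalidParameterError(f"xi must be positive, got {xi!r}")
    return tau * tau / (np.hypot(tau, xi) + xi)


@dataclass(frozen=True)
class GIGParams:
    """Parameters of the GIG mixing distribution.

    Attributes
    ----------
    tau : float
        Dispersion of the GIG random effect, > 0.
    xi : float
        Scale, > 0.
    gamma_shape : float
        Tail/shape index gamma (any real; the regression model uses
        half-integers).
    omega : float
        Derived Bessel argument, recomputed from (tau, xi) at construction.
    """

    tau: float
    xi: float
    gamma_shape: float
    omega: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "omega", gig_omega(self.tau, self.xi))


def log_kv(order, arg):
    """``log K_order(arg)`` elementwise, robust to order/argument extremes.

    Uses the exponentially scaled ``scipy.special.kve`` where it is finite and
    falls back to the upward order recurrence

        K_{v+1}(x) = K_{v-1}(x) + (2v/x) K_v(x)

    carried in the log domain (all terms positive, so the recurrence is
    forward stable) for large orders at small arguments where ``kve``
    overflows.  ``K`` is symmetric in its order, so negative orders are
    folded to positive ones.
    """
    order = np.abs(np.asarray(order, dtype=float))
    arg = np.asarray(arg, dtype=float)
    if np.any(arg <= 0.0):
        raise InvalidParameterError("Bessel argument must be positive")
    order, arg = np.broadcast_arrays(order, arg)
    scalar = order.ndim == 0
    v = np.atleast_1d(order).ravel()
    x = np.atleast_1d(arg).ravel()

    with np.errstate(over="ignore", divide="ignore"):
        out = np.log(special.kve(v, x)) - x
    bad = ~np.isfinite(out)
    if np.any(bad):
        out[bad] = _log_kv_recurrence(v[bad], x[bad])
    shape = np.shape(arg) if not scalar else ()
    if scalar:
        return float(out[0])
    return out.reshape(shape)


def _log_kv_asymptotic(v: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Large-argument expansion log K_v(x) ~ log sqrt(pi/2x) - x + log sum a_k/x^k.

    Valid when x >> v^2; used where ``kve`` itself overflows (x beyond ~1e9).
    """
    series = np.ones_like(x)
    term = np.ones_like(x)
    for k in range(1, 5):
        term = term * (4.0 * v * v - (2 * k - 1) ** 2) / (k * 8.0 * x)
        series = series + term
    return 0.5 * np.log(np.pi / (2.0 * x)) - x + np.log(series)


def _log_kv_recurrence(v: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Upward log-domain order recurrence from the fractional base order."""
    huge = x > np.maximum(1e6, 100.0 * v * v)
    if np.any(huge):
        out = np.empty_like(x)
        out[huge] = _log_kv_asymptotic(v[huge], x[huge])
        if np.any(~huge):
            out[~huge] = _log_kv_recurrence(v[~huge], x[~huge])
        return out
    frac = v - np.floor(v)
    steps = np.floor(v).astype(int)
    lk_prev = np.log(special.kve(frac, x)) - x        # K_{frac}
    lk_curr = np.log(special.kve(frac + 1.0, x)) - x  # K_{frac+1}
    if not np.all(np.isfinite(lk_prev) & np.isfinite(lk_curr)):
        raise InvalidParameterError(
            "Bessel base-order evaluation failed; argument too extreme"
        )
    out = np.where(steps == 0, lk_prev, lk_curr)
    nmax = int(steps.max(initial=0))
    for k in range(1, nmax):
        act = steps > k
        if not np.any(act):
            break
        nu_k = frac[act] + k
        nxt = np.logaddexp(
            np.log(2.0 * nu_k / x[act]) + lk_curr[act], lk_prev[act]
        )
        lk_prev = lk_prev.copy()
        lk_curr = lk_curr.copy()
        lk_prev[act] = lk_curr[act]
        lk_curr[act] = nxt
        out[steps == k + 1] = nxt[(steps[act] == k + 1)]
    return out


def bessel_k_ratio(order, arg):
    """``K_{order+1}(arg) / K_order(arg)`` computed in the log domain.

    Exact symmetry in the order makes ``bessel_k_ratio(-1/2, x) == 1``.
    """
    arg_arr = np.asarray(arg, dtype=float)
    if np.any(arg_arr <= 0.0):
        raise InvalidParameterError("Bessel ratio argument must be positive")
    order_arr = np.asarray(order, dtype=float)
    return np.exp(log_kv(order_arr + 1.0, arg_arr) - log_kv(order_arr, arg_arr))


def gig_logpdf(nu, params: GIGParams):
    """Log density of the GIG mixing law at ``nu > 0``."""
    nu = np.asarray(nu, dtype=float)
    if np.any(nu <= 0.0):
        raise InvalidParameterError("GIG density argument nu must be positive")
    g, xi, w = params.gamma_shape, params.xi, params.omega
    return (
        -g * np.log(xi)
        - np.log(2.0)
        - log_kv(g, w)
        + (g - 1.0) * np.log(nu)
        - 0.5 * w * (nu / xi + xi / nu)
    )


def gig_density(nu, params: GIGParams):
    """GIG density at ``nu > 0``; integrates to 1 over (0, inf)."""
    return np.exp(gig_logpdf(nu, params))


def gig_moment(k: int, params: GIGParams) -> float:
    """k-th raw moment ``E(nu^k) = xi^k K_{gamma+k}(omega) / K_gamma(omega)``."""
    if not float(k).is_integer() or k < 0:
        raise InvalidParameterError("moment order k must be a non-negative integer")
    k = int(k)
    if k == 0:
        return 1.0
    g, w = params.gamma_shape, params.omega
    return float(params.xi**k * np.exp(log_kv(g + k, w) - log_kv(g, w)))


def gig_mean(params: GIGParams) -> float:
    """``E(nu) = xi * R_gamma(omega)``."""
    return gig_moment(1, params)


def gig_variance(params: GIGParams) -> float:
    """``Var(nu) = xi^2 (K_{gamma+2}/K_gamma - R_gamma^2)`` at omega."""
    m1 = gig_moment(1, params)
    m2 = gig_moment(2, params)
    return m2 - m1 * m1


def gig_laplace(s, params: GIGParams):
    """Laplace transform ``E[exp(-s nu)]`` of the GIG law, in closed form.

    With the (p, a, b) parametrization (a = omega/xi, b = omega*xi) the
    transform is ``(a/(a+2s))^{p/2} K_p(sqrt((a+2s) b)) / K_p(sqrt(a b))``.
    Used in tests as an independent check of the mixed pmf at y = 0.
    """
    s = np.asarray(s, dtype=float)
    g, w, xi = params.gamma_shape, params.omega, params.xi
    a = w / xi
    b = w * xi
    return np.exp(
        0.5 * g * (np.log(a) - np.log(a + 2.0 * s))
        + log_kv(g, np.sqrt((a + 2.0 * s) * b))
        - log_kv(g, w)
    )


def gig_sample(n: int, params: GIGParams, seed=None) -> np.ndarray:
    """Draw ``n`` iid variates from the GIG mixing law.

    Delegates to ``scipy.stats.geninvgauss`` whose (p, b, scale)
    parametrization maps to ours as p=gamma, b=omega, scale=xi.
    """
    if n < 1:
        raise InvalidParameterError("sample size must be >= 1")
    rng = np.random.default_rng(seed)
    return stats.geninvgauss.rvs(
        params.gamma_shape, params.omega, scale=params.xi, size=int(n), random_state=rng
    )
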