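"""MCPGIGR: exposure-adjusted multivariate count regression with GIG mixing.

Mean structure and rate map
---------------------------
Each of the m responses follows the exposure-adjusted log link

    E(Y_ij) = mu_ij = q_ij * exp(x_i' beta_j),

with the first response column playing the common-shock role.  The underlying
common-shock Poisson rates are recovered from the means through

    lambda_i1 = mu_i1 / (xi R_gamma(w)),
    lambda_ij = (mu_ij - mu_i1) / (xi R_gamma(w))   (j >= 2),

which makes the MCPGIG moment identity xi R_gamma(w) (lambda_ij + lambda_i1)
return mu_ij exactly.  Feasibility requires mu_ij >= mu_i1 for j >= 2.

Estimation
----------
The log-likelihood is the sum of MCPGIG log pmfs over units.  BHHH maximizes
it using analytic per-observation score vectors (derived with the Bessel
identity dK_g(w)/dw = (g/w) K_g(w) - K_{g+1}(w)), the outer-product-of-
gradients Hessian approximation, a backtracking line search that enforces
monotone ascent, and the stopping rule ||theta_{t+1} - theta_t|| <= tol.
The dispersion pair (tau, xi) is optimized on the log scale to enforce
positivity; gamma is a fixed half-integer model setting, never estimated.

A note on identifiability: after the rate map above is substituted into the
MCPGIG pmf, the scale xi cancels algebraically and the likelihood depends on
(tau, xi) only through w(tau, xi).  The pair is therefore estimated jointly
on a likelihood ridge; the OPG matrix has a corresponding near-null direction
confined to the dispersion block (no slope component), which the solver
handles with a logged ridge regularization.  See docs/methods.md.

The unmixed common-shock multivariate Poisson regression (MPR) baseline uses
lambda_i1 = mu_i1, lambda_ij = mu_ij - mu_i1 and the same BHHH machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import linalg, special

from .gig import GIGParams, InvalidParameterError, bessel_k_ratio, gig_omega, log_kv

_PENALTY = -1e10
_ETA_MAX = 60.0  # linear predictors beyond this are treated as infeasible trial points


class FeasibilityError(ValueError):
    """Raised when the mean ordering mu_ij >= mu_i1 fails where it must hold."""


class ConvergenceError(RuntimeError):
    """Raised when a fit cannot provide the requested quantity."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class CountPanel:
    """n units by m responses, with matched exposures and p predictors.

    ``predictors`` excludes the intercept column; the design matrix adds it.
    """

    responses: np.ndarray
    exposures: np.ndarray
    predictors: np.ndarray
    labels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        y = np.asarray(self.responses)
        if np.any(y < 0) or np.any(y != np.floor(y)):
            raise InvalidParameterError("responses must be non-negative integers")
        self.responses = np.asarray(y, dtype=np.int64)
        self.exposures = np.asarray(self.exposures, dtype=float)
        self.predictors = np.asarray(self.predictors, dtype=float)
        if self.predictors.ndim == 1:
            self.predictors = self.predictors[:, np.newaxis]
        n, m = self.responses.shape
        if self.exposures.shape != (n, m):
            raise InvalidParameterError("exposures must match responses in shape")
        if m < 2:
            raise InvalidParameterError("need at least two response components")
        if self.predictors.shape[0] != n:
            raise InvalidParameterError("predictors must have one row per unit")
        if np.any(self.exposures <= 0.0):
            raise InvalidParameterError("exposures must be strictly positive")
        if not np.all(np.isfinite(self.predictors)):
            raise InvalidParameterError("predictors must be finite")

    @property
    def n(self) -> int:
        return self.responses.shape[0]

    @property
    def m(self) -> int:
        return self.responses.shape[1]

    @property
    def p(self) -> int:
        return self.predictors.shape[1]

    @property
    def design_matrix(self) -> np.ndarray:
        """Predictors with a leading intercept column, shape (n, p+1)."""
        return np.column_stack([np.ones(self.n), self.predictors])

    def support_violations(self) -> np.ndarray:
        """Row indices where y_ij < y_i1 for some j >= 2."""
        y = self.responses
        bad = np.any(y[:, 1:] < y[:, [0]], axis=1)
        return np.flatnonzero(bad)


@dataclass
class CoefficientSet:
    """Full parameter vector theta: m coefficient vectors plus GIG parameters.

    ``gig is None`` denotes the unmixed multivariate Poisson regression.
    ``gamma_shape`` is always a fixed model setting, not a free parameter.
    """

    betas: np.ndarray
    gig: Optional[GIGParams] = None

    def __post_init__(self) -> None:
        self.betas = np.atleast_2d(np.asarray(self.betas, dtype=float))

    @property
    def m(self) -> int:
        return self.betas.shape[0]

    @property
    def n_free(self) -> int:
        """Free-parameter count: m(p+1) + 2 with GIG mixing (gamma fixed)."""
        return self.betas.size + (2 if self.gig is not None else 0)


@dataclass
class FitResult:
    """Outcome of a BHHH maximization."""

    estimates: CoefficientSet
    loglik: float
    covariance: np.ndarray
    se: np.ndarray
    param_names: list
    iterations: int
    converged: bool
    trace: list
    n_obs: int
    model: str
    slope_mask: np.ndarray

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def se_table(self) -> dict:
        return dict(zip(self.param_names, self.se))


# ---------------------------------------------------------------------------
# Mean structure and rates
# ---------------------------------------------------------------------------

def mean_structure(panel: CountPanel, coeffs: CoefficientSet) -> np.ndarray:
    """mu_ij = q_ij * exp(x_i' beta_j), shape (n, m)."""
    eta = panel.design_matrix @ coeffs.betas.T
    too_big = eta > 700.0
    if np.any(too_big):
        i, j = np.argwhere(too_big)[0]
        raise OverflowError(
            f"linear predictor overflows exp() at unit {i}, response {j}"
        )
    return panel.exposures * np.exp(eta)


def _rate_numerators(mu: np.ndarray) -> np.ndarray:
    num = mu.copy()
    num[:, 1:] -= mu[:, [0]]
    return num


def rates_from_coefficients(panel: CountPanel, coeffs: CoefficientSet) -> np.ndarray:
    """Common-shock Poisson rates implied by the fitted means, shape (n, m).

    Raises :class:`FeasibilityError` when some mu_ij < mu_i1 (j >= 2); the
    likelihood handles that region with a penalty instead of calling this.
    """
    mu = mean_structure(panel, coeffs)
    num = _rate_numerators(mu)
    bad = np.argwhere(num[:, 1:] <= 0.0)
    if bad.size:
        rows = np.unique(bad[:, 0])[:10]
        raise FeasibilityError(
            f"mean ordering mu_ij >= mu_i1 violated at rows {rows.tolist()}"
        )
    if coeffs.gig is None:
        return num
    g = coeffs.gig
    return num / (g.xi * bessel_k_ratio(g.gamma_shape, g.omega))


# ---------------------------------------------------------------------------
# Likelihood and score kernels
# ---------------------------------------------------------------------------

def _count_diffs(panel: CountPanel) -> np.ndarray:
    c = panel.responses.astype(float)
    c[:, 1:] -= c[:, [0]].astype(float)
    if np.any(c[:, 1:] < 0):
        raise FeasibilityError(
            "responses violate the support law y_ij >= y_i1; "
            f"rows {panel.support_violations()[:10].tolist()}"
        )
    return c


def _infeasible_penalty(num: np.ndarray, eta: np.ndarray) -> float:
    """Smooth large-negative surrogate guiding the line search back inside."""
    viol = np.clip(-num[:, 1:], 0.0, None)
    scale = np.maximum(np.abs(num[:, [0]]), 1e-8)
    pen = float(np.sum((viol / scale) ** 2)) + float(
        np.sum(np.clip(np.abs(eta) - _ETA_MAX, 0.0, None) ** 2)
    )
    return _PENALTY * (1.0 + pen)


def _mcpgigr_kernel(panel, betas, tau, xi, gamma, want_score):
    """Per-unit log-likelihood (and analytic score) of the MCPGIGR model.

    Returns (ll_total, ll_units, scores) where scores has one column per
    entry of [beta_10..beta_1p, ..., beta_m0..beta_mp, ln tau, ln xi].
    For infeasible parameter points returns (penalty, None, None).
    """
    X = panel.design_matrix
    c = _count_diffs(panel)
    eta = X @ betas.T
    if np.any(np.abs(eta) > _ETA_MAX):
        return _infeasible_penalty(np.ones((1, panel.m)), eta), None, None
    mu = panel.exposures * np.exp(eta)
    num = _rate_numerators(mu)
    if np.any(num[:, 1:] <= 0.0):
        return _infeasible_penalty(num, eta), None, None

    w_full = np.hypot(tau, xi)
    omega = tau * tau / (w_full + xi)
    Rg = float(bessel_k_ratio(gamma, omega))
    a = num / Rg
    A = a.sum(axis=1)
    psi = 2.0 * A + omega
    u = np.sqrt(psi * omega)
    Y = c.sum(axis=1)
    order = Y + gamma

    lkv_gamma = log_kv(gamma, omega)
    lkv_ord = log_kv(order, u)
    ll_units = (
        -lkv_gamma
        + special.xlogy(c, a).sum(axis=1)
        - special.gammaln(c + 1.0).sum(axis=1)
        + 0.5 * order * (np.log(omega) - np.log(psi))
        + lkv_ord
    )
    ll = float(ll_units.sum())
    if not want_score:
        return ll, ll_units, None

    n, m = mu.shape
    q = X.shape[1]
    Rg1 = float(bessel_k_ratio(gamma + 1.0, omega))
    G = 1.0 / omega + Rg - Rg1  # d ln R_gamma / d omega
    R_ord = np.exp(log_kv(order + 1.0, u) - lkv_ord)
    B = order / u - R_ord  # d ln K_order(u) / du
    Wq = -0.5 * order / psi + 0.5 * B * omega / u  # d ll / d psi
    g_num = c / num + (2.0 / Rg) * Wq[:, np.newaxis]
    dl_dw = (
        (Rg - gamma / omega)
        - Y * G
        + 0.5 * order / omega
        + Wq * (1.0 - 2.0 * A * G)
        + 0.5 * B * psi / u
    )

    gb = np.empty((n, m))
    gb[:, 0] = mu[:, 0] * (g_num[:, 0] - g_num[:, 1:].sum(axis=1))
    gb[:, 1:] = mu[:, 1:] * g_num[:, 1:]
    scores = np.empty((n, m * q + 2))
    scores[:, : m * q] = (gb[:, :, np.newaxis] * X[:, np.newaxis, :]).reshape(n, m * q)
    scores[:, m * q] = dl_dw * (tau * tau / w_full)
    scores[:, m * q + 1] = dl_dw * (xi * xi / w_full - xi)
    return ll, ll_units, scores


def _mpr_kernel(panel, betas, want_score):
    """Per-unit log-likelihood (and score) of the common-shock MPR baseline."""
    X = panel.design_matrix
    c = _count_diffs(panel)
    eta = X @ betas.T
    if np.any(np.abs(eta) > _ETA_MAX):
        return _infeasible_penalty(np.ones((1, panel.m)), eta), None, None
    mu = panel.exposures * np.exp(eta)
    lam = _rate_numerators(mu)
    if np.any(lam[:, 1:] <= 0.0):
        return _infeasible_penalty(lam, eta), None, None

    ll_units = (
        -lam.sum(axis=1)
        + special.xlogy(c, lam).sum(axis=1)
        - special.gammaln(c + 1.0).sum(axis=1)
    )
    ll = float(ll_units.sum())
    if not want_score:
        return ll, ll_units, None

    n, m = mu.shape
    q = X.shape[1]
    g_num = c / lam - 1.0
    gb = np.empty((n, m))
    gb[:, 0] = mu[:, 0] * (g_num[:, 0] - g_num[:, 1:].sum(axis=1))
    gb[:, 1:] = mu[:, 1:] * g_num[:, 1:]
    scores = (gb[:, :, np.newaxis] * X[:, np.newaxis, :]).reshape(n, m * q)
    return ll, ll_units, scores


def log_likelihood(theta: CoefficientSet, panel: CountPanel) -> float:
    """Total log-likelihood; a large negative penalty on infeasible regions."""
    if theta.gig is None:
        ll, _, _ = _mpr_kernel(panel, theta.betas, want_score=False)
    else:
        g = theta.gig
        ll, _, _ = _mcpgigr_kernel(
            panel, theta.betas, g.tau, g.xi, g.gamma_shape, want_score=False
        )
    return ll


def score(theta: CoefficientSet, panel: CountPanel) -> np.ndarray:
    """Per-observation score table, shape (n, dim theta).

    Columns follow [beta_jk row-major, ln tau, ln xi]; the dispersion pair is
    differentiated on the log scale, matching the internal optimization
    parameterization.  Raises on infeasible theta.
    """
    if theta.gig is None:
        ll, _, sc = _mpr_kernel(panel, theta.betas, want_score=True)
    else:
        g = theta.gig
        ll, _, sc = _mcpgigr_kernel(
            panel, theta.betas, g.tau, g.xi, g.gamma_shape, want_score=True
        )
    if sc is None:
        raise FeasibilityError("score requested at an infeasible parameter point")
    return sc


# ---------------------------------------------------------------------------
# Parameter packing for the optimizer
# ---------------------------------------------------------------------------

class _ModelSpec:
    """Maps between the flat optimizer vector and CoefficientSet, honoring a
    slope mask (intercepts are always free; masked slopes are pinned at 0)."""

    def __init__(self, m, q, gamma=None, slope_mask=None, mixed=True):
        self.m, self.q, self.gamma, self.mixed = m, q, gamma, mixed
        mask = np.ones((m, q), dtype=bool) if slope_mask is None else np.asarray(slope_mask, bool).copy()
        mask[:, 0] = True
        self.mask = mask
        self.n_beta = int(mask.sum())
        self.dim = self.n_beta + (2 if mixed else 0)

    def param_names(self):
        names = [
            f"beta_{j + 1}{k}" for j in range(self.m) for k in range(self.q) if self.mask[j, k]
        ]
        if self.mixed:
            names += ["log_tau", "log_xi"]
        return names

    def pack(self, coeffs: CoefficientSet) -> np.ndarray:
        theta = np.empty(self.dim)
        theta[: self.n_beta] = coeffs.betas[self.mask]
        if self.mixed:
            theta[self.n_beta] = np.log(coeffs.gig.tau)
            theta[self.n_beta + 1] = np.log(coeffs.gig.xi)
        return theta

    def unpack(self, theta: np.ndarray) -> CoefficientSet:
        betas = np.zeros((self.m, self.q))
        betas[self.mask] = theta[: self.n_beta]
        gig = None
        if self.mixed:
            gig = GIGParams(
                tau=float(np.exp(theta[self.n_beta])),
                xi=float(np.exp(theta[self.n_beta + 1])),
                gamma_shape=self.gamma,
            )
        return CoefficientSet(betas=betas, gig=gig)

    def _dispersion_out_of_bounds(self, theta) -> bool:
        return self.mixed and bool(np.any(np.abs(theta[self.n_beta:]) > 30.0))

    def loglik(self, theta, panel) -> float:
        if self._dispersion_out_of_bounds(theta):
            return _PENALTY * (1.0 + float(np.sum(theta[self.n_beta:] ** 2)))
        c = self.unpack(theta)
        if self.mixed:
            ll, _, _ = _mcpgigr_kernel(
                panel, c.betas, c.gig.tau, c.gig.xi, self.gamma, want_score=False
            )
        else:
            ll, _, _ = _mpr_kernel(panel, c.betas, want_score=False)
        return ll

    def loglik_score(self, theta, panel):
        if self._dispersion_out_of_bounds(theta):
            return _PENALTY, None
        c = self.unpack(theta)
        if self.mixed:
            ll, _, sc = _mcpgigr_kernel(
                panel, c.betas, c.gig.tau, c.gig.xi, self.gamma, want_score=True
            )
        else:
            ll, _, sc = _mpr_kernel(panel, c.betas, want_score=True)
        if sc is None:
            return ll, None
        if self.mixed:
            cols = np.concatenate(
                [np.flatnonzero(self.mask.ravel()), [self.m * self.q, self.m * self.q + 1]]
            )
        else:
            cols = np.flatnonzero(self.mask.ravel())
        return ll, sc[:, cols]


# ---------------------------------------------------------------------------
# BHHH optimizer
# ---------------------------------------------------------------------------

def _ridge_solve(H, g, trace_msgs, rcond=1e-12):
    """Solve H d = g for the BHHH direction.

    The OPG matrix can carry an exactly null eigendirection (the
    unidentified dispersion combination); those directions are truncated
    from the solve so rounding-level gradient components are not amplified
    into spurious steps.  A logged escalating ridge remains as the fallback
    when the eigendecomposition itself fails.
    """
    dim = H.shape[0]
    try:
        lam, V = linalg.eigh(H)
        lmax = lam[-1]
        if np.isfinite(lmax) and lmax > 0.0:
            keep = lam > rcond * lmax
            if not np.all(keep):
                trace_msgs.append(
                    f"truncated {int((~keep).sum())} near-null OPG direction(s)"
                )
            Vk = V[:, keep]
            d = Vk @ ((Vk.T @ g) / lam[keep])
            if np.all(np.isfinite(d)):
                return d, 0.0
    except linalg.LinAlgError:
        pass
    ridge = 0.0
    base = 1e-8 * np.trace(H) / dim if np.trace(H) > 0 else 1e-8
    for _ in range(24):
        ridge = base if ridge == 0.0 else ridge * 2.0
        trace_msgs.append(f"ridge-regularized OPG solve (ridge={ridge:.3e})")
        try:
            cf = linalg.cho_factor(H + ridge * np.eye(dim), lower=True)
            d = linalg.cho_solve(cf, g)
            if np.all(np.isfinite(d)):
                return d, ridge
        except linalg.LinAlgError:
            pass
    raise ConvergenceError("outer-product-of-gradients matrix could not be solved")


def bhhh_fit(
    panel: CountPanel,
    init: CoefficientSet,
    tol: float = 1e-7,
    max_iter: int = 500,
    slope_mask: Optional[np.ndarray] = None,
    ll_tol: float = 1e-8,
    rel_ll_tol: float = 1.5e-8,
) -> FitResult:
    """Maximize the log-likelihood by BHHH with monotone-ascent line search.

    The update is theta <- theta + t * (sum_i g_i g_i')^{-1} sum_i g_i with
    backtracking step t; iteration stops when ||theta_{t+1} - theta_t|| <= tol,
    when an accepted near-full step improves the log-likelihood by less than
    ``ll_tol`` absolutely or ``rel_ll_tol`` relatively (the flatness criteria
    standard BHHH implementations also apply), or after ``max_iter``
    iterations.  The mixing shape gamma is held fixed at
    ``init.gig.gamma_shape`` throughout.
    """
    mixed = init.gig is not None
    spec = _ModelSpec(
        panel.m,
        panel.p + 1,
        gamma=(init.gig.gamma_shape if mixed else None),
        slope_mask=slope_mask,
        mixed=mixed,
    )
    theta = spec.pack(init)
    ll, sc = spec.loglik_score(theta, panel)
    if sc is None:
        raise FeasibilityError("BHHH initialization is infeasible")

    trace = []
    converged = False
    iterations = 0
    for it in range(1, max_iter + 1):
        iterations = it
        msgs = []
        g = sc.sum(axis=0)
        H = sc.T @ sc
        d, ridge = _ridge_solve(H, g, msgs)
        gd = float(g @ d)
        if gd <= 0.0:  # OPG direction lost ascent; fall back to the gradient
            d = g / max(np.linalg.norm(g), 1.0)
            gd = float(g @ d)
            msgs.append("steepest-ascent fallback (OPG direction not an ascent)")

        step = 1.0
        accepted = False
        for _ in range(45):
            cand = theta + step * d
            ll_new = spec.loglik(cand, panel)
            if np.isfinite(ll_new) and ll_new >= ll + 1e-4 * step * gd:
                accepted = True
                break
            step *= 0.5
        if accepted:
            # one parabolic refinement along d: compare the accepted step with
            # its half and the interpolated vertex, keep the best likelihood
            ll_half = spec.loglik(theta + 0.5 * step * d, panel)
            cands = [(ll_new, step)]
            if np.isfinite(ll_half):
                cands.append((ll_half, 0.5 * step))
                denom = ll - 2.0 * ll_half + ll_new
                if denom < 0.0:  # concave fit along the segment
                    t_vert = 0.25 * step * (3.0 * ll - 4.0 * ll_half + ll_new) / denom
                    if 0.05 * step < t_vert < 4.0 * step:
                        ll_vert = spec.loglik(theta + t_vert * d, panel)
                        if np.isfinite(ll_vert):
                            cands.append((ll_vert, t_vert))
            if step == 1.0:
                ll_two = spec.loglik(theta + 2.0 * d, panel)
                if np.isfinite(ll_two):
                    cands.append((ll_two, 2.0))
            ll_new, step = max(cands)
        move = step * np.linalg.norm(d)
        if not accepted:
            if np.linalg.norm(g) <= 1e-6 * max(1.0, abs(ll)) or move <= tol:
                converged = True
                trace.append(
                    {"iter": it, "loglik": ll, "grad_norm": float(np.linalg.norm(g)),
                     "step": 0.0, "messages": msgs + ["stationary: no ascent step found"]}
                )
            else:
                trace.append(
                    {"iter": it, "loglik": ll, "grad_norm": float(np.linalg.norm(g)),
                     "step": 0.0, "messages": msgs + ["line search failed"]}
                )
            break

        ll_prev = ll
        theta = theta + step * d
        ll, sc = spec.loglik_score(theta, panel)
        trace.append(
            {"iter": it, "loglik": ll, "grad_norm": float(np.linalg.norm(g)),
             "step": step, "ridge": ridge, "messages": msgs}
        )
        dll = abs(ll - ll_prev)
        if move <= tol or (
            step >= 0.5 and (dll <= ll_tol or dll <= rel_ll_tol * (abs(ll) + ll_tol))
        ):
            converged = True
            break

    # covariance from the inverse accumulated OPG at the final point
    H = sc.T @ sc
    msgs = []
    dim = H.shape[0]
    ridge = 0.0
    base = 1e-8 * np.trace(H) / dim if np.trace(H) > 0 else 1e-8
    cov = None
    for _ in range(24):
        try:
            cf = linalg.cho_factor(H + ridge * np.eye(dim), lower=True)
            cov = linalg.cho_solve(cf, np.eye(dim))
            break
        except linalg.LinAlgError:
            ridge = base if ridge == 0.0 else ridge * 2.0
            msgs.append(f"covariance ridge {ridge:.3e}")
    if cov is None:
        raise ConvergenceError("information matrix is not invertible at the optimum")
    cov = 0.5 * (cov + cov.T)
    if msgs:
        trace.append({"iter": iterations, "loglik": ll, "messages": msgs})

    est = spec.unpack(theta)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    if mixed:  # delta method back to the natural tau/xi scale
        se = se.copy()
        se[spec.n_beta] *= est.gig.tau
        se[spec.n_beta + 1] *= est.gig.xi
    return FitResult(
        estimates=est,
        loglik=ll,
        covariance=cov,
        se=se,
        param_names=spec.param_names(),
        iterations=iterations,
        converged=converged,
        trace=trace,
        n_obs=panel.n,
        model="MCPGIGR" if mixed else "MPR",
        slope_mask=spec.mask,
    )


# ---------------------------------------------------------------------------
# Initialization and front-end fits
# ---------------------------------------------------------------------------

def _poisson_glm_init(panel: CountPanel, slope_mask: np.ndarray) -> np.ndarray:
    """Separate Poisson GLMs with log-exposure offset, one per response."""
    import statsmodels.api as sm

    X = panel.design_matrix
    betas = np.zeros((panel.m, panel.p + 1))
    for j in range(panel.m):
        y = panel.responses[:, j]
        off = np.log(panel.exposures[:, j])
        cols = np.flatnonzero(slope_mask[j])
        try:
            res = sm.GLM(y, X[:, cols], family=sm.families.Poisson(), offset=off).fit()
            if not np.all(np.isfinite(res.params)):
                raise ValueError("non-finite GLM estimates")
            betas[j, cols] = res.params
        except Exception:
            mean_rate = (y.sum() + 0.5) / panel.exposures[:, j].sum()
            betas[j, 0] = np.log(mean_rate)
    return betas


def _tau_moment_init(panel: CountPanel) -> float:
    """Method-of-moments excess-dispersion summary, floored at 0.1."""
    y = panel.responses.astype(float)
    means = y.mean(axis=0)
    varis = y.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        excess = (varis - means) / np.maximum(means, 1e-12) ** 2
    val = float(np.nanmean(excess))
    return max(val, 0.1)


def _repair_feasibility(panel: CountPanel, betas: np.ndarray) -> np.ndarray:
    """Lower the shock intercept until mu_ij > mu_i1 holds everywhere."""
    betas = betas.copy()
    X = panel.design_matrix
    for _ in range(60):
        mu = panel.exposures * np.exp(np.clip(X @ betas.T, -700, 700))
        if np.all(mu[:, 1:] > mu[:, [0]]):
            return betas
        betas[0, 0] -= 0.5
    raise FeasibilityError(
        "could not find a feasible starting point: the shock component mean "
        "cannot be made smaller than every other component mean"
    )


def initialize(panel: CountPanel, gamma: float = -0.5,
               slope_mask: Optional[np.ndarray] = None) -> CoefficientSet:
    """Starting values: separate Poisson GLMs for the betas, xi = 1, and a
    moment-based excess-dispersion value for tau (floored at 0.1)."""
    mask = np.ones((panel.m, panel.p + 1), dtype=bool) if slope_mask is None \
        else np.asarray(slope_mask, bool).copy()
    mask[:, 0] = True
    betas = _poisson_glm_init(panel, mask)
    betas = _repair_feasibility(panel, betas)
    gig = GIGParams(tau=_tau_moment_init(panel), xi=1.0, gamma_shape=float(gamma))
    return CoefficientSet(betas=betas, gig=gig)


def _profile_tau_start(panel: CountPanel, init: CoefficientSet) -> CoefficientSet:
    """Replace the moment-based tau start by a coarse 1-D likelihood profile.

    The excess-dispersion summary estimates Var(nu)/E(nu)^2, not tau itself,
    so it can start BHHH far along the (tau, xi) likelihood ridge and let xi
    wander during the long walk back.  A cheap grid profile of the
    log-likelihood over tau (xi held at its starting value, betas at their
    GLM values) lands the optimizer near the identified w(tau, xi) optimum
    before the first BHHH step.
    """
    g = init.gig
    grid = np.unique(np.concatenate([np.geomspace(0.05, 50.0, 25), [g.tau]]))
    best_tau, best_ll = g.tau, -np.inf
    for t in grid:
        ll, _, _ = _mcpgigr_kernel(
            panel, init.betas, t, g.xi, g.gamma_shape, want_score=False
        )
        if ll > best_ll:
            best_ll, best_tau = ll, t
    return CoefficientSet(
        betas=init.betas,
        gig=GIGParams(tau=float(best_tau), xi=g.xi, gamma_shape=g.gamma_shape),
    )


def fit_mcpgigr(
    panel: CountPanel,
    gamma: float = -0.5,
    init: Optional[CoefficientSet] = None,
    tol: float = 1e-7,
    max_iter: int = 500,
    slope_mask: Optional[np.ndarray] = None,
    profile_tau: bool = True,
) -> FitResult:
    """Fit the MCPGIGR model at a fixed half-integer shape gamma."""
    if init is None:
        init = initialize(panel, gamma=gamma, slope_mask=slope_mask)
        if profile_tau:
            init = _profile_tau_start(panel, init)
    return bhhh_fit(panel, init, tol=tol, max_iter=max_iter, slope_mask=slope_mask)


def mpr_fit(
    panel: CountPanel,
    tol: float = 1e-7,
    max_iter: int = 500,
    slope_mask: Optional[np.ndarray] = None,
) -> FitResult:
    """Fit the common-shock multivariate Poisson regression baseline."""
    mask = np.ones((panel.m, panel.p + 1), dtype=bool) if slope_mask is None \
        else np.asarray(slope_mask, bool).copy()
    mask[:, 0] = True
    betas = _repair_feasibility(panel, _poisson_glm_init(panel, mask))
    init = CoefficientSet(betas=betas, gig=None)
    return bhhh_fit(panel, init, tol=tol, max_iter=max_iter, slope_mask=slope_mask)


def standard_errors(fit: FitResult) -> np.ndarray:
    """Standard errors from the inverse accumulated OPG matrix (natural scale
    for tau and xi via the delta method)."""
    if not fit.converged:
        raise ConvergenceError("standard errors requested from a non-converged fit")
    diag = np.diag(fit.covariance)
    if np.any(diag <= 0.0):
        k = int(np.argmin(diag))
        raise ConvergenceError(
            f"information matrix not positive definite along '{fit.param_names[k]}'"
        )
    return fit.se
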