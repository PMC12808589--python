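# mcpgig — multivariate correlated Poisson–GIG regression

Count outcomes observed jointly on the same units — deaths from related
causes across districts, claim counts of different types per policyholder,
crash types per road segment — are typically both **overdispersed** (variance
above the Poisson mean) and **positively correlated** across outcomes.
`mcpgig` implements a regression family built for exactly this situation:
the multivariate correlated Poisson generalized inverse Gaussian regression
(MCPGIGR), together with its distribution theory, maximum-likelihood
estimation, hypothesis tests and a simulation harness.

## The model

Dependence comes from a **common shock**: with independent Poisson variables
Z₁,…,Z_m of rates λ₁,…,λ_m,

    Y₁ = Z₁,   Y_j = Z₁ + Z_j   (j = 2,…,m),

so every response shares the latent component Z₁ and the support obeys
y_j ≥ y₁. Overdispersion comes from a **GIG frailty**: a single positive
multiplier ν per unit scales all rates, ν ~ GIG(τ, ξ, γ) with density

    g(ν) ∝ ν^{γ−1} exp(−(ϖ/2)(ν/ξ + ξ/ν)),   ϖ = √(τ²+ξ²) − ξ.

Integrating the common-shock Poisson kernel against g gives the MCPGIG pmf
in closed form through modified Bessel functions K; the workhorse quantity
is the Bessel ratio R_γ(ϖ) = K_{γ+1}(ϖ)/K_γ(ϖ), with E(ν) = ξR_γ(ϖ).

The regression attaches an exposure-adjusted log link per response,

    E(Y_ij) = q_ij · exp(x_iᵀ β_j),

inverts it to the underlying rates (component 1 is the shock), and maximizes
the resulting likelihood by **BHHH** — Newton steps with the Hessian replaced
by the sum of per-observation score outer products, a monotone-ascent line
search, and the stopping rule ‖θ⁽ᵗ⁺¹⁾ − θ⁽ᵗ⁾‖ ≤ 10⁻⁷. The shape γ is a fixed
half-integer setting (−1/2, −3/2, −5/2), chosen between by AICc. Simultaneous
slope significance uses G² = 2(lnL_full − lnL_null) against χ² with p·m
degrees of freedom; coefficient-wise tests use Wald Z = β̂/SE(β̂).

One structural fact worth knowing before reading any output: after the rate
inversion, ξ cancels from the likelihood, so (τ, ξ) are identified **only
through ϖ**. Estimates of τ and ξ individually therefore depend on where the
optimizer starts (ξ conventionally starts at 1); ϖ, the fit, the slopes and
all tests are unaffected. See `docs/methods.md` for the full account.

## Worked example

`python examples/02_fit_synthetic_panel.py` simulates one n=300 panel at the
built-in study truth (β₁ = [−5, −0.05, 0.4] for the shock component,
β₂ = [1, 0.07, 0.05], τ = 0.5, ξ = 1, γ = −1/2, two U(0,10) predictors) and
prints:

```
response means [0.083 4.64 ], variances [1.0000e-01 1.2896e+02] (heavy overdispersion)

MCPGIGR: converged=True in 25 iterations, loglik=-725.25
 parameter     true  estimate       se
   beta_10   -5.000    -4.035    0.992
   beta_11   -0.050    -0.022    0.115
   beta_12    0.400     0.283    0.157
   beta_20    1.000     1.492    0.371
   beta_21    0.070     0.046    0.043
   beta_22    0.050    -0.039    0.044
       tau    0.500     0.497
        xi    1.000     1.002

MPR baseline: loglik=-2249.93
AICc: MCPGIGR 1467.00  vs  MPR 4512.15
```

Single-draw estimates scatter around the truth within their standard errors
(the shock component, with mean counts near 0.08, is the noisy block), and
the AICc gap of ~3000 points shows how badly an unmixed multivariate Poisson
fit misrepresents data whose variance is ~28× the mean. Averaged over
replications the estimates centre on the truth — run
`examples/04_recovery_study.py`.

The other examples cover the pmf against its quadrature oracle (`01`),
MLRT/Wald testing (`03`), and the CSV/CLI workflow (`05`). A thin CLI wraps
the same calls: `mcpgig fit|test|simulate|aicc|pmf|critical --help`.

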