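# Methods

## Model

For unit i = 1,…,n the m count responses are built in two layers.

**Common-shock kernel.** Independent Poisson draws Z_{i1},…,Z_{im} with rates
λ_{i1},…,λ_{im} are combined as Y_{i1} = Z_{i1}, Y_{ij} = Z_{i1} + Z_{ij}
(j ≥ 2). The shared term induces Cov(Y_{ij}, Y_{ik}) = λ_{i1} > 0 and
restricts the support to y_{ij} ≥ y_{i1}. The construction cannot produce
negative correlation; that is a modelling assumption, not a software limit.

**GIG frailty.** A unit-level multiplier ν_i scales every rate,
ν_i ~ GIG(τ, ξ, γ) with density
ξ^{−γ}/(2K_γ(ϖ)) · ν^{γ−1} exp(−(ϖ/2)(ν/ξ + ξ/ν)) and ϖ = √(τ²+ξ²) − ξ.
In the classical two-parameter GIG(p, a, b) notation this is p = γ,
a = ϖ/ξ, b = ϖξ, which immediately gives E(ν^k) = ξ^k K_{γ+k}(ϖ)/K_γ(ϖ) and
the Laplace transform used as an independent oracle in the tests.

Integrating the kernel against the frailty density (standard GIG integral
identity) yields the closed-form mixed pmf

P(y) = ξ^{−γ}/K_γ(ϖ) · λ₁^{y₁}/y₁! · ∏_{j≥2} λ_j^{y_j−y₁}/(y_j−y₁)!
· (ϖξ²/ψ)^{(Y+γ)/2} · K_{Y+γ}(√(ψϖ)),

with total count Y = y₁ + Σ_{j≥2}(y_j − y₁) and ψ = 2ξΣ_j λ_j + ϖ. A single
Bessel factor of order Y+γ appears — not one per component. The
implementation is required by its test suite to agree with the brute-force
quadrature mixture to 1e−8 relative error, so the algebra is pinned by the
integral, not by transcription.

Moments follow from the mixed-Poisson law of total variance with effective
rate Λ_j (Λ₁ = λ₁, Λ_j = λ₁ + λ_j): E(Y_j) = ξR_γ(ϖ)Λ_j and
Var(Y_j) = E(Y_j) + Λ_j² Var(ν), Var(ν) = ξ²(K_{γ+2}/K_γ − R_γ²). Any
variance formula that is negative for E > 1 is wrong on its face; this one
is validated against Monte Carlo in the tests.

## Regression

E(Y_{ij}) = q_{ij} exp(x_iᵀβ_j) with known exposures q and the first
response column as the shock. Rates are recovered as
λ_{i1} = μ_{i1}/(ξR_γ(ϖ)) and λ_{ij} = (μ_{ij} − μ_{i1})/(ξR_γ(ϖ)), so the
moment identity returns μ exactly. Feasibility requires μ_{ij} ≥ μ_{i1};
trial points violating it (or with |linear predictor| > 60) receive a large
smooth penalty so the line search can retreat rather than crash. Which
column plays the shock is a user choice (`--shock-response` in the CLI);
the model is symmetric in the remaining components.

### Identifiability of (τ, ξ)

Substituting the rate map into the pmf cancels ξ completely: writing
a_j = (μ-difference)_j / R_γ(ϖ), the per-unit log-likelihood is

ℓ = −ln K_γ(ϖ) + Σ_j c_j ln a_j + ((Y+γ)/2)(ln ϖ − ln ψ) + ln K_{Y+γ}(√(ψϖ)),
ψ = 2Σ_j a_j + ϖ,

a function of β and ϖ(τ, ξ) only. Consequences, all deliberate:

- τ and ξ are reported individually (ξ starts at 1 by convention, τ from its
  initialization path below), but only ϖ is estimable. Reported (τ̂, ξ̂)
  pairs should be read as a point on the ridge {(τ,ξ): ϖ(τ,ξ) = ϖ̂}.
- The per-observation scores for (ln τ, ln ξ) are exactly proportional to a
  common vector, so the OPG matrix has an exact null eigendirection confined
  to the dispersion block. The BHHH solver truncates numerically-null
  directions (relative cutoff 1e−12) before inverting, with an escalating
  logged ridge as fallback; because the null direction has no slope
  component, slope standard errors are unaffected, while the reported
  dispersion standard errors are large — an honest statement of
  non-identification, not a numerical bug.
- Model fit, AICc, MLRT and Wald tests depend only on identified quantities.

## Estimation

**Initialization.** β_j from m separate Poisson GLMs with offset ln q_j
(statsmodels); an all-zero response column falls back to zero slopes with
intercept ln(mean/exposure-mean). ξ⁽⁰⁾ = 1. τ⁽⁰⁾ starts from the
excess-dispersion summary mean_j[(s_j² − ȳ_j)/ȳ_j²] floored at 0.1 — the
same relative-excess-variance statistic practitioners quote for such data —
but that summary estimates Var(ν)/E(ν)², not τ, so the fitter refines it by
a coarse likelihood profile over a 25-point log-grid τ ∈ [0.05, 50] (β and ξ
held at their starts) before the first BHHH step. The profile costs ~25
likelihood evaluations and starts the optimizer near the identified ϖ
optimum, which both speeds convergence and keeps ξ̂ from drifting along the
ridge during a long initial descent. If the shock GLM start violates
feasibility, its intercept is lowered in 0.5 steps until μ_1 is smallest.

**BHHH.** Update θ ← θ + t·(Σᵢ gᵢgᵢᵀ)⁻¹ Σᵢ gᵢ with analytic per-observation
scores; the Bessel derivative identity ∂K_γ(ϖ)/∂ϖ = (γ/ϖ)K_γ − K_{γ+1}
supplies every dispersion derivative, and the chain rule through
(μ, ϖ, ψ, u=√(ψϖ)) gives the slope block. Scores are verified against
central finite differences at 1e−5 relative in the suite. (τ, ξ) are
optimized as (ln τ, ln ξ) to enforce positivity; γ is never updated.

The line search backtracks from t = 1 (halving, Armijo 1e−4) and then
refines the accepted step by one parabolic interpolation along the
direction, also probing t = 2; every accepted step increases the
log-likelihood, so the iteration trace is monotone by construction.

**Stopping.** Convergence is declared when ‖θ⁽ᵗ⁺¹⁾ − θ⁽ᵗ⁾‖ ≤ 1e−7, or when
an accepted near-full step improves the log-likelihood by less than 1e−8
absolutely or 1.5e−8 relatively — the same flatness criteria standard BHHH
implementations (e.g. R's maxLik) apply. Without them, rounding-level
gradient components along the exact-null ridge direction keep the parameter
change above any tolerance indefinitely while the likelihood is flat to
1e−9. At the default study conditions fits converge in ≈6–25 iterations.

**Covariance.** Cov(θ̂) = (Σᵢ gᵢgᵢᵀ)⁻¹ at the optimum; natural-scale
standard errors for τ, ξ by the delta method. Non-invertibility raises,
naming the offending direction.

**MPR baseline.** The unmixed common-shock multivariate Poisson regression
(λ = μ-differences directly) shares the same BHHH machinery and serves as
initialization source and AICc comparator; it is the degenerate-mixing limit
of the mixture (τ → ∞ collapses ν to a constant).

## Inference

- MLRT: G² = 2(lnL_full − lnL_intercepts-only), df = p·m (intercepts and
  dispersion free under both hypotheses; nothing sits on a parameter
  boundary, so no mixture-chi-square correction applies). Small negative G²
  (< 1e−6 in magnitude) is clipped with a warning; anything more negative
  raises as an optimizer failure.
- Wald: Z = β̂/SE(β̂) against N(0,1), two-sided.
- AICc = −2lnL + 2P + 2P(P+1)/(n−P−1) with P the TOTAL free-parameter count
  (m(p+1)+2 for MCPGIGR with fixed γ; m(p+1) for MPR). Counting only
  predictors would give both models the same penalty and defeat the
  comparison.

## Simulation harness

The generator reproduces the reference study design: m=2 responses,
β₁ = [−5, −0.05, 0.4], β₂ = [1, 0.07, 0.05], τ = 0.5, ξ = 1, γ fixed at a
chosen half-integer, predictors iid U(0,10), exposures 1, n ∈ {100, 300},
500 replications by default (the acceptance script uses 100, and the
examples 25, to keep desk runtimes in seconds; Monte-Carlo standard errors
accompany every mean so the precision of any run is explicit). Replication
seeds spawn deterministically from one master seed.

At this truth the mixing is strong — Var(ν) = ξ²(K_{γ+2}/K_γ − R²) ≈ 8.5 at
γ = −1/2 — so component 2 has variance ≈25–30× its mean and component 1 has
mean counts near 0.08. The shock block (β₁) is therefore intrinsically
noisy at n = 300; its replication means centre on the truth but single-draw
estimates scatter widely. The type-I-error study uses intercept-only truth
β₀ = (−2, 1): non-degenerate counts in both components at n = 300, unlike
the −5 intercept of the recovery design, which would zero out the first
response in a sizeable fraction of replicates and confound the calibration
target with boundary effects.

What passing simulations do **not** show: robustness to misspecified mixing
(only MP-vs-MCPGIG switches are exercised), negative cross-response
dependence (impossible in this family), real-exposure heterogeneity
(exposures are 1 in the study design), or covariate distributions beyond
independent uniforms.

## Numerical choices

- All Bessel work is log-domain: `kve` (exponentially scaled) where finite,
  a stable upward order recurrence in logs for large order at small
  argument, and the large-argument asymptotic series where `kve` itself
  overflows (arguments beyond ~1e9). Ratios are formed as differences of
  log-K. Verified against exact half-integer closed forms across order up to
  300 and argument 1e−6…1e4.
- ϖ is computed as τ²/(√(τ²+ξ²)+ξ) to avoid cancellation at small τ.
- Pmf normalization tests pick the truncation radius from the mixture's
  geometric tail ratio r = 2ξΣλ/ψ (radius = log(ε(1−r))/log r), because the
  GIG mixture tail decays slowly (r ≈ 0.97 at the study parameters) and a
  moment-based radius is insufficient.
- GIG sampling delegates to `scipy.stats.geninvgauss` (p=γ, b=ϖ, scale=ξ);
  the package's own density/moment code cross-checks it in the tests.
- Quadrature oracles integrate the mixing integral with `scipy.integrate.quad`,
  split at the mixing scale, and raise if the estimated error exceeds 1e−6
  relative.
- Dispersion coordinates are bounded at |ln τ|, |ln ξ| ≤ 30; beyond that the
  mixing law is degenerate or overflows, and the likelihood treats such trial
  points as penalized infeasible regions. On equidispersed data the τ̂ path
  runs toward this boundary (degenerate mixing is the truth there) and stops
  on likelihood flatness.

## Known limitations

- τ and ξ are not separately identified (see above); only ϖ is.
- The common-shock design forces E(Y₁) ≤ E(Y_j) at feasible parameters;
  datasets where no response column can play the small-mean shock role are
  rejected at initialization.
- The MLRT calibration band was checked at n = 300; at n = 100 finite-sample
  size inflation is expected and is reported, not asserted.
- Estimating γ continuously is out of scope by design; it is a fixed
  half-integer compared by AICc.
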