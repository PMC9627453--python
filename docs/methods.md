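# Methods

## Model

The package implements the superstatistical fractional Brownian motion (fBm)
for one-dimensional single-particle-tracking data. Each trajectory is

    X_t = √λ · B_t^H,

with B^H a standard fBm (zero mean, Var B_t = t^(2H), covariance
½(s^(2H) + t^(2H) − |t−s|^(2H))) and λ a per-particle random diffusion scale
following the generalized Gamma law f(λ; λ₀, ν, ρ). The assumptions are:
trajectories are independent; each particle keeps one scale for its whole
observation window (quenched heterogeneity, no diffusing diffusivity); the
motion is unconfined, driftless and 1-D. Conditional on λ the displacement
is Gaussian with variance 2λt^(2H); marginally it is the Gaussian mixture
P(x;t), which evaluates in closed form through the Krätzel function and
solves a fractional diffusion equation of Erdélyi–Kober (EK) type with
time-dependent coefficient 2Hλ₀t^(2H−1). Heterogeneity enters only through
the time operator (a memory kernel in the flux); the space operator remains
∂²/∂x², so the equation stays linear and parabolic.

Two parameter conventions coexist. All analytic formulas are written in the
scale variable λ (the variance scale of the Gaussian kernel). Tracking
studies report the amplitude Y = √λ, whose law is the generalized Gamma with
doubled shape exponents and square-rooted scale — Weibull(√λ₀, 2ρ) in the
calibrated case. The package stores λ internally and exposes the amplitude
convention only at the simulator/inference boundary (`amplitude_law`,
`FitResult.shape_amplitude`).

## Parameters

| parameter | meaning | units | calibrated preset |
|---|---|---|---|
| H | Hurst exponent, MSD ~ t^(2H) | — | 0.35 (2H = 0.70) |
| λ₀ | diffusivity-population scale | length²/time^(2H) | 0.0036 (√λ₀ = 0.06) |
| ν | population power-law shape | — | 0.92 |
| ρ | population stretching exponent | — | 0.92 (2ρ = 1.84) |

The preset `golding-cox` carries the calibrated Weibull case (ν = ρ). The
Weibull flag uses a strict relative tolerance of 1e−12 because the Weibull
specialization changes which fractional equation applies; near-misses should
be treated as the general case, explicitly.

## Special functions

**Krätzel Z_ρ^ν(u).** Adaptive quadrature (QUADPACK) after splitting the
domain at the integrand mode, found by a bracketed root of the log-integrand
stationarity condition; the integrand is scaled by its peak value to avoid
under/overflow. Relative accuracy ~1e−8; validated against the Bessel
identity Z₁^ν(u) = 2u^(ν/2)K_ν(2√u) and a 2-million-point trapezoid oracle.

**M-Wright M_β(z).** The alternating series Σ(−z)ⁿ/(n!Γ(1−β−nβ)) is summed
in mpmath arbitrary precision with working digits grown like
0.5z + 0.5(1−β)z^(1/(1−β)) (the cancellation magnitude), stopping after five
consecutive negligible terms. β = ½ dispatches to the exact Gaussian form
exp(−z²/4)/√π. Once the leading decay exponent (1−β)β^(β/(1−β))·z^(1/(1−β))
exceeds 700 the value underflows float64 and 0.0 is returned instead of
summing an astronomically cancelling series; this caps the working precision
near 1000 digits.

**Mellin–Barnes route.** The rescaled density P(u) is also computed as a
vertical-contour integral with kernel Γ(s)·Γ((s + ν − ½)/ρ), contour
Re(s) = max(0, ½−ν) + ½ (strictly right of both pole ladders, checked
explicitly), truncated at |Im s| = T with T doubled until the endpoint
integrand is below 1e−12 (the kernel decays like exp(−π(1+1/ρ)|Im s|/2)).
This route shares no code with the Krätzel quadrature and serves as its
oracle; the two agree to ~1e−6 over u ∈ [1e−6, 50].

**Normalization convention for P(u).** Folding x onto u = x²/(4λ₀t^(2H))
maps both signs of x to one u, so the symmetric half-line collapse
(4πu)^(−1/2)Z(u)·ρ/Γ(ν/ρ) carries mass ½. `pdf_u` and
`mellin_barnes_density` return twice that value — the properly normalized
density of the random variable u. Slopes and shapes are unaffected.

## Fractional operators

The EK derivative is *defined* here by its Mellin multiplier — on powers,
D_η^(γ,μ) t^c = [Γ(1+γ+μ+c/η)/Γ(1+γ+c/η)] t^c — and *implemented* by the
classical factorization: the EK fractional integral of order n−μ (σ-kernel
on [0,1] with the (1−σ)^(n−μ−1) endpoint singularity folded into QUADPACK's
algebraic weight, and σ^γ likewise when γ > −1) followed by n Euler factors
(γ+j+(1/η)t d/dt), n = ⌈μ⌉, with Richardson-extrapolated central
differences (step max(1e−4·t, 1e−6)). The implementation is validated
against the multiplier on 20 random (γ, μ, η, c) tuples to 1e−6.

The Riemann–Liouville derivative of order μ ∈ (0,1] is d/dt of the
order-(1−μ) fractional integral, same quadrature treatment; orders above 1
are out of scope. The EK→RL reduction at η=1, γ=0 has two candidate
bracketings (with and without a t^(−μ) prefactor on the RL term);
`ek_rl_reduction_check` scores both against the multiplier and confirms
D₁^(0,μ)φ = D_RL^μ[t^μ φ] — the reading without the prefactor — which the
RL-form equation check then uses. Time profiles entering these operators
declare their power behaviour at t→0⁺ so the kernel quadrature can verify
integrability; the weighted rule may probe s = 0 exactly, which is floored
at t·1e−14.

## Equation verification

Each density/equation pair is checked on an interior grid
x ∈ {±0.2, ±0.6, ±1.2}·σ(t), t ∈ {0.5, 1, 2, 4} — avoiding x = 0 (cusp or
integrable singularity of the mixture density for ν ≤ ½) and the t→0 delta
initial layer, which is never evaluated. The time derivative is a
Richardson-extrapolated central difference; space derivatives of the
superstatistical density use the exact Krätzel recurrence
dZ_ρ^ν/du = −Z_ρ^(ν−1), while the M-Wright densities use five-point central
differences in x. The fractional right-hand side is evaluated two ways:
the exact parameter-shift route (the EK image of the family equals
Γ((ν+1)/ρ)/Γ(ν/ρ) times the ν→ν+1 member — this is the identity that makes
the equation hold) and the general numeric EK operator; their agreement on
the same grid ties solution-correctness to operator-correctness. Reports
carry residual norms at two derivative steps; shift-route residuals sit at
~1e−11, numeric-EK at ~1e−6, RL/CTRW/ggBm at 1e−6–1e−3, all at least 10×
below their negative controls (perturbed coefficient or mismatched density).
Residual pairs below 1e−8 are at the quadrature floor, where the refinement
comparison is reported but not informative.

The flux q = −2Hλ₀t^(2H−1)·EK[∂P/∂x] uses the shift route; continuity
∂P/∂t = −∂q/∂x is verified to ~1e−8 and total mass conservation to 1e−5.

## Simulator

fBm increments are generated by circulant embedding of the Toeplitz
increment covariance (Davies–Harte/Dietrich–Newsam): the embedding spectrum
is computed once per (n, H, dt), complex Gaussian spectral noise with
Hermitian endpoint handling is shaped and inverse-FFT'd, and the first n
increments are cumulated. The method is exact in distribution and O(n log n).
For H near 1 the embedding can fail positive-definiteness; a Cholesky
factorization fallback (capped at 2^13 steps) covers that corner. Standard
fBm (Var = t^(2H)) with amplitude √(2λ) is used rather than a kernel with a
built-in factor 2, so Var(X_t|λ) = 2λt^(2H) exactly matches the Gaussian
kernel; the choice is tested, not assumed.

All randomness flows from one master `SeedSequence`: one child stream for
the population draw, one per trajectory, so enlarging an ensemble never
perturbs earlier trajectories. TA-MSD uses overlapping windows (maximal data
use, the common SPT convention). Per-trajectory rescaling divides by
√TA-MSD at a reference lag of 10 steps (configurable), normalized by the
ensemble median; by construction the scatter at the reference lag collapses,
and the single-time marginal moves toward Gaussian (measured as ≥50% excess
kurtosis reduction).

What the generator emulates: the calibrated experimental setting —
ensembles of 21–1000 trajectories of a few hundred to a few thousand
uniformly sampled points, Weibull-distributed diffusivity amplitudes,
subdiffusive TA-MSD with large scatter. What it does not: localization
noise, blinking, drift, confinement, 2-D/3-D projection, finite exposure
time. Passing tests therefore demonstrate internal consistency of model,
equations and estimators, not robustness to those experimental artefacts.

## Inference

Stage 1: Ĥ is half the OLS slope of log ensemble-mean TA-MSD against log
lag on a geometric grid in [2, n/10] steps (defaults; lower cutoff skips the
single-step lag, upper stays inside the window). Amplitudes multiply the
TA-MSD, so heterogeneity shifts the intercept, not the slope. Stage 2:
per-trajectory λ̂ᵢ by through-origin regression of TA-MSD_i on 2Δ^(2Ĥ) over
a *short* lag window [2, min(64, n/10)] — the basis grows as Δ^(2H) while
the TA-MSD variance grows with Δ/T, so long lags add weight and noise
simultaneously; the short window keeps the homogeneous-control CV under 10%
at 2^12 steps. Stage 3: Weibull MLE on the amplitudes √λ̂ᵢ by profile
likelihood (scale has a closed form at fixed shape; the profiled score is
solved by brentq), with gengamma/Gamma/exponential alternatives via scipy
and AIC ranking. Uncertainties are trajectory-level bootstrap (200 resamples
by default, seeded).

Known limitations, stated rather than corrected: estimation noise in λ̂
broadens the apparent population and biases the fitted shape downward by
~3–4% at 2^10 steps (no deconvolution is applied); the Weibull shape MLE is
biased upward by ~8% at the 21-trajectory scale of the benchmark dataset
(measured by Monte Carlo in the tests); the amplitude estimator is this
package's design decision, not a reconstruction of any published estimator.

## Problem sizes

Default verification grids use 4–24 (x,t) points (the M-Wright-based checks
use 1–2 points, as each EK/RL application costs thousands of special-function
evaluations). Simulation-based tests use 200–500 trajectories of 2^10–2^12
steps; the end-to-end recovery benchmark uses 500 trajectories of 1024 steps,
where the ±10% population-recovery band corresponds to roughly three standard
errors of the Weibull-shape MLE.
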