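# Methods

## The estimators

Let `F = {f_θ : θ ∈ Θ}` be a parametric family on a common support and
`g` an arbitrary density. The minimum-Hellinger functional is

    T(g) = argmin_θ h(f_θ, g),     h²(f, g) = 2 − 2 ∫ √(f g) dx.

Given i.i.d. data `X = (X_1 … X_n)` and a nonparametric prior `π` on
densities, the package computes

* **MHB**: `θ̂ = T(g*_n)` with `g*_n = ∫ g π(dg | X)` the expected a
  posteriori density;
* **BMH**: the pushforward posterior `π(θ | X) = π(T(g) | X)`, realised by
  applying `T` to each posterior density draw and summarised by the draw
  mean (EAP) and per-coordinate sd.

Minimising `h` is equivalent to maximising the affinity `∫ √(f_θ g)`,
which is how the optimiser is implemented (the identity
`h² = 2 − 2·affinity` is exact in the results). `T` may be multi-valued;
the search is multi-start Nelder–Mead (moment-matched, robust
median/IQR, and mid-window starts, plus warm starts across BMH draws with
one fresh start per draw to avoid mode-locking), all local optima are
reported, and ties within 1e−8 in distance are broken by the
lexicographically smallest θ so results are deterministic.

Built-in families: univariate normal `(μ, σ)` (σ a standard deviation,
not a variance) and bivariate normal `(μ1, μ2, Σ11, Σ12, Σ22)`, optimised
internally in Cholesky coordinates so every iterate has a positive
definite covariance. Parameter intervals are open; the optimiser clamps
iterates to the bounds minus a 1e−8 margin. For theory-style compactness
arguments an `arctan` reparametrisation (`compactify`) embeds unbounded
parameter spaces in a bounded rectangle; by default optimisation runs in
the original coordinates with box bounds, which is equivalent in practice.

## Efficiency machinery

With `s_θ = √f_θ` and its parameter derivatives `ṡ, s̈`, the package
computes

* Fisher information `I(θ) = 4 ∫ ṡ ṡᵀ dx` (closed forms for the built-in
  normals, quadrature otherwise);
* the efficient influence function at `g0` with `θ = T(g0)`:
  `T̃(x) = −[∫ s̈ √g0 dx]^{-1} · ṡ(x) / (2 √g0(x))`, the vanishing
  remainder term set to zero (exact at `g0 = f_θ`, where `T̃` reduces to
  `I(θ)^{-1}` times the score);
* the centred `L²(g0)` norm `‖f‖_L² = ∫ (f − ∫ f g0)² g0`, satisfying
  `‖T̃‖_L² = I(θ)^{-1}` at the model — the optimal asymptotic variance.

The Bernstein–von-Mises diagnostic compares the BMH posterior with this
limit: sd ratio `post_sd / √(diag I(θ̂)^{-1} / n)` against a default pass
band `[0.7, 1.4]`, plus a per-coordinate one-sample Kolmogorov–Smirnov
test of the draws against `N(eap, post_sd²)` with p-value floor 0.01 (KS
chosen for having no tuning parameters; no multiple-testing correction —
at most two coordinates are in scope). The theoretical centring (an
unobservable efficient one-step estimator) is replaced by the EAP, the
standard practice.

## Random histogram prior

Densities on `[0,1]` of the form `k Σ_j ω_j 1{I_j}` with
`I_j = [(j−1)/k, j/k)` (last bin right-closed) and
`ω ~ Dirichlet(α_1 … α_k)`. The likelihood is multinomial in `ω`, so the
posterior is `Dirichlet(α + counts)` with marginal likelihood
`k^n B(α+counts)/B(α)`; the expected posterior density has bin heights
`k (α_j + n_j)/(Σα + n)` exactly, and density draws are Dirichlet draws.
`k` carries either a Dirac prior or a pmf with sub-exponential tails
(default: zero-truncated Poisson(10) restricted to
`{1 … ⌊n/(log n)²⌋}`).

Real-line data are carried to `[0,1]` by an affine map covering the data
range with 5% padding per side (configurable); all Hellinger computations
happen on the original scale with the Jacobian applied, and Hellinger
distance is affine-invariant so the map choice is immaterial beyond
coverage.

Defaults and their rationale:

* `α_j = 1` (uniform Dirichlet — least informative within the standard
  bracket). **Caveat**: with `k` comparable to or larger than `n` this
  adds `k` pseudo-counts and the prior dominates; the 66-point / k=100
  demonstration therefore uses `α_j = 1/k` (one pseudo-observation in
  total). A warning fires whenever `Σα > n/10`.
* The asymptotically efficient bin rate `K_n = √n (log n)^{-2}` is below
  1 for any practical `n`; it is clamped to 1 with a warning, and
  simulation-scale work uses the Rice rule `practical_k(n) = 2 n^{1/3}`
  (n=500 → 16 bins) or an explicit user `k`.

## Dirichlet-process mixture of normals

For 1-D/2-D data: `y_i ~ N(μ_i, Σ_i)`, `(μ_i, Σ_i) ~ G`,
`G ~ DP(α G0)` with conjugate base
`G0 = N(μ | m1, Σ/k0) IW(Σ | ν1, ψ1)` and hyperpriors
`m1 ~ N(m2, S2)`, `k0 ~ Gamma(τ1/2, τ2/2)`. Defaults mirror the
demonstration settings: `α = 1` fixed, `m2 = 0`, `S2 = diag(1000)`,
`τ1 = 1`, `τ2 = 100`, `ν2 = 2`, `ψ2 = I`, `ν1 = dim + 2` (weakly
informative with a finite prior mean; the demonstrations do not pin it
down), and `ψ1` fixed at the empirical covariance of the (possibly
contaminated) data.

Inference is collapsed Gibbs: assignments are resampled one observation at
a time from the conjugate multivariate-t predictives (cluster parameters
marginalised), then each sweep draws `(μ_c, Σ_c)` explicitly from the NIW
full conditionals and updates `m1` and `k0` from theirs. Two optional
updates are off by default:

* the DP concentration `α` by the auxiliary-variable Gamma-mixture scheme
  (its exact conditional law `π(α|C,n) ∝ α^{a0+C−1} e^{−b0 α}
  Γ(α)/Γ(α+n)` is verified in the tests against quadrature);
* `ψ1`, for which an inverse-Wishart hyperprior is **not** conjugate to
  the IW cluster-covariance likelihood — the implemented update reads the
  scale hyperprior as `Wishart(ν2, ψ2)`, whose full conditional is again
  Wishart. This is the package's own design choice, made for conjugacy;
  since both demonstrations effectively fix `ψ1`, it does not affect the
  headline numbers.

Chain defaults: 6000 iterations, burn-in 1000, thinning 10 → 500 retained
states. A retained state becomes a density draw via the conditional
mixture `Σ_c n_c/(n+α) N(·|μ_c, Σ_c) + α/(n+α) t_base(·)`, where
`t_base` is the Student-t predictive induced by the NIW base — a finite,
evaluable surrogate for a draw from the posterior over densities (the
choice of surrogate is a design decision; an infinite stick-breaking draw
would change nothing material at these sample sizes). Non-PD scatter
matrices (possible with duplicated points) are jittered by `1e−8·I` with
a warning.

## Gross-error model

`f_{θ,α,z} = (1−α) f_θ + α·U(z−ε, z+ε)` with default
`ε = 0.01 ×` (family scale at θ) — the contamination is "a narrow
spike", and nothing depends on ε beyond it being small. Sampling uses
exact counts by default (`round(αn)` spike points), matching the
demonstration designs; Bernoulli membership is available.
`robustness_curve` traces any of MHB / BMH-EAP / MLE over a sorted grid
of spike locations with fresh per-z sub-seeds spawned from the master
seed (reproducible, no cross-z coupling). Under contamination the
histogram's data map stretches with `z` — this is the faithful default
(the density estimate should track the contaminated model on its full
support); estimator failures at a given `z` are recorded as missing and
the curve continues.

## Quadrature

All integrals use composite Gauss–Legendre panels (default order 8–12,
uniform panels with user breakpoints merged in). Histogram integrands are
exact provided bin edges are passed as breakpoints — every pipeline that
holds a histogram does this. Default windows: the density's data range
±4 robust (IQR-based) sds per axis for sample-driven fits; a mass-coverage
warning fires if a window captures less than `1 − 1e−6` of a density.
2-D windows are tensor products. Densities with components on very
different scales (a tight cluster plus a diffuse base predictive) need
breakpoints resolving both — the tests show an example.

## Synthetic designs

The generators are pure functions of (spec, seed) on numpy's PCG64:

* the contaminated bivariate design: weights (0.9, 0.05, 0.05) with exact
  counts (90/5/5 at n=100), main component N((10,5), [[3,1],[1,2]])
  — the generating-parameter table fixes Σ22 = 2 — contaminants
  N((−2,5), [[.5,.1],[.1,.5]]) and N((10,14), [[.4,−.1],[−.1,.4]]);
* a light-speed-style 1-D sample: 64 inliers from N(27.75, 5.08²) plus
  fixed gross outliers at −44 and −2 (66 values). This is a synthetic
  stand-in that exercises the same code path as the historical data; no
  numeric claims about the real measurements are made from it;
* clean `f_θ` samples for efficiency studies.

What the generators do *not* emulate: real measurement data are neither
exactly Gaussian nor exactly 10% contaminated, and real contamination is
rarely a point mass. Passing tests demonstrate the estimators' behaviour
under the stated mixture designs, not performance guarantees on arbitrary
real data.

## Problem sizes used in the tests

Efficiency checks run at n ∈ {200, 500, 2000} with 300 BMH draws and 200
MHB replicates; robustness curves at n = 400 over z ∈ {2,…,10} with five
seeds; the bivariate demonstration at its native n = 100 with the full
6000-iteration chain. These sizes make every distributional claim
checkable in minutes on one core while keeping Monte Carlo error well
inside the asserted tolerances.

## Known limitations

* At n = 100 the demonstration design itself has substantial sampling
  noise (the clean-subsample covariance entries have sd ≈ 0.3); estimates
  from independently generated replicates scatter accordingly, which is
  why the acceptance script averages five replicates.
* The histogram prior is univariate; multivariate data go through the DPM.
* The BMH runtime is dominated by the per-draw optimisation (500
  Nelder–Mead runs); warm starting cuts this substantially but a full
  bivariate run is still ~1 minute.
* MHB standard errors require a nonparametric bootstrap (B = 200 default)
  and hence B full refits; they are exposed but not cheap.
* Families with discrete support are out of scope.
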