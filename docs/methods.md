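# Methods

## The movement model

`switchssm` implements a two-state switching first-difference correlated
random walk (CRW) observed through an error model, i.e. a discrete/continuous
state-space model for animal telemetry.

**Process model.** True locations x_t (planar km) on a regular time grid
(default Δ = 1 h) evolve through their displacements d_t = x_t − x_{t−1}:

    d_t | d_{t−1}, b_t  ~  N₂( γ_{b_t} · T(θ_{b_t}) · d_{t−1}, Σ )

where b_t ∈ {1, 2} is the behavioural state, γ ∈ [0, 1] the move persistence
(autocorrelation in speed and direction), T(θ) the rotation matrix of the
mean turn angle (counter-clockwise convention; results are invariant to the
sign convention because simulation and inference share it), and Σ a 2×2
process covariance shared by both states.  State 1 ("transient") is fast and
directionally persistent (γ₁ large, θ₁ ≈ 0); state 2 ("area-restricted
search", ARS) is slow with frequent reversals (γ₂ small, θ₂ ≈ π).  We treat
this displacement-level formulation as the canonical process equation of the
package.

**State model.** b_t follows a first-order Markov chain with 2×2
row-stochastic matrix α; α₁ = P(stay transient), α₂ = P(ARS → transient).
Only these two entries are free.  The initial state is drawn from the
stationary distribution of α.

**Observation models.**

* `none`: y_t = x_t (used for error-free simulation scenarios).
* `gps`:  y_t ~ N₂(x_t, Ω), constant bivariate-Normal error.
* `argos`: per-axis independent location-scale t errors with class-specific
  scale τ_q (km per axis) and degrees of freedom ν_q indexed by the Argos
  location-quality class q of each fix; smaller ν_q gives heavier tails.
  τ_q and ν_q are held fixed during fitting while a per-individual factor
  ψ > 0 rescales all τ's, absorbing tag-to-tag differences in error scale.

**Irregular times.** Observations need not fall on the latent grid.
Observation i at time τ_i is assigned interval k_i = ⌊(τ_i − τ₀)/Δ⌋ and
fraction j_i ∈ [0, 1); its predicted location is the straight-line
interpolation (1 − j_i)·x_{k_i} + j_i·x_{k_i+1}.  Latent steps containing
no observation contribute only process terms (missing-at-random by model
structure); they are never imputed away.  Seal-like Argos data are
typically fit with Δ = 6 h, giving roughly two observations per step at
8–9 fixes per day.

**SSM vs hSSM.** The per-individual form ("ssm") estimates
(γ, θ, α, Σ) separately for each track.  The joint-estimation form
("hssm") shares one set of movement parameters across all tracks while
states, locations and ψ remain individual-level.  This is deliberately the
simple identical-parameters pooling, not a random-effects hierarchy; the
point of the design is that pooling information across individuals
sharpens behavioural-state inference, most visibly under heavy-tailed
location error.

## Priors

All user-overridable via `Priors`:

| parameter | prior | rationale |
|---|---|---|
| α₁, α₂ | Beta(1, 1) | flat on probabilities |
| γ₁ | Uniform(0, 1) | flat persistence |
| γ₂ = γ₁·u, u ~ Uniform(0, 1) | — | enforces γ₁ > γ₂, preventing state-label switching |
| θ₁ | Uniform(−π/2, π/2) | transient ≈ straight ahead |
| θ₂ | Uniform(π/2, 3π/2) | ARS ≈ course reversal |
| Σ | per-axis SDs ~ half-t(3, 10 km); correlation ~ Uniform(−1, 1) | weakly informative at the 5 km/step scale of the study design |
| ψ | Uniform(0, 10) | wide positive rescale |
| x₁, x₂ | N₂(first observation, (50 km)²) | vague anchor for the first-difference boundary |

The θ ranges double as the second identifiability device: together with the
γ ordering they pin state 1 to "fast and straight" so labels cannot flip.

## Sampler

Metropolis-within-Gibbs, one sweep =

1. **States**: exact forward-filtering backward-sampling (FFBS) over the
   2-state chain, with process densities as emissions (observation terms do
   not involve b and drop out).  The first two time points carry no process
   term and receive flat emissions.
2. **Locations** (skipped in the error-free regime, where x ≡ y): single-site
   Gaussian random-walk Metropolis.  Under the second-order process
   dependence, sites ≥ 3 steps apart are conditionally independent, so sites
   are updated in three interleaved colour classes (t mod 3), each class
   accepted/rejected per site and vectorised across sites and tracks.  One
   scalar proposal SD is adapted from the mean acceptance rate.
3. **γ₁, u, θ₁, θ₂**: componentwise adaptive random-walk Metropolis,
   proposals outside the prior box rejected outright.
4. **Σ**: joint random-walk on (log σx, log σy, atanh ρ) with the
   half-t/uniform priors plus the corresponding Jacobians.
5. **α**: independence MH whose proposal is the conjugate
   Beta(1 + transition counts) full conditional; the acceptance ratio then
   reduces to the ratio of stationary-distribution priors on the initial
   states (exact Gibbs would ignore that one term).
6. **ψ** (Argos only): per-individual random-walk Metropolis against the
   observation likelihood.

Adaptation follows a Robbins–Monro recursion toward acceptance 0.44
(scalar) / 0.30 (3-d Σ block) and is frozen at the end of burn-in, so the
retained draws come from a fixed-kernel chain with the joint posterior as
stationary distribution.  In the batched "ssm" form every parameter vector
has one entry per track and accept/reject decisions are per-track; since no
likelihood term couples tracks this is mathematically identical to
independent per-track fits.

Chains are initialised over-dispersedly: parameters drawn from their priors
(SD draws clipped to [0.05, 100] km for numerical sanity), locations from
the observations interpolated onto the grid plus N(0, 0.1²) jitter, and
states by thresholding step lengths at their median so both states start
occupied.  All randomness derives from `SeedSequence([seed, chain_index])`;
the simulator spawns one child stream per track from the scenario seed, so
any track is reproducible in isolation.

## Reference protocol and desk-scale defaults

The reference MCMC protocol is 2 chains × 60 000 iterations, 40 000
burn-in, thinning by 20 — 1 000 retained draws per chain, 2 000 total —
with convergence accepted when the Brooks–Gelman–Rubin potential scale
reduction factor (classic between/within variance form, computed on
retained draws; a rank-normalised variant is available) is ≤ 1.1 for all
monitored parameters.

The reference simulation design is 50 tracks × 200 hourly locations per
scenario cell, six cells: Δγ ∈ {0.85 (γ₁ = 0.95), 0.55 (γ₁ = 0.65)} ×
error ∈ {none, GPS (Ω SD 0.05 km), Argos (packaged τ/ν class table)}, with
γ₂ = 0.10, θ = (0, π), α = (0.90, 0.10), Σ SD 5 km per axis and zero
covariance throughout.  Fitting that design at the reference protocol is a
multi-day CPU job, so the package's own desk-scale defaults — used by the
test suite, `reproduce-study --scale desk`, and the acceptance script —
shrink the problem while keeping every qualitative contrast: 10 tracks per
cell (at the reference 200-step track length — shortening tracks starves
the per-individual fits and overstates the benefit of pooling) with
2 × 3 000 iteration chains for the six-cell comparison; 5 GPS tracks × 100
steps with 2 × 10 000 iteration chains for the convergence benchmark; 20
replicates of 10 error-free tracks × 200 steps with 2 × 1 200 iteration
chains for parameter recovery.  These sizes are the package's definition
of a desk-scale study.  At this scale the SSM-vs-hSSM contrast is assessed
at the regime level (per-track RMSE pooled over the two persistence
contrasts of a regime): with only 10 tracks a single cell's median is
dominated by between-track noise, while paired per-track differences and
regime medians consistently favour the joint fit.

## Synthetic data: what it does and does not emulate

The simulator produces exactly the data-generating process the model
assumes: Markov switching, shared Σ, independent per-fix errors, and (for
the irregular-time generator) Poisson-process observation times with
straight-line interpolation between grid points.  Real telemetry violates
several of these — behaviour run lengths are not geometric, haul-outs and
gaps are behaviour-dependent, Argos error classes cluster in time, and
movement is not planar over large extents.  Passing tests therefore
demonstrate correctness of the machinery and the qualitative benefit of
joint estimation under the stated conditions, not performance guarantees on
field data.  Argos class frequencies in simulation default to uniform over
the packaged class table (configurable); the packaged τ/ν values are
synthetic defaults with realistic magnitudes and orderings, not a published
calibration, and nothing in the package depends on their specific values.

## Numerical choices and edge cases

* Process terms exist from the third location onward; tracks shorter than
  3 usable steps are rejected.
* Tracks of unequal length are padded to a common grid and masked; padded
  entries never enter likelihoods and are stored as state 0.
* Posterior-median states of exactly 1.5 are assigned to state 1 for kappa
  (configurable); kappa of a degenerate single-class table is NaN rather
  than an exception.
* The HPDI is the shortest contiguous interval containing ⌈prob·n⌉ sorted
  draws.
* Out-of-support parameter sets yield −∞ from the joint log posterior by
  contract (rejection), not an exception.
* Gap filtering keeps the longest contiguous run with inter-observation
  gaps ≤ 4 days (default), re-zeroing times and recording the drop count.
* The equirectangular lon/lat ↔ km projection is adequate for regional
  tracks only; all core math is projection-agnostic.

## Known limitations

* No random-effects ("fully hierarchical") parameter variants, 3-state
  models, state-dependent Σ, or biased-CRW extensions.
* No approximate inference (Laplace/TMB-style); MCMC only.
* Single-site location updates mix slowly when observation error per fix is
  much larger than the process scale; the desk-scale protocols are sized so
  this is not binding, but very noisy, very long tracks may need longer
  chains.
* Ω (GPS error covariance) is treated as known and fixed during fitting,
  as is standard when GPS error is small and externally characterised.
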