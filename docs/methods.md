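# Methods

## Model

For person i we observe (t_i, δ_i, x_i, s_i, w_i): the observed duration
t_i = min(T_i, C_i) with T_i the latent age at first sex and C_i the age
at interview, the event indicator δ_i = 1[T_i ≤ C_i], categorical
covariates x_i, the enumeration-area location s_i (shared by all members
of a cluster), and the survey weight w_i (inverse selection
probability).  The hazard model is proportional and geoadditive:

    λ_i(t) = λ₀(t) · exp{ x_i′β + S(s_i) },

with λ₀ unspecified and S a bivariate smooth.  S is expanded as a linear
coordinate part plus a low-rank radial spline,

    S(s) = s′β_s + Σ_{k=1..K} u_k z_k(s),      u ~ N(0, σ²ᵤ I),

whose basis is derived from an isotropic generalized covariance g_τ:
Z = C(s, κ) C(κ, κ)^(−1/2), where C(a,b)_{ij} = g_τ(‖a_i − b_j‖) and
κ_1..κ_K are knots.  Because u is penalized through a single variance
σ²ᵤ, the transformation by C(κ,κ)^(−1/2) is what makes the ridge
penalty equivalent to a kriging prior with covariance g_τ.

### Covariance families

Six isotropic families are implemented, all normalized to g(0) = 1 with
τ a length scale: exponential e^(−h/τ); Gaussian e^(−h²/τ²); Matérn at
smoothness 3/2, (1 + h/τ)e^(−h/τ); spherical
(1 − 1.5h/τ + 0.5h³/τ³)·1[h<τ]; circular
(2/π)(arccos ϑ − ϑ√(1−ϑ²)) with ϑ = min(h/τ, 1); and inverse quadratic
1/(1 + h²/τ²).  The circular and inverse-quadratic forms are the
standard ones; we normalize the inverse quadratic so that τ carries
units of distance like the other five.

Distances are Euclidean in the raw coordinate units.  For lat/lon data
at low latitudes (the intended use) degree anisotropy is modest; a
`project_km` switch applies a local equirectangular projection to
kilometres for users at higher latitudes.  Which convention the original
style of analysis used is generally unstated in applied work, so both
are supported and neither is asserted as canonical.

### Knots

K follows Ruppert's rule K = max{20, min(⌊n/4⌋, 150)} and is
additionally capped by the number of distinct locations (with
cluster-shared coordinates the candidates are the clusters, which can
number fewer than n/4).  Knots are chosen from the distinct observed
locations by a maximin space-filling rule: a greedy "coffee-house" pass
(start at the point nearest the centroid, repeatedly add the candidate
farthest from the current set) followed by pairwise swap improvement of
the minimum inter-knot distance until no swap helps.  The seed only
breaks exact ties, so the selection is deterministic in practice.

## Estimation

### Poisson reduction with Breslow offsets

With the counting and at-risk processes evaluated at t = ∞, the
censored-data likelihood reduces to independent Poisson cells
N_i = δ_i with mean Λ₀(t_i)·exp{x_i′β + S(s_i)}.  The unknown
Λ₀(t_i) is replaced by the Breslow estimate from a standard weighted
Cox fit,

    Λ̂₀(t) = Σ_{t_j ≤ t} ( Σ_{i∈D_j} w_i ) / ( Σ_{l∈R_j} w_l e^{x_l′β̂} ),

entering as a known offset log Λ̂₀(t_i); no intercept is included since
the baseline hazard plays that role.  Records censored before the first
event time have Λ̂ = 0 and no finite offset; they are dropped with a
logged count (they carry no information for the reduction).  This
plug-in makes the Poisson score identical to the partial-likelihood
score at β̂, so an unpenalized refit reproduces the Cox estimates — the
package's tests verify agreement to machine precision.

Breslow (not Efron) tie handling is used throughout, deliberately: the
Breslow baseline is exactly the quantity the offset plugs in, and with
ages recorded in whole years ties are heavy, making the choice material.

### Penalized quasi-likelihood

The mixed model is fitted by the Breslow–Clayton working-model
iteration: with η = Xβ + Zu + offset and μ = exp(η), iterate

1. working response  y* = η − offset + (N − μ)/μ,
2. penalized weighted least squares for (β, u) with observation weights
   w_i μ_i and penalty ‖u‖²/σ²ᵤ,
3. variance update  σ²ᵤ ← û′û / (K − tr(S_uu)/σ²ᵤ), the standard
   REML-type ratio with S_uu the u-block of the inverse penalized
   normal matrix,

until the relative change in (β, u, σ²ᵤ) falls below 1e−6 (cap 200
iterations).  Survey weights are normalized to mean one before fitting
so that their arbitrary scale cannot distort the variance component;
fitted coefficients are invariant to rescaling all weights by a
constant.  If σ²ᵤ collapses to the 1e−10 floor the fit reduces to the
fixed-effects model and a warning is issued.  The effective degrees of
freedom are the trace of the working-model hat matrix; AIC, AICc and
BIC use the weighted Poisson log-likelihood at convergence with edf as
the complexity term.

### Covariance of the fixed effects

The one-row-per-person Poisson frame treats the Breslow offsets as
known constants, which overstates the information in β̂ by roughly a
factor of two for balanced binary covariates (verified both analytically
and by simulation).  In the full joint formulation — one Poisson cell
per subject and event time, with the log baseline increments as free
parameters — profiling the increments out subtracts, at each event time,
the weighted risk-set outer product of the mean design row:

    I(β, u) = B′WB − Σ_j wd_j · B̄_j B̄_j′ ,

with B = [X Z], W = diag(w_i μ_i), B̄_j the exp(η−offset)-weighted mean
of B over the risk set at event time t_j, and wd_j the weighted event
mass there.  This corrected information equals the Cox observed
information when no spatial term is present.  Wald intervals for the
hazard ratios use the β-block of (I + P)^(−1) with P the ridge penalty;
simulation shows ~95% empirical coverage where the naive working-model
covariance gives ~80%.

### Range estimation

τ is estimated by a two-stage profile: (1) fit the mixed model at a
pilot τ (the geometric mean of the smallest and largest pairwise
distances) to fix the Gaussian working response y* and weights W;
(2) holding (y*, W) fixed, maximize the Gaussian restricted likelihood
of the working model over (σ²ᵤ, τ) — σ²ᵤ by Brent search at each τ, τ by
a coarse log-spaced grid on [d_min, d_max] followed by golden-section
refinement within the bracketing interval; (3) refit at the new τ and
repeat (at most three rounds) until τ moves by less than 1e−3·d_max.

Two details matter.  Comparing each τ's REML on *its own* working
response is incoherent (the data change with the candidate) and
empirically biases the estimate; fixing (y*, W) within a profile round
fixes this.  And the profile can be multimodal — a spurious shoulder
appears at large τ where a huge σ²ᵤ compensates a nearly flat basis —
so the grid scan before golden-section is load-bearing.  A flat profile
falls back to τ = d_max, the classical fixed choice.  Family selection
then ranks the per-family fits by AICc (chosen over AIC because edf of
the smooth is what AIC under-penalizes), with BIC as the tiebreak.

### Surface

The mapped quantity is the total spatial effect — centered-coordinate
linear terms plus the smooth — mean-centered over the masked prediction
grid: without an absolute baseline reference only spatial contrasts in
log(HR) are meaningful, and centering makes that explicit.  A switch
maps the smooth alone.  The default grid is 100×100 over the data's
bounding box with a convex-hull mask.

## Synthetic cohort

The generator emulates a national household survey of 15–24 year-olds:

- latent debut age T = a0 + b·(E/exp(x′β + S(s)))^(1/k), E ~ Exp(1) — a
  Weibull baseline with proportional-hazards shift, supported above
  a0 = 8 years (debut cannot precede late childhood, and the log-hazard
  offset degenerates near 0);
- interview age C ~ Uniform(15, 25), mirroring the survey's 15–24
  eligibility; t = min(T, C), δ = 1[T ≤ C];
- integer-year rounding of t (floored, minimum 1) on by default, to
  exercise Breslow tie handling — whether source surveys record integer
  ages is typically not documented, so rounding is a switch, not an
  assertion;
- clusters uniform over the study region, all members sharing the
  cluster point; cluster selection probabilities Uniform(0.1, 1), weight
  = 1/p rescaled to mean 1;
- defaults calibrated (shape k = 7.5, scale b = 8.9) so that the
  n = 5,000 cohort shows ≈19% debut before age 15 and a Kaplan–Meier
  median debut age of 16 years, the regime reported for this age group
  in southern-African surveys; three binary covariates (sex, residence,
  alcohol with true HR 1.5) at realistic prevalences; a two-bump
  Gaussian spatial field (amplitudes ±0.6, width 0.18 on the unit
  square), mean-centered over a reference grid.

What the generator does *not* emulate: multi-stage selection mechanics
beyond cluster-shared coordinates and inverse-probability weights,
covariates correlated with location, recall error in reported ages, and
non-ignorable non-response.  Passing tests therefore certify the
estimator under its own assumptions, not robustness to those features
of real survey data.

## Simulation-study conventions

Two deliberate choices in the recovery and coverage studies:

- **Continuous recorded times.**  With integer-year ties the Breslow
  partial likelihood targets a slightly attenuated discrete-time
  estimand (bias ≈ −0.1 on a log-HR of 0.4 at n = 400 here; visible in
  the worked example as an alcohol aHR of ≈1.33 against a generating
  value of 1.5).  That attenuation is a property of the method under
  grouped ages, not an implementation defect; comparisons against the
  continuous-time generating coefficients are made on continuous times
  so that they measure estimation error, not discretization.
- **Equal weights.**  Unequal survey weights inflate estimator variance
  (a design effect ≈1.5 under the default weight model) that
  model-based Wald intervals do not claim to cover; design-based
  (sandwich) variance estimation is out of scope.  Coverage is
  therefore assessed under equal weights — the intervals' own
  assumptions.

Problem sizes used by the test suite and the acceptance script: 200
replicates of n = 400 for the reduction and recovery studies, a single
n = 2,000 fit for surface recovery, 2,000 null simulations of n = 100
for the log-rank test's size, and a reduced two-family pipeline for the
determinism check.

## Numerical choices

- Cox Newton–Raphson from β = 0 with step-halving; convergence at
  max|score| < 1e−8 or relative log-likelihood change < 1e−10; rank
  deficiency detected up front and reported with the offending columns.
- C(κ,κ)^(−1/2) by symmetric eigendecomposition with eigenvalues floored
  at 1e−10·λ_max (floored directions contribute zero) — robust to the
  near-singular knot covariance at large τ, where Cholesky of the
  inverse fails.
- Censorings at an event time remain in the risk set for that event;
  ties pooled at their common time.
- Pearson chi-square on unweighted counts with survey-weighted
  percentages: survey tables conventionally print weighted percentages
  next to raw counts, and the test is computed on the counts.  No
  continuity correction.
- Wald intervals on the log scale at the 5% significance level.
- Stage seeds derive from one master seed by SHA-256 of
  (seed, stage-name), so runs are reproducible without user seed
  bookkeeping, and stratified fits on disjoint subsets are independent.

## Limitations

- The PQL working-model approximation is first-order; for rare events
  or tiny clusters its variance component can be biased low.
- The offset is computed once from the covariate-only Cox fit, not
  iterated against the spatial model; a strong spatial field therefore
  perturbs the baseline slightly (the package's simulations show the
  effect on covariate aHRs is within Monte-Carlo error at the study's
  scale).
- Isotropic covariances only; anisotropy and location measurement error
  (coordinates assigned at the enumeration-area level) are not modelled.
- Equidispersion of the Poisson cells is assumed, not tested.
- No uncertainty surface (pointwise SE bands) is exported yet.
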