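# Methods

## Model

Death counts on a grid of single ages `x = 0..X`, calendar years
`t = 1..T` and provinces `s = 1..S` (nested in regions `r`) are modelled
as

    Y_xts | lambda_xts ~ Poisson(E_xts * lambda_xts)
    log lambda_xts = alpha_x + beta_x kappa_t + omega_{s, g_x [, p_t]}
                     + u_{r_s} + z_xts

where `E_xts` is the exposure in person-years.  The pieces are:

* `alpha_x` — age profile of log mortality; iid Gaussian with a large
  fixed standard deviation (default 10 on the log-rate scale).
* `kappa_t` — period index shared by all provinces; second-order random
  walk `kappa_t = 2 kappa_{t-1} - kappa_{t-2} + eps_t`,
  `eps_t ~ N(0, sigma_kappa^2)`, flat on the first two values (hence
  flat on every linear trend — the data alone determine the slope).
* `beta_x` — age loading on `kappa`; same wide Gaussian prior as
  `alpha`.
* `omega_{s,g}` — BYM2 province effect, specific to the 10-year age
  class `g_x` (0-10, 11-20, ..., last class truncated at `X`):

      omega = sigma_omega (sqrt(1 - phi) v + sqrt(phi) u),

  `v` iid standard normal, `u` a scaled Besag (intrinsic CAR) field on
  the province adjacency graph, `phi in [0,1]` the share of marginal
  variance that is spatially structured.  In the period-split
  specification `omega` additionally depends on the period `p_t`
  (years up to a cutpoint vs after), with independent fields per
  period.
* `u_{r}` — iid Gaussian region effect (`sigma_r`), absorbing
  region-level heterogeneity such as decentralised health-system
  differences.
* `z_xts` — iid Gaussian cell-level overdispersion (`sigma_z`).

Identifiability constraints: `sum_x beta_x = 1`, `sum_t kappa_t = 0`,
and `sum_s omega_{s,g[,p]} = 0` within each age class (per graph
component; see below).

## Spatial structure and scaling

The Besag structure is `R = D - A` (degree minus adjacency), the
precision structure implied by "conditional mean = neighbour average,
conditional variance inversely proportional to the neighbour count".
`R` is scaled per connected component so the geometric mean of the
marginal variances — computed under a within-component sum-to-zero
constraint via the Moore-Penrose generalized inverse — equals one; the
variance parameter in front of the scaled structure is then comparable
across graphs and components.  Components with a single node carry no
spatial information and fall back to an independent standard-normal
effect.  These are the standard disconnected-graph adjustments for
intrinsic models; they matter because realistic province graphs
(islands) are disconnected.

The sum-to-zero constraint on `omega` is imposed per (age class,
period, non-singleton component).  A singleton component's single free
value would be annihilated by a sum-to-zero constraint, so singletons
are left unconstrained, consistent with their iid fallback role.

## Priors on hyperparameters

All standard deviations get the penalized-complexity (exponential)
prior calibrated through a tail statement with `upper = 3` and
`prob = 0.05`.  The conventional PC reading `P(sigma > 3) = 0.05`
(rate `-log(0.05)/3`) is the default; the lower-tail orientation
`P(sigma < 3) = 0.05` is also implemented and selectable in
`PriorSettings` because tail statements of this kind appear in the
literature in both directions and the package takes no position on
which was meant in any given application.

The mixing parameter `phi` gets the KLD-based PC prior: exponential in
the distance `d(phi) = sqrt(sum_i [phi (gamma_i - 1) - log(1 + phi
(gamma_i - 1))])` over the constrained eigen-directions of the scaled
structure (marginal variances `gamma_i`), truncated to the reachable
range `[0, d(1)]` and normalized.  The rate is found by root-finding so
that `P(phi < 0.5) = 2/3` (both values configurable).  Requested masses
below the `rate -> 0` limit `d(0.5)/d(1)` are unreachable and raise an
error rather than silently failing.

## Constraint handling

Constraints are enforced by a deterministic projection applied to every
draw rather than by degenerate priors: `beta` is rescaled to sum to one
with `kappa` compensated by the reciprocal factor; `kappa` is centred
with the shift absorbed into `alpha`; `omega` is centred per (age
class, period, component) by centring `v` and `u` there.  A mean
removed per component has no aligned additive term to absorb it
(`alpha` is age-only, the region effect region-aligned), so the removed
block means are added to the matching cells of `z` — the only term
indexed by all three of (age, year, province).  The projection
therefore leaves the linear predictor, and hence the Poisson
likelihood, exactly invariant, and it is idempotent.  The test-suite
checks both properties to 1e-10.

## Inference engine

Sampling is dynamic NUTS (multinomial variant, diagonal mass matrix,
dual-averaging step-size adaptation) with fully analytic gradients of
the joint log posterior.  The unconstrained parameterization:

* `beta` lives in the affine subspace `sum(beta) = 1` and `kappa` in
  `sum(kappa) = 0` (orthonormal sum-to-zero bases), so two of the three
  printed constraints hold for every draw by construction and the
  `beta -> c beta, kappa -> kappa/c` scale ridge is removed;
* the structured field `u` is sampled through the spectral basis of the
  scaled structure (one standard-normal coefficient per positive
  eigen-direction), which realizes exact constrained scaled-Besag draws;
* `v`, region effects and `z` are non-centred; standard deviations are
  sampled on the log scale, `phi` on the logit scale.

Chains start at the conditional posterior mode of the latent field
given fixed initial hyperparameters (L-BFGS on the analytic gradient,
seeded by a classic SVD Lee-Carter fit of pooled log crude rates with a
`log((y + 0.5)/E)` continuity correction).  The joint mode of a
non-centred hierarchy is degenerate in the standard deviations, which
is why the hyperparameters are held fixed during this inner
optimization.  The initial inverse mass matrix is the inverse of the
Poisson Fisher information plus prior precision, evaluated at the
start, with finite-difference curvature for the five hyperparameters;
model fits keep this mass fixed and adapt only the step size.  Windowed
variance-based mass adaptation is available in the generic sampler but
disabled for model fits: re-estimating a ~10^4-dimensional diagonal
mass from short non-equilibrated windows proved strictly worse than the
curvature-based mass, occasionally destabilizing warmup.

Every stored draw passes through the constraint projection before
summarization.  Summaries report posterior mean, SD and central 95%
intervals per scalar, split-chain R-hat per parameter block (via
ArviZ), and the derived products `beta_x kappa_t` (compound age-time
effect), the combined spatial surface `omega + u_region`, and — in the
period-split model — the per-(province, age class) posterior of
`omega_{p2} - omega_{p1}`.  An R-hat above 1.05 on any summarized
parameter is recorded in the output and emitted as a warning.

### Known limitation: the time-index scale at desk-scale data volumes

The transformation `beta -> c beta + (1 - c)/A, kappa -> kappa / c`
preserves both Lee-Carter constraints while perturbing the fitted
log-rates only by `((1 - c)/(A c)) kappa_t` — a small, age-constant,
time-varying term that the overdispersion field can partially absorb.
At the default desk-scale data volume (~2.7e5 deaths) the likelihood
penalty of this direction is of the same order as the entropy gained by
the widened conditional distribution of `beta`, so the marginal
posterior of the scale of `kappa` is genuinely wide and mixes slowly;
chains can equilibrate at an attenuated `kappa` with inflated `beta`
while the identified products `beta_x kappa_t`-at-observed-precision,
`alpha`, `omega` and the hyperparameters are essentially unaffected.
The shape of `kappa` (correlation with truth > 0.99) and everything the
spatial analysis rests on are recovered regardless; at
register-scale data volumes (tens of millions of person-years per
province) the likelihood pins the scale.  Users of the desk-scale
configuration should read `kappa` up to this scale caveat; the R-hat
warning flags it when it occurs.

## Synthetic-data generator

The generator is first-class, tested code and defines the study
conditions used everywhere:

* 20 provinces in 4 contiguous regions, a rook-adjacency lattice with a
  2-province detached island (so the graph is disconnected like
  realistic national graphs); single ages 0-50; 10 years; per-province
  exposure scales log-uniform on [1e3, 1e5] person-years with a mild
  declining age pyramid.
* Age profile: infant decline + Gaussian young-adult hump + Gompertz
  rise (`4e-3 exp(-x)`, `2e-4` around age 22, `2e-5 exp(0.095 x)`),
  i.e. rates from ~4e-3 at birth through ~2e-4 at young-adult ages to
  ~2e-3 at 50.
* `beta` smoothly declining in age, normalized to sum one; `kappa`
  linear decline of 7.6 over the window (roughly 1.5%/year mortality
  improvement at the mean loading) plus RW2 noise `sigma_kappa = 0.05`.
* Spatial truth `sigma_omega = 0.15`, `phi = 0.6`; region SD 0.1;
  overdispersion SD 0.03 — magnitudes typical of province-level
  log-mortality heterogeneity.
* Period-split option: the period-2 raw fields are
  `c * period-1 + sqrt(1 - c^2) * fresh` with `c = 1 - period_shift`,
  preserving variance; `period_shift` 0 duplicates the field, 2 flips
  its sign.

What the generator does not emulate: real adjacency geometry, cohort
effects, migration-driven exposure dynamics, age-heaping or
registration artefacts, and any cross-sex structure (sexes are
independent runs).  Passing recovery tests therefore demonstrates that
the inference machinery recovers the model's own generative structure
at desk scale — not that the model is adequate for any particular real
register.

## Problem sizes and numerical choices

Recovery experiments in the test-suite use the default desk-scale
configuration for the correlation check (one fit, 2 chains, 400
warmup + 400 draws) and 20 reduced-size replicates (12 provinces,
ages 0-30, 6 years, single chain, 300 + 300) for interval-coverage
estimation; the period-split checks run the default configuration with
a mid-window cutpoint and period shifts of 2 (sign flip) and 0 (null).
These sizes were chosen so a full validation pass completes in minutes
on a single CPU while leaving the recovery targets clearly resolvable.

Other conventions: divergence threshold 1000 on the Hamiltonian error;
target acceptance 0.9 (0.95 in the recovery experiments); maximum tree
depth 8; quantiles 2.5%/97.5%; `kappa` centring and `beta` rescaling
tolerances 1e-12; eigenvalues below `1e-10 * max` treated as null
directions in intrinsic structures; Poisson overflow guard at expected
counts above 1e12.  All randomness flows from explicit integer seeds
through `numpy.random.Generator`; identical seeds give bit-identical
posterior summaries.
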