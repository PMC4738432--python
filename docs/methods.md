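# Methods

This note records the models, numerical choices and open design decisions
behind `grassflam`, and what the synthetic-data tests do and do not show
about real burn data.

## Flammability components

Flammability is decomposed into ignitability (ease of ignition),
sustainability (persistence of flaming) and combustibility (intensity),
each measurable at leaf, plant and community scale.

**Leaf scale.** From epiradiator event times: TTI = first flame −
application, FT = flame out − first flame, combustion rate = sample mass /
FT (samples combust completely, so the average rate is well defined).
Records with FT = 0 are excluded with reason "no sustained flaming".  The
moisture effect is the fresh − dry difference per individual averaged per
species; relative versions (fresh/dry − 1) are reported alongside because
"fresh takes 42% longer to ignite" is the natural effect scale.  Unpaired
individuals are dropped to keep the contrast balanced.

**Plant scale.** The mass-loss series of a clump burn is fitted with the
falling Boltzmann sigmoid m(t) = A₂ + (A₁−A₂)/(1+exp((t−t₀)/dx)).  This is
the standard four-parameter Boltzmann with upper asymptote A₁ (initial
mass), lower asymptote A₂ (char residue), inflection t₀ and width dx.  The
width is the period over which mass drops steeply and serves directly as
the plant-scale flaming time.  Fitting uses trust-region nonlinear least
squares with multi-start initialization: t₀ from the steepest decline of a
lightly smoothed curve (perturbed by ±15% of the record span across
starts), dx from the 10–90% transit time divided by 2·ln 9 (the exact
Boltzmann relation), asymptotes from head/tail medians.  Fits with
R² < 0.95 (configurable) are excluded with reason "noise around the curve";
this reproduces the qualitative exclusion rule used with real balance data,
where detaching plant fragments corrupt the curve.

Maximum combustion rate is the absolute OLS slope of the *observed* masses
within ±3 s of t₀ (≥ 5 points required, error if the window leaves the
recorded range).  On a noiseless curve this is close to, but deliberately
not equal to, the tangent rate (A₁−A₂)/(4dx) — the windowed regression
averages curvature, and tests compare it against an independently coded
windowed regression rather than the tangent formula.

**Mass standardization.** log₁₀(max rate) is regressed on log₁₀(mass
burned) for fresh, dry and combined sets (balanced pairs only).  Slope
equality between states is tested with a nested-model F-test (interaction
term, α = 0.05), intercept equality with a second nested F-test under a
common slope; when intercepts do not differ the combined intercept is the
species' intrinsic combustibility, otherwise the fresh-only intercept is
used (field-state material takes precedence).  "Mass change" defaults to
A₁ − A₂ and can be switched to initial sample mass in config.  All
log-log work uses base 10; intercepts are therefore log₁₀(g/s) at 1 g.
Whole-plant rates extrapolate log₁₀(rate) = intercept + b·log₁₀(total
biomass) with the across-species slope b from the bivariate model.

## Plant traits

* moisture content = (fresh − dry)/dry, g water per g dry mass; fresh
  masses up to 1% below dry are clamped to 0 as weighing noise.
* leaf SA/V: the lamina is a thin two-sided slab, SA/V = 2/thickness
  (edge area neglected; the area term cancels).  Thickness is a mean over
  leaves, per the measurement protocol.
* biomass-density proxy: cumulative dry mass from the ground up, evaluated
  at interval-top heights, OLS of log₁₀(cumulative mass) on height
  (default, the literal protocol) or on log₁₀(height) (power-law variant).
  The log-linear slope has units log₁₀ g per cm; the log-log slope is a
  dimensionless exponent in (0, 1] for bottom-heavy plants.  Both are
  provided because the field protocol's printed slope range is more
  consistent with the power-law reading; neither is asserted as the only
  correct one.  Zero-mass points are dropped with a warning; fewer than 3
  usable points is an error.  Profiles use equal intervals from
  {2.5, 5, 10, 15} cm and warn below 5 intervals.
* EHoC: heat release / sample mass per microcalorimetry replicate, averaged
  per individual and species.  Individuals without calorimetry (the design
  samples 3 per species in duplicate) receive their species mean.
* fuel load = total dry biomass / cover area (g/cm²); height and cover come
  straight from the table.

Species aggregation is the arithmetic mean with CVs reported in percent.

## Fire-spread model

The steady-state surface spread model for a single homogeneous dead fuel
class: R = I_R ξ (1 + φ_w + φ_s)/(ρ_b ε Q_ig).  The equation chain is
implemented from the published coefficient set with the revised
reaction-velocity exponent A = 133 σ^−0.7913 and net load w_n = w₀/(1+S_T),
matching the widely used R implementation of the model.  Internal
computation is in the source model's imperial units — the units in which
the empirical coefficients were fitted — with exact SI conversions at the
boundary (foot 0.3048 m, pound 0.45359237 kg, Btu 1055.05585262 J); spread
rate is reported in m/min, reaction intensity in kW/m².

Moisture damping is the cubic η_M = 1 − 2.59r + 5.11r² − 3.52r³ in
r = M_f/M_x, clamped to zero for r ≥ 1 (the polynomial itself vanishes at
r = 1): fuel wetter than the moisture of extinction cannot carry steady
fire, so predicted spread is exactly 0 — the behaviour expected for very
wet invasive-grass fuels.

The grass clump is one fuel class; no live/dead partition is attempted
because whole fresh or dry clumps were burned.  Non-measured parameters
default to standard values (M_x = 0.25, S_T = 0.0555, S_e = 0.010,
ρ_p = 512.6 kg/m³) and are config-overridable; wind and slope default to 0.
Trait-to-fuel conversions: per-mm SA/V ×1000 → m²/m³, g/cm² ×10 → kg/m²,
cm /100 → m, kJ/g ×1000 → kJ/kg.

## Phylogenetic comparative statistics

The Brownian covariance V has V[i,j] = depth of the MRCA of tips i, j;
Pagel's λ multiplies the off-diagonals, interpolating between a star
phylogeny (λ = 0) and pure Brownian motion (λ = 1).  A ridge of
10⁻¹⁰·mean(diag V) is added only if the Cholesky factorization fails
(nearly simultaneous divergences).

PGLS solves GLS by Cholesky whitening; λ is fixed or profiled by bounded
1-D ML over [0, 1] with both endpoints always evaluated.  Wald 95% CIs use
the unbiased variance estimate with a t reference; the R² analog compares
whitened residual sums of squares against the GLS intercept-only model.
Likelihood-ratio tests against the boundaries λ = 0 and λ = 1 use the
one-sided halved reference p = ½·P(χ²₁ > LR), the standard correction for
a parameter tested at the edge of its space.  A star tree makes λ
unidentifiable and is flagged rather than failing.

The bivariate mixed model treats (log₁₀ mass burned, log₁₀ max rate) per
individual as bivariate normal with species random effects:
vec(U) ~ N(0, Σ_sp ⊗ A) with A the Brownian tree covariance, residuals iid
N(0, Σ_res).  All full conditionals are conjugate, giving a pure Gibbs
sampler; both covariances carry weakly informative inverse-Wishart priors
(scale ν·I with ν = 0.002), mirroring common practice for MCMC GLMMs in
comparative analysis.  Derived quantities per draw: b_within =
Σ_res[xy]/Σ_res[xx], b_across = Σ_sp[xy]/Σ_sp[xx], and their difference.
HPDs are shortest 95% intervals; diagnostics are initial-positive-sequence
effective size and split-R̂ (warning above 1.1).  Defaults run 50,000
iterations (burn-in 1,000, thinning 50) — a desk-scale setting chosen to
give effective sizes near 1,000; longer chains are config options.  The
trait-contribution tables are species-mean PGLS fits; the individual-level
mixed model is available for the biomass–rate relationship, where species
means would be misleading because burns subsample a range of masses within
each species.

## Synthetic-data generator

The generator emulates the field study design: 25 species × 7
individuals, each with a fresh and an oven-dried clump.  Species trait
values are drawn on a unit-depth Yule tree from N(0, V(λ)) and mapped
affinely onto configured ranges (affine maps preserve λ); leaf SA/V is
generated at λ = 1 (strong signal), the other traits at λ = 0.  Ranges are
chosen to be realistic for dry-season savanna grasses: biomass 5–120 g,
moisture 0.05–0.35 g/g (so the wettest species exceed the 0.25 extinction
moisture and predict zero spread, as real high-moisture invaders do), SA/V
5–25 mm⁻¹, EHoC 10–16 kJ/g, height 20–100 cm.  The vertical-profile slope
range (0.01–0.06 log₁₀ g cm⁻¹) is set so a profile spans a plausible 1–3
decades of cumulative mass over the plant height; it is deliberately *not*
the printed field range for this proxy, whose units are ambiguous (see the
density-slope discussion above).

Individuals scatter around species means with lognormal CV 15%.  Leaf
event times plant a fresh/dry TTI ratio of 1.42 (the moisture effect the
analysis must recover) and FT ratio 1.07, with 10% lognormal noise.
Mass-loss series are exact Boltzmann curves — A₁ from the burned fraction
(30–90%) of the clump, A₂ = 8% char, width increasing with moisture and
decreasing with SA/V, clipped to 2–12 s — plus Gaussian balance noise
(sd 0.01 g) at 0.2-s sampling.  Every parameter is stored in `truth.json`.
One RNG stream per stage, spawned from the master seed, so stages
regenerate independently and byte-identically.

What passing tests show: the estimators recover exactly the structures the
generator builds (sigmoidal mass loss, log-linear profiles, multiplicative
moisture effects, Brownian trait evolution).  What they do not show:
robustness to real-data pathologies — fragments falling off the balance
mid-burn (only mimicked as Gaussian noise plus the R² exclusion rule),
asymmetric mass-loss curves, correlated measurement error between paired
clumps, or phylogenetic error in an inferred tree.

## Numerical choices and degenerate inputs

* Boltzmann bounds: asymptotes ≥ 0, dx ≥ 10⁻⁶ s, t₀ within one record span
  of the data; convergence requires optimizer success and A₁ > A₂.
* Nested F-tests treat a nested RSS below 10⁻¹² of the response TSS as a
  perfect fit (p = 1) to avoid 0/0 ratios on exact data.
* Intrinsic combustibility requires ≥ 3 balanced pairs and a non-degenerate
  mass range ("intercept unidentifiable" otherwise).
* The λ optimizer uses |xatol| = 10⁻⁸; profile-likelihood ties between the
  interior optimum and a boundary resolve to the higher likelihood.
* Spread rate returns 0 (not an error) for η_M = 0; zero fuel load or depth
  is rejected by fuel-model validation.
* All table readers reject negative masses/lengths/times and mis-ordered
  event times with row-addressed messages; read/write round-trips are
  lossless to CSV precision.

## Problem sizes used in the test suite

Simulation-based checks run at sizes chosen to keep the full suite fast on
a laptop while leaving Monte-Carlo error well inside the asserted
tolerances: λ recovery and PGLS coverage use 200 replicates at 100 tips;
bivariate HPD coverage uses 50 replicates of 25 species × 14 records with
4,000-iteration chains; the end-to-end pipeline check runs the full
25 × 7 design once.  The acceptance script uses 20,000-iteration chains
for the pipeline posterior and 12,000 for the slope-recovery model.

## Known limitations

* The Boltzmann width is a proxy for flaming duration; burns with long
  smouldering tails violate the symmetric-sigmoid assumption.
* The spread model is a point prediction per individual, not a fire-growth
  simulation; its coefficients are empirical and extrapolate poorly to
  fuel beds far from those used to fit them.
* The species-mean PGLS tables approximate individual-level mixed models;
  within-species variance in predictors is ignored there.
* λ estimation on 25 species has low power; boundary p-values are
  asymptotic and conservative at this size.
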