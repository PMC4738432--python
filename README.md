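# grassflam

Grass flammability from plant functional traits: a tested, reusable Python
pipeline for fire ecologists working with burn experiments on herbaceous
fuels.

Grasses fuel most fires on Earth, yet fire-behaviour models usually treat
them as a single homogeneous fuel class.  This package implements the full
analysis chain needed to ask how individual grass species differ in
flammability and which traits drive those differences:

1. **Flammability components** from burn records, at two scales.
   Leaf scale (epiradiator tests): time to ignition *TTI* (ignitability),
   flaming time *FT* (sustainability) and combustion rate = mass / *FT*
   (combustibility), with fresh-minus-dry contrasts isolating the moisture
   effect.  Plant scale (clump burns on a balance): each mass-loss series is
   fitted with a falling Boltzmann sigmoid

   m(t) = A₂ + (A₁ − A₂) / (1 + exp((t − t₀)/dx))

   whose width *dx* is the plant-scale flaming time; the maximum combustion
   rate is the |slope| of an OLS line through the observations within ±3 s of
   the inflection t₀.  Because rate scales with the mass burned, species are
   standardized through the intercept of log₁₀(rate) on log₁₀(mass burned) —
   the species' *intrinsic combustibility* — and a common across-species
   slope extrapolates whole-plant combustion rates.

2. **Explanatory plant traits**: total dry biomass, the vertical
   biomass-packing slope (log₁₀ cumulative dry mass vs height), gravimetric
   moisture content (fresh − dry)/dry, leaf SA/V = 2/thickness, and the
   effective heat of combustion from microcalorimetry replicates.

3. **Fire spread** (community-scale ignitability): the Rothermel
   steady-state surface-fire model, implemented from its published equation
   set for a single fuel class and parameterized entirely from the measured
   traits; R = I_R ξ (1 + φ_w + φ_s) / (ρ_b ε Q_ig), in m/min, with every
   intermediate (reaction intensity, packing ratios, damping coefficients)
   exposed for sensitivity analysis.

4. **Phylogenetic comparative statistics**: Pagel's λ by maximum likelihood
   with boundary likelihood-ratio tests, PGLS trait-contribution
   regressions, and a bivariate Gaussian mixed model (conjugate Gibbs
   sampler, inverse-Wishart priors) separating within-species from
   across-species biomass–combustion slopes with 95% HPD intervals.

5. **A synthetic-study generator** that emulates the full design — 25
   species × 7 individuals, fresh/dry clump pairs, traits evolved on a Yule
   phylogeny under a Brownian/λ model, 0.2-s mass-loss logging — with every
   generating parameter stored, so each stage can be validated against
   known truth.

## Worked example

```python
from grassflam import burncurve, synthdata

bundle = synthdata.gen_study(synthdata.GeneratorSpec(seed=3, n_species=6, n_individuals=4))
s = bundle.mass_loss[0]
fit = burncurve.fit_boltzmann(s)
print(fit.dx, burncurve.max_combustion_rate(s, fit))
```

Running `python examples/03_burn_curves.py` (which wraps the above) prints

```
burn sp1/i1 (fresh):
  fitted width dx   = 2.272 s   (truth 2.277 s)
  inflection t0     = 21.83 s   (truth 21.83 s)
  max combustion    = 0.3440 g/s
  fit R^2           = 0.99995

fresh leaves took 36% longer to ignite than dry leaves
```

The fitted width (flaming time, 2.27 s) matches the value the generator
used to build this burn; the 0.344 g/s is the peak mass-loss rate in the
±3 s inflection window; the last line is the recovered moisture effect on
ignition delay.  The other scripts in `examples/` walk through trait
extraction, spread prediction (including the zero-spread regime above the
moisture of extinction), phylogenetic signal and the bivariate slope model.

The full pipeline, from an input bundle to the species summary tables, the
PGLS coefficient tables, the λ-signal table, the posterior slope summary
and a sign-concordance matrix against the a-priori trait/flammability
prediction matrix:

```bash
grassflam pipeline --config study.yml     # or: grassflam simulate / traits / ...
```

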