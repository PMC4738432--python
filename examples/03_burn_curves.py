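"""Fit a plant-scale mass-loss curve and extract flammability components.

A clump burn logs mass every 0.2 s; the falling Boltzmann sigmoid fitted to
it gives flaming time (the width parameter dx) and, from a +/-3 s window
around the inflection, the maximum combustion rate.  Leaf-scale records
give time to ignition and the fresh-minus-dry moisture effect.
"""

from grassflam import burncurve, synthdata

bundle = synthdata.gen_study(synthdata.GeneratorSpec(seed=3, n_species=6, n_individuals=4))

s = bundle.mass_loss[0]
fit = burncurve.fit_boltzmann(s)
rate = burncurve.max_combustion_rate(s, fit)
truth = bundle.truth["boltzmann"][f"{s.species_id}/{s.individual_id}/{s.state}"]
print(f"burn {s.species_id}/{s.individual_id} ({s.state}):")
print(f"  fitted width dx   = {fit.dx:.3f} s   (truth {truth['dx']:.3f} s)")
print(f"  inflection t0     = {fit.t0:.2f} s   (truth {truth['t0']:.2f} s)")
print(f"  max combustion    = {rate:.4f} g/s")
print(f"  fit R^2           = {fit.r_squared:.5f}")

leaf = burncurve.leaf_metrics_table(bundle.leaf_events)
_, per_species = burncurve.moisture_effect(leaf)
mean_pct = 100 * per_species["tti_s_rel"].mean()
print(f"\nfresh leaves took {mean_pct:.0f}% longer to ignite than dry leaves")
print("(the generator plants a 42% delay; a 6-species study recovers it with")
print("sampling noise, the full 25-species design much more closely)")
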