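"""Extract the five explanatory plant traits from raw measurements.

Moisture content from fresh/dry clump masses, the biomass-density proxy
from vertical biomass profiles (slope of log10 cumulative dry mass against
height), leaf SA/V from thickness, EHoC from calorimetry replicates, and
fuel load as biomass over cover area; then species means with CVs.
"""

from grassflam import synthdata, traits

bundle = synthdata.gen_study(synthdata.GeneratorSpec(seed=1, n_species=8, n_individuals=5))
ind = traits.individual_traits(bundle.trait_table, bundle.profiles, bundle.ehoc_table)
species = traits.aggregate_species(ind)

cols = ["species_id", "biomass_quantity_g_mean", "density_slope_mean",
        "moisture_content_mean", "leaf_sav_mm_mean", "leaf_ehoc_kj_g_mean"]
print(species[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print()
print("Each row is one species: total dry biomass (g), the vertical biomass")
print("packing slope (log10 g per cm; higher = biomass concentrated low),")
print("water per g dry mass, leaf surface-area/volume (per mm) and the")
print("effective heat of combustion (kJ/g).")
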