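"""Convert the printed 2022 survey densities to biomass densities.

Tiger densities are surveyed per 100 km^2 and prey per km^2; multiplying by
mean body masses (tiger 180 kg, pooled prey 54.43 kg on average) gives
biomass densities in kg/km^2 — the quantities the power law relates.
"""

import logging

from predprey import biomass_frame, densities_to_biomass, make_study_fixture, SpeciesWeights

logging.disable(logging.WARNING)  # the 2022 table carries no leopard densities

weights = SpeciesWeights()
print(f"mean prey body mass: {weights.prey_mean:.2f} kg "
      "(arithmetic mean of the seven principal prey species)\n")

biomass = densities_to_biomass(make_study_fixture(), weights)
print(biomass_frame(biomass).to_string(index=False, float_format=lambda v: f"{v:.2f}"))

print("\nEach row is one park in 2022: tiger biomass spans "
      f"{min(r.T for r in biomass):.2f}-{max(r.T for r in biomass):.2f} kg/km^2 "
      f"against prey biomass of {min(r.x for r in biomass):.0f}-"
      f"{max(r.x for r in biomass):.0f} kg/km^2 — roughly three orders of "
      "magnitude more prey than predator biomass.")
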