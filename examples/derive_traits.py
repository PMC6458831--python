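"""Simulate a small drought trial and derive the 14 per-cart traits.

Daily projected shoot area (days 32-59 after planting) is smoothed with a
GCV-penalised natural cubic spline; SAsm is the smoothed area at day 59,
AGR/RGR are absolute and log-scale growth rates over days 32-40, 42-50
and 52-59, and WUE is dry mass per gram of irrigation water.
"""

from namgwas import (SimulationTruth, TraitArchitecture, derive_trait_table,
                     generate_smarthouse, simulate_experiment,
                     simulate_map, simulate_population)

gmap = simulate_map(20, 150.0, seed=11)
pop = simulate_population(gmap, [14, 14, 14], seed=12,
                          allow_any_family_count=True)
layout = generate_smarthouse(list(pop.nam_lines()), zones=2, lanes=4,
                             positions=12, n_check_mainplots_per_zone=2,
                             n_recurrent_mainplots=2, seed=13)
truth = SimulationTruth(
    architecture=TraitArchitecture(intercept=0.0, family_effect_sd=10.0))
psa, harvest = simulate_experiment(pop, layout, truth, seed=14)

traits = derive_trait_table(psa, harvest)
cols = ["SAsm", "AGR42", "RGR42", "DW", "HEI", "TN", "WUE"]
print(traits.groupby("treatment")[cols].mean().round(4))
ratio = (traits.groupby("treatment")["SAsm"].mean()["drought"]
         / traits.groupby("treatment")["SAsm"].mean()["control"])
print(f"\ndrought/control final-area ratio: {ratio:.2f} "
      "(the stress roughly halves final shoot area)")
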