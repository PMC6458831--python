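"""Fit the stage-1 spatial mixed model and extract BLUEs and heritability.

The model corrects genotype-by-treatment means for Smarthouse, linear and
spline lane/position trends and main-plot effects, with a separate
residual variance per Smarthouse x treatment; the companion genotype-
random fit yields the generalised (Cullis) heritability
H2 = 1 - vbar_delta / (2 sigma2_g).
"""

from namgwas import (SimulationTruth, TraitArchitecture,
                     build_design_matrices, cullis_h2, derive_trait_table,
                     extract_blues, fit_stage_one, generate_smarthouse,
                     reduce_model, simulate_experiment, simulate_map,
                     simulate_population)
from namgwas.phenosim import GrowthModel

gmap = simulate_map(15, 150.0, seed=21)
pop = simulate_population(gmap, [14, 14, 14], seed=22,
                          allow_any_family_count=True)
layout = generate_smarthouse(list(pop.nam_lines()), zones=2, lanes=4,
                             positions=12, n_check_mainplots_per_zone=2,
                             n_recurrent_mainplots=2, seed=23)
truth = SimulationTruth(
    architecture=TraitArchitecture(family_effect_sd=10.0),
    growth=GrowthModel(noise_sd=1.0),
    lane_coef={"NE": 3.0}, mainposn_coef={"NE": -1.0})
psa, harvest = simulate_experiment(pop, layout, truth, seed=24)
traits = derive_trait_table(psa, harvest)

fit = reduce_model(fit_stage_one(build_design_matrices(traits, "SAsm")))
print("model reduction decisions:")
for t in fit.tests:
    print(f"  {t['term']:<28s} {t['kind']:<18s} p={t['p']:.4f} "
          f"kept={t['kept']}")

blues = extract_blues(fit, year=2015)
print("\nfirst BLUEs (spatially adjusted genotype x treatment means):")
print(blues.head(6).to_string(index=False))

for trt in ("control", "drought"):
    h2 = cullis_h2(traits, "SAsm", trt)
    print(f"\nCullis H2 for SAsm under {trt}: {h2.h2:.3f} "
          f"(sigma2_g={h2.sigma2_g:.1f}, vbar_delta={h2.vbar_delta:.1f})")
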