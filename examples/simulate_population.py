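"""Simulate a BC1S3 NAM population and check its Mendelian calibration.

Each line descends from one backcross of a donor x recurrent F1 to the
recurrent parent followed by three selfing generations, so at any locus
the expected wild-allele frequency is 1/4 and the expected residual
heterozygosity is 1/16.
"""

import numpy as np

from namgwas import simulate_map, simulate_population, draw_family_sizes

gmap = simulate_map(n_snps_per_chrom=100, chrom_lengths=150.0, seed=1)
sizes = draw_family_sizes(seed=2)  # 25 families, 23-61 lines each
pop = simulate_population(gmap, sizes, seed=3)

d = pop.dosage.loc[pop.nam_lines()].to_numpy()
print(f"lines: {len(pop.nam_lines())}  SNPs: {d.shape[1]}")
print(f"wild-allele frequency: {d.mean() / 2:.4f}   (expected 0.25)")
print(f"heterozygote frequency: {(d == 1).mean():.4f}  (expected {1 / 16:.4f})")

# linkage: dosage correlation decays with map distance on 1H
pos = gmap.positions("1H")
cols = gmap.chromosome_slice("1H")["snp_id"].to_numpy()
first = pop.dosage[cols[0]].loc[pop.nam_lines()]
for j in (1, 10, 50, 99):
    r = np.corrcoef(first, pop.dosage[cols[j]].loc[pop.nam_lines()])[0, 1]
    print(f"corr over {pos[j] - pos[0]:6.1f} cM: {r:+.3f}")
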