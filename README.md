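# namgwas

Simulation and analysis pipeline for drought-phenomics trials on
multi-parent nested association mapping (NAM) barley populations:
from a synthetic BC1S3 population and split-plot greenhouse design,
through smoothing-spline growth traits and spatially adjusted
mixed-model BLUEs with generalised heritability, to a cross-validated
multi-parent GWAS with detection-frequency QTL calling and
parent-specific wild-allele effects.

## Who this is for

Quantitative geneticists and phenomics analysts who want a tested,
reproducible re-implementation of this style of analysis — either to run
on their own plain-TSV trial data, or to study the statistical behaviour
of the design and the detection rule on simulated populations where the
ground truth is known.

## The models

**Population.** 25 wild donors are each crossed to one recurrent elite
parent; the F1 is backcrossed once and selfed three times (BC1S3).
Meioses follow Haldane's map function, `c = (1 − e^(−2d/100))/2` for a
distance of `d` cM. Genotypes are coded identity-by-state as wild-allele
dosage 0/1/2; per locus the pedigree implies frequencies 23/32, 1/16 and
7/32 (wild-allele frequency 1/4).

**Growth traits.** Daily projected shoot area (PSA, kilopixels, days
32–59 after planting) is smoothed per plant with a GCV-penalised natural
cubic spline `S(t)`. The traits are `SAsm = S(59)`,
`AGR = (S(d2) − S(d1))/(d2 − d1)` and
`RGR = (ln S(d2) − ln S(d1))/(d2 − d1)` over days 32–40, 42–50 and
52–59, the image integrals CHA/CL (pass-through), harvest FW, DW, HEI,
TN, and `WUE = DW / total irrigation water`.

**Stage 1 (per year).** `y = Xβ + Zu + e` with fixed mean, Smarthouse,
per-house linear lane/position trends, check class, genotype, treatment
and their interactions (plus a centred Zadoks-stage slope after year 1);
random spline lane/position trends and main-plot effects; and a separate
residual variance for each Smarthouse × treatment, estimated by REML.
Variance components are tested by boundary-corrected REML ratio tests
and fixed trends by Wald F; the reduced model yields genotype ×
treatment BLUEs. A genotype-random companion fit gives the generalised
heritability `H² = 1 − v̄_Δ/(2σ²_g)` (Cullis), with `v̄_Δ` the mean
variance of pairwise genotype-BLUP differences.

**Stage 2.** Per treatment, yearly BLUEs are combined with genotype
fixed and year random; replicated check lines connect the disjoint
yearly line sets.

**GWAS.** On the final BLUEs of the NAM lines (MAF > 1%), model-A
multiple regression `y = μ + X_SNP β_SNP + e` with bidirectional
stepwise cofactor selection on the marginal F test (enter/leave at
p < 0.001), repeated over 20 × 5-fold cross-validation; SNPs or 5-cM
windows selected in ≥ 20 of the 100 runs are putative QTL. Family-nested
joint regression estimates per-donor wild-homozygote substitution
effects; leave-one-QTL-out ΔR² partitions the variance explained. QTL
within 4 cM group into regions, which are classified as
treatment-common or treatment-specific and matched against a
user-supplied gene table (≤ 4 cM).

## Worked example

```bash
python examples/run_gwas.py
```

simulates 25 families (~450 lines, ~1000 SNPs) with one QTL planted at
~10% of phenotypic variance and prints, for example:

```
true QTL: 4H_0072 (4H)

top detection windows (count of 100 CV runs):
chromosome  window_start_cM  window_end_cM  count
        4H             90.0           95.0     54
        4H             85.0           90.0     46
        5H             70.0           75.0      5
...
putative QTL (SNP count >= 20/100): ['4H_0076', '4H_0071']
variance explained by the joint QTL model: 13.0%
```

The injected QTL sits almost on a 5-cM window boundary, so its 100
detections split 54/46 between the two adjacent windows; every
cross-validation run selects a SNP in tight linkage with it, the two
putative SNPs flank it, and the joint model's R² is close to the
simulated 10% variance share. The per-family substitution effects
printed below that scatter around the true value of 2.0 trait units
(twice the per-allele effect). Other examples cover the population simulator,
the split-plot design generator (264 main plots, 36 check main plots
and 72 check replicates per treatment per year), trait derivation,
the stage-1 mixed model, and the full pipeline
(`examples/full_pipeline.py`, or `namgwas run-all --out DIR`).

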