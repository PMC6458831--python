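# Methods

This note documents the models implemented in `namgwas`, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that matter for
reproducibility.

## Population simulator

Each NAM line is simulated gamete by gamete. The donor is assumed fixed
for the wild allele at every marker, so the F1 is fully heterozygous;
per-family polymorphic subsets can be emulated by masking markers
upstream, but are off by default because real per-family segregation
patterns cannot be reconstructed without the original genotypes. One
F1 gamete plus a recurrent gamete forms the BC1 individual; three
selfing generations follow, each with two independent meioses. Meiosis
is a Markov chain along each chromosome: the transmitted haplotype
starts on either parental chromosome with probability 1/2 and switches
between adjacent markers with the Haldane recombination fraction
`c = (1 − e^(−2d/100))/2`. Haldane (no interference) was chosen as the
simplest defensible meiosis model with a closed-form per-interval law.
Missing genotypes can be injected at a configurable rate (default 0).

Per-locus consequences used as calibration oracles: dosage frequencies
(23/32, 1/16, 7/32) for (0, 1, 2) and wild-allele frequency 1/4.
Family sizes default to uniform draws on [23, 61] (25 families,
~1,050 lines in expectation; the emulated study screened ~450 per
year).

## Growth and experiment generator

Shoot growth is logistic,
`PSA(t) = K / (1 + e^(−r (t − t0)))`, with defaults `K = 200` kPix,
`r = 0.25`/day, `t0 = 45` days; a line's latent genetic value shifts
`K` additively. Drought, imposed from day 32 (the first imaging day),
multiplies `K` by 0.50 and `r` by 0.95, chosen so the final-day
drought/control area ratio is ≈ 0.5, the reduction the emulated trials
observed. The logistic form matches the sigmoid trajectories of such
trials and gives closed-form oracles for every derived trait.

Spatial structure is added to the PSA series as a per-cart constant —
Smarthouse shift, per-house linear lane and main-plot-position trends,
a smooth sinusoidal field, a main-plot random deviation, and a per-cart
residual whose spread differs by Smarthouse × treatment — so it
propagates into every derived trait exactly in the form the stage-1
model assumes. Harvest traits are affine functions of final-day PSA
plus trait-specific noise (e.g. FW = 0.55 g/kPix, DW = 7% of the FW
slope, HEI = 30 cm + 0.15 cm/kPix, TN rounded); irrigation totals are
affine in plant size with treatment-specific bases (≈ 9 kg control vs
≈ 2.5 kg drought over the four watered weeks), which reproduces the
observed pattern that control WUE is roughly 60% of drought WUE. CHA
and CL are emitted as proxies proportional to the PSA integral, since
image geometry is out of scope.

What the generator does **not** emulate: crossover interference,
per-family marker polymorphism, dominance or epistasis at the QTL,
genotype-by-year interaction beyond a scalar year shift, germination
failure, and any image-level artefacts. Tests passing on this
generator therefore certify the statistical machinery under the stated
assumptions, not robustness to those excluded features of real data.

## Split-plot design generation

Main plots are consecutive cart pairs along a lane; treatments are
randomised within each pair. Check main plots obey the quota structure
of the emulated experiment (6 per zone; 3 or 4 per east-west column of
main plots, where a column is one of the 11 pair positions), sampled by
sequential weighted draws with retry; recurrent-parent main plots are
spread over distinct zones and columns; remaining main plots receive
the unreplicated test lines by seeded shuffling. The original
experiment used a row-column design optimiser; only its resulting
constraints are reproduced here, because downstream analysis depends on
the quotas, not on the optimiser's objective.

## Trait derivation

Smoothing is `scipy`'s penalised natural cubic smoothing spline with
the penalty chosen by generalised cross-validation (the default of the
spline tool the field uses); a fixed effective-degrees-of-freedom mode
(penalty found by bisection on the smoother trace) is available for
reproducibility. Linear series are in the penalty null space, so AGR of
a linear series is exactly its slope. RGR is set to missing (not an
exception) where the smoothed area is non-positive. If day 59 is
absent, SAsm falls back to the last evaluable day and the `sasm_day`
column flags it. WUE is reported in g dry mass per g water; multiply by
1000 for mg/g. An optional per-year PSA scale factor accommodates
camera changes between years.

## Stage-1 mixed model

Fixed effects: mean; Smarthouse; per-house centred linear lane and
main-plot-position trends; check class (test lines as reference);
genotype (first NAM line alphabetically as reference); treatment
(control reference); check × treatment and genotype × treatment; and,
from the second year on, a per-house slope in the Zadoks score centred
at stage 33. Random effects: natural-cubic-spline bases over the lane
and position grids per house (one variance each) and main plots (always
retained). Residuals: one variance per Smarthouse × treatment (4 groups
with two houses).

The spline random bases are constructed from the Green–Silverman
roughness penalty `K` of the knot grid: with eigendecomposition
`K = UΛU'`, the basis is `U₊Λ₊^(−1/2)`, so iid coefficients imply
roughness `u'u` — a single variance component is then exactly the
smoothing prior (verified by a quadratic-form identity test).

REML estimation works on log-variances with bounded L-BFGS-B from a
method-of-moments initialisation at 0.1×/1×/10×, relative tolerance
1e-8. The likelihood uses the Woodbury identity and the determinant
lemma, so only q×q and p×p systems are factorised; for ≤ 30
observations it agrees with a dense direct evaluation to < 1e-8.
Model reduction: each spline variance is tested by a REML ratio test
with the boundary-corrected `0.5·χ²₀ + 0.5·χ²₁` mixture (α = 0.05);
the 4-group residual structure against a pooled variance by a plain
χ²₃ test; dropped curved trends trigger a Wald F test of the matching
fixed linear trend, and the Zadoks slope is Wald-tested when present.
Wald denominators use the residual degrees of freedom `n − p`
(containment-style); a Kenward–Roger correction was judged
disproportionate for the single covariate test that would use it, and
the interface keeps the df rule swappable.

BLUEs are treatment-wise population marginal means: equal weights over
Smarthouses, centred covariates at 0, Zadoks at 33. Estimability of
each mean is checked against the row space of the full design; missing
plants are dropped listwise. Heritability uses a per-treatment
genotype-random fit (per-house residual variances, fixed linear trends)
and `H² = 1 − v̄_Δ/(2σ̂²_g)` with `v̄_Δ` from the
mixed-model-equation prediction-error-variance matrix; `σ̂²_g = 0`
yields `H² = 0`, and values are clipped to [0, 1] with a warning when
clipping occurs. On balanced data this reproduces `σ²_g/(σ²_g+σ²_e/r)`
to machine precision.

Stage 2 fits genotype (fixed, full dummy coding) plus year (random) per
treatment on the yearly BLUEs, unweighted; one year passes through
unchanged, and a year design with no shared genotypes warns and returns
unadjusted means. Year connectivity comes from the replicated check and
recurrent lines.

## GWAS

MAF is computed over non-missing NAM lines; SNPs at ≤ 1% minor allele
frequency are removed, as are all-missing SNPs (with a warning).
Missing dosages are mean-imputed within family for regression only.

Stepwise selection alternates a forward step (add the excluded SNP with
the smallest marginal-F p-value if below 0.001, computed by
residualising against the current design) and backward sweeps (drop any
included SNP whose drop-one p-value from the full OLS fit is ≥ 0.001).
Ties break deterministically on (p, chromosome, cM, snp_id), making
detection counts invariant to SNP column order. Termination is
guaranteed by the monotone RSS decrease of accepted additions and a
step cap. On small instances the result is verified against exhaustive
enumeration of all "stable" subsets (every member significant given the
rest, no outsider significant given the set).

Cross-validation reshuffles a 5-fold split 20 times; selection runs on
each 4/5 training set. Detection counts are kept both per SNP and per
5-cM map window (tightly linked SNPs substitute for each other across
runs, so window counts are the more stable detection measure and are
what the figures of such studies display); the ≥ 20/100 rule defines
putative QTL. Held-out predictive R² per run is reported but plays no
role in calling.

Parent-specific effects come from a joint regression on family-nested
dosage terms for the whole putative set; the reported effect is twice
the nested slope (wild-homozygote vs recurrent-homozygote
substitution), averaged over CV training runs when splits are supplied.
Families with no dosage variation at a QTL get a missing effect;
rank-deficient joint fits are flagged. A per-family marginal-regression
alternative exists behind the same interface. Variance explained is the
joint-model R², partitioned by leave-one-QTL-out ΔR² — a choice made
explicit because correlated QTL make any partition conventional
(shares are non-negative and sum to at most the total).

**Calibration caveat.** The 20-of-100 detection rule's type-I behaviour
depends on the map's linkage structure. On the simulated genome used in
the tests (~1,000 SNPs on 7 × 150 cM, BC1S3 LD, ~450 lines) the
effective number of independent marginal-F tests is ≈ 190, so under a
global null a noise SNP attains full-data p ≈ 2·10⁻⁴ often enough — and
is then re-selected across the 80%-overlapping training folds — that
roughly one simulated null genome in six to seven produces a spurious
≥ 20/100 call. The rule is a variance filter, not a genome-wise
error-rate guarantee; maps with stronger LD (fewer effective tests)
behave more conservatively.

## Report layer

QTL grouping is single linkage along each chromosome with a strict
≤ 4 cM gap (calls 4.1 cM apart stay separate); chains may span more
than one window, which is inherent to single linkage. Region positions
are detection-count-weighted mean cM. Treatment classification pairs
regions across treatments greedily within the grouping window.
Candidate genes match when within 4 cM (inclusive) of the region
interval on the same chromosome; distance is symmetric and strand-free.
Both the 4-cM grouping window and the 5-cM detection window are
exposed as parameters with those defaults.

## Problem sizes used in the test suite

Unit and calibration tests run on deliberately small instances chosen
to make each property measurable: 2-zone Smarthouses (~64–96 carts) for
the spatial model, 5,000 lines for Mendelian calibration, 25 families ×
18 lines × ~1,000 SNPs for GWAS power and null runs, 10–50 seeds for
Monte-Carlo checks, ≤ 6 SNPs for exhaustive stepwise enumeration. These
sizes are the package's own choice of smallest informative instances;
the pipeline itself handles the full ~1,400-line, ~5,300-SNP scale.

## Known limitations

- Variance-component tests use the simple `0.5/0.5` boundary mixture;
  with several variance parameters near the boundary the mixture
  weights are approximate.
- Wald F degrees of freedom are residual-based, not Kenward–Roger, so
  p-values for the trend tests are slightly liberal in small samples.
- Stage 2 ignores the heterogeneous standard errors of the stage-1
  BLUEs (unweighted combination), as the emulated analysis did.
- The GWAS controls genetic background only through selected cofactors;
  no kinship/mixed-model correction is attempted.
- The detection-frequency rule's false-call rate varies with map LD
  (see the calibration caveat above).
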