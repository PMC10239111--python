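# Methods

## Problem setting

Large longitudinal biobanks assign participants to ancestry groups before
running group-stratified GWAS. Two families of assignment are in use: (i)
classifiers that blend self-identified race/ethnicity with genetic
prediction, producing coarse continental groups, and (ii) purely genetic
assignment against a high-resolution labelled reference panel. When a coarse
group merges genetically distinct populations, a trait whose mean differs
between those populations inflates the association test statistics —
population stratification that the within-group principal components may not
fully absorb. The LD score regression (LDSC) intercept quantifies this
residual confounding. `strataforge` implements the full chain — synthetic
cohort generation, both assignment strategies, supervised admixture
proportions, birth-cohort statistics, GWAS, and LDSC — so that the whole
design can be exercised end to end with known ground truth.

## Synthetic genomes and cohorts (`simpanel`)

**Allele-frequency divergence.** Ancestral frequencies are drawn
Uniform(0.05, 0.95) on a single chromosome with uniformly spaced positions
(default 1 kb). Population `k`'s frequencies follow the Balding–Nichols
model: `p_k ~ Beta(p(1-F_k)/F_k, (1-p)(1-F_k)/F_k)`, giving
`Var(p_k) = F_k p(1-p)`; `F_k = 0` degenerates to the ancestral frequency.
For two populations with per-population drift `F`, the Hudson estimator of
pairwise F_ST concentrates on `F` (checked by a moment oracle in the tests).

**Admixture.** Each cohort draws per-individual admixture vectors `q` from a
cohort-specific Dirichlet prior; genotypes are Binomial(2, Σ_k q_k p_kj).
Coarse self-identified labels are the dominant component mapped through a
configurable fine→coarse map (which may merge populations), with optional
label noise and missingness. Birth years are uniform within per-cohort
ranges; age is reference year (default 2011) minus birth year; the female
fraction defaults to 0.1, typical of veteran cohorts.

**Linkage disequilibrium.** Two genome modes exist. The default is
*unlinked*: conditional on ancestry, variants are independent, and all LD is
of admixture origin. The *block-LD* mode tiles the chromosome with haplotype
blocks (block-constant frequencies); each haploid genome draws one local
ancestry per block from `q`, and successive alleles copy their left
neighbour with probability `rho`, else redraw from the local-ancestry
frequency. This keeps binomial marginals exact and gives genotype
correlation `rho**d` at distance `d` within a block, zero across blocks.

The block mode exists because LDSC's identifying assumption — that
stratification effects are uncorrelated with LD scores — *cannot hold* in a
purely unlinked genome. There, the only LD is admixture LD, with
`r_jk ∝ δ_j δ_k` where `δ_j` is the inter-population frequency gap; but the
stratification inflation of `χ²_j` is itself `∝ δ_j²`, exactly collinear
with the LD score. The regression then books confounding as slope
(spurious heritability) and the intercept stays at 1. With physical LD
dominating `ℓ_j`, the stratification signal is orthogonal to the regressor
and lands on the intercept, as in real genomes. The shipped experiments
therefore use a mixed genome: roughly half the variants are LD-free
singletons, half sit in blocks of mean 9 variants at `rho = 0.9`. The
singletons give the regression a mass of points with `ℓ ≈ 1`, anchoring the
intercept instead of extrapolating to it (measured per-replicate intercept
SE ≈ 0.035 versus ≈ 0.09 with blocks only).

**Phenotype.** `trait = genetic + noise + q·strat_shift + covariate terms`,
with the genetic component a sum of `n_causal` standardized dosages times
normal effects rescaled to variance `h2`, noise variance `1 - h2` (unit
total before shifts), and `strat_shift` a per-population mean offset in
trait-SD units. `strat_shift = 0` yields an unconfounded trait by
construction.

## Ancestry assignment (`ancestry`)

Greedy LD pruning (drop a variant whose r² with any retained variant within
the window exceeds the threshold; defaults r² = 0.01, 1500 kb) precedes a
reference-panel PCA with the usual genotype standardization (centre `2p̂`,
scale `sqrt(2p̂(1-p̂))`, `p̂` from the panel); study samples are projected onto
the frozen loadings without refitting. PC signs follow a
largest-loading-positive convention so runs are comparable. A random forest
(500 trees, sqrt-features, unlimited depth — the explicit rendering of
"default settings") trained on the panel scores assigns labels; a sample
whose maximum class probability is not strictly above 0.5 is Unclassified.
Assigned groups are then refined once: a fresh within-group PCA (top 20
PCs), and any sample farther than 6 *unscaled* median absolute deviations
from the group median on any PC is demoted to Unclassified. The unscaled MAD
(no 1.4826 consistency factor) is the stricter reading and is fixed here;
refinement is a single pass, and the probability threshold is applied before
refinement.

A caution for small panels: at reference size `n`, null `r̂²` has scale
`1/n`, so an r² threshold of 0.01 starts pruning pure noise once
`n ≲ 300` and can decimate the variant set. The defaults mirror large-panel
practice; small-panel configurations (such as `examples/demo.yaml`) should
raise `r2_max` accordingly.

The coarse-blended baseline emulates label-harmonizing classifiers: a random
forest learns the *coarse* label from the genetic PCs on the labelled
samples; a sample keeps its coarse label when it agrees with the genetic
prediction, a missing label is imputed when prediction confidence exceeds
0.5, and any disagreement is Unclassified. For labelled samples the
prediction is taken out-of-bag — a forest memorizes its training points, so
in-bag predictions would never flag a label that contradicts the genetic
structure.

## Supervised admixture EM (`admixture_em`)

Per individual, the genotype at variant `j` is Binomial(2, π_j) with
`π_j = Σ_k q_k p_kj` and fixed reference frequencies (clipped to
`[1e-6, 1 - 1e-6]`). The EM update

    q_k ← (1/2J) Σ_j [ g_j q_k p_kj / π_j + (2-g_j) q_k (1-p_kj) / (1-π_j) ]

is the responsibility-weighted share of allele copies attributed to
population `k`; it is monotone in the likelihood (asserted in tests against
a simplex grid-search oracle). Estimation starts at the uniform simplex and
stops when the per-sample log-likelihood gain drops below 1e-6 (default),
with a warning flag at 2000 iterations. Missing genotypes contribute
nothing. The EM assumes conditional independence across variants; under
block LD the estimates remain consistent but are computed as if variants
were independent, so their implicit precision is overstated — the recovery
experiment uses the unlinked genome.

## Cohort statistics (`cohort_stats`)

Birth cohorts are quantile bins of the midpoint empirical CDF of birth year,
so a single year is never split; a year straddling a cut goes with the
majority of its mass, and pathological tie masses may leave cohorts unequal
(or drop empty ones). Cohen's d uses the pooled-SD form (not Hedges' g).
Two-sided Z-tests compare estimates with standard errors; the Bonferroni
threshold is `alpha / n_tests` with `n_tests` the full factorial count; BH
q-values come from the standard step-up (delegated to statsmodels, verified
against a brute-force oracle). Relative group-size changes are reported
truncated (not rounded) to one decimal, matching the convention of the
tables they imitate; cells under 11 samples are suppressed in reports.

## GWAS (`gwas`)

Per-variant OLS of the trait on dosage plus intercept, age, sex and 10
within-group PCs (computed fresh per group on the LD-pruned variants).
Trait and dosages are residualized on the covariates once
(Frisch–Waugh–Lovell), so the scan is a few matrix products while betas,
SEs and Wald p-values equal the full regression to numerical precision
(normal-equations oracle at 1e-10 in tests). Dosages stay on the
allele-count scale (χ² is scale-free); missing genotypes are mean-imputed
per variant; monomorphic-in-group variants are skipped and counted.

## LD score regression (`ldsc`)

LD scores are `ℓ_j = Σ_k r̃²_jk` over variants within a window (default
1000 kb; the experiments use 100 kb, which generously covers the synthetic
LD range of ≤ ~17 kb — beyond the LD range a wider window only adds
sampling noise), including the self term, with the finite-sample adjustment
`r̃² = r² - (1-r²)/(n-2)` that makes cross terms mean-zero for independent
variants. Scores are computed in-sample on the GWAS group.

When the GWAS adjusted for covariates, the LD scores are computed on the
same covariate-residualized dosages. This keeps regressor and response in
the same space: the χ² statistics no longer contain the admixture LD that
the PCs removed, and leaving it in `ℓ` makes it a variant-level confounder
of the regression that biases the intercept downward (observed directly in
development: merged-group intercepts *below* 1 under strong stratification).

The regression `E[χ²_j] = intercept + (N h²/M) ℓ_j` is fitted by two-step
weighted least squares (first weights `1/max(ℓ,1)`, then
`1/(2 fitted² max(ℓ,1))`, the standard heteroskedasticity + over-counting
weights). Standard errors come from a delete-a-block jackknife over 200
contiguous variant blocks (reduced to `M/10` with a warning when `M` is
small). `h² = slope·M/N` is reported even outside `[0,1]` with a flag. The
attenuation ratio is `(intercept-1)/(mean χ² - 1)` — the proportion of mean
inflation not attributable to polygenicity — and is reported as missing
(NaN) when the mean χ² is at or below 1. Because LD scores and GWAS share
the sample, tagging of out-of-window causal variants through sampling
correlation adds a small uniform term to the intercept in heritable traits;
this does not affect the slope (h²) or any cross-method intercept
*comparison*, which is the quantity of interest.

## Shipped experiments (`experiments`)

All use the mixed singleton/block genome, M = 5000 variants, the 100 kb
LD-score window, and GWAS with age, sex and 10 within-group PCs; sizes were
fixed by the power analysis sketched above.

- **Null calibration** — 20 replicates, n = 2000 admixed samples
  (3 populations, F_ST 0.1, Dirichlet(2,2,2)), `h2 = 0`, no shift. Mean
  intercept should be 1 (20-replicate SE ≈ 0.008).
- **Heritability recovery** — identical design with `h2 = 0.5` over 500
  causal variants; mean LDSC h² should recover 0.5.
- **Confounding detection** — two populations at pairwise F_ST 0.05 with a
  0.5 SD between-population trait gap, 1500 samples each, merged under one
  coarse label versus fine panel assignment (full chain: prune, PCA, random
  forest, MAD refinement). The merged-group GWAS should show the higher
  intercept in nearly every replicate (measured differences ≈ 0.09–0.27
  against ≈ 0.05 SEs).
- **Admixture recovery** — unlinked genome, 3 populations at F_ST 0.1,
  5000 variants, 500 samples, Dirichlet(1,1,1): supervised-EM RMSE against
  the generator's truth (≈ 0.025).
- **Classifier accuracy** — self-classification of a well-separated panel
  (F_ST 0.1, ~1000 variants).

## What the generator does and does not emulate

It reproduces the statistical skeleton the analysis relies on: F_ST-scaled
frequency divergence, cohort-drifting admixture, coarse labels that merge
populations, a confounded polygenic trait, and (optionally) block-local LD.
It does not model recombination maps, LD decay beyond a block, phasing,
genotyping error, relatedness, sex chromosomes, or realistic site-frequency
spectra. Passing tests therefore demonstrate that the *methods* behave
correctly under their stated assumptions, not that effect sizes measured
here transfer to any particular real cohort; in particular real within-group
LD structure is far richer than the block model.

## Numerical and degenerate-input conventions

Frequencies clipped at 1e-6 before logs; zero-variance variants excluded
from PCAs with a log entry; MAD = 0 dimensions skipped in outlier
refinement; groups under 3 members skipped (warning) in refinement; ties at
probability exactly 0.5 are Unclassified (strict inequality); QC order is
variants first, then samples, and the filter is idempotent; all stochastic
stages take explicit seeds, and a pipeline rerun from the same config is
byte-identical.
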