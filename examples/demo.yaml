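# Small end-to-end demonstration: two populations (F_ST = 0.08) whose trait
# means differ by 0.6 SD. Coarse self-identified labels coincide with the
# fine populations here; see strataforge.experiments.confounding_comparison
# for the merged-label scenario. Runs in about a minute on one CPU.
seed: 5
n_variants: 800
n_pops: 2
fst: [0.08, 0.08]
n_per_pop: 80
cohort_sizes: [150, 150]
admixture_priors: [[19, 1], [1, 19]]
birth_year_ranges: [[1940, 1959], [1960, 1985]]
h2: 0.2
n_causal: 80
strat_shift: [0.3, -0.3]
n_pcs: 10
n_trees: 200
n_gwas_pcs: 4
ld_window_kb: 50
n_blocks: 20
min_cell: 50
n_birth_cohorts: 2
# r2 pruning at the default 0.01 assumes a large panel: at n=160 the sampling
# noise of r-hat^2 (~1/n) exceeds the threshold and prunes nearly everything.
r2_max: 0.2
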