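"""Canned simulation experiments: calibration, recovery and confounding.

These functions wire the generator and the analysis modules into the study
designs used to validate the pipeline: null calibration of the LDSC
intercept, heritability recovery, supervised-EM admixture recovery,
classifier accuracy on a well-separated panel, and the headline
coarse-versus-fine assignment comparison in which a coarse label merges two
diverged populations and the merged-group GWAS shows a higher LDSC intercept.

Genomes for the LDSC experiments use the block-LD mode -- roughly half the
variants in haplotype blocks (mean 9 variants at 1 kb spacing, copying
probability 0.9) and half LD-free singletons -- so that LD scores are
dominated by physical LD, which is orthogonal to any stratification axis
(the identifying assumption of the intercept test), and span a wide range
down to 1, anchoring the regression near its intercept. The LD-score window
is 100 kb, comfortably covering the synthetic LD range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ancestry
from .admixture_em import estimate_proportions
from .genotype_io import GenotypeMatrix
from .gwas import run_gwas, within_group_pcs
from .ldsc import compute_ld_scores, ldsc_regression
from .simpanel import (
    CohortSpec,
    PhenotypeSpec,
    PopulationModel,
    ReferencePanel,
    simulate_cohort,
    simulate_phenotype,
    simulate_reference_panel,
)

logger = logging.getLogger("strataforge")

# genome used by the LDSC experiments (see module docstring)
GENOME_LD = {"mean_block_size": 9, "rho": 0.9, "singleton_fraction": 0.9}
LD_WINDOW_KB = 100
N_GWAS_PCS = 10


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _gwas_with_pcs(
    g: GenotypeMatrix,
    pheno: pd.DataFrame,
    members: np.ndarray,
    pruned: np.ndarray,
    n_pcs: int = N_GWAS_PCS,
    **tags,
):
    """Scan one group: age + sex + within-group PCs as covariates."""
    sub = g.subset(samples=members)
    pcs = within_group_pcs(g, members, n_pcs=n_pcs, variant_subset=pruned)
    cov = pd.DataFrame(
        {"age": pheno["age"].to_numpy()[members], "sex": pheno["sex"].to_numpy()[members]}
    )
    for k in range(pcs.shape[1]):
        cov[f"PC{k + 1}"] = pcs[:, k]
    return run_gwas(sub, pheno["trait"].to_numpy()[members], cov, **tags), cov


def _ldsc_for_group(g, pheno, members, pruned, window_kb=LD_WINDOW_KB):
    stats, cov = _gwas_with_pcs(g, pheno, members, pruned)
    scores = compute_ld_scores(
        g.subset(samples=members), window_kb=window_kb, covariates=cov
    )
    return ldsc_regression(stats, scores)


def null_ldsc_calibration(
    n_replicates: int = 20,
    seed: int = 0,
    n_samples: int = 2000,
    n_variants: int = 5000,
) -> np.ndarray:
    """LDSC intercepts for replicated null GWAS (h2 = 0, no confound).

    Each replicate simulates an admixed three-population cohort (F_ST 0.1,
    Dirichlet(2, 2, 2)) with block LD, a pure-noise trait, a GWAS with age,
    sex and 10 within-cohort PCs, and in-sample LD scores. Returns the
    per-replicate intercepts; their mean should sit at 1.
    """
    intercepts = []
    for s in _child_seeds(seed, n_replicates):
        model = PopulationModel.random(
            n_variants, fst=[0.1, 0.1, 0.1], seed=s, **GENOME_LD
        )
        panel = simulate_reference_panel(model, n_per_pop=50, seed=s + 1)
        spec = CohortSpec(
            n_samples=[n_samples],
            admixture_priors=[[2.0, 2.0, 2.0]],
            birth_year_ranges=[(1940, 1990)],
            coarse_label_map={p: "ALL" for p in panel.pop_names},
        )
        g, meta, truth = simulate_cohort(panel, spec, seed=s + 2)
        pheno = simulate_phenotype(
            g, truth, PhenotypeSpec(h2=0.0, n_causal=0), seed=s + 3, metadata=meta
        )
        pruned = ancestry.ld_prune(panel.genotypes)
        fit = _ldsc_for_group(g, pheno, np.arange(g.n_samples), pruned)
        intercepts.append(fit.intercept)
        logger.info("null calibration replicate: intercept %.4f", fit.intercept)
    return np.asarray(intercepts)


def h2_recovery(
    n_replicates: int = 20,
    seed: int = 0,
    h2: float = 0.5,
    n_causal: int = 500,
    n_samples: int = 2000,
    n_variants: int = 5000,
) -> np.ndarray:
    """LDSC heritability estimates for replicated polygenic simulations.

    Same genome and cohort design as the null calibration but with a
    heritable, unconfounded trait; returns per-replicate h2 estimates whose
    mean should recover the generating value.
    """
    h2s = []
    for s in _child_seeds(seed, n_replicates):
        model = PopulationModel.random(
            n_variants, fst=[0.1, 0.1, 0.1], seed=s, **GENOME_LD
        )
        panel = simulate_reference_panel(model, n_per_pop=50, seed=s + 1)
        spec = CohortSpec(
            n_samples=[n_samples],
            admixture_priors=[[2.0, 2.0, 2.0]],
            birth_year_ranges=[(1940, 1990)],
            coarse_label_map={p: "ALL" for p in panel.pop_names},
        )
        g, meta, truth = simulate_cohort(panel, spec, seed=s + 2)
        pheno = simulate_phenotype(
            g, truth, PhenotypeSpec(h2=h2, n_causal=n_causal), seed=s + 3, metadata=meta
        )
        pruned = ancestry.ld_prune(panel.genotypes)
        fit = _ldsc_for_group(g, pheno, np.arange(g.n_samples), pruned)
        h2s.append(fit.h2)
        logger.info("h2 recovery replicate: h2 %.3f", fit.h2)
    return np.asarray(h2s)


@dataclass
class ConfoundingResult:
    """One replicate of the merged- vs fine-assignment comparison."""

    intercept_merged: float
    intercept_fine: float  # sample-size weighted mean over fine groups
    n_merged: int


def confounding_comparison(
    n_replicates: int = 10,
    seed: int = 0,
    fst: float = 0.05,
    trait_gap_sd: float = 0.5,
    n_per_pop: int = 1500,
    n_variants: int = 5000,
    panel_per_pop: int = 150,
) -> list[ConfoundingResult]:
    """Merged-label vs fine-assignment LDSC intercepts under stratification.

    Two populations at pairwise F_ST ``fst`` carry a between-population trait
    shift of ``trait_gap_sd`` SD and are merged under one coarse label
    ("ASN"-style). Fine groups come from the full panel chain (prune, PCA,
    projection, random forest, MAD refinement); the merged group comes from
    the coarse-blended baseline. Every group's GWAS uses age, sex and 10
    within-group PCs; the paper-style expectation is a higher intercept in the
    merged group.
    """
    results = []
    for s in _child_seeds(seed, n_replicates):
        model = PopulationModel.random(
            n_variants, fst=[fst, fst], seed=s, **GENOME_LD
        )
        panel = simulate_reference_panel(model, panel_per_pop, seed=s + 1)
        spec = CohortSpec(
            n_samples=[n_per_pop, n_per_pop],
            admixture_priors=[[19.0, 1.0], [1.0, 19.0]],
            birth_year_ranges=[(1940, 1960), (1961, 1985)],
            coarse_label_map={p: "ASN" for p in panel.pop_names},
        )
        g, meta, truth = simulate_cohort(panel, spec, seed=s + 2)
        shift = np.array([trait_gap_sd / 2.0, -trait_gap_sd / 2.0])
        pheno = simulate_phenotype(
            g, truth, PhenotypeSpec(h2=0.0, n_causal=0, strat_shift=shift),
            seed=s + 3, metadata=meta,
        )
        pruned = ancestry.ld_prune(panel.genotypes)
        model_pca, ref_scores = ancestry.fit_reference_pca(panel, n_pcs=20, pruned=pruned)
        scores = ancestry.project_samples(model_pca, g)
        fine = ancestry.classify_ancestry(
            ref_scores, panel.labels, scores, g.sample_ids, seed=s + 4, n_trees=200
        )
        fine = ancestry.refine_outliers(fine, g, n_pcs=20, variant_subset=pruned)
        merged = ancestry.coarse_blended_assignment(
            scores, meta["coarse_label"], g.sample_ids, seed=s + 5, n_trees=50
        )
        fine_fits = []
        for pop in panel.pop_names:
            members = np.where(fine.labels == pop)[0]
            fit = _ldsc_for_group(g, pheno, members, pruned)
            fine_fits.append((fit, len(members)))
        members_m = np.where(merged.labels == "ASN")[0]
        fit_m = _ldsc_for_group(g, pheno, members_m, pruned)
        w = np.array([n for _, n in fine_fits], dtype=float)
        fine_int = float(np.sum([f.intercept * n for f, n in fine_fits]) / w.sum())
        logger.info(
            "confounding replicate: merged %.4f vs fine %.4f",
            fit_m.intercept, fine_int,
        )
        results.append(
            ConfoundingResult(
                intercept_merged=fit_m.intercept,
                intercept_fine=fine_int,
                n_merged=len(members_m),
            )
        )
    return results


def admixture_recovery(
    seed: int = 0,
    n_samples: int = 500,
    n_variants: int = 5000,
    fst: float = 0.1,
    n_pops: int = 3,
) -> float:
    """RMSE of supervised-EM admixture estimates against the generator's truth."""
    model = PopulationModel.random(n_variants, fst=[fst] * n_pops, seed=seed)
    panel = simulate_reference_panel(model, n_per_pop=100, seed=seed + 1)
    spec = CohortSpec(
        n_samples=[n_samples],
        admixture_priors=[[1.0] * n_pops],
        birth_year_ranges=[(1940, 1990)],
        coarse_label_map={p: "ALL" for p in panel.pop_names},
    )
    g, meta, truth = simulate_cohort(panel, spec, seed=seed + 2)
    props = estimate_proportions(g, panel.pop_freqs, pop_names=panel.pop_names)
    q_true = truth[[f"q_{p}" for p in panel.pop_names]].to_numpy()
    return float(np.sqrt(np.mean((props.q.to_numpy() - q_true) ** 2)))


def classifier_accuracy(
    seed: int = 0,
    n_variants: int = 1000,
    fst: float = 0.1,
    n_pops: int = 3,
    n_per_pop: int = 200,
) -> float:
    """Self-classification accuracy (%) of the panel random forest.

    Well-separated panel (F_ST 0.1, ~1000 pruned variants); the panel's own
    samples are projected and classified against the model fitted on them.
    """
    model = PopulationModel.random(n_variants, fst=[fst] * n_pops, seed=seed)
    panel = simulate_reference_panel(model, n_per_pop=n_per_pop, seed=seed + 1)
    pruned = ancestry.ld_prune(panel.genotypes)
    pca, ref_scores = ancestry.fit_reference_pca(panel, n_pcs=min(20, len(pruned)), pruned=pruned)
    assign = ancestry.classify_ancestry(
        ref_scores, panel.labels, ref_scores, panel.genotypes.sample_ids, seed=seed + 2
    )
    return float(100.0 * np.mean(assign.labels == panel.labels))
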