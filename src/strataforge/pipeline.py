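"""End-to-end experiment runner driven by a YAML configuration.

One config describes a full factorial experiment: simulate a reference panel
and an admixed longitudinal cohort, apply QC, assign ancestry by both the
reference-panel method and the coarse-blended baseline, estimate admixture
proportions, build birth cohorts, and run a GWAS + LD score regression in
every (method x group x cohort) cell, ending with cross-method comparison
tables. Every stage writes tab-delimited files into the run directory so the
pipeline can be re-entered at any point, and a manifest records the config
(hash), seeds and package version. Outputs carry no timestamps: rerunning the
same config reproduces the result tables byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__, ancestry
from .admixture_em import estimate_proportions, group_mean_proportions
from .cohort_stats import assign_birth_cohorts, pairwise_cohort_comparisons, summarize_assignments
from .exceptions import ParameterError, StrataforgeError
from .genotype_io import qc_filter, write_dosage_table, write_vcf
from .gwas import run_gwas, within_group_pcs
from .ldsc import compare_methods, compute_ld_scores, ldsc_regression
from .simpanel import (
    CohortSpec,
    PhenotypeSpec,
    PopulationModel,
    simulate_cohort,
    simulate_phenotype,
    simulate_reference_panel,
)

logger = logging.getLogger("strataforge")

SUPPRESS_BELOW = 11  # privacy-style floor for reported cells


@dataclass
class PipelineConfig:
    """Validated parameters for one pipeline run (flag > file > default)."""

    seed: int
    # genome / panel
    n_variants: int = 2000
    n_pops: int = 3
    fst: list = field(default_factory=lambda: [0.1, 0.1, 0.1])
    spacing_bp: int = 1000
    mean_block_size: int = 1
    rho: float = 0.0
    singleton_fraction: float = 0.0
    n_per_pop: int = 100
    pop_names: list | None = None
    # cohort
    cohort_sizes: list = field(default_factory=lambda: [500, 500])
    admixture_priors: list = field(default_factory=lambda: [[5, 1, 1], [2, 2, 2]])
    birth_year_ranges: list = field(default_factory=lambda: [[1940, 1959], [1960, 1985]])
    coarse_label_map: dict | None = None
    label_noise: float = 0.0
    label_missing_rate: float = 0.0
    # phenotype
    h2: float = 0.3
    n_causal: int = 100
    strat_shift: list | None = None
    sex_effect: float = 0.0
    age_effect: float = 0.0
    # analysis
    maf_min: float = 0.01
    snp_missing_max: float = 0.05
    sample_missing_max: float = 0.03
    r2_max: float = 0.01
    prune_window_kb: int = 1500
    n_pcs: int = 20
    prob_min: float = 0.5
    n_mads: float = 6.0
    n_trees: int = 500
    n_gwas_pcs: int = 10
    ld_window_kb: int = 1000
    n_blocks: int = 200
    n_birth_cohorts: int = 2
    min_cell: int = 50
    write_vcf: bool = False
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ParameterError("config must set an explicit seed")
        if len(self.fst) != self.n_pops:
            raise ParameterError("fst must list one value per population")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "seed" not in raw:
            raise ParameterError("config must set an explicit seed")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig, outdir: str) -> dict:
    """Run the full experiment described by ``config`` into ``outdir``.

    Returns a dict of the in-memory results; all tables are also written to
    ``outdir``. Any stage failure raises with the stage name and cell.
    """
    os.makedirs(outdir, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s) % (2**31) for s in ss.generate_state(8)]
    stage = "simulate"
    try:
        model = PopulationModel.random(
            config.n_variants,
            fst=config.fst,
            seed=seeds[0],
            spacing_bp=config.spacing_bp,
            mean_block_size=config.mean_block_size,
            rho=config.rho,
            singleton_fraction=config.singleton_fraction,
        )
        panel = simulate_reference_panel(
            model, config.n_per_pop, seed=seeds[1], pop_names=config.pop_names
        )
        coarse_map = config.coarse_label_map or {p: p for p in panel.pop_names}
        cohort_spec = CohortSpec(
            n_samples=list(config.cohort_sizes),
            admixture_priors=np.asarray(config.admixture_priors, dtype=float),
            birth_year_ranges=[tuple(r) for r in config.birth_year_ranges],
            coarse_label_map=coarse_map,
            label_noise=config.label_noise,
            label_missing_rate=config.label_missing_rate,
        )
        g, meta, truth = simulate_cohort(panel, cohort_spec, seed=seeds[2])
        pheno_spec = PhenotypeSpec(
            h2=config.h2,
            n_causal=config.n_causal,
            strat_shift=None if config.strat_shift is None else np.asarray(config.strat_shift),
            sex_effect=config.sex_effect,
            age_effect=config.age_effect,
        )
        pheno = simulate_phenotype(g, truth, pheno_spec, seed=seeds[3], metadata=meta)
        write_dosage_table(panel.genotypes, os.path.join(outdir, "panel.dosage.tsv"))
        write_dosage_table(g, os.path.join(outdir, "cohort.dosage.tsv"))
        if config.write_vcf:
            write_vcf(panel.genotypes, os.path.join(outdir, "panel.vcf"))
            write_vcf(g, os.path.join(outdir, "cohort.vcf"))
        _write_tsv(meta, os.path.join(outdir, "metadata.tsv"))
        _write_tsv(truth, os.path.join(outdir, "true_admixture.tsv"))
        _write_tsv(pheno, os.path.join(outdir, "phenotype.tsv"))

        stage = "qc"
        g = qc_filter(g, config.maf_min, config.snp_missing_max, config.sample_missing_max)

        stage = "prune"
        # restrict the panel to the variants that survived cohort QC, then prune
        from .simpanel import ReferencePanel

        shared_ids = set(g.variants["id"])
        keep = np.where(panel.genotypes.variants["id"].isin(shared_ids))[0]
        panel_qc = ReferencePanel(
            panel.genotypes.subset(variants=keep), panel.labels,
            panel.pop_names, panel.pop_freqs[:, keep], panel.model,
        )
        pruned = ancestry.ld_prune(panel_qc.genotypes, config.r2_max, config.prune_window_kb)
        # pruned indexes panel columns; map to the post-QC cohort's columns
        pruned_ids = set(panel_qc.genotypes.variants["id"].to_numpy()[pruned])
        cohort_pruned = np.where(g.variants["id"].isin(pruned_ids))[0]

        stage = "assign"
        n_pcs = min(config.n_pcs, len(pruned), panel_qc.genotypes.n_samples - 1)
        pca, ref_scores = ancestry.fit_reference_pca(panel_qc, n_pcs=n_pcs, pruned=pruned)
        scores = ancestry.project_samples(pca, g)
        a_panel = ancestry.classify_ancestry(
            ref_scores, panel.labels, scores, g.sample_ids,
            prob_min=config.prob_min, seed=seeds[4], n_trees=config.n_trees,
        )
        a_panel = ancestry.refine_outliers(
            a_panel, g, n_pcs=n_pcs, n_mads=config.n_mads, variant_subset=None
        )
        a_coarse = ancestry.coarse_blended_assignment(
            scores, meta["coarse_label"], g.sample_ids,
            seed=seeds[5], conf_min=config.prob_min, n_trees=config.n_trees,
        )
        _write_tsv(a_panel.to_frame(), os.path.join(outdir, "assignments_panel.tsv"))
        _write_tsv(a_coarse.to_frame(), os.path.join(outdir, "assignments_coarse.tsv"))
        counts = summarize_assignments(a_coarse, a_panel)
        _write_tsv(counts, os.path.join(outdir, "assignment_counts.tsv"))

        stage = "admixture"
        # align the panel's realized frequencies with the post-QC variant set
        col_of = {vid: j for j, vid in enumerate(panel.genotypes.variants["id"])}
        shared = [col_of[v] for v in g.variants["id"] if v in col_of]
        props = estimate_proportions(
            g, panel.pop_freqs[:, shared], pop_names=panel.pop_names
        )
        _write_tsv(props.to_frame(), os.path.join(outdir, "admixture_q.tsv"))

        stage = "cohorts"
        bc = assign_birth_cohorts(meta["birth_year"].to_numpy(), config.n_birth_cohorts)
        meta = meta.assign(birth_cohort=bc.cohort)

        stage = "proportion-comparisons"
        qmeans = group_mean_proportions(
            props, a_coarse.labels, cohorts=bc.cohort, min_cell=SUPPRESS_BELOW
        )
        _write_tsv(qmeans, os.path.join(outdir, "proportion_means.tsv"))
        prop_tables = []
        for pop in panel.pop_names:
            tab = pairwise_cohort_comparisons(
                props.q[pop].to_numpy(), bc.cohort, a_coarse.labels
            )
            if len(tab):
                tab.insert(0, "reference_pop", pop)
                prop_tables.append(tab)
        prop_cmp = pd.concat(prop_tables, ignore_index=True) if prop_tables else pd.DataFrame()
        _write_tsv(prop_cmp, os.path.join(outdir, "proportion_changes.tsv"))

        stage = "gwas+ldsc"
        fits: dict[str, dict] = {"panel": {}, "coarse-blended": {}}
        rows = []
        for method, assign in (("panel", a_panel), ("coarse-blended", a_coarse)):
            for group in sorted(set(assign.labels) - {ancestry.UNCLASSIFIED}):
                for cohort in range(1, bc.n_cohorts + 1):
                    members = np.where(
                        (assign.labels == group) & (bc.cohort == cohort)
                    )[0]
                    if len(members) < max(config.min_cell, config.n_gwas_pcs + 3):
                        logger.info(
                            "skipping %s/%s/cohort%d (%d samples)",
                            method, group, cohort, len(members),
                        )
                        continue
                    pcs = within_group_pcs(
                        g, members, n_pcs=config.n_gwas_pcs, variant_subset=cohort_pruned
                    )
                    cov = pd.DataFrame(
                        {"age": meta["age"].to_numpy()[members],
                         "sex": meta["sex"].to_numpy()[members]}
                    )
                    for k in range(pcs.shape[1]):
                        cov[f"PC{k + 1}"] = pcs[:, k]
                    stats = run_gwas(
                        g.subset(samples=members),
                        pheno["trait"].to_numpy()[members],
                        cov, min_n=config.min_cell,
                        group=group, cohort=str(cohort), method=method,
                    )
                    stats.write(os.path.join(
                        outdir, f"sumstats_{method}_{group}_bc{cohort}.tsv"
                    ))
                    scores = compute_ld_scores(
                        g.subset(samples=members),
                        window_kb=config.ld_window_kb,
                        covariates=cov,
                    )
                    fit = ldsc_regression(stats, scores, n_blocks=config.n_blocks)
                    fits[method][(group, cohort)] = fit
                    rows.append({"method": method, "group": group, "cohort": cohort,
                                 **fit.to_dict()})
        ldsc_table = pd.DataFrame(rows)
        _write_tsv(ldsc_table, os.path.join(outdir, "ldsc_fits.tsv"))

        stage = "compare"
        shared = sorted(set(fits["coarse-blended"]) & set(fits["panel"]))
        comparison = compare_methods(
            {c: fits["coarse-blended"][c] for c in shared},
            {c: fits["panel"][c] for c in shared},
        ) if shared else pd.DataFrame()
        _write_tsv(comparison, os.path.join(outdir, "method_comparison.tsv"))

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "config": asdict(config),
            "config_sha256": config.digest(),
            "stage_seeds": seeds,
            "n_variants_post_qc": int(g.n_variants),
            "n_pruned": int(len(pruned)),
        }
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except StrataforgeError as exc:
        raise StrataforgeError(f"stage {stage!r} failed: {exc}") from exc
    return {
        "assignments": {"panel": a_panel, "coarse-blended": a_coarse},
        "counts": counts,
        "proportions": props,
        "proportion_changes": prop_cmp,
        "ldsc_fits": fits,
        "ldsc_table": ldsc_table,
        "comparison": comparison,
        "manifest": manifest,
    }


def _fmt_count(n: int) -> str:
    return f"<{SUPPRESS_BELOW}" if 0 < n < SUPPRESS_BELOW else str(n)


def report(outdir: str) -> str:
    """Render a plain-text summary of a finished run directory.

    Raises :class:`EmptyInputError` when the bundle has no results; lists
    missing tables when the bundle is incomplete.
    """
    from .exceptions import EmptyInputError

    required = ["assignment_counts.tsv", "ldsc_fits.tsv", "proportion_changes.tsv"]
    missing = [f for f in required if not os.path.exists(os.path.join(outdir, f))]
    if len(missing) == len(required):
        raise EmptyInputError(f"no result tables in {outdir}")
    lines = [f"strataforge run report: {outdir}", ""]
    if missing:
        lines.append("INCOMPLETE BUNDLE, missing: " + ", ".join(missing))
    if "assignment_counts.tsv" not in missing:
        counts = pd.read_csv(os.path.join(outdir, "assignment_counts.tsv"), sep="\t")
        lines.append("Assignment counts (method 1 = coarse-blended, 2 = panel):")
        for r in counts.itertuples(index=False):
            rel = "" if math.isnan(r.relative_change_pct) else f"  change {r.relative_change_pct:+.1f}%"
            lines.append(
                f"  {r.group:<14} {_fmt_count(r.n_method1):>8} {_fmt_count(r.n_method2):>8}{rel}"
            )
        lines.append("")
    if "ldsc_fits.tsv" not in missing:
        fits = pd.read_csv(os.path.join(outdir, "ldsc_fits.tsv"), sep="\t")
        lines.append("LDSC fits per (method, group, cohort):")
        for r in fits.itertuples(index=False):
            ar = "NA" if pd.isna(r.attenuation_ratio) else f"{r.attenuation_ratio:.2f}"
            lines.append(
                f"  {r.method:<15} {r.group:<10} bc{r.cohort}  intercept "
                f"{r.intercept:.3f} +- {r.intercept_se:.3f}  mean chi2 {r.mean_chi2:.3f}  AR {ar}"
            )
        lines.append("")
        cmp_path = os.path.join(outdir, "method_comparison.tsv")
        if os.path.exists(cmp_path) and os.path.getsize(cmp_path) > 1:
            try:
                cmp_df = pd.read_csv(cmp_path, sep="\t")
            except pd.errors.EmptyDataError:
                cmp_df = pd.DataFrame()
            if len(cmp_df):
                lines.append("Intercept comparisons (coarse-blended minus panel):")
                for r in cmp_df.itertuples(index=False):
                    lines.append(
                        f"  {r.cell:<20} diff {r.intercept_diff:+.3f}  p {r.p_intercept:.3g}"
                        f"  q {r.q_intercept:.3g}"
                    )
                lines.append("")
    if "proportion_changes.tsv" not in missing:
        path = os.path.join(outdir, "proportion_changes.tsv")
        try:
            pc = pd.read_csv(path, sep="\t")
        except pd.errors.EmptyDataError:
            pc = pd.DataFrame()
        if len(pc):
            lines.append("Ancestry-proportion changes between birth cohorts:")
            for r in pc.itertuples(index=False):
                star = "*" if r.q < 0.05 else ""
                lines.append(
                    f"  {r.group:<10} {r.reference_pop:<8} bc{r.cohortA}->bc{r.cohortB}"
                    f"  d {r.d:+.3f}  p {r.p:.3g}{star}"
                )
    return "\n".join(lines) + "\n"
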