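"""Per-group association scan of a quantitative trait.

Each variant is tested by ordinary least squares of the trait on the
alt-allele dosage plus an intercept and fixed covariates (age, sex and
within-group PCs). The implementation residualizes the trait and all dosage
columns on the covariates once (Frisch-Waugh-Lovell), so per-variant betas,
SEs and Wald p-values match the full regression exactly while the scan stays
a handful of matrix products. Dosages are left on the allele-count scale
(chi-square statistics are scale-invariant); missing genotypes are
mean-imputed per variant; monomorphic-in-group variants are skipped and
counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError
from .genotype_io import GenotypeMatrix

logger = logging.getLogger("strataforge")

SUMSTATS_COLUMNS = ["SNP", "CHR", "POS", "A1", "A2", "BETA", "SE", "P", "CHISQ", "N"]


@dataclass
class SummaryStats:
    """Per-variant association results plus scan provenance tags."""

    table: pd.DataFrame
    group: str = ""
    cohort: str = ""
    method: str = ""
    n_skipped: int = 0

    @property
    def n_variants(self) -> int:
        return len(self.table)

    @property
    def mean_chi2(self) -> float:
        return float(self.table["CHISQ"].mean())

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path, **tags) -> "SummaryStats":
        return cls(pd.read_csv(path, sep="\t"), **tags)


def within_group_pcs(
    g: GenotypeMatrix,
    members: np.ndarray,
    n_pcs: int = 10,
    variant_subset: np.ndarray | None = None,
) -> np.ndarray:
    """Fresh PCA on one group's members (LD-pruned variants recommended).

    Returns the ``(len(members), n_pcs)`` score matrix for those members only.
    """
    members = np.asarray(members)
    if len(members) < n_pcs + 2:
        raise ParameterError(
            f"group of {len(members)} too small for {n_pcs} PCs (need n_pcs + 2)"
        )
    sub = g.subset(samples=members, variants=variant_subset)
    x = sub.mean_imputed()
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    ok = sd > 0
    z = x[:, ok] / sd[ok]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    k = min(n_pcs, len(s))
    return u[:, :k] * s[:k]


def run_gwas(
    g: GenotypeMatrix,
    trait,
    covariates: pd.DataFrame | None = None,
    min_n: int = 50,
    group: str = "",
    cohort: str = "",
    method: str = "",
) -> SummaryStats:
    """OLS association scan: trait ~ dosage + covariates + intercept.

    Complete cases only for trait/covariates; requires at least ``min_n``
    samples. Raises on a rank-deficient covariate matrix, naming the
    collinear columns.
    """
    y = np.asarray(trait, dtype=float)
    if len(y) != g.n_samples:
        raise ParameterError("trait length must match the genotype samples")
    if covariates is not None:
        if len(covariates) != g.n_samples:
            raise ParameterError("covariates must align with the genotype samples")
        cov = covariates.to_numpy(dtype=float)
        complete = ~np.isnan(y) & ~np.isnan(cov).any(axis=1)
    else:
        cov = np.empty((g.n_samples, 0))
        complete = ~np.isnan(y)
    if complete.sum() < min_n:
        raise ParameterError(f"only {complete.sum()} complete cases (need >= {min_n})")
    y = y[complete]
    cov = cov[complete]
    n = len(y)
    c = np.column_stack([np.ones(n), cov])
    rank = np.linalg.matrix_rank(c)
    if rank < c.shape[1]:
        names = ["intercept"] + (list(covariates.columns) if covariates is not None else [])
        raise ParameterError(
            f"rank-deficient covariate matrix (rank {rank} < {c.shape[1]}); "
            f"columns: {names}"
        )
    q, _ = np.linalg.qr(c)
    x = g.mean_imputed()[complete]
    polymorphic = x.std(axis=0) > 0
    n_skipped = int((~polymorphic).sum())
    if n_skipped:
        logger.info("run_gwas: skipped %d monomorphic variants", n_skipped)
    x = x[:, polymorphic]
    # residualize on covariates (Frisch-Waugh-Lovell)
    y_r = y - q @ (q.T @ y)
    x_r = x - q @ (q.T @ x)
    gx = (x_r**2).sum(axis=0)
    gy = x_r.T @ y_r
    beta = gy / gx
    df = n - c.shape[1] - 1
    if df < 1:
        raise ParameterError("non-positive residual degrees of freedom")
    rss = (y_r**2).sum() - beta * gy
    sigma2 = np.maximum(rss, 0.0) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 / gx)
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    v = g.variants.loc[polymorphic].reset_index(drop=True)
    table = pd.DataFrame(
        {
            "SNP": v["id"], "CHR": v["chrom"], "POS": v["pos"],
            "A1": v["alt"], "A2": v["ref"],
            "BETA": beta, "SE": se, "P": p, "CHISQ": tstat**2,
            "N": n,
        },
        columns=SUMSTATS_COLUMNS,
    )
    return SummaryStats(table, group=group, cohort=cohort, method=method, n_skipped=n_skipped)
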