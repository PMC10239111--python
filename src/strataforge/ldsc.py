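"""LD score regression: intercept, heritability slope and attenuation ratio.

The expected association chi-square under a polygenic model is

    E[chi2_j] = intercept + (N h2 / M) * l_j,

where ``l_j`` is variant j's LD score: the sum over nearby variants (within a
window, including itself) of the bias-adjusted squared correlation
``r~2 = r2 - (1 - r2) / (n - 2)``. An intercept above 1 signals inflation not
attributable to polygenicity (population stratification and other
confounding); the attenuation ratio ``(intercept - 1) / (mean chi2 - 1)`` is
the fraction of the mean inflation so attributed. The regression is a
two-step weighted least squares (heteroskedasticity + over-counting weights,
as in standard LDSC); standard errors come from a delete-a-block jackknife
over contiguous variant blocks.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_stats import fdr_adjust, z_test_difference
from .exceptions import ParameterError
from .genotype_io import GenotypeMatrix
from .gwas import SummaryStats

logger = logging.getLogger("strataforge")


@dataclass
class LdScores:
    """Per-variant LD scores with their computation settings."""

    scores: np.ndarray
    variant_ids: np.ndarray
    window_kb: int
    n: int
    bias_adjusted: bool = True


@dataclass
class LdscFit:
    """LD score regression fit for one GWAS."""

    intercept: float
    intercept_se: float
    slope: float
    h2: float
    h2_se: float
    mean_chi2: float
    attenuation_ratio: float  # nan when mean chi2 <= 1
    ar_se: float
    n_blocks: int
    m_variants: int
    n_samples: float
    h2_out_of_range: bool = False

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept, "intercept_se": self.intercept_se,
            "h2": self.h2, "h2_se": self.h2_se, "mean_chi2": self.mean_chi2,
            "attenuation_ratio": self.attenuation_ratio, "ar_se": self.ar_se,
            "n_blocks": self.n_blocks, "M": self.m_variants, "N": self.n_samples,
        }


def compute_ld_scores(
    g: GenotypeMatrix, window_kb: int = 1000, covariates=None
) -> LdScores:
    """In-sample LD scores with the finite-sample bias adjustment.

    ``l_j = sum_k r~2_jk`` over variants k within ``window_kb`` of j on the
    same chromosome, including j itself (self term 1). The adjustment
    ``r~2 = r2 - (1 - r2)/(n - 2)`` makes cross terms mean-zero for truly
    uncorrelated variants.

    When ``covariates`` (the GWAS covariate matrix, e.g. the within-group
    PCs) is given, genotypes are residualized on them first, so the LD
    scores describe the correlation structure of the same adjusted dosages
    that produced the chi-square statistics. Without this, admixture LD --
    which the covariates have already removed from the test statistics --
    remains in the regressor and distorts the intercept.
    """
    n = g.n_samples
    if n < 3:
        raise ParameterError("need >= 3 samples for adjusted LD scores")
    x = g.mean_imputed()
    x = x - x.mean(axis=0)
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.shape[0] != n:
            raise ParameterError("covariates must align with the genotype samples")
        cov = cov - cov.mean(axis=0)
        q, _ = np.linalg.qr(cov)
        x = x - q @ (q.T @ x)
    norms = np.sqrt((x**2).sum(axis=0))
    nz = norms > 0
    x[:, nz] /= norms[nz]
    window_bp = window_kb * 1000
    m = g.n_variants
    scores = np.ones(m)
    chroms = g.variants["chrom"].to_numpy()
    pos = g.positions
    adj = 1.0 / (n - 2)
    block = 512
    for chrom in pd.unique(chroms):
        idx = np.where(chroms == chrom)[0]
        cpos = pos[idx]
        for start in range(0, len(idx), block):
            sel = idx[start:start + block]
            lo = np.searchsorted(cpos, pos[sel[0]] - window_bp, side="left")
            hi = np.searchsorted(cpos, pos[sel[-1]] + window_bp, side="right")
            neigh = idx[lo:hi]
            r = x[:, neigh].T @ x[:, sel]  # (n_neigh, n_sel)
            r2 = r**2
            r2adj = r2 - (1.0 - r2) * adj
            in_win = np.abs(pos[neigh][:, None] - pos[sel][None, :]) <= window_bp
            not_self = neigh[:, None] != sel[None, :]
            scores[sel] = 1.0 + (r2adj * in_win * not_self).sum(axis=0)
    return LdScores(
        scores=scores,
        variant_ids=g.variants["id"].to_numpy(),
        window_kb=window_kb,
        n=n,
    )


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least squares of y on [1, x]; returns (intercept, slope)."""
    sw = w.sum()
    mx = (w * x).sum() / sw
    my = (w * y).sum() / sw
    sxx = (w * (x - mx) ** 2).sum()
    if sxx <= 0:
        raise ParameterError("zero variance in LD scores")
    slope = (w * (x - mx) * (y - my)).sum() / sxx
    return my - slope * mx, slope


def _two_step_fit(l: np.ndarray, chi2: np.ndarray) -> tuple[float, float]:
    w = 1.0 / np.maximum(l, 1.0)
    a, b = _wls_line(l, chi2, w)
    fitted = np.maximum(a + b * l, 0.05)
    w2 = 1.0 / (2.0 * fitted**2 * np.maximum(l, 1.0))
    return _wls_line(l, chi2, w2)


def ldsc_regression(
    s: SummaryStats, l: LdScores, n_blocks: int = 200
) -> LdscFit:
    """Two-step weighted LD score regression with block-jackknife SEs.

    Variants are matched between the summary statistics and the LD scores by
    ID. When the variant count is below ``2 * n_blocks`` the block count is
    reduced to ``M // 10`` with a warning.
    """
    score_of = dict(zip(l.variant_ids, l.scores))
    tab = s.table
    mask = tab["SNP"].isin(score_of).to_numpy()
    if mask.sum() == 0:
        raise ParameterError("no variants shared between sumstats and LD scores")
    tab = tab.loc[mask]
    ell = np.array([score_of[v] for v in tab["SNP"]])
    chi2 = tab["CHISQ"].to_numpy(dtype=float)
    m = len(chi2)
    n_samp = float(tab["N"].median())
    if n_blocks > m:
        raise ParameterError(f"n_blocks={n_blocks} exceeds M={m}")
    if m < 2 * n_blocks:
        n_blocks = max(2, m // 10)
        warnings.warn(f"few variants: reducing jackknife blocks to {n_blocks}")
    if np.allclose(ell.var(), 0):
        raise ParameterError("zero variance in LD scores")

    intercept, slope = _two_step_fit(ell, chi2)
    mean_chi2 = float(chi2.mean())
    h2 = slope * m / n_samp

    # delete-a-block jackknife over contiguous variant blocks
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    ints, h2s, ars = [], [], []
    for b in range(n_blocks):
        keep = np.r_[0:edges[b], edges[b + 1]:m]
        a_b, s_b = _two_step_fit(ell[keep], chi2[keep])
        ints.append(a_b)
        h2s.append(s_b * m / n_samp)
        mc = chi2[keep].mean()
        ars.append((a_b - 1.0) / (mc - 1.0) if mc > 1.0 else np.nan)
    ints = np.asarray(ints)
    h2s = np.asarray(h2s)
    fac = (n_blocks - 1) / n_blocks
    intercept_se = math.sqrt(fac * ((ints - ints.mean()) ** 2).sum())
    h2_se = math.sqrt(fac * ((h2s - h2s.mean()) ** 2).sum())
    ar = attenuation_ratio(intercept, mean_chi2)
    ars = np.asarray(ars)
    if math.isnan(ar) or np.isnan(ars).any():
        ar_se = float("nan")
    else:
        ar_se = math.sqrt(fac * ((ars - ars.mean()) ** 2).sum())
    return LdscFit(
        intercept=intercept,
        intercept_se=intercept_se,
        slope=slope,
        h2=h2,
        h2_se=h2_se,
        mean_chi2=mean_chi2,
        attenuation_ratio=ar,
        ar_se=ar_se,
        n_blocks=n_blocks,
        m_variants=m,
        n_samples=n_samp,
        h2_out_of_range=not 0.0 <= h2 <= 1.0,
    )


def attenuation_ratio(intercept: float, mean_chi2: float) -> float:
    """(intercept - 1) / (mean chi2 - 1); NaN when the mean chi2 is <= 1.

    The NaN return is the "not defined" flag: with no inflation of the mean
    statistic there is no inflation to apportion.
    """
    if mean_chi2 <= 1.0:
        return float("nan")
    return (intercept - 1.0) / (mean_chi2 - 1.0)


def compare_methods(fits_method1: dict, fits_method2: dict) -> pd.DataFrame:
    """Z-tests of intercepts and attenuation ratios per (group x cohort) cell.

    ``fits_method1``/``fits_method2`` map cell keys (e.g. ``(group, cohort)``)
    to :class:`LdscFit`. Returns one row per cell with FDR q-values across
    cells; the mean intercept reduction (method1 - method2) and its SE across
    cells are stored in ``DataFrame.attrs``.
    """
    if set(fits_method1) != set(fits_method2):
        raise ParameterError("mismatched cells between the two methods")
    rows = []
    for cell in sorted(fits_method1):
        f1, f2 = fits_method1[cell], fits_method2[cell]
        z_i, p_i = z_test_difference(f1.intercept, f1.intercept_se, f2.intercept, f2.intercept_se)
        if any(math.isnan(v) for v in (f1.attenuation_ratio, f1.ar_se, f2.attenuation_ratio, f2.ar_se)) or f1.ar_se <= 0 or f2.ar_se <= 0:
            z_a, p_a = float("nan"), float("nan")
        else:
            z_a, p_a = z_test_difference(
                f1.attenuation_ratio, f1.ar_se, f2.attenuation_ratio, f2.ar_se
            )
        rows.append(
            {
                "cell": str(cell),
                "intercept_1": f1.intercept, "intercept_2": f2.intercept,
                "intercept_diff": f1.intercept - f2.intercept,
                "Z_intercept": z_i, "p_intercept": p_i,
                "ar_1": f1.attenuation_ratio, "ar_2": f2.attenuation_ratio,
                "Z_ar": z_a, "p_ar": p_a,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q_intercept"] = fdr_adjust(df["p_intercept"].to_numpy())
        ok = df["p_ar"].notna()
        df["q_ar"] = np.nan
        if ok.any():
            df.loc[ok, "q_ar"] = fdr_adjust(df.loc[ok, "p_ar"].to_numpy())
        diffs = df["intercept_diff"].to_numpy()
        df.attrs["mean_intercept_reduction"] = float(diffs.mean())
        df.attrs["mean_intercept_reduction_se"] = (
            float(diffs.std(ddof=1) / math.sqrt(len(diffs))) if len(diffs) > 1 else float("nan")
        )
    return df
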