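"""Birth-cohort construction and between-group comparison statistics.

Covers quantile birth cohorts (year-granular: a birth year is never split
across cohorts), Cohen's d with the pooled SD, two-sided Z-tests for
differences of estimates with standard errors, Bonferroni thresholds,
Benjamini-Hochberg q-values, assignment-count summaries with relative group
size changes, and the regression of between-cohort trait change on
between-cohort ancestry-proportion change.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ParameterError

logger = logging.getLogger("strataforge")


@dataclass
class BirthCohortLabels:
    """Per-sample cohort index (1..C) and the observed year boundaries."""

    cohort: np.ndarray
    boundaries: list  # [(min_year, max_year), ...] per cohort

    @property
    def n_cohorts(self) -> int:
        return len(self.boundaries)


def assign_birth_cohorts(birth_years, n_cohorts: int = 5) -> BirthCohortLabels:
    """Quantile-based birth cohorts from the empirical CDF of birth year.

    Cut points sit at the quantiles ``i / C`` of the year distribution; every
    sample born in the same year lands in the same cohort, so cohort sizes can
    be unequal when years carry large tied masses. A year straddling a cut is
    placed with the majority of its mass (midpoint empirical CDF). Cohorts
    left empty by ties are dropped and the remaining ones renumbered
    consecutively.
    """
    years = np.asarray(birth_years)
    if np.any(pd.isna(years)):
        raise ParameterError("birth years must be non-missing")
    if n_cohorts < 1:
        raise ParameterError("n_cohorts must be >= 1")
    if len(np.unique(years)) < n_cohorts:
        raise ParameterError("fewer distinct birth years than cohorts")
    order = np.sort(years)
    # midpoint empirical CDF: F(y) = P(Y < y) + P(Y = y) / 2
    left = np.searchsorted(order, years, side="left")
    right = np.searchsorted(order, years, side="right")
    cdf = (left + right) / (2 * len(years))
    raw = np.minimum(np.ceil(cdf * n_cohorts).astype(int), n_cohorts)
    raw = np.maximum(raw, 1)
    present = np.unique(raw)
    remap = {c: i + 1 for i, c in enumerate(present)}
    cohort = np.array([remap[c] for c in raw])
    boundaries = [
        (int(years[cohort == c].min()), int(years[cohort == c].max()))
        for c in range(1, len(present) + 1)
    ]
    logger.info("birth cohorts: %s", boundaries)
    return BirthCohortLabels(cohort=cohort, boundaries=boundaries)


def cohens_d(x, y) -> float:
    """Standardized mean difference with the pooled (Cohen) SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ParameterError("each group needs at least 2 observations")
    nx, ny = len(x), len(y)
    pooled = math.sqrt(
        ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    )
    if pooled == 0:
        raise ParameterError("zero pooled SD: effect size undefined")
    return (x.mean() - y.mean()) / pooled


def z_test_difference(est1: float, se1: float, est2: float, se2: float):
    """Two-sided Z-test for a difference of two independent estimates."""
    if se1 <= 0 or se2 <= 0:
        raise ParameterError("standard errors must be positive")
    z = (est1 - est2) / math.sqrt(se1**2 + se2**2)
    p = 2.0 * stats.norm.sf(abs(z))
    return z, p


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 1) -> float:
    if n_tests < 1:
        raise ParameterError("n_tests must be >= 1")
    return alpha / n_tests


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg q-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def truncate_percent(x: float, decimals: int = 1) -> float:
    """Truncate (toward zero) a percentage to the printed precision."""
    f = 10**decimals
    return math.trunc(x * f) / f


def compare_count_tables(
    counts1: dict, counts2: dict, unclassified_label: str = "Unclassified"
) -> pd.DataFrame:
    """Per-group counts for two assignment methods with derived ratios.

    Relative change is ``100 * (n2 - n1) / n1`` truncated to one decimal
    (method 1 is the baseline); the unclassified percentage is relative to
    each method's total.
    """
    groups = sorted(set(counts1) | set(counts2), key=lambda s: (s == unclassified_label, s))
    n1 = np.array([counts1.get(gp, 0) for gp in groups], dtype=float)
    n2 = np.array([counts2.get(gp, 0) for gp in groups], dtype=float)
    rel = np.array(
        [
            truncate_percent(100.0 * (b - a) / a) if a > 0 else np.nan
            for a, b in zip(n1, n2)
        ]
    )
    df = pd.DataFrame(
        {"group": groups, "n_method1": n1.astype(int), "n_method2": n2.astype(int),
         "relative_change_pct": rel}
    )
    tot1, tot2 = n1.sum(), n2.sum()
    unc1 = counts1.get(unclassified_label, 0)
    unc2 = counts2.get(unclassified_label, 0)
    df.attrs["total_method1"] = int(tot1)
    df.attrs["total_method2"] = int(tot2)
    df.attrs["unclassified_pct_method1"] = 100.0 * unc1 / tot1 if tot1 else np.nan
    df.attrs["unclassified_pct_method2"] = 100.0 * unc2 / tot2 if tot2 else np.nan
    return df


def summarize_assignments(a_method1, a_method2) -> pd.DataFrame:
    """Count table comparing two :class:`AncestryAssignment` results."""
    ids1 = set(a_method1.sample_ids)
    ids2 = set(a_method2.sample_ids)
    if ids1 != ids2:
        raise ParameterError("the two assignments cover different sample sets")
    return compare_count_tables(a_method1.counts(), a_method2.counts())


def regress_change_on_change(d_trait, d_prop):
    """OLS of between-cohort trait change on ancestry-proportion change.

    One observation per within-group cohort pair. Returns (slope, two-sided p).
    """
    d_trait = np.asarray(d_trait, dtype=float)
    d_prop = np.asarray(d_prop, dtype=float)
    if len(d_trait) != len(d_prop) or len(d_trait) < 3:
        raise ParameterError("need >= 3 cohort pairs with matching lengths")
    if np.allclose(d_prop.var(), 0):
        raise ParameterError("zero variance in the ancestry-proportion changes")
    fit = sm.OLS(d_trait, sm.add_constant(d_prop)).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


def pairwise_cohort_comparisons(
    values: pd.Series, cohorts: np.ndarray, groups: np.ndarray
) -> pd.DataFrame:
    """All within-group cohort-pair comparisons of a per-sample quantity.

    For each group and each (earlier, later) cohort pair: difference in
    means, Cohen's d, Z statistic from the per-cohort mean SEs (SD / sqrt(n))
    and its two-sided p. The number of tests for Bonferroni correction is the
    number of rows, logged explicitly.
    """
    values = np.asarray(values, dtype=float)
    cohorts = np.asarray(cohorts)
    groups = np.asarray(groups, dtype=object)
    rows = []
    for gp in sorted(set(groups)):
        gmask = groups == gp
        levels = sorted(set(cohorts[gmask]))
        for i, ca in enumerate(levels):
            for cb in levels[i + 1:]:
                x = values[gmask & (cohorts == ca)]
                y = values[gmask & (cohorts == cb)]
                if len(x) < 2 or len(y) < 2:
                    continue
                try:
                    d = cohens_d(y, x)
                except ParameterError:
                    continue
                z, p = z_test_difference(
                    y.mean(), y.std(ddof=1) / math.sqrt(len(y)),
                    x.mean(), x.std(ddof=1) / math.sqrt(len(x)),
                )
                rows.append(
                    {"group": gp, "cohortA": ca, "cohortB": cb,
                     "meanA": x.mean(), "meanB": y.mean(),
                     "diff": y.mean() - x.mean(), "d": d, "Z": z, "p": p}
                )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = fdr_adjust(df["p"].to_numpy())
        logger.info("pairwise cohort comparisons: %d tests", len(df))
    return df
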