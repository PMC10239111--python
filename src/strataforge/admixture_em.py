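"""Supervised admixture-proportion estimation by per-individual EM.

Each individual's genotype at variant ``j`` is modelled as Binomial(2, pi_j)
with pi_j = sum_k q_k p_kj, where the reference-population frequencies p_kj
are fixed and only the simplex vector q is estimated. The log-likelihood

    l(q) = sum_j [ g_j log(pi_j) + (2 - g_j) log(1 - pi_j) ]

is maximized by the EM update

    q_k <- (1 / 2J) sum_j [ g_j * q_k p_kj / pi_j
                            + (2 - g_j) * q_k (1 - p_kj) / (1 - pi_j) ],

which is the responsibility-weighted fraction of allele copies attributed to
population k. The update is monotone in the likelihood; individuals are
independent, so the implementation vectorizes over samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .genotype_io import GenotypeMatrix

logger = logging.getLogger("strataforge")

FREQ_CLIP = 1e-6  # keeps log(0) out of the likelihood; logged choice


@dataclass
class AdmixtureProportions:
    """Per-sample ancestry fractions over the reference populations."""

    q: pd.DataFrame  # sample_id index, one column per population
    loglik: np.ndarray
    n_iter: np.ndarray
    converged: np.ndarray

    @property
    def pop_names(self) -> list:
        return list(self.q.columns)

    def to_frame(self) -> pd.DataFrame:
        df = self.q.copy()
        df.columns = [f"q_{c}" for c in df.columns]
        df.insert(0, "sample_id", self.q.index)
        df["loglik"] = self.loglik
        df["converged"] = self.converged.astype(int)
        return df.reset_index(drop=True)


def _loglik(g: np.ndarray, miss: np.ndarray, pi: np.ndarray) -> np.ndarray:
    ll = g * np.log(pi) + (2.0 - g) * np.log1p(-pi)
    ll[miss] = 0.0
    return ll.sum(axis=1)


def estimate_proportions(
    g: GenotypeMatrix,
    ref_freqs: np.ndarray,
    pop_names: list | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> AdmixtureProportions:
    """Supervised EM for per-individual ancestry proportions.

    ``ref_freqs`` is the (K, M) matrix of reference allele frequencies over
    the same variants (and order) as ``g``; it is clipped to
    ``[1e-6, 1 - 1e-6]``. EM starts from the uniform simplex and stops when
    the per-sample log-likelihood gain drops below ``tol``; non-convergence
    at ``max_iter`` returns the current estimate with a warning flag.
    Missing genotypes contribute nothing to the likelihood.
    """
    ref_freqs = np.asarray(ref_freqs, dtype=float)
    if ref_freqs.ndim != 2 or ref_freqs.shape[1] != g.n_variants:
        raise ParameterError("ref_freqs must be (K, n_variants) aligned with the genotypes")
    if tol <= 0:
        raise ParameterError("tol must be positive")
    K = ref_freqs.shape[0]
    if pop_names is None:
        pop_names = [f"POP{k + 1}" for k in range(K)]
    p = np.clip(ref_freqs, FREQ_CLIP, 1.0 - FREQ_CLIP)  # (K, M)
    x = g.dosages
    miss = np.isnan(x)
    gdos = np.where(miss, 0.0, x)
    two_j = 2.0 * (~miss).sum(axis=1, keepdims=True)  # allele copies observed
    if np.any(two_j == 0):
        raise ParameterError("samples with no observed genotypes")

    n = g.n_samples
    q = np.full((n, K), 1.0 / K)
    pi = q @ p
    ll = _loglik(gdos, miss, pi)
    n_iter = np.zeros(n, dtype=int)
    converged = np.zeros(n, dtype=bool)
    for it in range(max_iter):
        a = np.where(miss, 0.0, gdos / pi)          # (n, M)
        b = np.where(miss, 0.0, (2.0 - gdos) / (1.0 - pi))
        q_new = q * (a @ p.T + b @ (1.0 - p).T) / two_j
        q_new /= q_new.sum(axis=1, keepdims=True)   # guard tiny drift
        pi = q_new @ p
        ll_new = _loglik(gdos, miss, pi)
        gain = ll_new - ll
        newly = (~converged) & (gain < tol)
        n_iter[newly] = it + 1
        converged |= newly
        q, ll = q_new, ll_new
        if converged.all():
            break
    if not converged.all():
        n_iter[~converged] = max_iter
        warnings.warn(
            f"{(~converged).sum()} samples did not converge in {max_iter} EM iterations"
        )
    qdf = pd.DataFrame(q, index=pd.Index(g.sample_ids, name="sample_id"), columns=pop_names)
    return AdmixtureProportions(q=qdf, loglik=ll, n_iter=n_iter, converged=converged)


def group_mean_proportions(
    props: AdmixtureProportions,
    groups,
    cohorts=None,
    min_cell: int = 11,
) -> pd.DataFrame:
    """Mean and SD of each ancestry proportion per group (x cohort) cell.

    Cells smaller than ``min_cell`` are marked suppressed (means/SDs set to
    NaN in the table), mirroring small-cell privacy floors in cohort reports.
    """
    groups = np.asarray(list(groups), dtype=object)
    if len(groups) != len(props.q):
        raise ParameterError("groups must have one label per sample")
    if pd.isna(groups).any():
        raise ParameterError("unknown (missing) group label")
    df = props.q.reset_index(drop=True)
    df["group"] = groups
    keys = ["group"]
    if cohorts is not None:
        df["cohort"] = np.asarray(list(cohorts))
        keys.append("cohort")
    rows = []
    for key, sub in df.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        rec = dict(zip(keys, key))
        rec["n"] = len(sub)
        rec["suppressed"] = len(sub) < min_cell
        for popname in props.pop_names:
            if rec["suppressed"]:
                rec[f"mean_{popname}"] = np.nan
                rec[f"sd_{popname}"] = np.nan
            else:
                rec[f"mean_{popname}"] = sub[popname].mean()
                rec[f"sd_{popname}"] = sub[popname].std(ddof=1)
        rows.append(rec)
    return pd.DataFrame(rows)
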