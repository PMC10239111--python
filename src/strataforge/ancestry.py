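"""Reference-panel ancestry assignment.

The assignment chain is: LD-prune the panel variants (greedy r^2 scan), fit a
PCA on the reference panel with allele-frequency standardization, project the
study samples onto the panel loadings (no refitting), classify the projected
scores with a random forest trained on the panel scores, and refine each
assigned group by flagging per-PC median-absolute-deviation outliers. Samples
whose maximum class probability does not exceed the threshold (strictly) are
Unclassified, as are flagged outliers.

A coarse-label baseline (:func:`coarse_blended_assignment`) emulates
classifiers that harmonize self-identified labels with genetic prediction:
agreeing labels are kept, missing labels are imputed at high confidence, and
disagreements become Unclassified.
"""

from __future__ import annotations

import bisect
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .exceptions import AlleleMismatchError, ParameterError
from .genotype_io import GenotypeMatrix
from .simpanel import ReferencePanel

logger = logging.getLogger("strataforge")

UNCLASSIFIED = "Unclassified"


# -- LD pruning ---------------------------------------------------------------

def ld_prune(
    g: GenotypeMatrix, r2_max: float = 0.01, window_kb: int = 1500
) -> np.ndarray:
    """Greedy left-to-right LD pruning; returns retained variant indices.

    A variant is dropped when its squared Pearson correlation with any
    *retained* variant within ``window_kb`` upstream (same chromosome) exceeds
    ``r2_max``. Deterministic given the input variant order.
    """
    if not 0.0 <= r2_max <= 1.0:
        raise ParameterError("r2_max must lie in [0, 1]")
    x = g.mean_imputed()
    x = x - x.mean(axis=0)
    norms = np.sqrt((x**2).sum(axis=0))
    nz = norms > 0
    x[:, nz] /= norms[nz]  # unit columns: dot product == Pearson r
    window_bp = window_kb * 1000
    keep: list[int] = []
    chroms = g.variants["chrom"].to_numpy()
    pos = g.positions
    kept_in_chrom: list[int] = []
    kept_pos: list[int] = []
    last_chrom = None
    for j in range(g.n_variants):
        if chroms[j] != last_chrom:
            kept_in_chrom = []
            kept_pos = []
            last_chrom = chroms[j]
        # retained upstream variants inside the window (kept_pos is sorted)
        start = bisect.bisect_left(kept_pos, pos[j] - window_bp)
        cand = kept_in_chrom[start:]
        if cand and nz[j]:
            r = x[:, cand].T @ x[:, j]
            if np.any(r**2 > r2_max):
                continue
        keep.append(j)
        kept_in_chrom.append(j)
        kept_pos.append(int(pos[j]))
    return np.asarray(keep, dtype=int)


# -- reference PCA and projection ----------------------------------------------

@dataclass
class PcModel:
    """Frozen PCA of a reference panel.

    Standardization is the usual genotype scaling: centre by ``2*p_hat`` and
    scale by ``sqrt(2*p_hat*(1-p_hat))`` with ``p_hat`` the panel allele
    frequency. Loadings are orthonormal; the sign convention makes the
    largest-magnitude loading of each PC positive.
    """

    variant_ids: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # (m_used, n_pcs)
    explained_variance: np.ndarray
    ref_alleles: pd.DataFrame = field(repr=False)

    @property
    def n_pcs(self) -> int:
        return self.loadings.shape[1]


def fit_reference_pca(
    panel: ReferencePanel, n_pcs: int = 20, pruned: np.ndarray | None = None
) -> tuple[PcModel, np.ndarray]:
    """Fit the panel PCA on the (optionally pruned) variants.

    Returns the frozen model and the panel's own scores. Variants that are
    monomorphic in the panel are excluded with a log entry.
    """
    g = panel.genotypes if pruned is None else panel.genotypes.subset(variants=pruned)
    if n_pcs > min(g.n_samples, g.n_variants):
        raise ParameterError("n_pcs exceeds min(samples, variants)")
    x = g.mean_imputed()
    p_hat = x.mean(axis=0) / 2.0
    scale = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    ok = scale > 0
    if not ok.all():
        logger.info("excluding %d zero-variance variants from reference PCA", (~ok).sum())
    x = x[:, ok]
    z = (x - 2.0 * p_hat[ok]) / scale[ok]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    loadings = vt[:n_pcs].T
    # sign convention: largest-magnitude loading positive
    flip = loadings[np.abs(loadings).argmax(axis=0), np.arange(n_pcs)] < 0
    loadings[:, flip] *= -1
    scores = z @ loadings
    explained = s[:n_pcs] ** 2 / (g.n_samples - 1)
    model = PcModel(
        variant_ids=g.variants["id"].to_numpy()[ok],
        center=2.0 * p_hat[ok],
        scale=scale[ok],
        loadings=loadings,
        explained_variance=explained,
        ref_alleles=g.variants.loc[ok, ["id", "ref", "alt"]].reset_index(drop=True),
    )
    return model, scores


def project_samples(model: PcModel, g: GenotypeMatrix) -> np.ndarray:
    """Project samples onto the panel loadings using panel centring/scaling."""
    id_to_col = {vid: j for j, vid in enumerate(g.variants["id"])}
    missing = [v for v in model.variant_ids if v not in id_to_col]
    if missing:
        raise ParameterError(
            f"{len(missing)} model variants absent from genotypes "
            f"(first few: {missing[:5]})"
        )
    cols = np.array([id_to_col[v] for v in model.variant_ids])
    sub = g.variants.iloc[cols]
    mism = (sub["ref"].to_numpy() != model.ref_alleles["ref"].to_numpy()) | (
        sub["alt"].to_numpy() != model.ref_alleles["alt"].to_numpy()
    )
    if mism.any():
        bad = model.variant_ids[mism][:5]
        raise AlleleMismatchError(f"REF/ALT mismatch at {mism.sum()} variants, e.g. {list(bad)}")
    x = g.mean_imputed()[:, cols]
    z = (x - model.center) / model.scale
    return z @ model.loadings


# -- random-forest classification ----------------------------------------------

@dataclass
class AncestryAssignment:
    """Per-sample ancestry labels with class probabilities.

    ``labels`` contains one of the reference groups or ``Unclassified``;
    ``probabilities`` is an ``(n, K)`` matrix over ``classes``; the outlier
    flag marks samples demoted by :func:`refine_outliers`.
    """

    sample_ids: np.ndarray
    labels: np.ndarray
    probabilities: np.ndarray
    classes: list
    outlier_flag: np.ndarray
    method: str

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "method": self.method,
                "label": self.labels,
                "max_prob": self.probabilities.max(axis=1),
                "outlier_flag": self.outlier_flag.astype(int),
            }
        )
        for k, c in enumerate(self.classes):
            df[f"prob_{c}"] = self.probabilities[:, k]
        return df

    def counts(self) -> dict:
        out: dict = {}
        for lab in self.labels:
            out[lab] = out.get(lab, 0) + 1
        return out


def labels_from_probabilities(
    probs: np.ndarray, classes, prob_min: float = 0.5
) -> np.ndarray:
    """Map class probabilities to labels; max prob must strictly exceed prob_min."""
    probs = np.asarray(probs, dtype=float)
    classes = np.asarray(classes, dtype=object)
    best = probs.argmax(axis=1)
    labels = classes[best]
    labels = np.where(probs.max(axis=1) > prob_min, labels, UNCLASSIFIED)
    return labels.astype(object)


def _fit_forest(scores, labels, seed, n_trees, oob_score=False):
    counts = pd.Series(labels).value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ParameterError(
            f"reference classes with < 2 members: {list(small.index)}"
        )
    # a single-class forest cannot produce an OOB decision function
    oob_score = oob_score and len(counts) > 1
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=int(seed) % (2**31),
        oob_score=oob_score,
        n_jobs=1,
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        # samples never out-of-bag are handled by falling back to predict_proba
        _warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
        rf.fit(scores, labels)
    return rf


def classify_ancestry(
    ref_scores: np.ndarray,
    ref_labels: np.ndarray,
    sample_scores: np.ndarray,
    sample_ids: np.ndarray,
    prob_min: float = 0.5,
    seed: int = 0,
    n_trees: int = 500,
) -> AncestryAssignment:
    """Random-forest assignment of projected samples to panel groups.

    The forest (default 500 trees, sqrt-of-features splits, unlimited depth)
    is trained on the reference scores; a sample whose maximum class
    probability is <= ``prob_min`` is Unclassified.
    """
    if ref_scores.shape[1] != sample_scores.shape[1]:
        raise ParameterError("reference and sample scores differ in number of PCs")
    rf = _fit_forest(ref_scores, np.asarray(ref_labels), seed, n_trees)
    probs = rf.predict_proba(sample_scores)
    labels = labels_from_probabilities(probs, rf.classes_, prob_min)
    return AncestryAssignment(
        sample_ids=np.asarray(sample_ids, dtype=object),
        labels=labels,
        probabilities=probs,
        classes=list(rf.classes_),
        outlier_flag=np.zeros(len(labels), dtype=bool),
        method="panel",
    )


def refine_outliers(
    a: AncestryAssignment,
    g: GenotypeMatrix,
    n_pcs: int = 20,
    n_mads: float = 6.0,
    variant_subset: np.ndarray | None = None,
) -> AncestryAssignment:
    """Demote per-group PC-space outliers to Unclassified (single pass).

    Within each assigned group a fresh PCA is computed on that group's
    members; a sample is flagged when, on any of the top ``n_pcs`` dimensions,
    its score lies more than ``n_mads`` unscaled median absolute deviations
    from the group median. Dimensions with MAD = 0 are skipped. Groups with
    fewer than 3 members are skipped with a warning.
    """
    sub = g if variant_subset is None else g.subset(variants=variant_subset)
    order = {sid: i for i, sid in enumerate(sub.sample_ids)}
    rows = np.array([order[sid] for sid in a.sample_ids])
    imputed = sub.mean_imputed()
    labels = a.labels.copy()
    flags = a.outlier_flag.copy()
    for group in sorted(set(labels) - {UNCLASSIFIED}):
        members = np.where(labels == group)[0]
        if len(members) < 3:
            warnings.warn(f"group {group} has <3 members; outlier refinement skipped")
            continue
        x = imputed[rows[members]]
        x = x - x.mean(axis=0)
        sd = x.std(axis=0)
        ok = sd > 0
        z = x[:, ok] / sd[ok]
        k = min(n_pcs, len(members) - 1, int(ok.sum()))
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        scores = z @ vt[:k].T
        med = np.median(scores, axis=0)
        mad = np.median(np.abs(scores - med), axis=0)
        use = mad > 0
        if not use.any():
            continue
        dev = np.abs(scores[:, use] - med[use]) > n_mads * mad[use]
        out = dev.any(axis=1)
        flags[members[out]] = True
        labels[members[out]] = UNCLASSIFIED
    return AncestryAssignment(
        sample_ids=a.sample_ids,
        labels=labels,
        probabilities=a.probabilities,
        classes=a.classes,
        outlier_flag=flags,
        method=a.method,
    )


def coarse_blended_assignment(
    sample_scores: np.ndarray,
    coarse_labels,
    sample_ids: np.ndarray,
    seed: int = 0,
    conf_min: float = 0.5,
    n_trees: int = 500,
) -> AncestryAssignment:
    """Baseline that blends coarse self-identified labels with genetic PCs.

    A random forest learns the coarse label from the genetic PCs on samples
    whose label is non-missing. A sample keeps its coarse label when it agrees
    with the genetic prediction; a missing label is imputed by the prediction
    when its confidence exceeds ``conf_min``; anything else (disagreement, or
    low-confidence imputation) is Unclassified.

    For the labelled (training) samples the genetic prediction is taken
    out-of-bag, so a sample cannot vouch for its own label: a forest otherwise
    memorizes its training points and would never flag a label that
    contradicts the genetic structure.
    """
    coarse = pd.Series(list(coarse_labels), dtype=object)
    have = coarse.notna().to_numpy()
    if not have.any():
        raise ParameterError("all coarse labels are missing")
    frac = have.mean()
    if frac < 0.9:
        raise ParameterError(
            f"coarse labels present for only {frac:.0%} of samples (need >= 90%)"
        )
    rf = _fit_forest(
        sample_scores[have], coarse[have].to_numpy(), seed, n_trees, oob_score=True
    )
    probs = rf.predict_proba(sample_scores)
    if len(np.unique(coarse[have])) > 1:
        oob = rf.oob_decision_function_
        usable = ~np.isnan(oob).any(axis=1) & (oob.sum(axis=1) > 0)
        rows = np.where(have)[0][usable]
        probs[rows] = oob[usable]
    classes = np.asarray(rf.classes_, dtype=object)
    pred = classes[probs.argmax(axis=1)]
    conf = probs.max(axis=1)
    labels = np.full(len(coarse), UNCLASSIFIED, dtype=object)
    agree = have & (coarse.to_numpy() == pred)
    labels[agree] = pred[agree]
    impute = ~have & (conf > conf_min)
    labels[impute] = pred[impute]
    return AncestryAssignment(
        sample_ids=np.asarray(sample_ids, dtype=object),
        labels=labels,
        probabilities=probs,
        classes=list(classes),
        outlier_flag=np.zeros(len(labels), dtype=bool),
        method="coarse-blended",
    )
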