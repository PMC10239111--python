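"""Synthetic reference panels, admixed cohorts and confounded phenotypes.

The generator emulates the statistical structure that the ancestry/GWAS
analysis assumes: K ancestral populations whose allele frequencies diverge
from a common ancestral frequency under the Balding-Nichols model
(``p_k ~ Beta(p(1-F_k)/F_k, (1-p)(1-F_k)/F_k)``, so ``Var(p_k) = F_k p(1-p)``),
birth cohorts whose admixture proportions drift over time (Dirichlet priors
per cohort), coarse self-identified labels that may merge genetically distinct
populations, and a polygenic quantitative trait with an optional
population-mean confound.

Two genome modes are available. In the default *unlinked* mode every variant
is drawn independently given ancestry, so all linkage disequilibrium is of
admixture origin. The *block-LD* mode additionally tiles the chromosome with
haplotype blocks: within a block the ancestral (and population) frequencies
are constant, each haploid genome draws one local ancestry per block from the
individual's admixture vector, and successive alleles copy the previous one
with probability ``rho`` (a first-order Markov haplotype). This yields a
physical LD structure, with pairwise genotype correlation ``rho**d`` at
variant distance ``d`` inside a block and zero across blocks, while keeping
binomial marginals exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .genotype_io import GenotypeMatrix, VARIANT_COLUMNS

logger = logging.getLogger("strataforge")

DEFAULT_REFERENCE_YEAR = 2011


# -- population model -------------------------------------------------------

@dataclass
class PopulationModel:
    """Ancestral frequencies, per-population drift and variant coordinates.

    ``block_ids`` groups variants into haplotype blocks (all equal for the
    unlinked mode this is a trivial one-variant-per-block labelling) and
    ``rho`` is the within-block allele-copying probability (0 = unlinked).
    Frequencies are constant within a block so that Markov copying preserves
    the marginal allele frequency.
    """

    n_pops: int
    ancestral_freqs: np.ndarray
    fst: np.ndarray
    positions: np.ndarray
    block_ids: np.ndarray = None
    rho: float = 0.0
    chrom: str = "1"

    def __post_init__(self) -> None:
        self.ancestral_freqs = np.asarray(self.ancestral_freqs, dtype=float)
        self.fst = np.asarray(self.fst, dtype=float)
        self.positions = np.asarray(self.positions, dtype=int)
        if self.n_pops < 1 or len(self.fst) != self.n_pops:
            raise ParameterError("fst must have one entry per population")
        if np.any(self.fst < 0) or np.any(self.fst >= 1):
            raise ParameterError("F_ST values must lie in [0, 1)")
        if np.any(self.ancestral_freqs <= 0.05) or np.any(self.ancestral_freqs >= 0.95):
            raise ParameterError("ancestral frequencies must lie strictly inside (0.05, 0.95)")
        if np.any(np.diff(self.positions) <= 0):
            raise ParameterError("positions must be strictly increasing")
        if len(self.positions) != len(self.ancestral_freqs):
            raise ParameterError("positions and ancestral_freqs length mismatch")
        if not 0.0 <= self.rho < 1.0:
            raise ParameterError("rho must lie in [0, 1)")
        if self.block_ids is None:
            self.block_ids = np.arange(self.n_variants)
        self.block_ids = np.asarray(self.block_ids, dtype=int)
        if len(self.block_ids) != self.n_variants or np.any(np.diff(self.block_ids) < 0):
            raise ParameterError("block_ids must be non-decreasing, one per variant")

    @property
    def n_variants(self) -> int:
        return len(self.ancestral_freqs)

    @classmethod
    def random(
        cls,
        n_variants: int,
        fst,
        seed: int,
        spacing_bp: int = 1000,
        mean_block_size: int = 1,
        rho: float = 0.0,
        singleton_fraction: float = 0.0,
        chrom: str = "1",
    ) -> "PopulationModel":
        """Draw ancestral frequencies Uniform(0.05, 0.95) on a uniform grid.

        ``mean_block_size > 1`` tiles the chromosome with blocks whose sizes
        are uniform on ``1..2*mean_block_size - 1``; frequencies are drawn per
        block and shared by the block's variants. ``singleton_fraction`` makes
        that share of blocks single-variant (LD-free), interleaving variants
        with no local LD among the blocks the way real genomes mix low- and
        high-LD regions; these anchor the LD-score regression near its
        intercept.
        """
        rng = np.random.default_rng(seed)
        fst = np.atleast_1d(np.asarray(fst, dtype=float))
        positions = spacing_bp * np.arange(1, n_variants + 1)
        if mean_block_size <= 1:
            block_ids = np.arange(n_variants)
        else:
            sizes = rng.integers(1, 2 * mean_block_size, size=n_variants)
            if singleton_fraction > 0:
                sizes = np.where(
                    rng.random(n_variants) < singleton_fraction, 1, sizes
                )
            block_ids = np.repeat(np.arange(n_variants), sizes)[:n_variants]
        n_blocks = block_ids[-1] + 1
        per_block = rng.uniform(0.05 + 1e-9, 0.95 - 1e-9, size=n_blocks)
        return cls(
            n_pops=len(fst),
            ancestral_freqs=per_block[block_ids],
            fst=fst,
            positions=positions,
            block_ids=block_ids,
            rho=rho,
            chrom=chrom,
        )


@dataclass
class ReferencePanel:
    """Labelled reference genotypes plus the realized per-population frequencies."""

    genotypes: GenotypeMatrix
    labels: np.ndarray
    pop_names: list
    pop_freqs: np.ndarray  # (K, M) frequencies the genotypes were drawn from
    model: PopulationModel = field(repr=False, default=None)

    @property
    def n_pops(self) -> int:
        return len(self.pop_names)


@dataclass
class CohortSpec:
    """Birth-cohort layout of an admixed study cohort.

    ``admixture_priors`` holds one Dirichlet concentration vector per cohort;
    ``coarse_label_map`` sends each fine population name to the coarse
    self-identified label recorded in the metadata (it may merge populations);
    ``label_noise`` is the probability that a coarse label is replaced by a
    random different one, and ``label_missing_rate`` the probability it is
    missing altogether.
    """

    n_samples: list
    admixture_priors: np.ndarray
    birth_year_ranges: list
    coarse_label_map: dict
    label_noise: float = 0.0
    label_missing_rate: float = 0.0
    female_fraction: float = 0.1
    reference_year: int = DEFAULT_REFERENCE_YEAR

    def __post_init__(self) -> None:
        self.admixture_priors = np.atleast_2d(np.asarray(self.admixture_priors, dtype=float))
        if np.any(self.admixture_priors <= 0):
            raise ParameterError("Dirichlet concentrations must be strictly positive")
        if len(self.n_samples) != self.admixture_priors.shape[0] or len(
            self.birth_year_ranges
        ) != len(self.n_samples):
            raise ParameterError("n_samples, priors and year ranges must align per cohort")
        if any(n < 1 for n in self.n_samples):
            raise ParameterError("every cohort must contain at least one sample")

    @property
    def n_cohorts(self) -> int:
        return len(self.n_samples)


@dataclass
class PhenotypeSpec:
    """Polygenic trait with heritability ``h2`` and a population-mean confound.

    The genetic and residual components sum to unit variance; ``strat_shift``
    adds ``sum_k q_k * shift_k`` on top, so an all-zero shift gives an
    unconfounded trait. ``sex_effect`` and ``age_effect`` are fixed covariate
    coefficients (age is centred before scaling).
    """

    h2: float
    n_causal: int
    strat_shift: np.ndarray = None
    sex_effect: float = 0.0
    age_effect: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ParameterError("h2 must lie in [0, 1]")
        if self.n_causal < 0:
            raise ParameterError("n_causal must be non-negative")
        if self.strat_shift is not None:
            self.strat_shift = np.asarray(self.strat_shift, dtype=float)

    @property
    def noise_sd(self) -> float:
        return float(np.sqrt(1.0 - self.h2))


# -- genotype sampling ------------------------------------------------------

def _draw_population_freqs(model: PopulationModel, rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols per-population frequencies, drawn once per block."""
    first = np.r_[True, np.diff(model.block_ids) > 0]
    p_anc = model.ancestral_freqs[first]
    freqs = np.empty((model.n_pops, model.n_variants))
    for k, f in enumerate(model.fst):
        if f == 0.0:
            block_p = p_anc
        else:
            block_p = rng.beta(p_anc * (1 - f) / f, (1 - p_anc) * (1 - f) / f)
            block_p = np.clip(block_p, 1e-6, 1 - 1e-6)
        freqs[k] = block_p[np.searchsorted(np.where(first)[0], np.arange(model.n_variants), "right") - 1]
    return freqs


def _sample_genotypes(
    q: np.ndarray, pop_freqs: np.ndarray, model: PopulationModel, rng: np.random.Generator
) -> np.ndarray:
    """Genotypes for admixture vectors ``q`` (n, K) under the model's LD mode."""
    n = q.shape[0]
    if model.rho == 0.0 and np.all(np.diff(model.block_ids) > 0):
        mix = q @ pop_freqs  # (n, M) per-individual allele probabilities
        return rng.binomial(2, mix).astype(float)
    # block-LD mode: per haplotype, one local ancestry per block, Markov copying
    m = model.n_variants
    cum_q = np.cumsum(q, axis=1)
    g = np.zeros((n, m))
    block_start = np.r_[True, np.diff(model.block_ids) > 0]
    for _hap in range(2):
        allele = np.zeros(n, dtype=bool)
        z = np.zeros(n, dtype=int)
        for j in range(m):
            if block_start[j]:
                u = rng.random(n)
                z = (u[:, None] > cum_q).sum(axis=1)
                allele = rng.random(n) < pop_freqs[z, j]
            else:
                fresh = rng.random(n) < pop_freqs[z, j]
                allele = np.where(rng.random(n) < model.rho, allele, fresh)
            g[:, j] += allele
    return g


def _variant_table(model: PopulationModel) -> pd.DataFrame:
    m = model.n_variants
    return pd.DataFrame(
        {
            "id": [f"snp{j + 1}" for j in range(m)],
            "chrom": model.chrom,
            "pos": model.positions,
            "ref": "A",
            "alt": "G",
        },
        columns=VARIANT_COLUMNS,
    )


def simulate_reference_panel(
    model: PopulationModel,
    n_per_pop: int,
    seed: int,
    pop_names: list | None = None,
) -> ReferencePanel:
    """Draw a labelled reference panel of unadmixed individuals.

    Population frequencies come from the Balding-Nichols Beta draw (with
    ``F_k = 0`` every population keeps the ancestral frequency exactly);
    genotypes are Binomial(2, p_kj) per individual, or block-haplotype draws
    in the block-LD mode. The panel carries the realized ``p_kj``.
    """
    if n_per_pop < 2:
        raise ParameterError("n_per_pop must be at least 2")
    rng = np.random.default_rng(seed)
    if pop_names is None:
        pop_names = [f"POP{k + 1}" for k in range(model.n_pops)]
    if len(pop_names) != model.n_pops:
        raise ParameterError("pop_names must match the number of populations")
    pop_freqs = _draw_population_freqs(model, rng)
    blocks = []
    for k in range(model.n_pops):
        q = np.zeros((n_per_pop, model.n_pops))
        q[:, k] = 1.0
        blocks.append(_sample_genotypes(q, pop_freqs, model, rng))
    dosages = np.vstack(blocks)
    labels = np.repeat(pop_names, n_per_pop)
    sample_ids = np.array(
        [f"ref_{pop_names[k]}_{i + 1}" for k in range(model.n_pops) for i in range(n_per_pop)],
        dtype=object,
    )
    g = GenotypeMatrix(dosages, sample_ids, _variant_table(model))
    return ReferencePanel(g, labels, list(pop_names), pop_freqs, model)


def simulate_cohort(
    panel: ReferencePanel, spec: CohortSpec, seed: int
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Draw an admixed longitudinal cohort against a reference panel.

    Returns ``(genotypes, metadata, true_admixture)``. Metadata holds birth
    year (uniform within the cohort's range), sex (0 male / 1 female), age at
    the reference year, the cohort index and the (noisy, possibly missing)
    coarse self-identified label. The truth table stores the drawn admixture
    vector and the dominant fine population.
    """
    if spec.admixture_priors.shape[1] != panel.n_pops:
        raise ParameterError("cohort priors and panel disagree on K")
    missing_pops = [p for p in panel.pop_names if p not in spec.coarse_label_map]
    if missing_pops:
        raise ParameterError(f"coarse_label_map lacks populations {missing_pops}")
    rng = np.random.default_rng(seed)
    model = panel.model
    qs, years, cohorts = [], [], []
    for c in range(spec.n_cohorts):
        n_c = spec.n_samples[c]
        qs.append(rng.dirichlet(spec.admixture_priors[c], size=n_c))
        lo, hi = spec.birth_year_ranges[c]
        years.append(rng.integers(lo, hi + 1, size=n_c))
        cohorts.append(np.full(n_c, c + 1))
    q = np.vstack(qs)
    years = np.concatenate(years)
    cohorts = np.concatenate(cohorts)
    n = len(years)
    dosages = _sample_genotypes(q, panel.pop_freqs, model, rng)
    sample_ids = np.array([f"s{i + 1:06d}" for i in range(n)], dtype=object)
    g = GenotypeMatrix(dosages, sample_ids, _variant_table(model))

    dominant = np.asarray(panel.pop_names, dtype=object)[np.argmax(q, axis=1)]
    coarse = np.array([spec.coarse_label_map[p] for p in dominant], dtype=object)
    all_coarse = sorted(set(spec.coarse_label_map.values()))
    if spec.label_noise > 0 and len(all_coarse) > 1:
        flip = rng.random(n) < spec.label_noise
        for i in np.where(flip)[0]:
            others = [c for c in all_coarse if c != coarse[i]]
            coarse[i] = others[rng.integers(len(others))]
    if spec.label_missing_rate > 0:
        coarse[rng.random(n) < spec.label_missing_rate] = None

    sex = (rng.random(n) < spec.female_fraction).astype(int)
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "birth_year": years,
            "sex": sex,
            "age": spec.reference_year - years,
            "cohort": cohorts,
            "coarse_label": coarse,
        }
    )
    truth = pd.DataFrame(q, columns=[f"q_{p}" for p in panel.pop_names])
    truth.insert(0, "sample_id", sample_ids)
    truth["dominant_pop"] = dominant
    return g, metadata, truth


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    truth: pd.DataFrame,
    spec: PhenotypeSpec,
    seed: int,
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Simulate the quantitative trait for a cohort.

    trait = genetic + noise + confound + covariate terms, where the genetic
    component is a sum of ``n_causal`` standardized dosages times normal
    effects rescaled to variance ``h2``, the noise has variance ``1 - h2``,
    and the confound is ``q @ strat_shift``. Returns a table with the trait,
    age, sex and the individual latent components (for variance-decomposition
    checks).
    """
    if spec.n_causal > genotypes.n_variants:
        raise ParameterError(
            f"n_causal={spec.n_causal} exceeds {genotypes.n_variants} variants"
        )
    rng = np.random.default_rng(seed)
    n = genotypes.n_samples
    qcols = [c for c in truth.columns if c.startswith("q_")]
    q = truth[qcols].to_numpy()
    if metadata is not None:
        age = metadata["age"].to_numpy(dtype=float)
        sex = metadata["sex"].to_numpy(dtype=float)
        sample_ids = metadata["sample_id"].to_numpy()
    else:
        age = rng.integers(20, 90, size=n).astype(float)
        sex = (rng.random(n) < 0.5).astype(float)
        sample_ids = genotypes.sample_ids

    genetic = np.zeros(n)
    if spec.h2 > 0 and spec.n_causal > 0:
        causal = rng.choice(genotypes.n_variants, size=spec.n_causal, replace=False)
        x = genotypes.mean_imputed()[:, causal]
        sd = x.std(axis=0)
        ok = sd > 0
        z = (x[:, ok] - x[:, ok].mean(axis=0)) / sd[ok]
        raw = z @ rng.normal(size=ok.sum())
        raw_sd = raw.std()
        if raw_sd > 0:
            genetic = raw * np.sqrt(spec.h2) / raw_sd
    noise = rng.normal(scale=spec.noise_sd, size=n)
    confound = np.zeros(n)
    if spec.strat_shift is not None and np.any(spec.strat_shift != 0):
        if len(spec.strat_shift) != q.shape[1]:
            raise ParameterError("strat_shift length must equal K")
        confound = q @ spec.strat_shift
    trait = (
        genetic
        + noise
        + confound
        + spec.sex_effect * sex
        + spec.age_effect * (age - age.mean())
    )
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "trait": trait,
            "age": age,
            "sex": sex,
            "genetic": genetic,
            "confound": confound,
        }
    )
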