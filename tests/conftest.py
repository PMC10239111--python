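import numpy as np
import pandas as pd
import pytest

from strataforge.genotype_io import GenotypeMatrix, VARIANT_COLUMNS
from strataforge.simpanel import (
    CohortSpec,
    PopulationModel,
    simulate_cohort,
    simulate_reference_panel,
)


def make_matrix(dosages, positions=None, chrom="1", sample_prefix="s") -> GenotypeMatrix:
    """Small helper: wrap a raw array into a GenotypeMatrix."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if positions is None:
        positions = 1000 * np.arange(1, m + 1)
    variants = pd.DataFrame(
        {
            "id": [f"v{j + 1}" for j in range(m)],
            "chrom": chrom,
            "pos": positions,
            "ref": "A",
            "alt": "G",
        },
        columns=VARIANT_COLUMNS,
    )
    ids = np.array([f"{sample_prefix}{i + 1}" for i in range(n)], dtype=object)
    return GenotypeMatrix(dosages, ids, variants)


@pytest.fixture(scope="session")
def two_pop_panel():
    """Well-separated two-population reference panel (F_ST = 0.1)."""
    model = PopulationModel.random(800, fst=[0.1, 0.1], seed=11)
    return simulate_reference_panel(model, n_per_pop=80, seed=12)


@pytest.fixture(scope="session")
def admixed_cohort(two_pop_panel):
    """Uniformly admixed cohort of 200 samples against the two-pop panel."""
    spec = CohortSpec(
        n_samples=[200],
        admixture_priors=[[1.0, 1.0]],
        birth_year_ranges=[(1940, 1990)],
        coarse_label_map={p: "ALL" for p in two_pop_panel.pop_names},
    )
    return simulate_cohort(two_pop_panel, spec, seed=13)
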