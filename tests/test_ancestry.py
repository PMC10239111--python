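import numpy as np
import pytest

from strataforge import ancestry
from strataforge.ancestry import (
    UNCLASSIFIED,
    classify_ancestry,
    coarse_blended_assignment,
    fit_reference_pca,
    labels_from_probabilities,
    ld_prune,
    project_samples,
    refine_outliers,
)
from strataforge.exceptions import AlleleMismatchError, ParameterError
from strataforge.simpanel import (
    CohortSpec,
    PopulationModel,
    simulate_cohort,
    simulate_reference_panel,
)

from conftest import make_matrix


def brute_force_prune_check(g, kept, r2_max, window_kb):
    """Oracle: exhaustively re-verify the greedy pruning contract."""
    x = g.mean_imputed()
    x = x - x.mean(axis=0)
    norms = np.sqrt((x**2).sum(axis=0))
    x[:, norms > 0] /= norms[norms > 0]
    pos = g.positions
    kept_set = set(kept)
    # no retained pair within the window exceeds r2_max
    for j in kept:
        for k in kept:
            if k < j and pos[j] - pos[k] <= window_kb * 1000:
                assert (x[:, j] @ x[:, k]) ** 2 <= r2_max + 1e-12
    # every dropped variant violates against some retained upstream variant
    for j in range(g.n_variants):
        if j in kept_set:
            continue
        partners = [
            k for k in kept if k < j and pos[j] - pos[k] <= window_kb * 1000
        ]
        assert any((x[:, j] @ x[:, k]) ** 2 > r2_max for k in partners)


class TestLdPrune:
    def test_identical_columns_second_dropped(self):
        col = np.array([0, 1, 2, 1, 0, 2], dtype=float)
        g = make_matrix(np.column_stack([col, col]), positions=[1000, 11000])
        kept = ld_prune(g, r2_max=0.01, window_kb=1500)
        assert list(kept) == [0]

    def test_identical_columns_outside_window_both_kept(self):
        col = np.array([0, 1, 2, 1, 0, 2], dtype=float)
        g = make_matrix(np.column_stack([col, col]), positions=[1000, 2_000_000])
        kept = ld_prune(g, r2_max=0.01, window_kb=1500)
        assert list(kept) == [0, 1]

    def test_uncorrelated_variants_all_retained(self):
        rng = np.random.default_rng(1)
        g = make_matrix(rng.binomial(2, 0.5, size=(5000, 5)).astype(float))
        kept = ld_prune(g, r2_max=0.01, window_kb=1500)
        assert list(kept) == [0, 1, 2, 3, 4]

    def test_matches_exhaustive_pair_oracle(self):
        rng = np.random.default_rng(2)
        base = rng.binomial(2, 0.4, size=(60, 30)).astype(float)
        # plant correlated copies to exercise drops
        for j in (5, 12, 19):
            noise = rng.binomial(1, 0.1, size=60)
            base[:, j] = np.clip(base[:, j - 1] + noise, 0, 2)
        g = make_matrix(base)
        kept = ld_prune(g, r2_max=0.2, window_kb=10)
        brute_force_prune_check(g, kept, r2_max=0.2, window_kb=10)

    def test_single_variant_returned_as_is(self):
        g = make_matrix([[0], [1], [2]])
        assert list(ld_prune(g)) == [0]


class TestReferencePca:
    def test_pc1_separates_fixed_difference_populations(self):
        # near-fixed differences at every variant
        g1 = np.tile([0.0, 0.0, 2.0], (30, 1))
        g2 = np.tile([2.0, 2.0, 0.0], (30, 1))
        g1[0, 0] = 1  # break exact degeneracy
        from strataforge.simpanel import ReferencePanel

        gm = make_matrix(np.vstack([g1, g2]))
        panel = ReferencePanel(
            gm, np.repeat(["A", "B"], 30), ["A", "B"], np.zeros((2, 3))
        )
        model, scores = fit_reference_pca(panel, n_pcs=2)
        a, b = scores[:30, 0], scores[30:, 0]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or max(b.max(), a.max()) > 0
        assert (a.max() < b.min()) or (b.max() < a.min())

    def test_explained_variance_non_increasing(self, two_pop_panel):
        model, _ = fit_reference_pca(two_pop_panel, n_pcs=10)
        assert np.all(np.diff(model.explained_variance) <= 1e-9)

    def test_loadings_orthonormal(self, two_pop_panel):
        model, _ = fit_reference_pca(two_pop_panel, n_pcs=10)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(10), atol=1e-8)

    def test_truncation_error_bounded_by_discarded_singular_values(self, two_pop_panel):
        g = two_pop_panel.genotypes
        x = g.mean_imputed()
        p = x.mean(axis=0) / 2
        scale = np.sqrt(2 * p * (1 - p))
        ok = scale > 0
        z = (x[:, ok] - 2 * p[ok]) / scale[ok]
        svals = np.linalg.svd(z, compute_uv=False)
        k = 10
        model, scores = fit_reference_pca(two_pop_panel, n_pcs=k)
        recon = scores @ model.loadings.T
        err = np.linalg.norm(z - recon, ord="fro")
        bound = np.sqrt((svals[k:] ** 2).sum())
        assert err <= bound * (1 + 1e-8)

    def test_projection_self_consistent(self, two_pop_panel):
        model, scores = fit_reference_pca(two_pop_panel, n_pcs=8)
        again = project_samples(model, two_pop_panel.genotypes)
        np.testing.assert_allclose(again, scores, atol=1e-8)

    def test_sample_at_centering_point_scores_zero(self, two_pop_panel):
        model, _ = fit_reference_pca(two_pop_panel, n_pcs=5)
        g = two_pop_panel.genotypes
        # a fake sample whose dosage equals 2*p_hat at every model variant
        centered = np.tile(g.mean_imputed().mean(axis=0), (1, 1))
        from strataforge.genotype_io import GenotypeMatrix

        fake = GenotypeMatrix(
            np.clip(np.round(centered), 0, 2), np.array(["x"], dtype=object), g.variants
        )
        # use the exact centering values instead of rounded dosages
        cols = {v: j for j, v in enumerate(fake.variants["id"])}
        idx = [cols[v] for v in model.variant_ids]
        z = (fake.mean_imputed()[:, idx] - model.center) / model.scale
        exact = (model.center - model.center) / model.scale @ model.loadings
        np.testing.assert_allclose(exact, 0.0, atol=1e-12)

    def test_admixed_sample_projects_between_centroids(self, two_pop_panel, admixed_cohort):
        g, _, truth = admixed_cohort
        model, ref_scores = fit_reference_pca(two_pop_panel, n_pcs=2)
        scores = project_samples(model, g)
        mid = np.abs(truth["q_POP1"].to_numpy() - 0.5) < 0.05
        c1 = ref_scores[:80, 0].mean()
        c2 = ref_scores[80:, 0].mean()
        expected_mid = (c1 + c2) / 2
        spread = abs(c1 - c2)
        assert abs(scores[mid, 0].mean() - expected_mid) < 0.15 * spread

    def test_allele_mismatch_detected(self, two_pop_panel):
        model, _ = fit_reference_pca(two_pop_panel, n_pcs=3)
        g = two_pop_panel.genotypes
        flipped = g.variants.copy()
        flipped.loc[0, ["ref", "alt"]] = ["G", "A"]
        from strataforge.genotype_io import GenotypeMatrix

        g2 = GenotypeMatrix(g.dosages, g.sample_ids, flipped)
        with pytest.raises(AlleleMismatchError):
            project_samples(model, g2)


class TestClassification:
    def test_panel_self_classification_perfect(self, two_pop_panel):
        model, scores = fit_reference_pca(two_pop_panel, n_pcs=5)
        a = classify_ancestry(
            scores, two_pop_panel.labels, scores,
            two_pop_panel.genotypes.sample_ids, seed=0, n_trees=200,
        )
        assert (a.labels == two_pop_panel.labels).all()
        assert np.all(a.probabilities.sum(axis=1) == pytest.approx(1.0, abs=1e-8))

    def test_centroid_sample_confident(self, two_pop_panel):
        model, scores = fit_reference_pca(two_pop_panel, n_pcs=5)
        centroid = scores[:80].mean(axis=0, keepdims=True)
        a = classify_ancestry(
            scores, two_pop_panel.labels, centroid, np.array(["c"], dtype=object),
            seed=0, n_trees=200,
        )
        assert a.labels[0] == "POP1"
        assert a.probabilities.max() > 0.9

    def test_probability_exactly_half_is_unclassified(self):
        labels = labels_from_probabilities(
            np.array([[0.5, 0.5], [0.51, 0.49]]), ["A", "B"], prob_min=0.5
        )
        assert labels[0] == UNCLASSIFIED
        assert labels[1] == "A"

    def test_sample_order_invariance(self, two_pop_panel, admixed_cohort):
        g, _, _ = admixed_cohort
        model, ref_scores = fit_reference_pca(two_pop_panel, n_pcs=5)
        scores = project_samples(model, g)
        a = classify_ancestry(
            ref_scores, two_pop_panel.labels, scores, g.sample_ids, seed=3, n_trees=100
        )
        perm = np.random.default_rng(0).permutation(len(scores))
        b = classify_ancestry(
            ref_scores, two_pop_panel.labels, scores[perm], g.sample_ids[perm],
            seed=3, n_trees=100,
        )
        assert (a.labels[perm] == b.labels).all()

    def test_small_reference_class_rejected(self):
        with pytest.raises(ParameterError):
            classify_ancestry(
                np.zeros((3, 2)), np.array(["A", "A", "B"]),
                np.zeros((1, 2)), np.array(["x"]), seed=0, n_trees=10,
            )

    def test_every_sample_gets_exactly_one_label(self, two_pop_panel, admixed_cohort):
        g, _, _ = admixed_cohort
        model, ref_scores = fit_reference_pca(two_pop_panel, n_pcs=5)
        scores = project_samples(model, g)
        a = classify_ancestry(
            ref_scores, two_pop_panel.labels, scores, g.sample_ids, seed=1, n_trees=100
        )
        assert len(a.labels) == g.n_samples
        assert set(a.labels) <= {"POP1", "POP2", UNCLASSIFIED}


class TestRefineOutliers:
    def test_planted_foreign_sample_flagged(self, two_pop_panel):
        g = two_pop_panel.genotypes
        # assign everyone to POP1: the 80 POP2 members are extreme within-group
        a = classify_ancestry(
            *_self_scores(two_pop_panel), g.sample_ids, seed=0, n_trees=100
        )
        forced = a.labels.copy()
        forced[:] = "POP1"
        forced[100:] = UNCLASSIFIED  # keep POP1 group = 80 POP1 + 20 POP2 samples
        from strataforge.ancestry import AncestryAssignment

        b = AncestryAssignment(
            a.sample_ids, forced, a.probabilities, a.classes,
            np.zeros(len(forced), dtype=bool), "panel",
        )
        refined = refine_outliers(b, g, n_pcs=5, n_mads=6.0)
        planted = slice(80, 100)
        assert (refined.labels[planted] == UNCLASSIFIED).all()
        assert refined.outlier_flag[planted].all()
        # the genuine members overwhelmingly survive
        assert (refined.labels[:80] == "POP1").mean() > 0.9

    def test_constant_scores_produce_no_flags(self):
        g = make_matrix(np.tile([1.0, 0.0, 2.0, 1.0], (6, 1)))
        from strataforge.ancestry import AncestryAssignment

        a = AncestryAssignment(
            g.sample_ids, np.array(["A"] * 6, dtype=object),
            np.ones((6, 1)), ["A"], np.zeros(6, dtype=bool), "panel",
        )
        refined = refine_outliers(a, g, n_pcs=3)
        assert (refined.labels == "A").all()

    def test_tiny_group_skipped_with_warning(self, two_pop_panel):
        g = two_pop_panel.genotypes.subset(samples=np.arange(2))
        from strataforge.ancestry import AncestryAssignment

        a = AncestryAssignment(
            g.sample_ids, np.array(["A", "A"], dtype=object),
            np.ones((2, 1)), ["A"], np.zeros(2, dtype=bool), "panel",
        )
        with pytest.warns(UserWarning, match="<3 members"):
            refined = refine_outliers(a, g)
        assert (refined.labels == "A").all()


def _self_scores(panel):
    model, scores = fit_reference_pca(panel, n_pcs=5)
    return scores, panel.labels, scores


@pytest.fixture(scope="module")
def separated_cohort(two_pop_panel):
    """Cohort of mostly-pure individuals, projected onto the panel PCA."""
    spec = CohortSpec(
        n_samples=[100, 100],
        admixture_priors=[[40.0, 1.0], [1.0, 40.0]],
        birth_year_ranges=[(1940, 1960), (1961, 1985)],
        coarse_label_map={p: p for p in two_pop_panel.pop_names},
    )
    g, meta, truth = simulate_cohort(two_pop_panel, spec, seed=41)
    model, ref_scores = fit_reference_pca(two_pop_panel, n_pcs=5)
    return project_samples(model, g), g, meta, truth, ref_scores


class TestCoarseBlended:
    def test_identity_labels_match_panel_classifier(self, two_pop_panel, separated_cohort):
        scores, g, meta, truth, ref_scores = separated_cohort
        coarse = truth["dominant_pop"].to_numpy(dtype=object)
        a_panel = classify_ancestry(
            ref_scores, two_pop_panel.labels, scores, g.sample_ids, seed=0, n_trees=200
        )
        a_blend = coarse_blended_assignment(scores, coarse, g.sample_ids, seed=0, n_trees=200)
        both = (a_panel.labels != UNCLASSIFIED) & (a_blend.labels != UNCLASSIFIED)
        assert both.mean() > 0.9
        assert (a_panel.labels[both] == a_blend.labels[both]).all()

    def test_missing_label_imputed_at_high_confidence(self, separated_cohort):
        scores, g, meta, truth, _ = separated_cohort
        coarse = truth["dominant_pop"].to_numpy(dtype=object).copy()
        clear = np.abs(truth["q_POP1"].to_numpy() - 0.5) > 0.45  # far from boundary
        victim = np.where(clear)[0][0]
        expected = coarse[victim]
        coarse[victim] = None
        a = coarse_blended_assignment(scores, coarse, g.sample_ids, seed=0, n_trees=200)
        assert a.labels[victim] == expected

    def test_contradicting_label_unclassified(self, separated_cohort):
        scores, g, meta, truth, _ = separated_cohort
        coarse = truth["dominant_pop"].to_numpy(dtype=object).copy()
        clear = np.abs(truth["q_POP1"].to_numpy() - 0.5) > 0.45
        victim = np.where(clear)[0][0]
        coarse[victim] = "POP2" if coarse[victim] == "POP1" else "POP1"
        a = coarse_blended_assignment(scores, coarse, g.sample_ids, seed=0, n_trees=200)
        assert a.labels[victim] == UNCLASSIFIED

    def test_all_missing_rejected(self, separated_cohort):
        scores, g, *_ = separated_cohort
        with pytest.raises(ParameterError):
            coarse_blended_assignment(
                scores, [None] * len(scores), g.sample_ids, seed=0
            )


def test_merged_coarse_group_more_heterogeneous_than_fine_groups():
    """Merging two diverged populations under one coarse label inflates the
    within-group PC variance relative to the panel method's separate groups."""
    wins = 0
    for rep in range(10):
        model = PopulationModel.random(300, fst=[0.1, 0.1], seed=100 + rep)
        panel = simulate_reference_panel(model, 60, seed=200 + rep)
        spec = CohortSpec(
            n_samples=[120, 120],
            admixture_priors=[[15.0, 1.0], [1.0, 15.0]],
            birth_year_ranges=[(1940, 1960), (1961, 1985)],
            coarse_label_map={p: "ASN" for p in panel.pop_names},
        )
        g, meta, truth = simulate_cohort(panel, spec, seed=300 + rep)
        pca, ref_scores = fit_reference_pca(panel, n_pcs=4)
        scores = project_samples(pca, g)
        fine = classify_ancestry(
            ref_scores, panel.labels, scores, g.sample_ids, seed=rep, n_trees=100
        )
        merged = coarse_blended_assignment(
            scores, meta["coarse_label"], g.sample_ids, seed=rep, n_trees=50
        )
        var_merged = scores[merged.labels == "ASN"].var(axis=0).sum()
        fine_vars = [
            scores[fine.labels == p].var(axis=0).sum()
            for p in panel.pop_names
            if (fine.labels == p).sum() > 2
        ]
        wins += var_merged > max(fine_vars)
    assert wins == 10
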