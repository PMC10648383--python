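"""PCA, LDA, leave-one-out species assignment and landmark contrasts."""

import numpy as np
import pytest
from sklearn.decomposition import PCA as SkPCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from wingmorph import (
    Sex,
    Species,
    SyntheticSpec,
    generate_study,
    gpa,
    landmark_differences,
    lda_fit,
    loocv_classify,
    pca,
    report_from_confusion,
)
from wingmorph.classify import RankDeficiencyError


class TestPca:
    def test_collinear_data_one_component(self, rng):
        direction = rng.standard_normal(10)
        x = np.outer(rng.standard_normal(20), direction)
        res = pca(x)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_explained_variance_sums_to_one(self, rng):
        res = pca(rng.standard_normal((30, 12)))
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)

    def test_scores_orthogonal_and_reconstruction(self, rng):
        x = rng.standard_normal((25, 8))
        res = pca(x)
        gram = res.scores.T @ res.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8
        reconstructed = res.scores @ res.loadings.T + res.mean
        assert np.abs(reconstructed - x).max() < 1e-8

    def test_matches_sklearn_eigenvalues(self, rng):
        x = rng.standard_normal((40, 6))
        res = pca(x)
        sk = SkPCA().fit(x)
        np.testing.assert_allclose(
            res.explained_variance_ratio, sk.explained_variance_ratio_, atol=1e-10
        )

    def test_rank_capped_after_superimposition(self, small_study):
        res = gpa(small_study)
        p = pca(res.shape_vectors())
        n = len(small_study)
        assert p.m <= min(n - 1, 2 * 18 - 4)

    def test_sign_gauge_deterministic(self, rng):
        x = rng.standard_normal((30, 5))
        res = pca(x)
        for j in range(res.m):
            load = res.loadings[:, j]
            assert load[np.argmax(np.abs(load))] > 0

    def test_too_few_specimens(self, rng):
        with pytest.raises(ValueError):
            pca(rng.standard_normal((2, 5)))


class TestLda:
    def test_separated_clouds_fully_assigned(self, rng):
        x = np.concatenate(
            [rng.normal(0, 0.1, (15, 3)), rng.normal(5, 0.1, (15, 3))]
        )
        labels = np.repeat(["a", "b"], 15)
        model = lda_fit(x, labels)
        assert (model.predict(x) == labels).all()

    def test_label_swap_negates_scores(self, rng):
        x = rng.standard_normal((20, 4))
        labels = np.repeat(["a", "b"], 10)
        swapped = np.repeat(["b", "a"], 10)
        s1 = lda_fit(x, labels).scores(x)
        s2 = lda_fit(x[np.r_[10:20, 0:10]], swapped[np.r_[10:20, 0:10]]).scores(x)
        np.testing.assert_allclose(s1, -s2, atol=1e-9)

    def test_direction_matches_fisher_grid_search(self, rng):
        # 2-D oracle: maximize the Fisher criterion over a fine angle grid
        x = np.concatenate(
            [
                rng.multivariate_normal([0, 0], [[2.0, 0.8], [0.8, 1.0]], 60),
                rng.multivariate_normal([1.5, 0.5], [[2.0, 0.8], [0.8, 1.0]], 60),
            ]
        )
        labels = np.repeat(["a", "b"], 60)
        model = lda_fit(x, labels)
        mu_d = x[:60].mean(0) - x[60:].mean(0)
        r1, r2 = x[:60] - x[:60].mean(0), x[60:] - x[60:].mean(0)
        w_cov = (r1.T @ r1 + r2.T @ r2) / (120 - 2)
        best, best_j = None, -np.inf
        for theta in np.arange(0, np.pi, 1e-4):
            w = np.array([np.cos(theta), np.sin(theta)])
            j = (w @ mu_d) ** 2 / (w @ w_cov @ w)
            if j > best_j:
                best, best_j = w, j
        cos = abs(best @ model.w) / np.linalg.norm(model.w)
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_matches_sklearn_predictions(self, rng):
        x = np.concatenate(
            [rng.normal(0, 1.0, (40, 5)), rng.normal(0.8, 1.0, (30, 5))]
        )
        labels = np.repeat(["a", "b"], [40, 30])
        model = lda_fit(x, labels, priors="proportional")
        sk = LinearDiscriminantAnalysis(solver="svd").fit(x, labels)
        assert (model.predict(x) == sk.predict(x)).all()
        np.testing.assert_allclose(
            model.posteriors(x), sk.predict_proba(x)[:, 0], atol=1e-6
        )

    def test_singular_covariance_instructs_pca(self, rng):
        base = rng.standard_normal((20, 2))
        x = np.column_stack([base, base[:, 0]])  # duplicated column
        with pytest.raises(RankDeficiencyError, match="PCA"):
            lda_fit(x, np.repeat(["a", "b"], 10))


class TestLoocv:
    def test_accuracy_from_published_female_confusion(self):
        # 3 of 77 and 2 of 67 misclassified -> 139/144
        rep = report_from_confusion([[74, 3], [2, 65]])
        assert rep.accuracy == pytest.approx(139 / 144)
        assert round(100 * rep.accuracy, 1) == 96.5

    def test_accuracy_from_published_male_confusion(self):
        # 7 of 70 and 4 of 57 misclassified -> 116/127
        rep = report_from_confusion([[63, 7], [4, 53]])
        assert rep.accuracy == pytest.approx(116 / 127)
        assert round(100 * rep.accuracy, 1) == 91.3

    def test_confusion_sums_to_n_and_accuracy_is_trace(self, small_study):
        meta = small_study.metadata_frame()
        mask = ((meta["sex"] == "female") & (meta["replicate"] == 1)).to_numpy()
        res = gpa(small_study.subset(mask))
        labels = meta[mask]["species"].to_numpy()
        rep = loocv_classify(res.shape_vectors(), labels)
        assert rep.confusion.sum() == mask.sum()
        assert rep.accuracy == np.trace(rep.confusion) / mask.sum()

    def test_invariant_to_orthogonal_feature_rotation(self, rng):
        x = np.concatenate(
            [rng.normal(0, 1, (20, 6)), rng.normal(1.0, 1, (20, 6))]
        )
        labels = np.repeat(["a", "b"], 20)
        q, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        r1 = loocv_classify(x, labels, feature_mode="raw")
        r2 = loocv_classify(x @ q.T, labels, feature_mode="raw")
        np.testing.assert_array_equal(r1.confusion, r2.confusion)

    def test_null_signal_collapses_to_majority_class(self, rng):
        x = rng.standard_normal((90, 4))
        labels = np.repeat(["big", "small"], [60, 30])
        rep = loocv_classify(x, labels, feature_mode="raw", priors="proportional")
        # majority prior 2/3; allow generous binomial slack
        assert rep.accuracy >= 2 / 3 - 0.17

    def test_effect_free_generator_near_chance(self):
        spec = SyntheticSpec(
            group_sizes={
                (Species.JAPONICUS, Sex.FEMALE): 40,
                (Species.KOREICUS, Sex.FEMALE): 30,
            },
            species_effect_d=0.0,
            n_replicate_specimens=0,
            seed=13,
        )
        ds = generate_study(spec)
        res = gpa(ds)
        rep = loocv_classify(
            res.shape_vectors(), ds.metadata_frame()["species"].to_numpy()
        )
        # chance = majority prior 4/7; binomial sd ~ 0.06
        assert abs(rep.accuracy - 4 / 7) < 0.2

    def test_fold_minimums_enforced(self, rng):
        x = rng.standard_normal((8, 3))
        with pytest.raises(ValueError):
            loocv_classify(x, ["a"] * 2 + ["b"] * 6, feature_mode="raw")


class TestLandmarkDifferences:
    def test_identical_group_means_zero(self, rng):
        block = rng.standard_normal((10, 36))
        shapes = np.concatenate([block, block])
        labels = np.repeat(["a", "b"], 10)
        res = landmark_differences(shapes, labels, single_landmark_loocv=False)
        assert np.abs(res.magnitudes).max() < 1e-12

    def test_ranking_is_permutation(self, rng):
        shapes = rng.standard_normal((20, 36)) * 0.01
        labels = np.repeat(["a", "b"], 10)
        res = landmark_differences(shapes, labels, single_landmark_loocv=False)
        assert sorted(res.ranking.tolist()) == list(range(1, 19))

    def test_magnitudes_invariant_to_common_rotation(self, rng):
        shapes = rng.standard_normal((20, 36)) * 0.01
        labels = np.repeat(["a", "b"], 10)
        theta = 1.1
        rot = np.kron(
            np.eye(18),
            np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            ),
        )
        r1 = landmark_differences(shapes, labels, single_landmark_loocv=False)
        r2 = landmark_differences(shapes @ rot.T, labels, single_landmark_loocv=False)
        np.testing.assert_allclose(r1.magnitudes, r2.magnitudes, atol=1e-12)

    def test_focal_landmark_recovered_from_generator(self):
        spec = SyntheticSpec(
            group_sizes={
                (Species.JAPONICUS, Sex.FEMALE): 50,
                (Species.KOREICUS, Sex.FEMALE): 50,
            },
            n_replicate_specimens=0,
            seed=17,
        )
        ds = generate_study(spec)
        res = gpa(ds)
        labels = ds.metadata_frame()["species"].to_numpy()
        summary = landmark_differences(res.shape_vectors(), labels)
        assert summary.ranking[0] == 18
        # no single landmark approaches the full-configuration accuracy
        full = loocv_classify(res.shape_vectors(), labels)
        assert summary.single_landmark_accuracy.max() < full.accuracy
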