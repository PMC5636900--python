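"""Mahalanobis cluster model and chi-squared assignment confidence."""

import math

import numpy as np
import pytest

from barrelpt.classifier import (
    ClusterModel,
    FeatureSpaceSpec,
    classify,
    evaluate_cohort,
    feature_matrix,
    fit_clusters,
    mahalanobis,
)


def chi2_sf_oracle(x, k, tol=1e-14):
    """1 - F(x; k) via series / continued-fraction regularized incomplete
    gamma (independent of scipy): Q(k/2, x/2)."""
    a, z = k / 2.0, x / 2.0
    if z <= 0:
        return 1.0
    lg = math.lgamma(a)
    if z < a + 1:
        # lower series P(a, z)
        term = 1.0 / a
        total = term
        n = a
        while abs(term) > abs(total) * tol:
            n += 1
            term *= z / n
            total += term
        p = total * math.exp(-z + a * math.log(z) - lg)
        return 1.0 - p
    # Lentz continued fraction for Q(a, z)
    tiny = 1e-300
    b = z + 1.0 - a
    c = 1.0 / tiny
    d = 1.0 / b
    h = d
    for i in range(1, 10_000):
        an = -i * (i - a)
        b += 2.0
        d = an * d + b
        d = tiny if abs(d) < tiny else d
        c = b + an / c
        c = tiny if abs(c) < tiny else c
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < tol:
            break
    return h * math.exp(-z + a * math.log(z) - lg)


class TestFitClusters:
    def test_default_merge_yields_three_clusters(self, rng):
        X = rng.normal(size=(12, 2))
        labels = ["POm", "SC", "Pons", "Sp5C"] * 3
        model = fit_clusters(X, labels)
        assert sorted(model.labels) == ["POm", "SC/Pons", "Sp5C"]

    def test_identical_points_ridge_keeps_model_valid(self):
        X = np.vstack([np.zeros((3, 2)), np.ones((3, 2))])
        labels = ["A"] * 3 + ["B"] * 3
        model = fit_clusters(X, labels, merge_map={})
        for c in model.clusters:
            assert np.all(np.linalg.eigvalsh(c.cov) > 0)

    def test_estimator_consistency(self, rng):
        mean = np.array([2.0, -1.0])
        cov = np.array([[2.0, 0.7], [0.7, 1.0]])
        X = rng.multivariate_normal(mean, cov, size=10_000)
        model = fit_clusters(X, ["A"] * len(X), merge_map={})
        c = model.clusters[0]
        np.testing.assert_allclose(c.mean, mean, atol=3 * np.sqrt(2.0 / 10_000) * 3)
        np.testing.assert_allclose(c.cov, cov, atol=0.1)

    def test_small_cluster_uses_diagonal_fallback(self, rng):
        X = rng.normal(size=(7, 5))
        labels = ["A"] * 4 + ["B"] * 3
        with pytest.warns(UserWarning, match="diagonal covariance"):
            model = fit_clusters(X, labels, merge_map={})
        assert all(c.diagonal_fallback for c in model.clusters)

    def test_tiny_cluster_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_clusters(np.zeros((3, 1)), ["A", "A", "B"], merge_map={})


class TestMahalanobis:
    def test_zero_at_mean(self, rng):
        X = rng.normal(size=(50, 3))
        model = fit_clusters(X, ["A"] * 50, merge_map={})
        assert mahalanobis(model.clusters[0].mean, model.clusters[0]) == 0.0

    def test_1d_definition(self):
        X = np.array([[-1.0], [1.0], [0.0], [2.0], [-2.0]]) * np.sqrt(2.5)
        model = fit_clusters(X, ["A"] * 5, merge_map={}, ridge=0.0)
        c = model.clusters[0]
        sd = np.sqrt(c.cov[0, 0])
        assert mahalanobis(np.array([2.0 * sd]), c) == pytest.approx(2.0, rel=1e-9)

    def test_diagonal_covariance_equals_zscore_rss(self, rng):
        X = rng.normal(size=(2000, 4)) * np.array([1.0, 2.0, 0.5, 3.0])
        model = fit_clusters(X, ["A"] * len(X), merge_map={})
        c = model.clusters[0]
        c.cov = np.diag(np.diag(c.cov))  # force diagonal
        x = rng.normal(size=4)
        z = (x - c.mean) / np.sqrt(np.diag(c.cov))
        assert mahalanobis(x, c) == pytest.approx(np.sqrt(np.sum(z**2)), rel=1e-9)


class TestClassify:
    @staticmethod
    def two_gaussian_model(rng, d=1, sep=4.0, n=500):
        X = np.vstack(
            [rng.normal(0, 1, size=(n, d)), rng.normal(sep, 1, size=(n, d))]
        )
        return fit_clusters(X, ["A"] * n + ["B"] * n, merge_map={})

    def test_equidistant_confidences_are_uniform(self, rng):
        # identical spherical clusters on an equilateral triangle: the
        # centroid is equidistant, so P(k) = 1/3 for each cluster
        means = np.array([[0.0, 0.0], [8.0, 0.0], [4.0, 8.0 * np.sqrt(3) / 2]])
        X = np.vstack([rng.normal(m, 1, size=(200, 2)) for m in means])
        model = fit_clusters(X, ["A"] * 200 + ["B"] * 200 + ["C"] * 200, merge_map={})
        for c, m in zip(model.clusters, means):
            c.cov = np.eye(2)
            c.mean = m
        res = classify(means.mean(axis=0), model)
        np.testing.assert_allclose(res.confidences, 1 / 3, atol=1e-9)

    def test_at_cluster_mean_confidence_near_one(self, rng):
        model = self.two_gaussian_model(rng, d=1, sep=10.0)
        res = classify(model.clusters[0].mean, model)
        assert res.assigned == "A"
        assert res.p_values[0] == pytest.approx(1.0)
        assert res.assigned_confidence > 0.999

    def test_confidence_matches_incomplete_gamma_oracle(self, rng):
        """P(k) computed from scipy's chi-squared CDF agrees with an
        independent series/continued-fraction incomplete-gamma evaluation."""
        for d in (1, 2, 3, 5):
            X = rng.normal(size=(400, d))
            model = fit_clusters(
                np.vstack([X, X + 4.0]), ["A"] * 400 + ["B"] * 400, merge_map={}
            )
            for _ in range(50):
                x = rng.normal(1.5, 2.0, size=d)
                res = classify(x, model)
                oracle_p = np.array(
                    [chi2_sf_oracle(di**2, d) for di in res.distances]
                )
                np.testing.assert_allclose(res.p_values, oracle_p, atol=1e-8)
                if oracle_p.sum() > 0:
                    np.testing.assert_allclose(
                        res.confidences, oracle_p / oracle_p.sum(), atol=1e-8
                    )

    def test_confidences_sum_to_one(self, rng):
        model = self.two_gaussian_model(rng, d=2)
        for _ in range(20):
            res = classify(rng.normal(2, 3, size=2), model)
            assert res.confidences.sum() == pytest.approx(1.0)

    def test_confidence_decays_moving_away_from_cluster(self, rng):
        model = self.two_gaussian_model(rng, d=1, sep=12.0)
        confs = [
            classify(np.array([x]), model).confidences[0] for x in (0.0, 1.0, 2.0, 3.0, 4.0)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(confs, confs[1:]))

    def test_affine_rescaling_invariance_after_refit(self, rng):
        X = np.vstack([rng.normal(0, 1, size=(100, 2)), rng.normal(5, 1, size=(100, 2))])
        labels = ["A"] * 100 + ["B"] * 100
        x = rng.normal(2, 2, size=2)
        # ridge 0: the trace-normalized ridge is deliberately isotropic and
        # therefore not itself scale-equivariant
        res1 = classify(x, fit_clusters(X, labels, merge_map={}, ridge=0.0))
        scale = np.array([10.0, 0.2])
        res2 = classify(x * scale, fit_clusters(X * scale, labels, merge_map={}, ridge=0.0))
        np.testing.assert_allclose(res1.distances, res2.distances, rtol=1e-6)
        np.testing.assert_allclose(res1.confidences, res2.confidences, rtol=1e-6)

    def test_dimension_mismatch_rejected(self, rng):
        model = self.two_gaussian_model(rng, d=2)
        with pytest.raises(ValueError, match="dimension"):
            classify(np.zeros(3), model)


class TestFeatureSpaceSpec:
    def test_standardize_flag_and_mahalanobis_invariance(self, rng):
        import pandas as pd

        table = pd.DataFrame(
            {"depth": rng.normal(1100, 100, size=40), "rate": rng.normal(4, 2, size=40)}
        )
        labels = ["A"] * 20 + ["B"] * 20
        raw = feature_matrix(table, FeatureSpaceSpec(("depth", "rate")))
        z = feature_matrix(table, FeatureSpaceSpec(("depth", "rate"), standardize=True))
        assert z.mean(axis=0) == pytest.approx([0, 0], abs=1e-12)
        assert z.std(axis=0) == pytest.approx([1, 1], abs=1e-12)
        # classification refit on z-scored features is unchanged (ridge 0)
        a = evaluate_cohort(raw, labels, merge_map={}, ridge=0.0)
        b = evaluate_cohort(z, labels, merge_map={}, ridge=0.0)
        np.testing.assert_allclose(a["confidence"], b["confidence"], rtol=1e-8)

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            FeatureSpaceSpec(())


class TestEvaluateCohort:
    def test_training_means_classified_perfectly(self, rng):
        X = np.vstack([rng.normal(0, 1, size=(50, 2)), rng.normal(20, 1, size=(50, 2))])
        labels = ["A"] * 50 + ["B"] * 50
        model_table = evaluate_cohort(X, labels, merge_map={})
        assert model_table["correct"].all()

    def test_well_separated_gaussians_high_accuracy(self, rng):
        X = np.vstack(
            [rng.normal(0, 1, size=(100, 2)), rng.normal([8, 8], 1, size=(100, 2))]
        )
        labels = ["A"] * 100 + ["B"] * 100
        table = evaluate_cohort(X, labels, merge_map={}, leave_one_out=False)
        assert table["correct"].mean() > 0.98

    def test_dual_cells_held_out_from_fitting(self, rng):
        X = np.vstack([rng.normal(0, 1, size=(30, 2)), rng.normal(9, 1, size=(30, 2))])
        labels = ["A"] * 30 + ["B"] * 30
        dual = [False] * 59 + [True]
        table = evaluate_cohort(X, labels, merge_map={}, is_dual=dual)
        assert table["is_dual"].sum() == 1
        assert table.loc[table["is_dual"], "assigned"].iloc[0] == "B"

    def test_combined_space_beats_single_features(self, small_cohort):
        """The combined structure-function space predicts targets with higher
        confidence than any single feature alone."""
        import warnings

        from barrelpt.pipeline import STRUCTURE_FEATURES, cell_table
        from barrelpt.classifier import loo_confidences

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = cell_table(small_cohort, with_similarity=False)
            labels = table["label"].tolist()
            combined, _ = loo_confidences(
                table[list(STRUCTURE_FEATURES)].to_numpy(), labels
            )
            singles = [
                loo_confidences(table[[f]].to_numpy(), labels)[0]
                for f in STRUCTURE_FEATURES
            ]
        assert combined > max(singles) - 0.05
        assert combined > np.mean(singles)
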