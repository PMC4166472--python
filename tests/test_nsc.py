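import numpy as np
import pandas as pd
import pytest

import intclust as ic
from intclust.nsc import threshold_grid
from _naive import naive_fit, naive_predict, naive_shrunken_centroids
from conftest import make_matrix, random_fixture


class TestFitAgainstOracle:
    @pytest.mark.parametrize("seed", range(20))
    def test_all_symbols_match_naive_implementation(self, seed):
        """d_kj, shrunken centroids, discriminants and posteriors agree with
        a loop-based transcription of the formulas to 1e-10."""
        rng = np.random.default_rng(seed)
        matrix, labels = random_fixture(rng)
        model = ic.fit_centroids(matrix, labels)
        oracle = naive_fit([list(r) for r in matrix.values.to_numpy()], labels)

        assert model.class_labels == oracle["classes"]
        np.testing.assert_allclose(model.class_centroids,
                                   np.array(oracle["class_mean"]), atol=1e-10)
        np.testing.assert_allclose(model.overall_centroid,
                                   np.array(oracle["overall"]), atol=1e-10)
        np.testing.assert_allclose(model.pooled_sd, np.array(oracle["s"]), atol=1e-10)
        assert model.s0 == pytest.approx(oracle["s0"], abs=1e-10)
        np.testing.assert_allclose(model.d_kj, np.array(oracle["d"]), atol=1e-10)

        delta = float(rng.uniform(0, np.abs(model.d_kj).max()))
        shrunk = ic.shrink(model, delta)
        np.testing.assert_allclose(
            shrunk.shrunken_centroids(),
            np.array(naive_shrunken_centroids(oracle, delta)), atol=1e-10)

        res = ic.predict(shrunk, matrix, min_feature_fraction=0.0)
        labels_o, delta_o, post_o = naive_predict(
            oracle, [list(r) for r in matrix.values.to_numpy()], delta)
        np.testing.assert_allclose(res.discriminant_scores, np.array(delta_o), atol=1e-10)
        np.testing.assert_allclose(res.posteriors, np.array(post_o), atol=1e-10)
        assert list(res.assigned_class) == labels_o

    def test_equal_class_sizes_give_equal_mk(self):
        matrix = make_matrix(np.random.default_rng(0).normal(size=(3, 8)), normalized=True)
        model = ic.fit_centroids(matrix, ["A"] * 4 + ["B"] * 4)
        assert model.m_k[0] == pytest.approx(model.m_k[1])

    def test_plus_convention_switch(self):
        matrix = make_matrix(np.random.default_rng(1).normal(size=(3, 9)), normalized=True)
        labels = ["A"] * 3 + ["B"] * 6
        minus = ic.fit_centroids(matrix, labels, m_convention="minus")
        plus = ic.fit_centroids(matrix, labels, m_convention="plus")
        n, na = 9, 3
        assert minus.m_k[0] == pytest.approx(np.sqrt(1 / na - 1 / n))
        assert plus.m_k[0] == pytest.approx(np.sqrt(1 / na + 1 / n))

    def test_zero_dispersion_guarded_by_s0_floor(self):
        matrix = make_matrix([[0.0, 0.0, 2.0, 2.0]], normalized=True)
        model = ic.fit_centroids(matrix, ["A", "A", "B", "B"])
        assert model.pooled_sd[0] == 0.0
        assert model.s0 == 1e-6
        res = ic.predict(model, matrix, min_feature_fraction=0.0)
        assert np.isfinite(res.discriminant_scores).all()
        assert list(res.assigned_class) == ["A", "A", "B", "B"]

    def test_class_with_one_sample_rejected(self):
        matrix = make_matrix(np.random.default_rng(2).normal(size=(2, 5)))
        with pytest.raises(ic.DataValidationError, match="<2 samples"):
            ic.fit_centroids(matrix, ["A", "A", "A", "A", "B"])


class TestShrinkage:
    def test_zero_delta_is_identity(self):
        rng = np.random.default_rng(3)
        matrix, labels = random_fixture(rng)
        model = ic.fit_centroids(matrix, labels)
        np.testing.assert_array_equal(
            ic.shrink(model, 0.0).shrunken_centroids(), model.class_centroids)

    def test_full_shrinkage_collapses_to_overall_centroid(self):
        rng = np.random.default_rng(4)
        matrix, labels = random_fixture(rng)
        model = ic.fit_centroids(matrix, labels)
        top = float(np.abs(model.d_kj).max())
        collapsed = ic.shrink(model, top).shrunken_centroids()
        for k in range(model.n_classes):
            np.testing.assert_allclose(collapsed[k], model.overall_centroid, atol=1e-12)

    def test_soft_threshold_magnitudes(self):
        matrix = make_matrix(
            np.array([[1.0, 1.0, -1.0, -1.0], [-1.0, -1.0, 1.0, 1.0]]), normalized=True)
        model = ic.fit_centroids(matrix, ["A", "A", "B", "B"])
        d = model.d_kj.copy()
        dp = ic.shrink(model, 0.5).shrunken_offsets()
        np.testing.assert_allclose(np.abs(dp), np.maximum(np.abs(d) - 0.5, 0.0), atol=1e-12)

    def test_active_features_monotone_in_delta(self):
        rng = np.random.default_rng(5)
        matrix, labels = random_fixture(rng, p=5)
        model = ic.fit_centroids(matrix, labels)
        grid = threshold_grid(model, 15)
        counts = [model.n_active_features(d) for d in grid]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_negative_delta_rejected(self):
        rng = np.random.default_rng(6)
        matrix, labels = random_fixture(rng)
        model = ic.fit_centroids(matrix, labels)
        with pytest.raises(ic.DataValidationError):
            ic.shrink(model, -0.1)


class TestPrediction:
    def test_sample_at_centroid_is_assigned_there(self):
        matrix = make_matrix(
            np.array([[1.0, 1.2, -1.0, -1.2], [1.1, 0.9, -1.1, -0.9]]), normalized=True)
        model = ic.fit_centroids(matrix, ["A", "A", "B", "B"])
        probe = make_matrix(model.class_centroids[0:1].T.reshape(2, 1),
                            feature_ids=matrix.feature_ids, sample_ids=["q"],
                            normalized=True)
        res = ic.predict(model, probe, min_feature_fraction=0.0)
        assert res.assigned_class[0] == "A"
        assert res.posteriors[0, 0] > 0.5

    def test_fully_shrunk_model_assigns_by_prior(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(4, 10))
        labels = ["A"] * 7 + ["B"] * 3
        matrix = make_matrix(X, normalized=True)
        model = ic.fit_centroids(matrix, labels)
        full = ic.shrink(model, float(np.abs(model.d_kj).max()) + 1.0)
        res = ic.predict(full, matrix, min_feature_fraction=0.0)
        assert set(res.assigned_class) == {"A"}  # prior 0.7 dominates

    def test_posteriors_normalized(self):
        rng = np.random.default_rng(8)
        matrix, labels = random_fixture(rng)
        model = ic.train(matrix, labels, n_folds=2, n_thresholds=5, seed=0)
        res = ic.predict(model, matrix, min_feature_fraction=0.0)
        np.testing.assert_allclose(res.posteriors.sum(axis=1), 1.0, atol=1e-9)

    def test_too_few_features_rejected(self):
        rng = np.random.default_rng(9)
        matrix, labels = random_fixture(rng, p=5)
        model = ic.fit_centroids(matrix, labels)
        tiny = ic.ExpressionMatrix(matrix.values.iloc[:1], is_normalized=True)
        with pytest.raises(ic.DataValidationError, match="combined mode"):
            ic.predict(model, tiny, min_feature_fraction=0.5)

    def test_missing_cells_rescale_distance_sums(self):
        """A sample with a masked feature gets its squared sums rescaled by
        p_model/p_present, reproducing a hand computation."""
        matrix = make_matrix(
            np.array([[1.0, 1.0, -1.0, -1.0],
                      [0.8, 1.2, -0.8, -1.2],
                      [1.1, 0.9, -1.1, -0.9]]), normalized=True)
        model = ic.fit_centroids(matrix, ["A", "A", "B", "B"])
        q = np.array([[1.0], [np.nan], [0.9]])
        probe = make_matrix(q, feature_ids=matrix.feature_ids, sample_ids=["q"],
                            normalized=True)
        res = ic.predict(model, probe, min_feature_fraction=0.0)
        cent = model.shrunken_centroids()
        denom = model.pooled_sd + model.s0
        for k in range(2):
            sq = sum((q[j, 0] - cent[k, j]) ** 2 / denom[j] ** 2 for j in (0, 2))
            expected = sq * (3 / 2) - 2 * np.log(model.priors[k])
            assert res.discriminant_scores[0, k] == pytest.approx(expected, abs=1e-10)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(10)
        matrix, labels = random_fixture(rng, p=4)
        model = ic.fit_centroids(matrix, labels)
        res = ic.predict(model, matrix, min_feature_fraction=0.0)
        perm = rng.permutation(matrix.n_samples)
        shuffled = ic.ExpressionMatrix(matrix.values.iloc[:, perm], is_normalized=True)
        res2 = ic.predict(model, shuffled, min_feature_fraction=0.0)
        np.testing.assert_allclose(
            res2.discriminant_scores, res.discriminant_scores[perm], atol=1e-12)
        # feature order must not matter either
        fperm = rng.permutation(matrix.n_features)
        refit = ic.fit_centroids(
            ic.ExpressionMatrix(matrix.values.iloc[fperm], is_normalized=True), labels)
        res3 = ic.predict(refit, matrix, min_feature_fraction=0.0)
        np.testing.assert_allclose(
            res3.discriminant_scores, res.discriminant_scores, atol=1e-10)


class TestCrossValidation:
    def test_separated_classes_keep_zero_error_and_largest_delta(self):
        rng = np.random.default_rng(11)
        X = np.hstack([rng.normal(-5, 0.3, size=(4, 12)), rng.normal(5, 0.3, size=(4, 12))])
        matrix = make_matrix(X, normalized=True)
        labels = ["A"] * 12 + ["B"] * 12
        best, curve = ic.cross_validate_threshold(matrix, labels, n_thresholds=10,
                                                  n_folds=4, seed=0)
        zero_error = [g for g, e in curve if e == min(e for _, e in curve)]
        assert curve[0][1] == 0  # delta=0 separates perfectly
        assert best == pytest.approx(max(zero_error))

    def test_same_seed_bitwise_identical(self):
        rng = np.random.default_rng(12)
        matrix, labels = random_fixture(rng, p=5)
        out1 = ic.cross_validate_threshold(matrix, labels, n_thresholds=8, n_folds=2, seed=42)
        out2 = ic.cross_validate_threshold(matrix, labels, n_thresholds=8, n_folds=2, seed=42)
        assert out1 == out2

    def test_single_point_grid_returns_zero(self):
        rng = np.random.default_rng(13)
        matrix, labels = random_fixture(rng)
        best, curve = ic.cross_validate_threshold(matrix, labels, n_thresholds=1,
                                                  n_folds=2, seed=0)
        assert best == 0.0 and len(curve) == 1

    def test_fewer_than_two_folds_rejected(self):
        rng = np.random.default_rng(14)
        matrix, labels = random_fixture(rng)
        with pytest.raises(ic.DataValidationError, match="folds"):
            ic.cross_validate_threshold(matrix, labels, n_folds=1, seed=0)


class TestRetraining:
    def test_full_feature_subset_reproduces_model(self):
        rng = np.random.default_rng(15)
        matrix, labels = random_fixture(rng, p=5)
        full = ic.train(matrix, labels, n_thresholds=6, n_folds=2, seed=5)
        re = ic.retrain_on_features((matrix, labels), matrix.feature_ids,
                                    seed=5, n_thresholds=6, n_folds=2)
        assert re.threshold == full.threshold
        np.testing.assert_array_equal(re.d_kj, full.d_kj)
        assert re.cv_error_curve == full.cv_error_curve

    def test_below_min_fraction_advises_other_modes(self):
        rng = np.random.default_rng(16)
        matrix, labels = random_fixture(rng, p=5)
        with pytest.raises(ic.DataValidationError, match="copy-number or"):
            ic.retrain_on_features((matrix, labels), matrix.feature_ids[:1], seed=0)

    def test_partial_panel_trains_and_predicts(self, small_cohort, small_reference):
        keep = small_reference.matrix.feature_ids[::2]
        model = ic.retrain_on_features(
            (small_reference.matrix, small_reference.labels), keep, seed=2)
        sub = ic.ExpressionMatrix(small_reference.matrix.values.loc[keep],
                                  is_normalized=True)
        res = ic.predict(model, sub)
        acc = (res.assigned_class == small_cohort.true_labels.values).mean()
        assert acc > 0.9


class TestSerialization:
    def test_json_round_trip_enables_exact_reprediction(self, tmp_path):
        rng = np.random.default_rng(17)
        matrix, labels = random_fixture(rng)
        model = ic.train(matrix, labels, n_thresholds=5, n_folds=2, seed=1)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ic.CentroidModel.from_json(path)
        res1 = ic.predict(model, matrix, min_feature_fraction=0.0)
        res2 = ic.predict(back, matrix, min_feature_fraction=0.0)
        np.testing.assert_array_equal(res1.assigned_class, res2.assigned_class)
        np.testing.assert_array_equal(res1.posteriors, res2.posteriors)
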