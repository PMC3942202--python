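import numpy as np
import pytest

from srclatlrr import (ExpressionMatrix, InvalidInputError, LatLRRParams,
                       fit, load_model, normalize_columns, predict,
                       predict_batch, save_model)


def _em(values, prefix="g"):
    m, n = values.shape
    return ExpressionMatrix(values=values,
                            gene_ids=[f"{prefix}{i}" for i in range(m)],
                            sample_ids=[f"s{j}" for j in range(n)])


@pytest.fixture
def orthogonal_two_class(rng):
    """Class A spans rows 0-4, class B rows 5-9 (orthogonal subspaces)."""
    X = np.zeros((10, 8))
    X[:5, :4] = rng.standard_normal((5, 4))
    X[5:, 4:] = rng.standard_normal((5, 4))
    return _em(X), ["A"] * 4 + ["B"] * 4


class TestNormalizeColumns:
    def test_three_four_five(self):
        out, norms = normalize_columns(np.array([[3.0, 0.0], [4.0, 1.0]]))
        np.testing.assert_allclose(out[:, 0], [0.6, 0.8])
        np.testing.assert_allclose(norms, [5.0, 1.0])

    def test_idempotent_on_unit_columns(self, rng):
        X = rng.standard_normal((6, 3))
        X /= np.linalg.norm(X, axis=0)
        out, _ = normalize_columns(X)
        np.testing.assert_allclose(out, X, atol=1e-15)

    def test_zero_column_names_sample(self):
        X = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(InvalidInputError, match="s1"):
            normalize_columns(X, sample_ids=["s0", "s1"])


class TestFit:
    def test_src_bypasses_latlrr(self, orthogonal_two_class):
        em, labels = orthogonal_two_class
        model = fit(em, labels, method="src")
        np.testing.assert_array_equal(model.L, np.eye(10))
        expected, _ = normalize_columns(em.values)
        np.testing.assert_allclose(model.D, expected)
        assert model.latlrr_meta == {}

    def test_latlrr_dictionary_is_LX(self, low_rank_normalized):
        X = low_rank_normalized
        em = _em(X)
        labels = ["A"] * 30 + ["B"] * 30
        model = fit(em, labels, method="src-latlrr",
                    latlrr_params=LatLRRParams(lambda_latlrr=1e4))
        # with E ~ 0 the constraint forces LX = X - XZ
        np.testing.assert_allclose(model.D, model.L @ X, atol=1e-12)
        assert model.latlrr_meta["primal_residual"] <= 1e-6

    def test_latlrr_noise_free_limit_constraint_algebra(self, low_rank_normalized):
        X = low_rank_normalized
        em = _em(X)
        model = fit(em, ["A"] * 30 + ["B"] * 30, method="src-latlrr",
                    latlrr_params=LatLRRParams(lambda_latlrr=1e4))
        # reconstruct XZ from the fitted pieces: D = LX, so X - D ~ XZ
        resid = np.linalg.norm(X - model.D - (X - model.L @ X))
        assert resid <= 1e-5 * np.linalg.norm(X)

    def test_end_to_end_on_synthetic(self, clean_subspace_dataset):
        em, labels, _ = clean_subspace_dataset
        model = fit(em, labels, method="src-latlrr",
                    latlrr_params=LatLRRParams(lambda_latlrr=0.5))
        assert model.latlrr_meta["primal_residual"] <= 1e-6
        assert model.classes == ["class_0", "class_1", "class_2"]

    def test_single_class_rejected(self, rng):
        em = _em(rng.standard_normal((5, 4)))
        with pytest.raises(InvalidInputError):
            fit(em, ["A"] * 4, method="src")

    def test_label_count_mismatch_rejected(self, rng):
        em = _em(rng.standard_normal((5, 4)))
        with pytest.raises(InvalidInputError):
            fit(em, ["A", "B"], method="src")


class TestPredict:
    def test_self_representation(self, orthogonal_two_class):
        em, labels = orthogonal_two_class
        model = fit(em, labels, method="src")
        res = predict(model, em.values[:, 0], lambda_src=1e-6)
        assert res.predicted_class == "A"
        assert res.residuals["A"] <= 1e-3

    def test_orthogonal_subspaces_cross_class_residual(self, rng,
                                                       orthogonal_two_class):
        em, labels = orthogonal_two_class
        model = fit(em, labels, method="src")
        y = np.zeros(10)
        y[:5] = em.values[:5, :4] @ rng.standard_normal(4)   # class-A span
        res = predict(model, y, lambda_src=1e-4)
        assert res.predicted_class == "A"
        assert res.residuals["B"] >= res.residuals["A"]

    def test_exact_tie_breaks_to_smallest_class(self):
        # identical dictionary columns with different labels: the coder
        # splits the weight symmetrically, so the class residuals tie
        v = np.array([1.0, 0.0, 1.0, 0.0])
        em = _em(np.column_stack([v, v]))
        model = fit(em, ["B", "A"], method="src")
        res = predict(model, v, lambda_src=0.01)
        assert res.residuals["A"] == res.residuals["B"]
        assert res.predicted_class == "A"

    def test_scale_invariance(self, clean_subspace_dataset):
        em, labels, _ = clean_subspace_dataset
        model = fit(em, labels, method="src")
        y = em.values[:, 5]
        a = predict(model, y, lambda_src=0.01)
        b = predict(model, 37.5 * y, lambda_src=0.01)
        assert a.predicted_class == b.predicted_class
        np.testing.assert_allclose(
            [a.residuals[c] for c in model.classes],
            [b.residuals[c] for c in model.classes], atol=1e-10)

    def test_length_mismatch_and_zero_vector_rejected(self, orthogonal_two_class):
        em, labels = orthogonal_two_class
        model = fit(em, labels, method="src")
        with pytest.raises(InvalidInputError):
            predict(model, np.ones(3))
        with pytest.raises(InvalidInputError):
            predict(model, np.zeros(10))

    def test_residual_decomposition_sanity(self, clean_subspace_dataset):
        em, labels, _ = clean_subspace_dataset
        model = fit(em, labels, method="src")
        res = predict(model, em.values[:, 0], lambda_src=0.01)
        x = res.sparse_code.x
        parts = sum(np.where(np.asarray(model.labels) == c, x, 0.0)
                    for c in model.classes)
        np.testing.assert_array_equal(parts, x)
        full = np.linalg.norm(res.projected_test - model.D @ x)
        assert full <= min(res.residuals.values()) + 1e-9


class TestPredictBatch:
    def test_empty(self, orthogonal_two_class):
        em, labels = orthogonal_two_class
        model = fit(em, labels, method="src")
        assert predict_batch(model, np.zeros((10, 0))) == []

    def test_single_column_matches_predict(self, orthogonal_two_class, rng):
        em, labels = orthogonal_two_class
        model = fit(em, labels, method="src")
        y = em.values[:, 2]
        single = predict(model, y)
        batch = predict_batch(model, y[:, None])
        assert len(batch) == 1
        assert batch[0].predicted_class == single.predicted_class
        assert batch[0].residuals == single.residuals

    def test_batch_equals_map_of_predict(self, clean_subspace_dataset):
        em, labels, _ = clean_subspace_dataset
        model = fit(em, labels, method="src")
        Y = em.values[:, :10]
        batch = predict_batch(model, Y, sample_ids=em.sample_ids[:10])
        for j, res in enumerate(batch):
            alone = predict(model, Y[:, j])
            assert res.predicted_class == alone.predicted_class
            assert res.sample_id == em.sample_ids[j]


class TestPersistence:
    def test_save_load_identical_predictions(self, clean_subspace_dataset,
                                             tmp_path):
        em, labels, _ = clean_subspace_dataset
        model = fit(em, labels, method="src-latlrr",
                    latlrr_params=LatLRRParams(lambda_latlrr=0.5))
        path = tmp_path / "model.npz"
        save_model(path, model)
        back = load_model(path)
        np.testing.assert_array_equal(back.D, model.D)
        np.testing.assert_array_equal(back.L, model.L)
        assert back.labels == model.labels
        assert back.latlrr_meta == model.latlrr_meta
        y = em.values[:, 11]
        a, b = predict(model, y), predict(back, y)
        assert a.predicted_class == b.predicted_class
        assert a.residuals == b.residuals
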