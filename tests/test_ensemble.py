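"""Dirichlet weighted-average ensemble: pdf, sampling, quantization, search."""

import numpy as np
import pytest
from scipy.stats import dirichlet as scipy_dirichlet

import glaucopt as g
from glaucopt.ensemble import (
    DirichletParams,
    ModelPredictions,
    WeightVector,
    dirichlet_pdf,
    quantize,
    sample_weights,
    search_weights,
    weighted_average_predict,
)


class TestPdf:
    def test_uniform_on_2simplex_is_2(self):
        w = WeightVector((0.2, 0.5, 0.3))
        assert dirichlet_pdf(w, DirichletParams((1, 1, 1))) == pytest.approx(2.0)

    def test_symmetric_alpha2_at_center(self):
        w = WeightVector((1 / 3, 1 / 3, 1 / 3))
        assert dirichlet_pdf(w, DirichletParams((2, 2, 2))) == pytest.approx(120 / 27, rel=1e-9)

    def test_off_simplex_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            WeightVector((0.5, 0.6, 0.1))

    def test_zero_weight_with_small_alpha_unbounded(self):
        w = WeightVector((0.0, 0.4, 0.6))
        with pytest.raises(ValueError, match="unbounded"):
            dirichlet_pdf(w, DirichletParams((0.5, 1, 1)))

    def test_matches_scipy_on_interior_points(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            alpha = rng.uniform(0.5, 4.0, size=3)
            w = rng.dirichlet(alpha)
            ours = dirichlet_pdf(WeightVector(tuple(w)), DirichletParams(tuple(alpha)))
            assert ours == pytest.approx(scipy_dirichlet.pdf(w, alpha), rel=1e-9)

    def test_pdf_and_sampler_are_consistent(self):
        """Mean density of uniform simplex draws is ~2 under alpha = 1."""
        params = DirichletParams((1.0, 1.0, 1.0))
        draws = sample_weights(params, n_trials=2000, seed=0)
        mean_pdf = np.mean([dirichlet_pdf(w, params) for w in draws])
        assert mean_pdf == pytest.approx(2.0, abs=1e-9)


class TestSampling:
    def test_draws_lie_on_simplex(self):
        for w in sample_weights(DirichletParams((2, 1, 3)), n_trials=100, seed=1):
            arr = w.as_array()
            assert np.all(arr >= 0) and np.all(arr <= 1)
            assert abs(arr.sum() - 1.0) <= 1e-9

    def test_sample_mean_matches_dirichlet_mean(self):
        draws = sample_weights(DirichletParams((1, 1, 1)), n_trials=10_000, seed=2)
        mean = np.mean([w.as_array() for w in draws], axis=0)
        assert np.allclose(mean, 1 / 3, atol=0.01)

    def test_same_seed_identical(self):
        a = sample_weights(DirichletParams((1, 1, 1)), 10, seed=7)
        b = sample_weights(DirichletParams((1, 1, 1)), 10, seed=7)
        assert [x.weights for x in a] == [x.weights for x in b]

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            DirichletParams((1.0, 0.0, 1.0))


class TestQuantize:
    def test_thirds_round_with_residual_to_first(self):
        q = quantize(WeightVector((1 / 3, 1 / 3, 1 / 3)))
        assert q.weights == (0.3334, 0.3333, 0.3333)
        assert q.quantized

    def test_vertex_is_fixed_point(self):
        assert quantize(WeightVector((1.0, 0.0, 0.0))).weights == (1.0, 0.0, 0.0)

    def test_quantized_sum_exactly_one(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            w = quantize(WeightVector(tuple(rng.dirichlet([1, 1, 1]))))
            assert round(sum(w.weights), 4) == 1.0


class TestWeightedAverage:
    def _preds(self):
        return ModelPredictions(
            probs=np.array([[0.2], [0.6], [0.9]]), labels=np.array([1])
        )

    def test_one_hot_recovers_member(self):
        out = weighted_average_predict(self._preds(), WeightVector((1.0, 0.0, 0.0)))
        assert out == pytest.approx([0.2])

    def test_single_sample_arithmetic(self):
        out = weighted_average_predict(self._preds(), WeightVector((0.2, 0.3, 0.5)))
        assert out == pytest.approx([0.67])

    def test_identical_members_unchanged(self):
        p = np.tile(np.array([0.1, 0.7, 0.4]), (3, 1))
        preds = ModelPredictions(probs=p, labels=np.array([0, 1, 0]))
        out = weighted_average_predict(preds, WeightVector((0.5, 0.25, 0.25)))
        assert np.allclose(out, p[0])

    def test_convexity_bounds(self):
        rng = np.random.default_rng(4)
        preds = ModelPredictions(probs=rng.random((3, 50)), labels=rng.integers(0, 2, 50))
        w = WeightVector(tuple(rng.dirichlet([1, 1, 1])))
        out = weighted_average_predict(preds, w)
        assert np.all(out >= preds.probs.min(axis=0) - 1e-12)
        assert np.all(out <= preds.probs.max(axis=0) + 1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="weights for"):
            weighted_average_predict(self._preds(), WeightVector((0.5, 0.5)))


class TestSearchWeights:
    def _separable(self, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, 200)
        perfect = np.clip(y + rng.normal(0, 0.05, 200), 0, 1)
        noise = rng.random((2, 200))
        return ModelPredictions(
            probs=np.vstack([perfect[None], noise]),
            labels=y,
            model_names=["sharp", "noise1", "noise2"],
        ), y

    def test_best_accuracy_is_max_of_log(self):
        preds, _ = self._separable()
        res = search_weights(preds, n_trials=50, seed=1)
        assert res.best_accuracy == max(a for _, a in res.trial_log)
        assert res.trial_log[res.winning_trial_index - 1][1] == res.best_accuracy

    def test_informative_model_dominates_and_ensemble_wins(self):
        preds, y = self._separable()
        res = search_weights(preds, n_trials=200, seed=2)
        assert res.best_weights.weights[0] > 1 / 3
        individual = [np.mean((p >= 0.5).astype(int) == y) for p in preds.probs]
        assert res.best_accuracy >= max(individual)

    def test_identical_models_tie_to_first_trial(self):
        p = np.tile(np.linspace(0, 1, 20), (3, 1))
        preds = ModelPredictions(probs=p, labels=(p[0] > 0.3).astype(int))
        res = search_weights(preds, n_trials=40, seed=3)
        assert res.winning_trial_index == 1

    def test_permutation_invariance_up_to_ties(self):
        preds, _ = self._separable(seed=5)
        res = search_weights(preds, DirichletParams((2.0, 1.0, 1.5)), n_trials=100, seed=4)
        perm = [1, 2, 0]
        preds_p = ModelPredictions(probs=preds.probs[perm], labels=preds.labels)
        res_p = search_weights(
            preds_p, DirichletParams(tuple(np.array([2.0, 1.0, 1.5])[perm])), n_trials=100, seed=4
        )
        assert res_p.best_accuracy == pytest.approx(res.best_accuracy)

    def test_single_model_degenerates_to_its_accuracy(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 50)
        p = rng.random(50)
        preds = ModelPredictions(probs=p[None], labels=y)
        res = search_weights(preds, n_trials=10, seed=0)
        assert res.best_weights.weights == (1.0,)
        assert res.best_accuracy == pytest.approx(np.mean((p >= 0.5).astype(int) == y))

    def test_empty_predictions_rejected(self):
        preds = ModelPredictions(probs=np.empty((3, 0)), labels=np.empty(0, dtype=int))
        with pytest.raises(ValueError, match="empty"):
            search_weights(preds, n_trials=5, seed=0)


def test_predictions_csv_round_trip(tmp_path):
    rng = np.random.default_rng(7)
    preds = ModelPredictions(
        probs=rng.random((3, 10)),
        labels=rng.integers(0, 2, 10),
        model_names=["multibranch", "mobilenet", "densenet201"],
    )
    preds.to_csv(tmp_path / "p.csv")
    back = ModelPredictions.from_csv(tmp_path / "p.csv")
    assert back.model_names == preds.model_names
    assert np.allclose(back.probs, preds.probs)
    assert np.array_equal(back.labels, preds.labels)
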