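"""Bayesian optimization: EI closed forms, trace contracts, search behavior."""

import numpy as np
import pytest
from scipy.stats import chisquare, norm

import glaucopt as g
from glaucopt.arch import ACTIVATION_CHOICES
from glaucopt.bo import SearchSpace, expected_improvement, run_bo


class TestExpectedImprovement:
    def test_no_uncertainty_no_improvement_is_zero(self):
        assert expected_improvement(0.5, 0.0, 0.6, xi=0.0) == 0.0

    def test_at_incumbent_with_unit_sd_equals_phi0(self):
        val = expected_improvement(0.6, 1.0, 0.6, xi=0.0)
        assert val == pytest.approx(norm.pdf(0.0), abs=1e-12)
        assert val == pytest.approx(0.398942, abs=1e-6)

    def test_sure_improvement_limit(self):
        assert expected_improvement(1.6, 1e-12, 0.6, xi=0.0) == pytest.approx(1.0, abs=1e-9)
        assert expected_improvement(1.6, 0.0, 0.6, xi=0.0) == 1.0

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            expected_improvement(0.5, -0.1, 0.4)

    def test_monotone_in_mu_and_sigma(self):
        """EI grows with the surrogate mean and, below the incumbent with
        xi=0, with the surrogate sd."""
        mus = np.linspace(0.0, 1.0, 21)
        ei_mu = expected_improvement(mus, 0.3, best=0.5)
        assert np.all(np.diff(ei_mu) > 0)
        sigmas = np.linspace(0.01, 2.0, 30)
        ei_sigma = expected_improvement(0.3, sigmas, best=0.5, xi=0.0)
        assert np.all(np.diff(ei_sigma) > 0)

    def test_nonnegative_everywhere(self):
        rng = np.random.default_rng(0)
        ei = expected_improvement(rng.normal(size=200), rng.random(200), best=0.2, xi=0.01)
        assert np.all(ei >= 0)


class TestRunBO:
    def test_trace_has_exactly_n_iterations(self):
        trace, _ = run_bo(lambda c: 0.5, SearchSpace(), n_iterations=12, n_initial=4, seed=0)
        assert len(trace.trials) == 12
        assert [t.index for t in trace.trials] == list(range(1, 13))

    def test_best_so_far_nondecreasing(self):
        rng = np.random.default_rng(1)
        trace, _ = run_bo(
            lambda c: float(rng.random()), SearchSpace(), n_iterations=15, n_initial=5, seed=1
        )
        best = trace.best_so_far
        assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))

    def test_failing_objective_recorded_as_zero(self):
        calls = {"n": 0}

        def flaky(config):
            calls["n"] += 1
            if calls["n"] % 2 == 0:
                raise RuntimeError("boom")
            return 0.4

        trace, _ = run_bo(flaky, SearchSpace(), n_iterations=8, n_initial=8, seed=2)
        assert len(trace.trials) == 8
        failed = [t for t in trace.trials if t.failed]
        assert failed and all(t.objective == 0.0 for t in failed)

    def test_same_seed_same_trace(self):
        def obj(config, trial_seed=0):
            return (config.n_dense_blocks / 5 + config.dropout_rate) / 2

        t1, b1 = run_bo(obj, SearchSpace(), n_iterations=14, n_initial=5, seed=9)
        t2, b2 = run_bo(obj, SearchSpace(), n_iterations=14, n_initial=5, seed=9)
        assert b1 == b2
        assert [t.config for t in t1.trials] == [t.config for t in t2.trials]
        assert [t.objective for t in t1.trials] == [t.objective for t in t2.trials]

    def test_pure_random_search_samples_uniformly(self):
        """With n_initial = n_iterations the trace is plain random search;
        the activation marginal over 1000 trials passes a chi-square
        goodness-of-fit test against uniform."""
        trace, _ = run_bo(
            lambda c: 0.5, SearchSpace(), n_iterations=1000, n_initial=1000, seed=3
        )
        counts = [
            sum(t.config.activation == a for t in trace.trials) for a in ACTIVATION_CHOICES
        ]
        assert chisquare(counts).pvalue > 0.001

    def test_exhausts_small_discrete_space(self):
        """On a 20-point discrete space, enough iterations make the
        incumbent equal the exhaustive optimum."""
        points = [
            g.HeadConfig(n_dense_blocks=b, activation=a)
            for b in range(1, 5)
            for a in ACTIVATION_CHOICES
        ]

        class DiscreteSpace(SearchSpace):
            def sample(self, rng):
                return points[rng.integers(len(points))]

        def obj(config):
            return 0.3 * config.n_dense_blocks / 5 + {"relu": 0.0, "elu": 0.1, "tanh": 0.2, "swish": 0.15, "softplus": 0.05}[config.activation]

        exhaustive = max(obj(p) for p in points)
        trace, best = run_bo(obj, DiscreteSpace(), n_iterations=60, n_initial=20, seed=4)
        assert trace.best_so_far[-1] == pytest.approx(exhaustive)

    def test_recovers_grid_optimum_in_most_seeds(self, bo_recovery):
        hits, _ = bo_recovery
        assert sum(hits) >= 4


class TestTrainingObjective:
    def _constant_image_manifest(self, tmp_path, n_glaucoma, n_normal):
        from PIL import Image
        from glaucopt.data import ImageManifest, ManifestRecord

        tmp_path.mkdir(parents=True, exist_ok=True)
        img = Image.fromarray(np.full((16, 16, 3), 120, dtype=np.uint8))
        recs = []
        for i, label in enumerate(["glaucoma"] * n_glaucoma + ["normal"] * n_normal):
            p = tmp_path / f"{label}_{i}.png"
            img.save(p)
            recs.append(ManifestRecord(path=str(p), label=label, source="constant"))
        return ImageManifest(recs)

    def test_constant_images_give_majority_class_accuracy(self, tmp_path):
        """With no signal, the trained head converges to the base rate and
        validation accuracy equals the majority-class fraction."""
        train_m = self._constant_image_manifest(tmp_path / "t", 9, 3)
        val_m = self._constant_image_manifest(tmp_path / "v", 6, 2)
        objective = g.make_training_objective(
            "multibranch", train_m, val_m, epochs=4, batch_size=4, image_size=16, width=0.1
        )
        acc = objective(g.HeadConfig(n_dense_nodes=32), trial_seed=1)
        assert acc == pytest.approx(6 / 8)

    def test_objective_is_deterministic(self, easy_split, tmp_path):
        train_m, val_m, _ = easy_split
        objective = g.make_training_objective(
            "multibranch", train_m, val_m, epochs=1, batch_size=8, image_size=32, width=0.1
        )
        cfg = g.HeadConfig(n_dense_nodes=32, flatten_type="gap")
        assert objective(cfg, trial_seed=7) == objective(cfg, trial_seed=7)

    def test_empty_manifest_rejected(self):
        from glaucopt.data import ImageManifest

        with pytest.raises(ValueError, match="non-empty"):
            g.make_training_objective("multibranch", ImageManifest([]), ImageManifest([]))


def test_trace_jsonl_round_trip():
    trace, _ = run_bo(lambda c: 0.25, SearchSpace(), n_iterations=5, n_initial=5, seed=0)
    back = g.BOTrace.from_jsonl(trace.to_jsonl(), seed=0)
    assert [t.config for t in back.trials] == [t.config for t in trace.trials]
    assert back.best_so_far == trace.best_so_far
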