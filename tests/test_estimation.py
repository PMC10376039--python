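"""Weight estimation: starts, grid-search oracles, multistart selection."""

import math

import numpy as np
import pytest

import empisim as es
from conftest import make_dataset
from empisim.similarity_model import SimilarityEngine

EX_WED = es.ModelSpec("m1", es.DistanceSpec("wed", delta=1), es.SimilaritySpec("ex"))


class TestInitialStarts:
    def test_m1_pairs_from_cell_means(self, tooth):
        means = es.cell_means(tooth)
        y1 = [means[("dose", d)] for d in (0.5, 1.0, 2.0)]
        y2 = [means[("supp", s)] for s in ("VC", "OJ")]
        starts = es.initial_starts(tooth, "m1").starts
        expected = [
            (y1[0], y2[0]), (y1[0], y2[1]), (y1[1], y2[0]), (y1[1], y2[1]), (y1[2], y2[0]),
        ]
        for got, exp in zip(starts, expected):
            np.testing.assert_allclose(got, exp)

    def test_m2_quadruples_repeat_dose_mean(self, tooth):
        means = es.cell_means(tooth)
        starts = es.initial_starts(tooth, "m2").starts
        first = starts[0]
        assert first.shape == (4,)
        np.testing.assert_allclose(first[:3], means[("dose", 0.5)])
        np.testing.assert_allclose(first[3], means[("supp", "VC")])

    def test_constant_response_gives_constant_starts(self):
        d = es.generate_toothlike(es.ToothlikeConfig(sigma=0.0, reps_per_cell=1, seed=0))
        d = es.Dataset(d.schema, d.covariates, np.full(d.n, 7.0))
        for s in es.initial_starts(d, "m1").starts:
            np.testing.assert_allclose(s, 7.0)

    def test_non_demo_schema_rejected(self):
        d = make_dataset([[0.0], [1.0], [2.0]], [1.0, 2.0, 3.0])
        with pytest.raises(es.ValidationError, match="explicit starts"):
            es.initial_starts(d, "m1")


class TestFitOls:
    def test_constant_response_returns_start(self):
        d = make_dataset([[0], [1], [2], [3]], [5.0] * 4)
        fit = es.fit_ols(d, EX_WED, [2.5])
        assert fit.objective == pytest.approx(0.0, abs=1e-20)
        np.testing.assert_allclose(fit.weights, [2.5])

    def test_objective_beats_coarse_grid(self, toy_factorial):
        """Optimizer SSE must match an exhaustive 2-weight grid to 1e-6."""
        engine = SimilarityEngine(toy_factorial, EX_WED)

        def sse(w):
            e = engine.residuals_loo(np.asarray(w))
            return float(e @ e)

        grid = np.arange(0.0, 10.01, 0.5)
        best_grid = min(sse((a, b)) for a in grid for b in grid)
        fit = es.fit_ols(toy_factorial, EX_WED, [1.0, 1.0])
        assert fit.objective <= best_grid + 1e-6

    def test_descent_from_start(self, toy_factorial):
        engine = SimilarityEngine(toy_factorial, EX_WED)
        start = np.array([4.0, 0.5])
        fit = es.fit_ols(toy_factorial, EX_WED, start)
        e0 = engine.residuals_loo(start)
        assert fit.objective <= float(e0 @ e0) + 1e-12

    def test_reported_objective_is_recomputable(self, toy_factorial):
        fit = es.fit_ols(toy_factorial, EX_WED, [1.0, 1.0])
        e = es.residuals_loo(toy_factorial, fit.weights, EX_WED)
        assert fit.objective == pytest.approx(float(e @ e), rel=1e-8)

    def test_small_delta_warns(self, toy_factorial):
        spec = es.ModelSpec("m1", es.DistanceSpec("wed", delta=0.5), es.SimilaritySpec("ex"))
        with pytest.warns(RuntimeWarning, match="delta"):
            es.fit_ols(toy_factorial, spec, [1.0, 1.0])


class TestFitMl:
    def test_profiled_alpha_is_sample_mean(self, toy_factorial):
        fit = es.fit_ml(toy_factorial, EX_WED, [1.0, 1.0])
        assert fit.alpha == pytest.approx(float(toy_factorial.response.mean()))

    def test_sigma2_matches_profile_formula(self, toy_factorial):
        fit = es.fit_ml(toy_factorial, EX_WED, [1.0, 1.0])
        y = toy_factorial.response
        e = es.residuals_sequential(toy_factorial, fit.weights, EX_WED)
        s2 = ((y[0] - y.mean()) ** 2 + float(e @ e)) / toy_factorial.n
        assert fit.sigma2 == pytest.approx(s2, rel=1e-10)

    def test_one_weight_grid_oracle(self):
        """Profiled log-likelihood at the optimum beats a 1000-point grid."""
        rng = np.random.default_rng(11)
        x = rng.integers(0, 3, size=20).astype(float)
        d = make_dataset(x[:, None], rng.normal(size=20) + x)
        n, y = d.n, d.response
        engine = SimilarityEngine(d, EX_WED)
        first_sq = (y[0] - y.mean()) ** 2

        def nll(w):
            e = engine.residuals_sequential([w])
            s2 = (first_sq + float(e @ e)) / n
            return 0.5 * n * (math.log(2 * math.pi * s2) + 1)

        fit = es.fit_ml(d, EX_WED, [1.0])
        best_grid = min(nll(w) for w in np.linspace(0.0, 10.0, 1000))
        assert fit.objective <= best_grid + 1e-6

    def test_constant_response_hits_sentinel(self):
        d = make_dataset([[0], [1], [2]], [3.0, 3.0, 3.0])
        fit = es.fit_ml(d, EX_WED, [1.0])
        assert fit.sigma2 == 0.0
        assert fit.objective == -math.inf
        assert fit.converged
        assert fit.alpha == 3.0

    def test_local_optimality_of_each_weight(self, toy_factorial):
        """±1% single-weight perturbations never improve the likelihood."""
        fit = es.fit_ml(toy_factorial, EX_WED, [1.0, 1.0])
        y = toy_factorial.response
        n = toy_factorial.n
        engine = SimilarityEngine(toy_factorial, EX_WED)
        first_sq = (y[0] - y.mean()) ** 2

        def nll(w):
            e = engine.residuals_sequential(w)
            s2 = (first_sq + float(e @ e)) / n
            return 0.5 * n * (math.log(2 * math.pi * s2) + 1)

        base = nll(fit.weights)
        for j in range(2):
            for mult in (0.99, 1.01):
                w = fit.weights.copy()
                w[j] *= mult
                assert nll(w) >= base - 1e-6


class TestRecovery:
    def test_ml_estimates_track_generating_weights(self):
        """Sanity check of the generator/likelihood pairing: the seed-median
        ML estimate concentrates around the generating weights w*=(1,3).

        The per-seed estimates are high-variance (the sequential process is
        linear in the noise, so the likelihood carries limited information
        about w at n=200); the stringent per-seed recovery bound lives in the
        acceptance suite.
        """
        w_star = np.array([1.0, 3.0])
        W = []
        for seed in range(20):
            data = es.generate_similarity_process(
                es.SimProcessConfig(
                    true_weights=tuple(w_star), model=EX_WED, sigma=1.0,
                    alpha=10.0, n=200, seed=seed,
                )
            )
            fit = es.fit_ml(data, EX_WED, [1.0, 1.0])
            W.append(fit.weights)
        med = np.median(np.array(W), axis=0)
        np.testing.assert_allclose(med, w_star, rtol=0.5)


class TestMultistart:
    def test_identical_starts_tie_break_to_first(self, toy_factorial):
        split = es.split_train_test(toy_factorial.n, 0.7, 1)
        train, test = toy_factorial.subset(split.train), toy_factorial.subset(split.test)
        starts = es.StartSet(tuple([np.array([1.0, 1.0])] * 5))
        fit = es.fit_multistart(train, test, EX_WED, "ols", starts)
        assert fit.start_index == 1
        assert len(fit.per_start_mse) == 5
        assert len(set(np.round(fit.per_start_mse, 12))) == 1

    def test_selected_mse_is_minimum_recomputed(self, tooth):
        split = es.split_train_test(tooth.n, 0.7, 3)
        train, test = tooth.subset(split.train), tooth.subset(split.test)
        starts = es.initial_starts(train, "m1")
        fit = es.fit_multistart(train, test, EX_WED, "ols", starts)
        # recompute each start's test MSE independently
        mses = []
        for start in starts.starts:
            f = es.fit_ols(train, EX_WED, start)
            pred, _ = es.predict_many(test, train, f.weights, EX_WED)
            mses.append(float(np.mean((pred - test.response) ** 2)))
        assert fit.test_mse == pytest.approx(min(mses), rel=1e-10)
        assert fit.start_index == int(np.argmin(mses)) + 1

    def test_empty_test_rejected(self, toy_factorial):
        starts = es.StartSet(tuple([np.array([1.0, 1.0])] * 5))
        empty = toy_factorial.subset([])
        with pytest.raises(es.ValidationError):
            es.fit_multistart(toy_factorial, empty, EX_WED, "ols", starts)


def test_startset_requires_five():
    with pytest.raises(es.ValidationError):
        es.StartSet((np.ones(2), np.ones(2)))
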