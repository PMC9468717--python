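"""Shapley attribution: exact oracle axioms, sampler agreement, dependence
curves with changepoint fits, subgroup re-ranking and personalized records."""

import numpy as np
import pytest

from onsetforge.explain import (
    attribute,
    attribute_exact,
    dependence_curve,
    exact_shapley,
    fit_changepoint,
    importance_ranking,
    personalized_explanation,
    subgroup_importance,
)
from onsetforge.features import SelectionResult
from onsetforge.models import FittedModel, ModelConfig, fit, predict

from conftest import make_matrix, select_all


class _FunctionEstimator:
    """Wraps an arbitrary vectorized function as an estimator; combined with
    an identity scaler this gives models with known attribution structure."""

    def __init__(self, fn):
        self.fn = fn

    def predict(self, X):
        return self.fn(np.asarray(X))


def model_from_function(fn, names):
    k = len(names)
    return FittedModel(
        config=ModelConfig("LR"),
        feature_names=list(names),
        scaler_mean=np.zeros(k),
        scaler_sd=np.ones(k),
        estimator=_FunctionEstimator(fn),
        best_params={},
        cv_score=0.0,
    )


def _random_matrices(seed, n=40, k=4, n_samples=5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, k))
    y = rng.normal(size=n)
    names = [f"f{i}" for i in range(k)]
    background = make_matrix(X, y, names)
    samples = make_matrix(X[:n_samples], y[:n_samples], names)
    return background, samples


class TestExactOracle:
    def test_single_feature_contribution_is_pred_minus_base(self):
        background, samples = _random_matrices(0, k=1)
        model = model_from_function(lambda X: 3.0 * X[:, 0] + 1.0, ["f0"])
        phi = exact_shapley(model, samples.values[0], background)
        base = 3.0 * background.values[:, 0].mean() + 1.0
        pred = 3.0 * samples.values[0, 0] + 1.0
        assert phi[0] == pytest.approx(pred - base)

    def test_symmetry_axiom(self):
        """f = x1 + x2 with x1 = x2 on a symmetric background gives equal
        contributions."""
        rng = np.random.default_rng(1)
        z = rng.normal(size=30)
        bg = make_matrix(np.column_stack([z, z]), z, ["a", "b"])
        model = model_from_function(lambda X: X[:, 0] + X[:, 1], ["a", "b"])
        phi = exact_shapley(model, np.array([2.0, 2.0]), bg)
        assert phi[0] == pytest.approx(phi[1])

    def test_dummy_axiom(self):
        """A feature the model ignores gets exactly zero contribution."""
        background, samples = _random_matrices(2, k=3)
        model = model_from_function(lambda X: 5.0 * X[:, 0] - 2.0 * X[:, 2],
                                    ["f0", "f1", "f2"])
        attr = attribute_exact(model, samples, background)
        assert np.allclose(attr.contributions[:, 1], 0.0)

    def test_additivity_on_random_forest(self):
        rng = np.random.default_rng(3)
        n, k = 120, 6
        X = rng.normal(size=(n, k))
        y = X[:, 0] * X[:, 1] + X[:, 2] + rng.normal(0, 0.2, n)
        fm = make_matrix(X, y)
        model = fit(ModelConfig("RF", grid={"n_estimators": [60]}, cv_folds=3),
                    fm, select_all(fm))
        background = make_matrix(X[:40], y[:40], fm.feature_names)
        samples = make_matrix(X[:20], y[:20], fm.feature_names)
        attr = attribute_exact(model, samples, background)
        recon = attr.base_value + attr.contributions.sum(axis=1)
        assert np.max(np.abs(recon - attr.predictions)) < 1e-8

    def test_too_many_features_rejected(self):
        background, samples = _random_matrices(4, k=13 if False else 4)
        model = model_from_function(lambda X: X[:, 0], background.feature_names)
        big = make_matrix(np.random.default_rng(0).normal(size=(5, 13)),
                          np.zeros(5), [f"g{i}" for i in range(13)])
        big_model = model_from_function(lambda X: X[:, 0], big.feature_names)
        with pytest.raises(ValueError, match="12 features"):
            exact_shapley(big_model, big.values[0], big)


class TestSampler:
    def test_linear_model_closed_form(self):
        """For f = sum w_i x_i, the contribution of feature i is exactly
        w_i (x_i - mean background x_i)."""
        w = np.array([2.0, -1.5, 0.5])
        background, samples = _random_matrices(5, k=3)
        model = model_from_function(lambda X: X @ w, background.feature_names)

        exact = attribute_exact(model, samples, background)
        closed = w * (samples.values - background.values.mean(axis=0))
        assert np.allclose(exact.contributions, closed, atol=1e-10)

        sampled = attribute(model, samples, background, n_permutations=200,
                            seed=0)
        assert np.allclose(sampled.contributions, closed, atol=1e-8)

    def test_sampler_tracks_oracle_on_nonlinear_model(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 5))
        y = X[:, 0] * X[:, 1] - X[:, 2] ** 2 + rng.normal(0, 0.1, 60)
        fm = make_matrix(X, y)
        model = fit(ModelConfig("SVM", grid={"C": [1.0], "epsilon": [0.1]},
                                cv_folds=3), fm, select_all(fm))
        background = make_matrix(X[:30], y[:30], fm.feature_names)
        samples = make_matrix(X[:3], y[:3], fm.feature_names)
        exact = attribute_exact(model, samples, background)
        sampled = attribute(model, samples, background, n_permutations=600,
                            seed=1)
        assert np.max(np.abs(sampled.contributions - exact.contributions)) < 0.1

    def test_sampler_tolerance_tightens_with_budget(self):
        background, samples = _random_matrices(7, k=4, n_samples=3)
        model = model_from_function(
            lambda X: X[:, 0] * X[:, 1] + 2.0 * X[:, 2] - X[:, 3],
            background.feature_names,
        )
        exact = attribute_exact(model, samples, background)
        devs = []
        for n_perm in (8, 64, 512):
            sampled = attribute(model, samples, background,
                                n_permutations=n_perm, seed=2)
            devs.append(np.max(np.abs(sampled.contributions
                                      - exact.contributions)))
        assert devs[2] < devs[0]
        assert devs[2] < 0.1

    def test_sampler_unbiased_across_runs(self):
        """The mean over independent sampler runs approaches the oracle
        within two standard errors per cell."""
        background, samples = _random_matrices(8, k=4, n_samples=2)
        model = model_from_function(
            lambda X: np.tanh(X[:, 0]) + X[:, 1] * X[:, 2] - 0.5 * X[:, 3],
            background.feature_names,
        )
        exact = attribute_exact(model, samples, background)
        runs = np.stack([
            attribute(model, samples, background, n_permutations=32,
                      seed=100 + i).contributions
            for i in range(50)
        ])
        mean = runs.mean(axis=0)
        se = runs.std(axis=0, ddof=1) / np.sqrt(runs.shape[0])
        assert np.all(np.abs(mean - exact.contributions) <= 2.5 * se + 1e-12)

    def test_deterministic_given_seed(self):
        background, samples = _random_matrices(9, k=3)
        model = model_from_function(lambda X: X[:, 0] ** 2,
                                    background.feature_names)
        a1 = attribute(model, samples, background, n_permutations=16, seed=5)
        a2 = attribute(model, samples, background, n_permutations=16, seed=5)
        assert np.array_equal(a1.contributions, a2.contributions)

    def test_invalid_inputs_rejected(self):
        background, samples = _random_matrices(10, k=3)
        model = model_from_function(lambda X: X[:, 0],
                                    background.feature_names)
        with pytest.raises(ValueError, match="n_permutations"):
            attribute(model, samples, background, n_permutations=0)
        wrong = make_matrix(samples.values[:, :2], samples.target[:5],
                            ["f0", "f1"])
        with pytest.raises(ValueError, match="missing model features"):
            attribute(model, wrong, background)


class TestImportanceAndDependence:
    def _attr(self, contributions, names, raw=None):
        contributions = np.asarray(contributions, dtype=float)
        n, k = contributions.shape
        from onsetforge.explain import AttributionResult

        return AttributionResult(
            base_value=35.0, contributions=contributions,
            feature_names=list(names), background_size=10,
            estimator="exact", n_permutations=0, seed=0,
            sample_values=np.zeros((n, k)) if raw is None else np.asarray(raw),
            predictions=35.0 + contributions.sum(axis=1),
        )

    def test_single_nonzero_feature_ranks_first(self):
        attr = self._attr([[0.0, 2.0, 0.0]] * 4, ["a", "b", "c"])
        ranking = importance_ranking(attr)
        assert ranking[0] == ("b", 2.0)
        assert [name for name, _ in ranking] == ["b", "a", "c"]

    def test_ranking_invariant_to_sample_order(self):
        rng = np.random.default_rng(11)
        c = rng.normal(size=(20, 5))
        names = [f"f{i}" for i in range(5)]
        r1 = importance_ranking(self._attr(c, names))
        r2 = importance_ranking(self._attr(c[::-1], names))
        assert [f for f, _ in r1] == [f for f, _ in r2]
        assert [v for _, v in r1] == pytest.approx([v for _, v in r2],
                                                   abs=1e-12)

    def test_dependence_pairs_sorted_without_aggregation(self):
        attr = self._attr([[1.0], [3.0], [2.0]], ["x"])
        pairs = dependence_curve(attr, "x", np.array([70.0, 61.0, 65.0]))
        assert np.array_equal(pairs[:, 0], [61.0, 65.0, 70.0])
        assert np.array_equal(pairs[:, 1], [3.0, 2.0, 1.0])

    def test_v_shape_passes_through(self):
        x = np.arange(61.0, 81.0)
        phi = np.abs(x - 68.0)
        attr = self._attr(phi[:, None], ["cag"])
        pairs = dependence_curve(attr, "cag", x)
        assert np.array_equal(pairs[:, 1], phi)

    def test_dependence_round_trips_through_tsv(self, tmp_path):
        from onsetforge.io import read_dependence_tsv, write_dependence_tsv

        rng = np.random.default_rng(12)
        pairs = np.column_stack([np.sort(rng.uniform(61, 80, 30)),
                                 rng.normal(size=30)])
        path = tmp_path / "dep.tsv"
        write_dependence_tsv(pairs, path)
        back = read_dependence_tsv(path)
        assert np.array_equal(back, pairs)


class TestChangepoint:
    def test_hand_made_v_with_knot_at_five(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        y = np.where(x <= 5, -(x - 5.0), 2.0 * (x - 5.0))
        fit_ = fit_changepoint(np.column_stack([x, y]))
        assert fit_.breakpoint == 5.0
        assert fit_.sse == pytest.approx(0.0, abs=1e-18)
        assert fit_.left_slope == pytest.approx(-1.0)
        assert fit_.right_slope == pytest.approx(2.0)

    def test_matches_brute_force_candidate_loop(self):
        rng = np.random.default_rng(13)
        x = rng.integers(61, 81, 80).astype(float)
        y = np.where(x < 70, -0.4 * (x - 70), 0.9 * (x - 70))
        y += rng.normal(0, 0.3, 80)
        pairs = np.column_stack([x, y])
        fit_ = fit_changepoint(pairs)

        distinct = np.unique(x)
        best = (np.inf, None)
        for c in distinct[2:-2]:
            sse = 0.0
            for mask in (x <= c, x > c):
                if np.ptp(x[mask]) == 0:
                    sse += np.sum((y[mask] - y[mask].mean()) ** 2)
                else:
                    coef = np.polyfit(x[mask], y[mask], 1)
                    sse += np.sum((y[mask] - np.polyval(coef, x[mask])) ** 2)
            if sse <= best[0] + 1e-12:  # ties -> larger breakpoint
                best = (sse, c)
        assert fit_.breakpoint == best[1]
        assert fit_.sse == pytest.approx(best[0], abs=1e-9)

    def test_linear_data_shows_no_changepoint(self):
        x = np.arange(61.0, 81.0)
        y = 0.7 * x - 3.0
        fit_ = fit_changepoint(np.column_stack([x, y]))
        assert fit_.sse <= fit_.sse_linear + 1e-12
        assert abs(fit_.sse - fit_.sse_linear) < 1e-9

    def test_two_segment_never_worse_than_one(self):
        rng = np.random.default_rng(14)
        for seed in range(5):
            x = rng.uniform(61, 80, 50)
            y = rng.normal(size=50)
            fit_ = fit_changepoint(np.column_stack([x, y]))
            assert fit_.sse <= fit_.sse_linear + 1e-12

    def test_too_few_distinct_values_rejected(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.raises(ValueError, match="distinct"):
            fit_changepoint(np.column_stack([x, x]))

    def test_planted_knot_recovery_quick(self):
        from onsetforge.studies import planted_dependence_pairs

        hits = 0
        for seed in range(20):
            fit_ = fit_changepoint(planted_dependence_pairs(seed))
            hits += abs(fit_.breakpoint - 68.0) <= 1.0
        assert hits >= 19


class TestSubgroupsAndPersonalized:
    def test_one_sided_split_rejected(self):
        attr = TestImportanceAndDependence()._attr([[1.0]] * 5, ["x"])
        raw = np.full(5, 70.0)
        with pytest.raises(ValueError, match="below threshold is empty"):
            subgroup_importance(attr, raw, 60.0)
        with pytest.raises(ValueError, match="above threshold is empty"):
            subgroup_importance(attr, raw, 75.0)

    def test_constant_contributions_give_identical_rankings(self):
        attr = TestImportanceAndDependence()._attr(
            [[1.0, -2.0]] * 6, ["a", "b"]
        )
        raw = np.array([61, 62, 63, 70, 71, 72], dtype=float)
        le, gt = subgroup_importance(attr, raw, 68.0)
        assert le == gt

    def test_threshold_gated_interaction_ranks_higher_above_threshold(self):
        """A planted interaction active only above 68 repeats outranks its
        below-threshold importance in nearly all replicate draws."""
        names = ["cag", "inter", "other"]
        wins = 0
        n_rep = 25
        for seed in range(n_rep):
            rng = np.random.default_rng(300 + seed)
            n = 80
            cag = rng.integers(61, 81, n).astype(float)
            inter = rng.normal(size=n)
            other = rng.normal(size=n)
            X = np.column_stack([cag, inter, other])
            fm = make_matrix(X, np.zeros(n), names)

            model = model_from_function(
                lambda Z: -2.0 * Z[:, 0] + np.where(Z[:, 0] > 68,
                                                    3.0 * Z[:, 1], 0.0)
                + 1.2 * Z[:, 2],
                names,
            )
            attr = attribute_exact(model, fm, fm)
            le, gt = subgroup_importance(attr, cag, 68.0)
            rank_le = [f for f, _ in le].index("inter")
            rank_gt = [f for f, _ in gt].index("inter")
            wins += rank_gt < rank_le
        assert wins / n_rep >= 0.8

    def test_personalized_record_is_additive(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(50, 4))
        y = X @ [1.0, -2.0, 0.5, 3.0] + rng.normal(0, 0.1, 50)
        fm = make_matrix(X, y)
        model = fit(ModelConfig("LR", cv_folds=3), fm, select_all(fm))
        background = make_matrix(X[:30], y[:30], fm.feature_names)
        attr = attribute_exact(model, fm, background)
        idx = int(np.argmax(attr.predictions))
        record = personalized_explanation(attr, idx)
        assert record["final_prediction"] == pytest.approx(
            record["model_prediction"], abs=1e-6
        )
        assert record["final_prediction"] == pytest.approx(
            predict(model, fm)[idx], abs=1e-6
        )
        contribs = [f["contribution"] for f in record["features"]]
        assert sorted(np.abs(contribs), reverse=True) == pytest.approx(
            list(np.abs(contribs))
        )

    def test_background_mean_sample_has_zero_contributions(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(40, 3))
        names = ["a", "b", "c"]
        model = model_from_function(lambda Z: Z @ np.array([2.0, -1.0, 4.0]),
                                    names)
        background = make_matrix(X, np.zeros(40), names)
        mean_sample = make_matrix(X.mean(axis=0, keepdims=True), [0.0], names)
        attr = attribute_exact(model, mean_sample, background)
        assert np.allclose(attr.contributions, 0.0, atol=1e-10)

    def test_index_out_of_range(self):
        attr = TestImportanceAndDependence()._attr([[1.0]], ["x"])
        with pytest.raises(IndexError):
            personalized_explanation(attr, 3)
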