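"""Logistic fitting, backward-AIC selection, AUC, effect sizes, dedup."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cantare.models import (
    NeighborhoodModel,
    _glm_fit,
    auc,
    backward_aic,
    dedupe_models,
    effect_sizes,
    fit_logistic,
)


def all_subsets_aic_oracle(data, y, predictors):
    """Exhaustive AIC over every predictor subset (intercept-only included)."""
    best_aic, best_set = np.inf, None
    for k in range(len(predictors) + 1):
        for subset in itertools.combinations(sorted(predictors), k):
            fit = _glm_fit(data, y, list(subset))
            if fit.aic < best_aic:
                best_aic, best_set = fit.aic, frozenset(subset)
    return best_set, best_aic


class TestFitLogistic:
    def test_two_by_two_closed_form_log_odds_ratio(self):
        # exposed: 10 case / 5 control; unexposed: 5 case / 10 control
        x = np.array([1] * 15 + [0] * 15, dtype=float)
        y = np.array([1] * 10 + [0] * 5 + [1] * 5 + [0] * 10, dtype=float)
        frame = pd.DataFrame({"exposed": x})
        fit = fit_logistic(frame, y)
        assert fit.params["exposed"] == pytest.approx(np.log(4.0), abs=1e-6)
        assert fit.converged

    def test_null_predictor_flat_model(self, rng):
        n = 200
        frame = pd.DataFrame({"noise": rng.normal(size=n)})
        y = np.array([0, 1] * (n // 2), dtype=float)
        fit = fit_logistic(frame, y)
        assert abs(fit.params["noise"]) < 0.35
        assert abs(auc(fit.probabilities, y) - 0.5) < 0.1

    def test_perfect_separation_flagged(self):
        x = np.concatenate([np.zeros(10), np.ones(10)])
        y = x.copy()
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        assert not fit.converged

    def test_constant_predictor_dropped_with_warning(self, rng):
        frame = pd.DataFrame(
            {"const": np.ones(40), "real": rng.normal(size=40)}
        )
        y = (frame["real"] + rng.normal(size=40) > 0).astype(float).to_numpy()
        fit = fit_logistic(frame, y)
        assert fit.predictors == ["real"]
        assert fit.dropped_constant == ["const"]

    def test_single_class_outcome_errors(self):
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(pd.DataFrame({"x": [1.0, 2.0]}), np.ones(2))

    def test_aic_definition(self, rng):
        n = 80
        frame = pd.DataFrame({"x": rng.normal(size=n)})
        y = (frame["x"] + rng.normal(size=n) > 0).astype(float).to_numpy()
        fit = fit_logistic(frame, y)
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.llf, abs=1e-9)


class TestBackwardAIC:
    @pytest.fixture
    def informative_plus_noise(self):
        rng = np.random.default_rng(404)
        n = 300
        x = rng.normal(size=n)
        noise = rng.normal(size=(n, 2))
        logit = 1.5 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        frame = pd.DataFrame({"signal": x, "noise_a": noise[:, 0],
                              "noise_b": noise[:, 1]})
        return frame, y

    def test_noise_removed_matches_all_subsets_oracle(self, informative_plus_noise):
        frame, y = informative_plus_noise
        reduced = backward_aic(frame, y, list(frame.columns))
        assert reduced.predictors == ["signal"]
        best_set, best_aic = all_subsets_aic_oracle(frame, y, list(frame.columns))
        assert frozenset(reduced.predictors) == best_set
        assert reduced.aic == pytest.approx(best_aic, abs=1e-9)

    def test_all_informative_reduction_is_identity(self):
        rng = np.random.default_rng(7)
        n = 400
        X = rng.normal(size=(n, 3))
        logit = X @ np.array([1.2, -1.0, 0.9])
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        frame = pd.DataFrame(X, columns=["a", "b", "c"])
        reduced = backward_aic(frame, y, ["a", "b", "c"])
        assert sorted(reduced.predictors) == ["a", "b", "c"]
        best_set, _ = all_subsets_aic_oracle(frame, y, ["a", "b", "c"])
        assert best_set == frozenset("abc")

    def test_pure_noise_collapses_to_intercept_only(self):
        rng = np.random.default_rng(12)
        n = 250
        frame = pd.DataFrame(rng.normal(size=(n, 3)), columns=["u", "v", "w"])
        y = np.array([0, 1] * (n // 2) + [1] * (n % 2), dtype=float)
        reduced = backward_aic(frame, y, ["u", "v", "w"])
        assert reduced.predictors == []
        best_set, _ = all_subsets_aic_oracle(frame, y, ["u", "v", "w"])
        assert best_set == frozenset()

    def test_reduced_aic_never_above_full(self, small_cohort):
        dataset, _, _ = small_cohort
        frame = dataset.predictor_frame(
            list(dataset.omes["met"].columns[:4]), ["age", "calprotectin"]
        )
        y = dataset.group.astype(float)
        full = fit_logistic(frame, y)
        reduced = backward_aic(frame, y, full.predictors)
        assert reduced.aic <= full.aic
        assert set(reduced.predictors) <= set(full.predictors)

    def test_each_greedy_step_is_reachable_in_oracle(self):
        # greedy path: every accepted removal strictly decreases AIC
        rng = np.random.default_rng(5)
        n = 200
        frame = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        logit = 1.0 * frame["a"].to_numpy()
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        full = _glm_fit(frame, y, list("abcd"))
        reduced = backward_aic(frame, y, list("abcd"))
        assert reduced.aic < full.aic or reduced.predictors == list("abcd")

    def test_force_keep_retains_predictor(self):
        rng = np.random.default_rng(9)
        n = 150
        frame = pd.DataFrame(rng.normal(size=(n, 2)), columns=["keepme", "x"])
        y = (rng.random(n) < 1 / (1 + np.exp(-frame["x"]))).astype(float)
        reduced = backward_aic(frame, y, ["keepme", "x"], force_keep=("keepme",))
        assert "keepme" in reduced.predictors


class TestAUC:
    def test_printed_four_score_example(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1])
        assert auc(scores, labels) == pytest.approx(0.75)

    def test_all_tied_scores_give_half(self):
        assert auc(np.full(10, 0.3), np.array([0, 1] * 5)) == pytest.approx(0.5)

    def test_perfect_ordering_gives_one(self):
        scores = np.linspace(0, 1, 8)
        labels = (scores > 0.5).astype(int)
        assert auc(scores, labels) == pytest.approx(1.0)

    def test_one_class_absent_errors(self):
        with pytest.raises(ValueError):
            auc(np.array([0.2, 0.8]), np.array([1, 1]))

    def test_matches_sklearn_on_random_scores(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(10):
            y = rng.integers(0, 2, 50)
            if y.min() == y.max():
                continue
            s = np.round(rng.random(50), 1)  # coarse scores force ties
            assert auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(
        # quarter-unit grid keeps the logistic transform strictly monotone
        # in floating point (no new ties from underflow)
        st.lists(st.integers(-20, 20).map(lambda i: i / 4), min_size=4,
                 max_size=30),
        st.floats(0.1, 3.0),
    )
    def test_invariant_under_strictly_increasing_transform(self, scores, rate):
        scores = np.asarray(scores)
        labels = (np.arange(len(scores)) % 2).astype(int)
        direct = auc(scores, labels)
        transformed = auc(1 / (1 + np.exp(-rate * scores)), labels)
        assert direct == pytest.approx(transformed, abs=1e-12)


class TestEffectSizes:
    def test_iqr_odds_ratio_for_continuous_predictor(self):
        # beta chosen so an IQR move of 74 ppm multiplies the odds by 5.69
        x = np.concatenate([np.linspace(200, 236, 38), np.linspace(236.5, 310, 38),
                            np.linspace(311, 400, 37)])
        rng = np.random.default_rng(2)
        x = rng.permutation(x)
        frame = pd.DataFrame({"enzyme": x})
        q1, q3 = np.quantile(x, [0.25, 0.75])
        beta = np.log(5.69) / (q3 - q1)
        fit = _glm_fit(frame, (x > np.median(x)).astype(float), ["enzyme"])
        fit.params["enzyme"] = beta  # evaluate the OR formula at a known beta
        (es,) = effect_sizes(fit, frame)
        assert es.kind == "IQR"
        assert es.odds_ratio == pytest.approx(5.69, rel=1e-10)

    def test_zero_heavy_predictor_uses_range(self):
        x = np.concatenate([np.zeros(90), np.linspace(0.01, 0.07, 10)])
        frame = pd.DataFrame({"microbe": x})
        beta = np.log(0.5) / 0.07
        fit = _glm_fit(frame, (np.arange(100) % 2).astype(float), ["microbe"])
        fit.params["microbe"] = beta
        (es,) = effect_sizes(fit, frame)
        assert es.kind == "range"
        assert (es.q1, es.q3) == (0.0, pytest.approx(0.07))
        assert es.odds_ratio == pytest.approx(0.5, rel=1e-10)

    def test_zero_beta_gives_unit_odds_ratio(self, rng):
        frame = pd.DataFrame({"x": rng.normal(size=30)})
        fit = _glm_fit(frame, (np.arange(30) % 2).astype(float), ["x"])
        fit.params["x"] = 0.0
        (es,) = effect_sizes(fit, frame)
        assert es.odds_ratio == 1.0

    def test_sorted_ascending_by_odds_ratio(self, rng):
        frame = pd.DataFrame(rng.normal(size=(50, 3)), columns=["a", "b", "c"])
        y = (np.arange(50) % 2).astype(float)
        fit = _glm_fit(frame, y, ["a", "b", "c"])
        fit.params.update({"a": 1.0, "b": -1.0, "c": 0.1})
        out = effect_sizes(fit, frame)
        ors = [e.odds_ratio for e in out]
        assert ors == sorted(ors)

    def test_type7_quantiles_used(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        frame = pd.DataFrame({"x": x})
        fit = _glm_fit(frame, np.array([0.0, 1, 0, 1]), ["x"])
        fit.params["x"] = 1.0
        (es,) = effect_sizes(fit, frame)
        # linear-interpolation quartiles of [1,2,3,4] are 1.75 and 3.25
        assert (es.q1, es.q3) == (1.75, 3.25)
        assert es.odds_ratio == pytest.approx(np.exp(1.5))


def _model(seed, reduced, converged=True):
    return NeighborhoodModel(
        seed=seed, full_predictors=reduced + ["age"],
        reduced_predictors=list(reduced), coefficients={},
        aic_full=10.0, aic_reduced=9.0, converged=converged, auc=0.9,
    )


class TestDedupeModels:
    def test_identical_sets_collapse_listing_all_seeds(self):
        models = [
            _model("mb_a", ["met_x", "e_y"]),
            _model("mb_b", ["e_y", "met_x"]),  # same set, different order
        ]
        out = dedupe_models(models)
        assert len(out) == 1
        assert out[0].seeds == ["mb_a", "mb_b"]

    def test_nested_but_unequal_sets_stay_distinct(self):
        models = [
            _model("mb_s", ["met_x"]),
            _model("mb_a", ["met_x", "e_y"]),  # superset of the S model
        ]
        assert len(dedupe_models(models)) == 2

    def test_empty_input(self):
        assert dedupe_models([]) == []

    def test_non_converged_records_pass_through(self):
        models = [_model("mb_a", ["met_x"]), _model("mb_b", [], converged=False)]
        out = dedupe_models(models)
        assert len(out) == 2
        assert sum(m.converged for m in out) == 1


class TestRunNeighborhoodModels:
    def test_bookkeeping_and_auc_bounds(self, small_cohort):
        import cantare

        dataset, _, _ = small_cohort
        fits = cantare.run_all_pairs(dataset)
        top = cantare.build_top_table(fits)
        net = cantare.build_network(top)
        hoods = cantare.enumerate_seed_neighborhoods(net)
        models = cantare.run_neighborhood_models(dataset, hoods)
        assert len(models) == len(hoods)
        for m in models:
            if m.converged:
                assert 0.45 <= m.auc <= 1.0
                assert set(m.reduced_predictors) <= set(m.full_predictors)
                assert m.aic_reduced <= m.aic_full + 1e-9
                assert np.all((m.probabilities > 0) & (m.probabilities < 1))
            else:
                assert m.reduced_predictors == []
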