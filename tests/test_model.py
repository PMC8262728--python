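"""Feature matrix, scaling, J-statistic threshold learning, scoring."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from kgprio.enrichment import find_predictors
from kgprio.exceptions import KgprioError, MetricUndefinedError, TrainingError
from kgprio.model import (
    GenePrioritizer,
    TrainedModel,
    WeightedProfileClassifier,
    best_threshold,
    build_feature_matrix,
    fit_model,
    scale_features,
    score_and_predict,
    simplex_grid,
    youden_j,
)

from oracles import best_threshold_by_scan


class TestBuildFeatureMatrix:
    def test_counts_predictor_adjacency(self, tiny_kg, tiny_seeds):
        # lax q: this test exercises the counting, not selection stringency
        pset = find_predictors(tiny_kg, tiny_seeds, q_threshold=0.25,
                               exclude_features={"D1"})
        m = build_feature_matrix(tiny_kg, pset)
        # t1 (GO) is the only survivor: adjacent to G1, G2
        assert list(m.columns) == ["GO"]
        assert m.loc["G1", "GO"] == 1
        assert m.loc["G3", "GO"] == 0

    def test_rows_cover_full_universe(self, planted_truth):
        pset = find_predictors(planted_truth.kg, planted_truth.seeds)
        m = build_feature_matrix(planted_truth.kg, pset)
        assert set(m.index) == set(planted_truth.kg.genes)

    def test_non_predictor_neighbors_do_not_count(self, tiny_kg, tiny_seeds):
        pset = find_predictors(tiny_kg, tiny_seeds, q_threshold=0.25,
                               exclude_features={"D1"})
        m = build_feature_matrix(tiny_kg, pset)
        # t2 touches every gene but is not a predictor; G4 touches only t2
        assert m.loc["G4", "GO"] == 0

    def test_empty_predictor_set_raises(self, tiny_kg):
        empty = find_predictors(tiny_kg, frozenset({"G5", "G6"}))
        del_genes = [t.feature for t in empty.tests if t.significant]
        assert not del_genes
        with pytest.raises(TrainingError):
            build_feature_matrix(tiny_kg, empty)


class TestScaleFeatures:
    def test_minmax_to_unit_interval(self):
        m = pd.DataFrame({"GO": [0, 2, 4]}, index=["a", "b", "c"])
        scaled, params = scale_features(m)
        assert list(scaled["GO"]) == [0.0, 0.5, 1.0]

    def test_constant_column_maps_to_zero(self):
        m = pd.DataFrame({"GO": [3, 3, 3]}, index=list("abc"))
        scaled, _ = scale_features(m)
        assert list(scaled["GO"]) == [0.0, 0.0, 0.0]

    def test_stored_params_reproduce_bounds(self):
        m = pd.DataFrame({"GO": [0, 2, 4]}, index=list("abc"))
        _, params = scale_features(m)
        new = pd.DataFrame({"GO": [4]}, index=["z"])
        assert params.transform(new).iloc[0, 0] == 1.0


class TestYoudenJ:
    def test_perfect_prediction(self):
        assert youden_j([1, 1, 0, 0], [1, 1, 0, 0]) == 1.0

    def test_predict_all_positive_is_zero(self):
        assert youden_j([1, 1, 0, 0], [1, 1, 1, 1]) == 0.0

    def test_half_sensitivity_full_specificity(self):
        assert youden_j([1, 1, 0, 0], [1, 0, 0, 0]) == pytest.approx(0.5)

    def test_degenerate_labels_raise(self):
        with pytest.raises(MetricUndefinedError):
            youden_j([1, 1], [1, 0])


class TestBestThreshold:
    def test_perfect_separation_midpoint(self):
        scores = [0.9, 0.8, 0.7, 0.1]
        labels = [1, 1, 0, 0]
        thr, j = best_threshold(scores, labels)
        assert j == 1.0
        assert thr == pytest.approx(0.75)

    def test_tie_break_to_lowest_threshold(self):
        scores = [0.9, 0.3, 0.5, 0.1]
        labels = [1, 1, 0, 0]
        thr, j = best_threshold(scores, labels)
        assert j == pytest.approx(0.5)
        assert thr == pytest.approx(0.2)  # lower of the two J=0.5 candidates

    def test_identical_scores_give_zero_j(self):
        thr, j = best_threshold([0.4, 0.4, 0.4], [1, 0, 0])
        assert j == 0.0
        assert thr == pytest.approx(0.4)

    def test_matches_exhaustive_scan_on_random_inputs(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(4, 25))
            scores = rng.choice(np.round(rng.random(6), 2), size=n)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            thr, j = best_threshold(scores, labels)
            assert j == pytest.approx(best_threshold_by_scan(scores, labels), abs=1e-12)


class TestSimplexGrid:
    def test_covers_simplex_and_sums_to_one(self):
        grid = list(simplex_grid(3, 0.1))
        assert len(grid) == 66  # C(12,2) compositions of 10 into 3 parts
        assert all(abs(sum(w) - 1) < 1e-12 for w in grid)
        assert grid[0] == (1.0, 0.0, 0.0)  # leading column takes weight first


class TestFitModel:
    def test_single_column_weight_one(self):
        m = pd.DataFrame({"GO": [3, 2, 1, 0]}, index=list("abcd"))
        model = fit_model(m, frozenset({"a", "b"}))
        assert list(model.weights) == [1.0]
        assert model.training_j == 1.0

    def test_perfect_column_dominates_noise(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(20)]
        seeds = frozenset(genes[:5])
        matrix = pd.DataFrame(
            {
                "A": [3 if g in seeds else 0 for g in genes],
                "B": rng.integers(0, 4, 20),
            },
            index=genes,
        )
        model = fit_model(matrix, seeds)
        assert model.training_j == 1.0
        assert model.weights["A"] >= model.weights["B"]

    def test_deterministic_given_inputs(self, planted_truth):
        pset = find_predictors(planted_truth.kg, planted_truth.seeds)
        m = build_feature_matrix(planted_truth.kg, pset)
        m1 = fit_model(m, planted_truth.seeds)
        m2 = fit_model(m, planted_truth.seeds)
        assert m1.weights.equals(m2.weights)
        assert m1.threshold == m2.threshold
        assert m1.training_j == m2.training_j

    def test_self_consistency_of_returned_j(self, planted_truth):
        pset = find_predictors(planted_truth.kg, planted_truth.seeds)
        matrix = build_feature_matrix(planted_truth.kg, pset)
        model = fit_model(matrix, planted_truth.seeds)
        scores = model.scores(matrix)
        y = [g in planted_truth.seeds.genes for g in matrix.index]
        yhat = scores >= model.threshold
        assert youden_j(y, yhat) == pytest.approx(model.training_j, abs=1e-12)

    def test_too_few_seeds_raise(self):
        m = pd.DataFrame({"GO": [1, 0]}, index=["a", "b"])
        with pytest.raises(TrainingError):
            fit_model(m, frozenset({"a"}))

    def test_coordinate_ascent_used_beyond_grid_limit(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(30)]
        seeds = frozenset(genes[:6])
        data = {f"C{j}": rng.integers(0, 3, 30) for j in range(5)}
        data["C0"] = [5 if g in seeds else 0 for g in genes]
        matrix = pd.DataFrame(data, index=genes)
        model = fit_model(matrix, seeds)
        assert model.training_j == 1.0


class TestScoreAndPredict:
    @pytest.fixture
    def two_class_model(self):
        matrix = pd.DataFrame(
            {"GO": [2, 2, 1, 0], "PPI": [1, 0, 1, 0]}, index=list("abcd")
        )
        return fit_model(matrix, frozenset({"a", "b"})), matrix

    def test_weighted_sum_arithmetic(self):
        model = TrainedModel(
            weights=pd.Series({"GO": 0.5, "PPI": 0.5}),
            threshold=0.5,
            training_j=1.0,
            scaling=__import__("kgprio.model", fromlist=["ScalingParams"]).ScalingParams(
                pd.Series({"GO": 0.0, "PPI": 0.0}), pd.Series({"GO": 1.0, "PPI": 1.0})
            ),
        )
        matrix = pd.DataFrame({"GO": [1.0], "PPI": [0.2]}, index=["g"])
        assert model.scores(matrix).iloc[0] == pytest.approx(0.6)

    def test_zero_row_negative(self, two_class_model):
        model, matrix = two_class_model
        table = score_and_predict(model, matrix, frozenset({"a", "b"}))
        row = table[table["gene"] == "d"].iloc[0]
        assert row["score"] == 0.0
        assert row["label"] == "negative"

    def test_seed_below_threshold_stays_known(self, two_class_model):
        model, matrix = two_class_model
        table = score_and_predict(model, matrix, frozenset({"a", "b", "d"}))
        assert table.loc[table["gene"] == "d", "label"].iloc[0] == "known"

    def test_ranks_are_permutation_sorted_by_score(self, two_class_model):
        model, matrix = two_class_model
        table = score_and_predict(model, matrix, frozenset({"a", "b"}))
        assert sorted(table["rank"]) == [1, 2, 3, 4]
        assert list(table["score"]) == sorted(table["score"], reverse=True)

    def test_contributions_sum_to_one_for_scored_genes(self, two_class_model):
        model, matrix = two_class_model
        table = score_and_predict(model, matrix, frozenset({"a", "b"}))
        contrib = table.filter(like="contrib_").sum(axis=1)
        for total, score in zip(contrib, table["score"]):
            assert total == pytest.approx(1.0 if score > 0 else 0.0)

    def test_column_mismatch_raises(self, two_class_model):
        model, matrix = two_class_model
        bad = matrix.rename(columns={"PPI": "XX"})
        with pytest.raises(KgprioError):
            model.scores(bad)


class TestModelInvariants:
    def test_zero_weight_column_never_changes_scores(self):
        matrix = pd.DataFrame({"A": [2, 1, 0, 0]}, index=list("abcd"))
        seeds = frozenset({"a", "b"})
        base = fit_model(matrix, seeds)
        wide = matrix.assign(B=0)
        model = fit_model(wide, seeds)
        assert model.scores(wide).tolist() == base.scores(matrix).tolist()

    def test_scores_invariant_to_row_permutation(self, planted_truth):
        pset = find_predictors(planted_truth.kg, planted_truth.seeds)
        matrix = build_feature_matrix(planted_truth.kg, pset)
        model = fit_model(matrix, planted_truth.seeds)
        shuffled = matrix.sample(frac=1.0, random_state=0)
        s1 = model.scores(matrix).sort_index()
        s2 = model.scores(shuffled).sort_index()
        assert np.allclose(s1, s2)

    def test_doubling_raw_counts_leaves_scores_unchanged(self):
        matrix = pd.DataFrame(
            {"A": [4, 2, 1, 0], "B": [0, 1, 2, 3]}, index=list("abcd")
        )
        seeds = frozenset({"a", "b"})
        m1 = fit_model(matrix, seeds)
        m2 = fit_model(matrix * 2, seeds)
        assert np.allclose(m1.scores(matrix), m2.scores(matrix * 2))

    def test_scores_stay_in_unit_interval(self, planted_truth):
        pset = find_predictors(planted_truth.kg, planted_truth.seeds)
        matrix = build_feature_matrix(planted_truth.kg, pset)
        model = fit_model(matrix, planted_truth.seeds)
        s = model.scores(matrix)
        assert (s >= 0).all() and (s <= 1).all()


class TestModelPersistence:
    def test_text_round_trip(self, planted_truth):
        pipe = GenePrioritizer().fit(planted_truth.kg, planted_truth.seeds)
        text = pipe.model_.to_text()
        back = TrainedModel.from_text(text)
        assert back.weights.equals(pipe.model_.weights)
        assert back.threshold == pipe.model_.threshold
        assert back.training_j == pipe.model_.training_j
        assert back.predictor_set.predictors_by_class == {
            c: frozenset(v)
            for c, v in pipe.model_.predictor_set.predictors_by_class.items()
        }


class TestSklearnCompatibility:
    def test_get_set_params_and_clone(self):
        est = WeightedProfileClassifier(step=0.2)
        assert est.get_params()["step"] == 0.2
        est.set_params(step=0.1)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_estimator_fit_predict_interface(self):
        X = pd.DataFrame({"A": [3, 2, 0, 0], "B": [0, 0, 1, 2]}, index=list("abcd"))
        y = [1, 1, 0, 0]
        est = WeightedProfileClassifier().fit(X, y)
        assert est.training_j_ == 1.0
        assert list(est.predict(X)) == y
        assert est.decision_function(X).shape == (4,)

    def test_pipeline_estimator_clone(self, planted_truth):
        pipe = GenePrioritizer(fdr_q=0.01)
        assert clone(pipe).fdr_q == 0.01
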