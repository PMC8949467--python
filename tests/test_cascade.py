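import numpy as np
import pandas as pd
import pytest

from rrfdetect import (
    CVSpec,
    LearnerSpec,
    SplitSpec,
    predict_cascade,
    split_train_test,
    train_cascade,
    tune_learner,
)
from rrfdetect.cascade import TrainedCascade, StageResult
from rrfdetect.pipeline import FEATURE_NAMES, LABEL_COLUMN, feature_matrix
from sklearn.ensemble import RandomForestClassifier

from .conftest import cheap_learners, gaussian_feature_table


class TestSplit:
    def test_80_20_row_counts(self):
        table = gaussian_feature_table({"a": 50, "b": 50}, shift=0.0)
        train, test = split_train_test(table, SplitSpec(seed=1))
        assert len(train) == 80 and len(test) == 20
        assert not set(train) & set(test)

    def test_deterministic(self):
        table = gaussian_feature_table({"a": 30, "b": 20}, shift=0.0)
        assert split_train_test(table, SplitSpec(seed=7)) == split_train_test(
            table, SplitSpec(seed=7)
        )

    def test_stratification_preserves_balance(self):
        table = gaussian_feature_table({"a": 25, "b": 25}, shift=0.0)
        for seed in range(10):
            train, _ = split_train_test(table, SplitSpec(seed=seed))
            n_a = sum(table.loc[i, LABEL_COLUMN] == "a" for i in train)
            assert abs(n_a - 20) <= 1

    def test_tiny_class_rejected_under_stratification(self):
        table = gaussian_feature_table({"a": 10, "b": 1}, shift=0.0)
        with pytest.raises(ValueError, match="2 rows per class"):
            split_train_test(table, SplitSpec())


class TestTuneLearner:
    def test_collapsed_search_space_returns_the_point(self):
        table = gaussian_feature_table({"a": 30, "b": 30}, shift=2.0)
        learner = LearnerSpec(
            name="rf",
            factory=lambda seed: RandomForestClassifier(random_state=seed),
            space={"clf__n_estimators": [25], "clf__min_samples_leaf": [2]},
            n_iter=1,
        )
        tune_learner(
            feature_matrix(table), table[LABEL_COLUMN], learner,
            CVSpec(n_folds=5), positive="a", seed=0,
        )
        assert learner.tuned_params == {"n_estimators": 25, "min_samples_leaf": 2}

    def test_separable_classes_reach_perfect_f1(self):
        table = gaussian_feature_table({"a": 30, "b": 30}, shift=6.0, seed=2)
        learner = cheap_learners()[0]
        search = tune_learner(
            feature_matrix(table), table[LABEL_COLUMN], learner,
            CVSpec(n_folds=10, seed=0), positive="a", seed=0,
        )
        assert search.cv_results_["mean_test_f1"][search.best_index_] == 1.0

    def test_permuted_labels_score_near_majority_rate(self):
        table = gaussian_feature_table({"a": 36, "b": 24}, shift=0.0, seed=3)
        learner = cheap_learners()[2]
        search = tune_learner(
            feature_matrix(table), table[LABEL_COLUMN], learner,
            CVSpec(n_folds=10, seed=0), positive="a", seed=0,
        )
        acc = search.cv_results_["mean_test_accuracy"][search.best_index_]
        assert abs(acc - 0.6) < 0.2  # majority-class rate of the 36/24 mix

    def test_reproducible_given_seed(self):
        table = gaussian_feature_table({"a": 20, "b": 20}, shift=1.0)
        results = []
        for _ in range(2):
            learner = cheap_learners()[1]
            tune_learner(
                feature_matrix(table), table[LABEL_COLUMN], learner,
                CVSpec(n_folds=5, seed=3), positive="a", seed=3,
            )
            results.append(learner.tuned_params)
        assert results[0] == results[1]


@pytest.fixture(scope="module")
def separable_cascade():
    table = gaussian_feature_table(
        {"waste": 40, "ragged": 25, "not_ragged": 30}, shift=4.0, seed=4
    )
    model = train_cascade(
        table, cv=CVSpec(n_folds=5), learners=cheap_learners(), seed=11
    )
    return table, model


class TestTrainCascade:
    def test_two_stages_three_candidates_each(self, separable_cascade):
        _, model = separable_cascade
        assert len(model.stage1.candidates) == 3
        assert len(model.stage2.candidates) == 3
        assert model.stage1.positive == "tissue"
        assert model.stage2.positive == "ragged"

    def test_selected_model_has_highest_test_auc(self, separable_cascade):
        _, model = separable_cascade
        for stage in (model.stage1, model.stage2):
            best = max(c.test_auc for c in stage.candidates.values())
            assert stage.candidates[stage.selected].test_auc == best

    def test_stage2_trained_only_on_tissue_rows(self, separable_cascade):
        table, model = separable_cascade
        used = set(model.stage2.train_ids) | set(model.stage2.test_ids)
        labels = table.loc[sorted(used), LABEL_COLUMN]
        assert set(labels) == {"ragged", "not_ragged"}

    def test_separated_classes_give_high_auc(self, separable_cascade):
        _, model = separable_cascade
        for stage in (model.stage1, model.stage2):
            assert stage.candidates[stage.selected].test_auc >= 0.95

    def test_missing_class_rejected(self):
        table = gaussian_feature_table({"ragged": 10, "waste": 10}, shift=1.0)
        with pytest.raises(ValueError, match="must contain labels"):
            train_cascade(table, learners=cheap_learners())

    def test_reproducible_end_to_end(self):
        table = gaussian_feature_table(
            {"waste": 24, "ragged": 18, "not_ragged": 18}, shift=3.0, seed=6
        )
        preds = []
        for _ in range(2):
            model = train_cascade(
                table, cv=CVSpec(n_folds=5), learners=cheap_learners(), seed=5
            )
            preds.append(predict_cascade(model, table))
        pd.testing.assert_frame_equal(preds[0], preds[1])


class _FixedProbability:
    """Stub stage model emitting a constant positive-class probability."""

    def __init__(self, classes, p_positive, positive):
        self.classes_ = np.asarray(classes)
        self._p = p_positive
        self._positive = positive

    def predict_proba(self, x):
        out = np.zeros((len(x), 2))
        pos = list(self.classes_).index(self._positive)
        out[:, pos] = self._p
        out[:, 1 - pos] = 1 - self._p
        return out


def _stub_cascade(p_tissue, p_ragged):
    def stage(classes, p, positive, negative):
        return StageResult(
            positive=positive, negative=negative, selected="stub",
            model=_FixedProbability(classes, p, positive),
            candidates={}, train_ids=(), test_ids=(),
        )

    return TrainedCascade(
        stage1=stage(["tissue", "waste"], p_tissue, "tissue", "waste"),
        stage2=stage(["not_ragged", "ragged"], p_ragged, "ragged", "not_ragged"),
    )


class TestPredictCascade:
    def _features(self, n=4):
        return gaussian_feature_table({"x": n}, shift=0.0).drop(columns=[LABEL_COLUMN])

    def test_low_tissue_probability_short_circuits_to_waste(self):
        out = predict_cascade(_stub_cascade(0.2, 0.99), self._features())
        assert (out["label"] == "waste").all()
        assert out["p_ragged"].isna().all()

    def test_tissue_then_ragged(self):
        out = predict_cascade(_stub_cascade(0.9, 0.8), self._features())
        assert (out["label"] == "ragged").all()
        assert (out["p_tissue"] == 0.9).all() and (out["p_ragged"] == 0.8).all()

    def test_exact_half_counts_as_positive(self):
        out = predict_cascade(_stub_cascade(0.5, 0.4), self._features())
        assert (out["label"] == "not_ragged").all()  # tissue at 0.5, not ragged

    def test_every_row_gets_exactly_one_label(self, separable_cascade):
        table, model = separable_cascade
        out = predict_cascade(model, table)
        assert len(out) == len(table)
        assert set(out["label"]) <= {"waste", "ragged", "not_ragged"}
        # stage-2 probability exists iff stage 1 said tissue
        assert ((out["p_tissue"] >= 0.5) == out["p_ragged"].notna()).all()

    def test_schema_mismatch_rejected(self, separable_cascade):
        _, model = separable_cascade
        broken = self._features().drop(columns=[FEATURE_NAMES[0]])
        with pytest.raises(ValueError, match="schema mismatch"):
            predict_cascade(model, broken)
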