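"""Two-stage (waste/tissue, ragged/not-ragged) classifier cascade.

Stage 1 separates analyzable muscle tissue from waste tiles on the full
dataset (ragged and not-ragged collapsed to "tissue"); stage 2 separates
ragged from not-ragged fibers on the tissue tiles only.  For each stage,
three learners — random forest, gradient boosting, RBF-kernel SVM — are
tuned by random search under 10-fold cross-validation on an 80% training
split (selection by mean validation F1, ties broken by mean accuracy then
draw order), retrained on the full training split, and compared by test-set
AUC; the highest-AUC learner becomes that stage's model.

Feature normalization is part of each model's pipeline, so it is re-fit
inside every cross-validation fold's training portion and never sees
validation or test rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import loguniform, randint
from sklearn.base import BaseEstimator
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import f1_score, make_scorer
from sklearn.model_selection import (
    RandomizedSearchCV,
    StratifiedKFold,
    train_test_split,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import LABEL_NOT_RAGGED, LABEL_RAGGED, LABEL_TISSUE, LABEL_WASTE, logger
from .evaluation import ROCCurve, confusion, metrics, roc_auc
from .pipeline import FEATURE_NAMES, LABEL_COLUMN, feature_matrix


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    seed: int = 0
    stratify: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class CVSpec:
    n_folds: int = 10
    seed: int = 0


@dataclass
class LearnerSpec:
    """One candidate algorithm with its random-search space."""

    name: str
    factory: Callable[[int], BaseEstimator]
    space: dict
    n_iter: int = 50
    tuned_params: dict | None = None


def default_learners(n_iter: int = 50, n_features: int = len(FEATURE_NAMES)) -> list[LearnerSpec]:
    """The three benchmark learners with their search spaces."""
    return [
        LearnerSpec(
            name="random_forest",
            factory=lambda seed: RandomForestClassifier(random_state=seed),
            space={
                "clf__n_estimators": randint(100, 1001),
                "clf__max_features": randint(1, n_features + 1),
                "clf__min_samples_leaf": randint(1, 11),
            },
            n_iter=n_iter,
        ),
        LearnerSpec(
            # histogram-binned gradient boosting; same algorithm family,
            # fit cost stays bounded even on unstructured labels
            name="gradient_boosting",
            factory=lambda seed: HistGradientBoostingClassifier(random_state=seed),
            space={
                "clf__max_iter": randint(50, 501),
                "clf__learning_rate": loguniform(0.01, 0.3),
                "clf__max_depth": randint(1, 9),
            },
            n_iter=n_iter,
        ),
        LearnerSpec(
            # RBF-kernel SVM; Platt-scaled so the cascade gets probabilities
            name="svm_rbf",
            factory=lambda seed: CalibratedClassifierCV(
                SVC(kernel="rbf", random_state=seed), ensemble=False, cv=3
            ),
            space={
                "clf__estimator__C": loguniform(2.0**-5, 2.0**15),
                "clf__estimator__gamma": loguniform(2.0**-15, 2.0**3),
            },
            n_iter=n_iter,
        ),
    ]


@dataclass
class CandidateReport:
    """Tuning and test outcome for one learner on one stage."""

    learner: str
    best_params: dict
    cv_f1: float
    cv_accuracy: float
    test_auc: float
    roc: ROCCurve


@dataclass
class StageResult:
    """The selected model for one cascade stage plus all candidates."""

    positive: str
    negative: str
    selected: str
    model: Pipeline
    candidates: dict[str, CandidateReport]
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]


@dataclass
class TrainedCascade:
    stage1: StageResult  # waste vs tissue; positive = tissue
    stage2: StageResult  # ragged vs not_ragged; positive = ragged
    feature_names: tuple[str, ...] = field(default=tuple(FEATURE_NAMES))


def collapse_stage1_labels(table: pd.DataFrame) -> pd.DataFrame:
    """Stage-1 view of a table: ragged and not_ragged become tissue."""
    out = table.copy()
    out[LABEL_COLUMN] = np.where(
        table[LABEL_COLUMN] == LABEL_WASTE, LABEL_WASTE, LABEL_TISSUE
    )
    return out


def split_train_test(
    table: pd.DataFrame, spec: SplitSpec
) -> tuple[list[str], list[str]]:
    """Stratified, seeded 80/20 row split; returns (train_ids, test_ids)."""
    labels = table[LABEL_COLUMN]
    if spec.stratify:
        counts = labels.value_counts()
        if (counts < 2).any():
            raise ValueError(
                f"stratified split needs >= 2 rows per class, got {counts.to_dict()}"
            )
    train_ids, test_ids = train_test_split(
        table.index.to_list(),
        train_size=spec.train_fraction,
        random_state=spec.seed,
        stratify=labels if spec.stratify else None,
        shuffle=True,
    )
    return list(train_ids), list(test_ids)


def _select_best(cv_results: dict) -> int:
    """Pick the draw with the best mean F1; ties go to higher mean
    accuracy, then to the earlier draw."""
    f1 = np.asarray(cv_results["mean_test_f1"])
    acc = np.asarray(cv_results["mean_test_accuracy"])
    order = np.arange(len(f1))
    best = max(zip(f1, acc, -order), key=lambda t: t)
    return int(-best[2])


def tune_learner(
    x: pd.DataFrame,
    y: pd.Series,
    learner: LearnerSpec,
    cv: CVSpec,
    positive: str,
    seed: int = 0,
) -> RandomizedSearchCV:
    """Random-search tuning of one learner under stratified k-fold CV.

    Returns the fitted search object; its ``best_estimator_`` is the
    winning pipeline retrained on all supplied rows.
    """
    class_counts = y.value_counts()
    if len(class_counts) != 2:
        raise ValueError(f"need exactly two classes, got {class_counts.to_dict()}")
    n_folds = cv.n_folds
    if class_counts.min() < n_folds:
        n_folds = max(2, int(class_counts.min()))
        logger.warning(
            "reducing folds from %d to %d: smallest class has %d rows",
            cv.n_folds, n_folds, class_counts.min(),
        )
    pipeline = Pipeline(
        [("scale", StandardScaler()), ("clf", learner.factory(seed))]
    )
    scoring = {
        "f1": make_scorer(f1_score, pos_label=positive, zero_division=0),
        "accuracy": "accuracy",
    }
    search = RandomizedSearchCV(
        pipeline,
        learner.space,
        n_iter=learner.n_iter,
        scoring=scoring,
        refit=_select_best,
        cv=StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=cv.seed),
        random_state=seed,
        error_score="raise",
        n_jobs=None,
    )
    search.fit(x, y)
    learner.tuned_params = {
        k.split("__")[-1]: v for k, v in search.best_params_.items()
    }
    return search


def positive_probability(model: Pipeline, x: pd.DataFrame, positive: str) -> np.ndarray:
    idx = list(model.classes_).index(positive)
    return model.predict_proba(x)[:, idx]


def _train_stage(
    table: pd.DataFrame,
    positive: str,
    negative: str,
    split: SplitSpec,
    cv: CVSpec,
    learners: list[LearnerSpec],
    seed: int,
) -> StageResult:
    train_ids, test_ids = split_train_test(table, split)
    x_train = feature_matrix(table.loc[train_ids])
    y_train = table.loc[train_ids, LABEL_COLUMN]
    x_test = feature_matrix(table.loc[test_ids])
    y_test = table.loc[test_ids, LABEL_COLUMN]

    sub_seeds = np.random.SeedSequence(seed).generate_state(len(learners)) % (2**31)
    candidates: dict[str, CandidateReport] = {}
    models: dict[str, Pipeline] = {}
    for learner, sub_seed in zip(learners, sub_seeds):
        search = tune_learner(
            x_train, y_train, learner, cv, positive, seed=int(sub_seed)
        )
        scores = positive_probability(search.best_estimator_, x_test, positive)
        roc = roc_auc(scores, y_test, positive)
        best_idx = search.best_index_
        candidates[learner.name] = CandidateReport(
            learner=learner.name,
            best_params=dict(learner.tuned_params or {}),
            cv_f1=float(search.cv_results_["mean_test_f1"][best_idx]),
            cv_accuracy=float(search.cv_results_["mean_test_accuracy"][best_idx]),
            test_auc=roc.auc,
            roc=roc,
        )
        models[learner.name] = search.best_estimator_
        logger.info(
            "stage %s/%s learner %s: CV F1 %.3f, test AUC %.3f",
            positive, negative, learner.name,
            candidates[learner.name].cv_f1, roc.auc,
        )
    selected = max(candidates, key=lambda name: candidates[name].test_auc)
    return StageResult(
        positive=positive,
        negative=negative,
        selected=selected,
        model=models[selected],
        candidates=candidates,
        train_ids=tuple(train_ids),
        test_ids=tuple(test_ids),
    )


def train_cascade(
    table: pd.DataFrame,
    split: SplitSpec = SplitSpec(),
    cv: CVSpec = CVSpec(),
    learners: list[LearnerSpec] | None = None,
    seed: int = 0,
) -> TrainedCascade:
    """Train both cascade stages and select each stage's best learner.

    ``table`` must carry all three tile labels.  Stage 1 uses every row
    with labels collapsed to waste/tissue; stage 2 uses the ragged and
    not-ragged rows only.  Each stage draws its own stratified 80/20
    split, shared across the three learners.
    """
    present = set(table[LABEL_COLUMN])
    required = {LABEL_WASTE, LABEL_RAGGED, LABEL_NOT_RAGGED}
    if not required <= present:
        raise ValueError(f"table must contain labels {sorted(required)}, got {sorted(present)}")

    seeds = np.random.SeedSequence(seed).generate_state(4) % (2**31)

    stage1_table = collapse_stage1_labels(table)
    stage1 = _train_stage(
        stage1_table, LABEL_TISSUE, LABEL_WASTE,
        SplitSpec(split.train_fraction, int(seeds[0]), split.stratify),
        CVSpec(cv.n_folds, int(seeds[1])),
        learners if learners is not None else default_learners(),
        seed=int(seeds[0]),
    )

    stage2_table = table[table[LABEL_COLUMN].isin([LABEL_RAGGED, LABEL_NOT_RAGGED])]
    stage2 = _train_stage(
        stage2_table, LABEL_RAGGED, LABEL_NOT_RAGGED,
        SplitSpec(split.train_fraction, int(seeds[2]), split.stratify),
        CVSpec(cv.n_folds, int(seeds[3])),
        learners if learners is not None else default_learners(),
        seed=int(seeds[2]),
    )
    return TrainedCascade(stage1=stage1, stage2=stage2)


def predict_cascade(cascade: TrainedCascade, features: pd.DataFrame) -> pd.DataFrame:
    """Apply the cascade: waste if p(tissue) < 0.5, otherwise ragged vs
    not-ragged by p(ragged) with the same >= 0.5 rule.

    Returns a frame indexed like ``features`` with columns ``p_tissue``,
    ``p_ragged`` (NaN where stage 2 was skipped) and ``label``.
    """
    x = features[list(cascade.feature_names)] if set(cascade.feature_names) <= set(
        features.columns
    ) else None
    if x is None:
        missing = sorted(set(cascade.feature_names) - set(features.columns))
        raise ValueError(f"feature schema mismatch; missing columns: {missing[:5]}")

    p_tissue = positive_probability(cascade.stage1.model, x, cascade.stage1.positive)
    is_tissue = p_tissue >= 0.5
    p_ragged = np.full(len(x), np.nan)
    if is_tissue.any():
        p_ragged[is_tissue] = positive_probability(
            cascade.stage2.model, x.loc[is_tissue], cascade.stage2.positive
        )
    label = np.where(
        ~is_tissue, LABEL_WASTE,
        np.where(p_ragged >= 0.5, LABEL_RAGGED, LABEL_NOT_RAGGED),
    )
    return pd.DataFrame(
        {"p_tissue": p_tissue, "p_ragged": p_ragged, "label": label},
        index=features.index,
    )


def stage_test_report(table: pd.DataFrame, stage: StageResult) -> dict:
    """Confusion matrix and metrics of a stage's selected model on its own
    held-out test rows (labels taken from ``table``, collapsed for stage 1
    by the caller)."""
    x_test = feature_matrix(table.loc[list(stage.test_ids)])
    y_test = table.loc[list(stage.test_ids), LABEL_COLUMN]
    pred = stage.model.predict(x_test)
    cm = confusion(y_test, pred, stage.positive)
    return {"confusion": cm, "metrics": metrics(cm)}
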