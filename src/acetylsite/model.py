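"""RBF-SVM training, balanced cross-validation and threshold metrics.

The evaluation protocol mirrors the balanced-sampling design used for
acetylation-site benchmarks: the positive fragments are paired in turn
with each of five equal-size random negative sets; within each pairing a
stratified 10-fold cross-validation is run, and the reported value of
each metric is the mean ± standard deviation over the five negative-set
repetitions (each repetition's metric first averaged over its folds).

Inside every fold the KNN reference set, any feature scaling, and the
(C, γ) grid search are restricted to the training fold, so no test
information leaks into the features or the tuned parameters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .corpus import NEGATIVE, POSITIVE, SiteFragment, WindowSpec
from .encoding import BLOCK_NAMES, FeatureEncoder, KnnConfig
from .positions import PositionMask

# ---------------------------------------------------------------------------
# Confusion counts and threshold metrics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fn + other.fn, self.tn + other.tn, self.fp + other.fp
        )


METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "mcc")


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Acc, Sn, Sp and MCC from confusion counts, each in percent.

    Acc = (TP+TN)/total, Sn = TP/(TP+FN), Sp = TN/(TN+FP),
    MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)); MCC is defined
    as 0 when any denominator factor vanishes.
    """
    tp, fn, tn, fp = counts.tp, counts.fn, counts.tn, counts.fp
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("metrics need at least one positive and one negative")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return {
        "accuracy": 100.0 * (tp + tn) / (tp + tn + fp + fn),
        "sensitivity": 100.0 * tp / (tp + fn),
        "specificity": 100.0 * tn / (tn + fp),
        "mcc": 100.0 * mcc,
    }


# ---------------------------------------------------------------------------
# SVM configuration and training


def _pow2_grid(lo: int, hi: int, step: int = 2) -> tuple[float, ...]:
    return tuple(float(2.0 ** e) for e in range(lo, hi + 1, step))


@dataclass(frozen=True)
class SvmConfig:
    """RBF-SVM hyperparameter search space.

    The default grids follow the LIBSVM recipe (C over 2^−5..2^15, γ over
    2^−15..2^3, ×4 steps) with 5-fold inner cross-validation for tuning.
    Single-point grids skip the inner search entirely, which is the cheap
    configuration for large synthetic calibration runs.
    """

    c_grid: tuple[float, ...] = _pow2_grid(-5, 15)
    gamma_grid: tuple[float, ...] = _pow2_grid(-15, 3)
    inner_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("parameter grids must be non-empty")
        if any(v <= 0 for v in self.c_grid + self.gamma_grid):
            raise ValueError("C and gamma values must be positive")


def grid_search_train(
    X: np.ndarray, y: np.ndarray, config: SvmConfig = SvmConfig()
) -> SVC:
    """Fit an RBF SVM with (C, γ) chosen by inner-CV accuracy.

    Ties resolve to the smaller C, then the smaller γ (first best candidate
    in C-major grid order).  The returned classifier is refit on all the
    given data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.all(X.std(axis=0) == 0):
        raise ValueError("degenerate features: zero variance in every column")
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() == 0 or counts.min() / counts.max() < 0.9:
        warnings.warn(
            f"unbalanced labels ({counts[1]} positive vs {counts[0]} negative); "
            "the evaluation protocol assumes balanced classes",
            stacklevel=2,
        )
    if len(config.c_grid) == 1 and len(config.gamma_grid) == 1:
        clf = SVC(kernel="rbf", C=config.c_grid[0], gamma=config.gamma_grid[0])
        return clf.fit(X, y)
    inner = StratifiedKFold(
        n_splits=config.inner_folds, shuffle=True, random_state=config.seed
    )
    search = GridSearchCV(
        SVC(kernel="rbf"),
        {"C": list(config.c_grid), "gamma": list(config.gamma_grid)},
        scoring="accuracy",
        cv=inner,
        n_jobs=1,
    )
    search.fit(X, y)
    return search.best_estimator_


# ---------------------------------------------------------------------------
# Trained model bundle

BUNDLE_VERSION = 1


@dataclass
class TrainedModel:
    """A fitted SVM plus everything needed to featurize new fragments."""

    classifier: SVC
    encoder: FeatureEncoder
    mask: PositionMask
    window: WindowSpec
    reference: list[SiteFragment]     # KNN reference = full training corpus
    training_protein_ids: frozenset[str]
    c: float
    gamma: float

    def save(self, path) -> None:
        joblib.dump({"version": BUNDLE_VERSION, "model": self}, path)

    @staticmethod
    def load(path) -> "TrainedModel":
        bundle = joblib.load(path)
        if bundle.get("version") != BUNDLE_VERSION:
            raise ValueError(f"unsupported model bundle version {bundle.get('version')}")
        return bundle["model"]


def train_model(
    positives: Sequence[SiteFragment],
    negatives: Sequence[SiteFragment],
    mask: PositionMask,
    blocks: Sequence[str] = BLOCK_NAMES,
    svm_config: SvmConfig = SvmConfig(),
    knn_config: KnnConfig = KnnConfig(),
    encoder: FeatureEncoder | None = None,
) -> TrainedModel:
    """Grid-search-train a model on a balanced corpus; KNN reference = that corpus."""
    fragments = list(positives) + list(negatives)
    y = np.array([1] * len(positives) + [0] * len(negatives))
    if encoder is None:
        encoder = FeatureEncoder(mask.offsets, blocks, knn_config=knn_config)
    X = encoder.encode_matrix(fragments, reference=fragments)
    clf = grid_search_train(X, y, svm_config)
    return TrainedModel(
        classifier=clf,
        encoder=encoder,
        mask=mask,
        window=fragments[0].window,
        reference=fragments,
        training_protein_ids=frozenset(f.protein_id for f in fragments),
        c=float(clf.C),
        gamma=float(clf.gamma) if isinstance(clf.gamma, (int, float)) else clf.gamma,
    )


def predict(
    model: TrainedModel, fragments: Sequence[SiteFragment]
) -> pd.DataFrame:
    """Labels and decision-function scores for new fragments (threshold 0)."""
    if not fragments:
        raise ValueError("no fragments to predict")
    for f in fragments:
        if f.window.length != model.window.length:
            raise ValueError(
                f"fragment window length {f.window.length} != model window "
                f"length {model.window.length}"
            )
    X = model.encoder.encode_matrix(list(fragments), reference=model.reference)
    if X.shape[1] != model.encoder.layout.n_features:
        raise ValueError("feature layout mismatch between model and input")
    scores = model.classifier.decision_function(X)
    labels = np.where(scores > 0, POSITIVE, NEGATIVE)
    return pd.DataFrame(
        {
            "protein_id": [f.protein_id for f in fragments],
            "position": [f.center_position for f in fragments],
            "score": scores,
            "predicted_label": labels,
        }
    )


# ---------------------------------------------------------------------------
# Cross-validation protocol


@dataclass
class EvaluationResult:
    """Per-repetition confusion counts/metrics with mean ± sd aggregation.

    ``records`` has one row per (negative set, fold); ``set_means`` one row
    per negative set (fold-averaged); ``summary`` maps each metric to its
    (mean, sd) over sets, in percent (sample sd, ddof=1; 0 for one set).
    """

    records: pd.DataFrame
    set_means: pd.DataFrame
    summary: dict[str, tuple[float, float]]

    def format_summary(self) -> str:
        parts = [
            f"{name.capitalize() if name != 'mcc' else 'MCC'} "
            f"{mean:.2f} ± {sd:.2f}%"
            for name, (mean, sd) in self.summary.items()
        ]
        return ", ".join(parts)


def _aggregate(records: pd.DataFrame) -> EvaluationResult:
    set_means = records.groupby("negative_set")[list(METRIC_NAMES)].mean().reset_index()
    summary = {}
    for name in METRIC_NAMES:
        vals = set_means[name].to_numpy()
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        summary[name] = (float(vals.mean()), sd)
    return EvaluationResult(records=records, set_means=set_means, summary=summary)


def cross_validate(
    positives: Sequence[SiteFragment],
    negative_sets: Sequence[Sequence[SiteFragment]],
    mask: PositionMask,
    blocks: Sequence[str] = BLOCK_NAMES,
    svm_config: SvmConfig = SvmConfig(),
    knn_config: KnnConfig = KnnConfig(),
    folds: int = 10,
    seed: int = 0,
) -> EvaluationResult:
    """Balanced five-negative-set stratified k-fold cross-validation.

    For each negative set the positives are pooled with that set, split
    into stratified folds, and per fold the model is trained (KNN
    reference, scaling and grid search on the training fold only) and
    scored on the held-out fold.
    """
    positives = list(positives)
    if len(positives) < folds:
        raise ValueError("need at least `folds` positive fragments")
    encoder = FeatureEncoder(mask.offsets, blocks, knn_config=knn_config)
    rows = []
    for set_idx, negset in enumerate(negative_sets):
        fragments = positives + list(negset)
        if len(negset) < folds:
            raise ValueError("need at least `folds` negative fragments per set")
        y = np.array([1] * len(positives) + [0] * len(negset))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + set_idx)
        for fold_idx, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
            train = [fragments[i] for i in train_idx]
            test = [fragments[i] for i in test_idx]
            X_train = encoder.encode_matrix(train, reference=train)
            X_test = encoder.encode_matrix(test, reference=train)
            fold_cfg = SvmConfig(
                c_grid=svm_config.c_grid,
                gamma_grid=svm_config.gamma_grid,
                inner_folds=svm_config.inner_folds,
                seed=svm_config.seed + 1000 * set_idx + fold_idx,
            )
            clf = grid_search_train(X_train, y[train_idx], fold_cfg)
            pred = clf.predict(X_test)
            truth = y[test_idx]
            counts = ConfusionCounts(
                tp=int(np.sum((pred == 1) & (truth == 1))),
                fn=int(np.sum((pred == 0) & (truth == 1))),
                tn=int(np.sum((pred == 0) & (truth == 0))),
                fp=int(np.sum((pred == 1) & (truth == 0))),
            )
            rows.append(
                {
                    "negative_set": set_idx,
                    "fold": fold_idx,
                    "tp": counts.tp,
                    "fn": counts.fn,
                    "tn": counts.tn,
                    "fp": counts.fp,
                    **confusion_metrics(counts),
                }
            )
    return _aggregate(pd.DataFrame(rows))


def evaluate_holdout(
    model: TrainedModel, holdout: Sequence[SiteFragment], *, allow_overlap: bool = False
) -> EvaluationResult:
    """Single-pass evaluation on a protein-level holdout corpus.

    The holdout proteins must be disjoint from the training proteins
    unless ``allow_overlap`` is set (used only by leakage sanity tests).
    """
    holdout = list(holdout)
    if not holdout:
        raise ValueError("empty holdout corpus")
    overlap = {f.protein_id for f in holdout} & model.training_protein_ids
    if overlap and not allow_overlap:
        raise ValueError(
            f"holdout proteins overlap training proteins: {sorted(overlap)[:5]}"
        )
    frame = predict(model, holdout)
    truth = np.array([f.label == POSITIVE for f in holdout])
    pred = frame["predicted_label"].to_numpy() == POSITIVE
    counts = ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        fn=int(np.sum(~pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
        fp=int(np.sum(pred & ~truth)),
    )
    rows = pd.DataFrame(
        [{"negative_set": 0, "fold": 0, "tp": counts.tp, "fn": counts.fn,
          "tn": counts.tn, "fp": counts.fp, **confusion_metrics(counts)}]
    )
    return _aggregate(rows)


def compare_mcc(
    results_a: EvaluationResult | Sequence[float],
    results_b: EvaluationResult | Sequence[float],
    paired: bool = False,
) -> tuple[float, float]:
    """Welch's unequal-variance t-test on per-negative-set MCC values.

    Returns (t statistic, two-sided p).  ``paired=True`` switches to the
    paired t-test for designs where the same negative sets back both runs.
    """
    a = _mcc_values(results_a)
    b = _mcc_values(results_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 repetitions per side")
    if np.allclose(a, b) and np.std(a) == 0:
        return 0.0, 1.0
    if paired:
        t, p = stats.ttest_rel(a, b)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _mcc_values(r) -> np.ndarray:
    if isinstance(r, EvaluationResult):
        return r.set_means["mcc"].to_numpy(dtype=float)
    return np.asarray(r, dtype=float)
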