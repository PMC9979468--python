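"""Classifier training, evaluation metrics, sensitivity t-test and the sweep.

Scattering feature vectors feed a binary SVM or logistic-regression
classifier.  Hyperparameters are tuned by seeded sequential model-based
(Bayesian) search — or a seeded random search — minimizing the stratified
5-fold cross-validated misclassification rate, with features standardized
inside each training fold only (a scaler embedded in the model pipeline).
Evaluation designates glaucoma as the positive class; an F1-score is
*missing* (never zero) whenever the classifier makes no positive prediction,
since precision is then a 0/0 form.

A Welch two-sample t-test per feature column quantifies how sensitive the
scattering features are to a change in one transform parameter, and
``run_sweep`` drives the full (channel x configuration x classifier) study.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import _search
from .filterbank import ScatteringConfig
from .preprocessing import RawImage, extract_channel, resize_image
from .scattering import feature_matrix

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "glaucoma"


@dataclass(frozen=True)
class HyperparamSpace:
    """Search space and budget for classifier tuning.

    SVM searches kernel function, box constraint (C) and kernel scale (the
    RBF/polynomial length scale, applied as gamma = 1/scale^2); logistic
    regression searches the L2 penalty strength lambda (inverse of
    scikit-learn's C).  Ranges are log-uniform.
    """

    svm_kernels: tuple[str, ...] = ("linear", "rbf", "poly")
    svm_box_constraint: tuple[float, float] = (1e-3, 1e3)
    svm_kernel_scale: tuple[float, float] = (1e-2, 1e2)
    logreg_penalty: tuple[float, float] = (1e-6, 1e2)
    budget: int = 30
    folds: int = 5
    seed: int = 0
    method: str = "bayes"  # or "random": seeded random-search fallback

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.budget < 1:
            raise ValueError("budget must be >= 1")

    def dimensions(self, classifier: str) -> list:
        if classifier == "svm":
            return [
                _search.Categorical("kernel", self.svm_kernels),
                _search.Real("box_constraint", *self.svm_box_constraint),
                _search.Real("kernel_scale", *self.svm_kernel_scale),
            ]
        if classifier == "logreg":
            return [_search.Real("penalty", *self.logreg_penalty)]
        raise ValueError(f"unknown classifier {classifier!r}")


@dataclass
class EvalResult:
    """Confusion counts and derived metrics with glaucoma as positive.

    ``precision``, ``recall`` and ``f1`` are ``None`` when their defining
    ratio is a 0/0 form; in particular F1 is missing exactly when the
    classifier makes no positive prediction (TP + FP = 0).
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def precision(self) -> float | None:
        return None if self.tp + self.fp == 0 else self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float | None:
        return None if self.tp + self.fn == 0 else self.tp / (self.tp + self.fn)

    @property
    def f1(self) -> float | None:
        p, r = self.precision, self.recall
        if p is None or r is None:
            return None
        if p + r == 0:
            return 0.0
        return 2 * p * r / (p + r)

    def per_class(self) -> dict[str, dict[str, float | None]]:
        """Precision/recall/F1 for both classes (healthy = swapped confusion)."""
        flipped = EvalResult(tp=self.tn, fp=self.fn, tn=self.tp, fn=self.fp)
        return {
            "glaucoma": {"precision": self.precision, "recall": self.recall, "f1": self.f1},
            "healthy": {
                "precision": flipped.precision,
                "recall": flipped.recall,
                "f1": flipped.f1,
            },
        }


@dataclass
class FitResult:
    model: Pipeline
    cv_loss: float
    best_hyperparams: dict
    classifier: str


def _encode_labels(labels) -> np.ndarray:
    return np.asarray([1 if l == POSITIVE_LABEL else 0 for l in labels])


def make_classifier(classifier: str, params: dict) -> Pipeline:
    """A leak-proof pipeline: per-fold standardization then the classifier."""
    if classifier == "svm":
        kernel = params["kernel"]
        clf = SVC(
            kernel=kernel,
            C=params["box_constraint"],
            gamma=(1.0 / params["kernel_scale"] ** 2) if kernel != "linear" else "scale",
            degree=3,
        )
    elif classifier == "logreg":
        clf = LogisticRegression(C=1.0 / params["penalty"], max_iter=2000)
    else:
        raise ValueError(f"unknown classifier {classifier!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def fit_with_search(
    features: np.ndarray,
    labels,
    classifier: str = "svm",
    space: HyperparamSpace | None = None,
) -> FitResult:
    """Tune, then refit on all training data.

    Minimizes the stratified k-fold cross-validated misclassification rate
    over the classifier's hyperparameter space using seeded Bayesian
    optimization (or random search when ``space.method == "random"``).
    """
    space = space or HyperparamSpace()
    features = np.asarray(features, dtype=np.float64)
    y = _encode_labels(labels)
    if features.shape[0] != y.shape[0]:
        raise ValueError("feature rows and labels disagree")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class; need both")
    if features.shape[0] < space.folds:
        raise ValueError(
            f"fewer samples ({features.shape[0]}) than folds ({space.folds})"
        )

    cv = StratifiedKFold(n_splits=space.folds, shuffle=True, random_state=space.seed)

    def objective(params: dict) -> float:
        model = make_classifier(classifier, params)
        acc = cross_val_score(model, features, y, cv=cv, scoring="accuracy")
        return 1.0 - float(acc.mean())

    result = _search.minimize(
        objective,
        space.dimensions(classifier),
        n_calls=space.budget,
        seed=space.seed,
        method=space.method,
    )
    model = make_classifier(classifier, result.best_params)
    model.fit(features, y)
    return FitResult(model, result.best_value, result.best_params, classifier)


def evaluate(model: Pipeline, test_features: np.ndarray, test_labels) -> EvalResult:
    """Confusion counts and metrics on a held-out set (glaucoma positive)."""
    test_features = np.asarray(test_features, dtype=np.float64)
    expected = model.named_steps["scale"].n_features_in_
    if test_features.shape[1] != expected:
        raise ValueError(
            f"feature width {test_features.shape[1]} does not match model ({expected})"
        )
    y = _encode_labels(test_labels)
    pred = model.predict(test_features)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    return EvalResult(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass
class TTestSummary:
    p_values: np.ndarray
    t_statistics: np.ndarray
    alpha: float

    @property
    def significant_fraction(self) -> float:
        return float(np.mean(self.p_values < self.alpha))


def sensitivity_ttest(
    feature_matrix_a: np.ndarray,
    feature_matrix_b: np.ndarray,
    alpha: float = 0.05,
) -> TTestSummary:
    """Welch two-sample t-test per feature column.

    The matrices hold features of the same images under two transform
    parameter settings; when the settings yield different feature counts the
    comparison runs on the common leading columns (path order is stable, so
    these index matching low-order paths).
    """
    a = np.asarray(feature_matrix_a, dtype=np.float64)
    b = np.asarray(feature_matrix_b, dtype=np.float64)
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"row counts differ: {a.shape[0]} vs {b.shape[0]}")
    k = min(a.shape[1], b.shape[1])
    t, p = stats.ttest_ind(a[:, :k], b[:, :k], axis=0, equal_var=False)
    # identical zero-variance columns give a 0/0 t: no evidence of difference
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)
    return TTestSummary(p_values=p, t_statistics=t, alpha=alpha)


@dataclass
class SweepRecord:
    config: ScatteringConfig
    channel: str
    classifier: str
    cv_loss: float
    test_eval: EvalResult
    best_hyperparams: dict
    n_features: int


def _prep(images: list[RawImage], channel: str, size) -> list:
    return [resize_image(extract_channel(im, channel), size) for im in images]


def run_sweep(
    train_set: list[RawImage],
    test_set: list[RawImage],
    channel_list: list[str],
    config_grid: list[ScatteringConfig],
    classifiers: list[str] = ("svm", "logreg"),
    space: HyperparamSpace | None = None,
) -> list[SweepRecord]:
    """Train and evaluate every (channel, configuration, classifier) triple.

    Features are extracted separately on train and test; tuning sees the
    training set only.  Records follow the loop order channel, config,
    classifier.
    """
    if not config_grid:
        raise ValueError("empty grid: no scattering configurations to sweep")
    if not channel_list:
        raise ValueError("empty grid: no channels to sweep")
    space = space or HyperparamSpace()
    records: list[SweepRecord] = []
    for channel in channel_list:
        for config in config_grid:
            size = tuple(config.image_size)
            xtr, ytr, _ = feature_matrix(_prep(train_set, channel, size), config)
            xte, yte, _ = feature_matrix(_prep(test_set, channel, size), config)
            for classifier in classifiers:
                fit = fit_with_search(xtr, ytr, classifier, space)
                ev = evaluate(fit.model, xte, yte)
                records.append(
                    SweepRecord(
                        config=config,
                        channel=channel,
                        classifier=classifier,
                        cv_loss=fit.cv_loss,
                        test_eval=ev,
                        best_hyperparams=fit.best_hyperparams,
                        n_features=xtr.shape[1],
                    )
                )
                logger.info(
                    "sweep %s s=%s q=%s %s: cv_loss=%.3f f1=%s",
                    channel, config.invariance_scale, config.quality_factors,
                    classifier, fit.cv_loss, ev.f1,
                )
    return records


def sweep_frame(records: list[SweepRecord]) -> pd.DataFrame:
    """Long-format results table, one row per sweep record."""
    rows = []
    for r in records:
        ev = r.test_eval
        rows.append(
            {
                "channel": r.channel,
                "s": r.config.invariance_scale,
                "q1": r.config.quality_factors[0],
                "q2": r.config.quality_factors[1],
                "r": r.config.num_rotations,
                "classifier": r.classifier,
                "n_features": r.n_features,
                "cv_loss": r.cv_loss,
                "TP": ev.tp, "FP": ev.fp, "TN": ev.tn, "FN": ev.fn,
                "precision": ev.precision,
                "recall": ev.recall,
                "f1": ev.f1,
                "best_hyperparams": json.dumps(r.best_hyperparams, sort_keys=True),
            }
        )
    return pd.DataFrame(rows)


def best_settings(records: list[SweepRecord]) -> pd.DataFrame:
    """Per (channel, classifier) best setting by test F1 (missing F1 excluded)."""
    frame = sweep_frame(records)
    frame = frame[frame["f1"].notna()]
    if frame.empty:
        return frame
    idx = frame.groupby(["channel", "classifier"])["f1"].idxmax()
    return frame.loc[idx].sort_values(["classifier", "f1"], ascending=[True, False])
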