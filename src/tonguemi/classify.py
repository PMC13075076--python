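"""Command classification: schemes, leakage-free splits, four families.

Class schemes group the six imagined tongue actions into the evaluated
command sets: three 2-class pairs (LL-LR, CL-CR, LU-LD), two 4-class
sets (LL-LR-LU-LD, CL-CR-LU-LD) and the full 6-class set.

Evaluation is subject-independent: a participant-level 70/30 holdout
(with 15 subjects: 10 train / 5 test, flooring on the training side)
plus stratified 10-fold cross-validation at trial level *within* the
training partition.

Classifier families, all at their conventional defaults:

* ``lda`` — pooled-covariance linear discriminant (shrinkage is enabled
  automatically, with a logged warning, if the pooled covariance is
  near-singular);
* ``svm`` — linear-kernel SVM, unit cost, one-vs-one multi-class,
  features standardized by training statistics;
* ``nb``  — Gaussian naive Bayes on raw ERD%;
* ``ann`` — the shallow SCG-trained softmax network of
  :mod:`tonguemi.ann`, standardized features, seeded initialization.

Standardization (z-score by training-set statistics) is applied to the
scale-sensitive families (SVM, ANN); LDA and NB consume raw ERD%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .ann import ScgMlpClassifier
from .features import FeatureMatrix
from .io import COMMANDS

logger = logging.getLogger(__name__)

FAMILIES = ("lda", "svm", "nb", "ann")


@dataclass(frozen=True)
class ClassScheme:
    """An ordered subset of the six commands forming one task."""

    name: str
    commands: tuple[str, ...]

    def __post_init__(self) -> None:
        unknown = [c for c in self.commands if c not in COMMANDS]
        if unknown or len(set(self.commands)) != len(self.commands):
            raise ValueError(f"invalid command set {self.commands}")

    @property
    def n_classes(self) -> int:
        return len(self.commands)


_BUILTIN_SCHEMES = {
    "LL-LR": ("LL", "LR"),
    "CL-CR": ("CL", "CR"),
    "LU-LD": ("LU", "LD"),
    "LL-LR-LU-LD": ("LL", "LR", "LU", "LD"),
    "CL-CR-LU-LD": ("CL", "CR", "LU", "LD"),
    "LL-LR-CL-CR-LU-LD": ("LL", "LR", "CL", "CR", "LU", "LD"),
}

SCHEME_NAMES = tuple(_BUILTIN_SCHEMES)


def make_scheme(name: str | Sequence[str]) -> ClassScheme:
    """Built-in scheme by name, or a custom scheme from a command list."""
    if not isinstance(name, str):
        commands = tuple(name)
        return ClassScheme(name="-".join(commands), commands=commands)
    if name not in _BUILTIN_SCHEMES:
        raise ValueError(
            f"unknown scheme {name!r}; built-ins: {list(_BUILTIN_SCHEMES)}")
    return ClassScheme(name=name, commands=_BUILTIN_SCHEMES[name])


@dataclass(frozen=True)
class SplitPlan:
    """A subject-disjoint train/test partition."""

    train_subjects: tuple[str, ...]
    test_subjects: tuple[str, ...]
    ratio: float
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_subjects) & set(self.test_subjects):
            raise ValueError("train and test subject sets overlap")


def plan_split(subject_ids: Sequence[str], ratio: float = 0.7,
               seed: int = 0) -> SplitPlan:
    """Seeded participant-level split; training side takes
    ``floor(ratio * n)`` subjects (15 subjects at 0.7 -> 10/5)."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    subjects = sorted(set(subject_ids))
    if len(subjects) < 2:
        raise ValueError("need at least two subjects to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(subjects)
    n_train = int(np.floor(ratio * len(subjects)))
    n_train = min(max(n_train, 1), len(subjects) - 1)
    return SplitPlan(train_subjects=tuple(sorted(order[:n_train])),
                     test_subjects=tuple(sorted(order[n_train:])),
                     ratio=ratio, seed=seed)


def split_by_participant(fm: FeatureMatrix, ratio: float = 0.7,
                         seed: int = 0
                         ) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Split a feature matrix into subject-disjoint train/test parts."""
    plan = plan_split(fm.subjects, ratio, seed)
    return (fm.filter_subjects(plan.train_subjects),
            fm.filter_subjects(plan.test_subjects))


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family plus hyper-parameter overrides."""

    family: str = "lda"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; choose from {FAMILIES}")


@dataclass
class TrainedModel:
    """A fitted classifier with its scheme and training metadata."""

    spec: ClassifierSpec
    scheme: ClassScheme
    estimator: Pipeline
    seed: int
    n_train: int

    def predict(self, fm: FeatureMatrix) -> np.ndarray:
        return predict(self, fm)


def _pooled_cov_condition(X: np.ndarray, y: np.ndarray) -> float:
    classes = np.unique(y)
    n, d = X.shape
    cov = np.zeros((d, d))
    for c in classes:
        Xi = X[y == c]
        if len(Xi) > 1:
            cov += (len(Xi) - 1) * np.cov(Xi, rowvar=False)
    denom = max(n - len(classes), 1)
    cov /= denom
    return float(np.linalg.cond(cov))


def _build_estimator(spec: ClassifierSpec, scheme: ClassScheme,
                     seed: int, X: np.ndarray,
                     y: np.ndarray) -> Pipeline:
    params = dict(spec.params)
    if spec.family == "lda":
        if _pooled_cov_condition(X, y) > 1e10:
            logger.warning(
                "LDA pooled covariance is near-singular; enabling "
                "automatic shrinkage")
            params.setdefault("solver", "lsqr")
            params.setdefault("shrinkage", "auto")
        clf = LinearDiscriminantAnalysis(**params)
        steps = [("clf", clf)]
    elif spec.family == "nb":
        steps = [("clf", GaussianNB(**params))]
    elif spec.family == "svm":
        params.setdefault("kernel", "linear")
        params.setdefault("C", 1.0)
        steps = [("scale", StandardScaler()),
                 ("clf", SVC(**params))]
    else:  # ann
        params.setdefault("hidden_units", 10)
        params.setdefault("class_order", scheme.commands)
        params.setdefault("random_state", seed)
        steps = [("scale", StandardScaler()),
                 ("clf", ScgMlpClassifier(**params))]
    return Pipeline(steps)


def train_classifier(train: FeatureMatrix, spec: ClassifierSpec,
                     scheme: ClassScheme | None = None,
                     seed: int = 0) -> TrainedModel:
    """Fit one classifier family on a (scheme-filtered) training matrix."""
    scheme = scheme or make_scheme(
        [c for c in COMMANDS if c in set(train.y)])
    fm = train.filter_commands(scheme.commands)
    X, y = fm.X, fm.y
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(
            f"training data contains a single class ({classes.tolist()})")
    est = _build_estimator(spec, scheme, seed, X, y)
    est.fit(X, y)
    return TrainedModel(spec=spec, scheme=scheme, estimator=est,
                        seed=seed, n_train=len(y))


def predict(model: TrainedModel, fm: FeatureMatrix) -> np.ndarray:
    """Predict one command per trial row."""
    X = fm.X
    if X.shape[1] != len(fm.channels):
        raise ValueError("feature matrix has wrong width")
    expected = model.estimator.named_steps["clf"].n_features_in_
    if X.shape[1] != expected:
        raise ValueError(
            f"model expects {expected} features, got {X.shape[1]}")
    return np.asarray(model.estimator.predict(X))


def predict_proba(model: TrainedModel, fm: FeatureMatrix) -> np.ndarray:
    clf = model.estimator.named_steps["clf"]
    if not hasattr(clf, "predict_proba"):
        raise AttributeError(
            f"{model.spec.family} does not expose probabilities")
    return model.estimator.predict_proba(fm.X)


@dataclass(frozen=True)
class CrossValSummary:
    """Stratified k-fold accuracy summary (percent)."""

    k: int
    fold_accuracy: np.ndarray            # (k,) overall accuracy per fold
    mean: float
    sd: float
    per_class_mean: dict[str, float]     # recall per class, fold-averaged
    per_class_sd: dict[str, float]


def crossvalidate(train: FeatureMatrix, spec: ClassifierSpec,
                  scheme: ClassScheme | None = None, k: int = 10,
                  seed: int = 0) -> CrossValSummary:
    """Trial-level stratified k-fold CV within the training partition.

    Reports overall and per-class (recall) accuracy as mean ± SD across
    folds, in percent.  Folds partition the trials: every trial lands
    in exactly one validation fold.
    """
    scheme = scheme or make_scheme(
        [c for c in COMMANDS if c in set(train.y)])
    fm = train.filter_commands(scheme.commands)
    X, y = fm.X, fm.y
    counts = {c: int(np.sum(y == c)) for c in scheme.commands}
    too_small = {c: n for c, n in counts.items() if n < k}
    if too_small:
        raise ValueError(
            f"classes {too_small} have fewer than k={k} trials; "
            "use a smaller k")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_acc = []
    per_class = {c: [] for c in scheme.commands}
    for fold, (tr, va) in enumerate(skf.split(X, y)):
        est = _build_estimator(spec, scheme, seed + fold, X[tr], y[tr])
        est.fit(X[tr], y[tr])
        pred = est.predict(X[va])
        fold_acc.append(float(np.mean(pred == y[va]) * 100.0))
        for c in scheme.commands:
            mask = y[va] == c
            if mask.any():
                per_class[c].append(
                    float(np.mean(pred[mask] == c) * 100.0))
    fold_acc = np.asarray(fold_acc)
    return CrossValSummary(
        k=k, fold_accuracy=fold_acc,
        mean=float(fold_acc.mean()), sd=float(fold_acc.std(ddof=1)),
        per_class_mean={c: float(np.mean(v)) for c, v in per_class.items()},
        per_class_sd={c: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
                      for c, v in per_class.items()})
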