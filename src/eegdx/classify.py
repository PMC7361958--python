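"""Classifier bank and k-fold cross-validation.

Four classifiers are provided, with the hyperparameters fixed to the
values standard for this pipeline:

* ``lda`` — linear discriminant analysis (pooled-covariance Gaussian
  classes, linear decision boundary);
* ``svm_linear_ova`` — linear soft-margin SVMs, hinge loss, one binary
  machine per class fused by maximum decision value (one-vs-all);
* ``knn`` — k-nearest neighbours, Euclidean distance, k = 5, majority
  vote with a nearer-neighbour tie-break then fixed class order;
* ``ann`` — a feed-forward network with a single 5-node sigmoidal
  hidden layer, softmax output, early stopping on a 10% validation
  split of the training fold.

Evaluation is stratified k-fold cross-validation (k = 10 by default):
each fold's accuracy is 100 x correct / held-out count and the overall
accuracy is the arithmetic mean of the fold accuracies.  Feature
standardization (z-scoring) is fit on the training fold only, so no
test-fold statistics leak into training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, FoldError, ParameterError, TrainingError

CLASSIFIER_KINDS = ("lda", "svm_linear_ova", "knn", "ann")


@dataclass
class LabeledFeatures:
    """A feature matrix with per-row class labels and subject groups.

    ``ordering`` carries the (channel, subband, statistic) triple for
    each column, so grid runs can slice out one statistic's columns.
    """

    matrix: np.ndarray
    labels: np.ndarray
    groups: np.ndarray | None = None
    ordering: tuple[tuple[str, str, str], ...] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.matrix.ndim != 2:
            raise ParameterError("feature matrix must be 2-D")
        if len(self.labels) != self.matrix.shape[0]:
            raise ContractError("one label per feature row required")
        if self.groups is not None:
            self.groups = np.asarray(self.groups)
            if len(self.groups) != self.matrix.shape[0]:
                raise ContractError("one group per feature row required")
        if self.ordering is not None and len(self.ordering) != self.matrix.shape[1]:
            raise ContractError("ordering length must match column count")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    def select_statistic(self, statistic: str) -> "LabeledFeatures":
        """Restrict the matrix to columns produced by one statistic."""
        if self.ordering is None:
            raise ParameterError("no column ordering metadata to select by")
        keep = [i for i, (_, _, s) in enumerate(self.ordering) if s == statistic]
        if not keep:
            raise ParameterError(f"no columns for statistic {statistic!r}")
        return LabeledFeatures(
            matrix=self.matrix[:, keep],
            labels=self.labels,
            groups=self.groups,
            ordering=tuple(self.ordering[i] for i in keep),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LabeledFeatures":
        """Build from a feature DataFrame as written by
        :func:`eegdx.dwt_features.features_to_frame`."""
        meta = ("class_label", "subject_id", "segment_index")
        feat_cols = [c for c in df.columns if c not in meta]
        ordering = tuple(tuple(c.split("|")) for c in feat_cols)
        return cls(
            matrix=df[feat_cols].to_numpy(float),
            labels=df["class_label"].to_numpy(),
            groups=df["subject_id"].to_numpy() if "subject_id" in df else None,
            ordering=ordering,
        )

    @classmethod
    def from_vectors(cls, vectors: Sequence) -> "LabeledFeatures":
        """Build from a list of FeatureVector objects sharing one ordering."""
        from .dwt_features import features_to_frame

        return cls.from_frame(features_to_frame(vectors))


@dataclass
class ClassifierSpec:
    """Which classifier to train, and its (fixed) hyperparameters."""

    kind: Literal["lda", "svm_linear_ova", "knn", "ann"]
    k_neighbors: int = 5
    hidden_nodes: int = 5
    max_epochs: int = 500
    max_iter: int = 5000
    standardize: bool | None = None  # None = on except for lda
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ParameterError(
                f"unknown classifier {self.kind!r}; valid: {CLASSIFIER_KINDS}"
            )
        if self.k_neighbors < 1:
            raise ParameterError("k_neighbors must be >= 1")
        if self.hidden_nodes < 1:
            raise ParameterError("hidden_nodes must be >= 1")

    @property
    def standardize_effective(self) -> bool:
        if self.standardize is None:
            return self.kind != "lda"
        return self.standardize


@dataclass
class TrainedModel:
    """A fitted classifier plus the preprocessing it was trained with."""

    spec: ClassifierSpec
    classes: tuple
    n_features: int
    _estimator: object = field(repr=False, default=None)
    _scaler_mean: np.ndarray | None = field(repr=False, default=None)
    _scaler_scale: np.ndarray | None = field(repr=False, default=None)
    _knn_X: np.ndarray | None = field(repr=False, default=None)
    _knn_y: np.ndarray | None = field(repr=False, default=None)


def _standardize_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0  # constant columns pass through centred
    return mean, scale


def train(spec: ClassifierSpec, data: LabeledFeatures) -> TrainedModel:
    """Fit one classifier on a labeled feature matrix.

    Deterministic given ``spec.seed``.  Raises :class:`TrainingError`
    on single-class input or non-finite feature values.
    """
    x, y = data.matrix, data.labels
    classes = tuple(sorted(np.unique(y).tolist()))
    if len(classes) < 2:
        raise TrainingError(f"training needs >= 2 classes, got {classes}")
    if not np.all(np.isfinite(x)):
        raise TrainingError("feature matrix contains non-finite values")

    mean = scale = None
    if spec.standardize_effective:
        mean, scale = _standardize_fit(x)
        x = (x - mean) / scale

    model = TrainedModel(
        spec=spec,
        classes=classes,
        n_features=x.shape[1],
        _scaler_mean=mean,
        _scaler_scale=scale,
    )

    if spec.kind == "lda":
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        est = LinearDiscriminantAnalysis()
        try:
            est.fit(x, y)
        except (np.linalg.LinAlgError, IndexError, ValueError):
            # degenerate within-class scatter (features constant per
            # class): LDA's limit is the nearest class centroid
            from sklearn.neighbors import NearestCentroid

            est = NearestCentroid()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                with np.errstate(divide="ignore", invalid="ignore"):
                    est.fit(x, y)
        model._estimator = est
    elif spec.kind == "svm_linear_ova":
        from sklearn.svm import LinearSVC

        # LinearSVC is natively one-vs-all with max-decision-value fusion.
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = LinearSVC(
                loss="hinge",
                max_iter=spec.max_iter,
                random_state=int(spec.seed) % (2**31),
            )
            est.fit(x, y)
        model._estimator = est
    elif spec.kind == "knn":
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=min(spec.k_neighbors, len(y)))
        nn.fit(x)
        model._estimator = nn
        model._knn_X = x
        model._knn_y = y
    elif spec.kind == "ann":
        from sklearn.neural_network import MLPClassifier

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = MLPClassifier(
                hidden_layer_sizes=(spec.hidden_nodes,),
                activation="logistic",
                max_iter=spec.max_epochs,
                early_stopping=True,
                validation_fraction=0.1,
                n_iter_no_change=50,
                learning_rate_init=0.2,
                random_state=int(spec.seed) % (2**31),
            )
            est.fit(x, y)
        model._estimator = est
    return model


def _knn_predict(model: TrainedModel, x: np.ndarray) -> np.ndarray:
    """Majority vote over the k nearest training points.

    Ties are broken by the class owning the nearer neighbour, then by
    fixed (sorted) class order.
    """
    dist, idx = model._estimator.kneighbors(x)
    y = model._knn_y
    out = []
    class_rank = {c: r for r, c in enumerate(model.classes)}
    for di, ii in zip(dist, idx):
        votes: dict = {}
        nearest: dict = {}
        for d, j in zip(di, ii):
            lab = y[j]
            votes[lab] = votes.get(lab, 0) + 1
            if lab not in nearest or d < nearest[lab]:
                nearest[lab] = d
        # sort by (votes desc, nearest distance asc, class order asc)
        best = sorted(
            votes, key=lambda c: (-votes[c], nearest[c], class_rank[c])
        )[0]
        out.append(best)
    return np.asarray(out)


def predict(model: TrainedModel, features: LabeledFeatures | np.ndarray) -> np.ndarray:
    """Predict one label per row; labels are always from ``model.classes``."""
    x = features.matrix if isinstance(features, LabeledFeatures) else np.asarray(features, float)
    x = np.atleast_2d(x)
    if x.shape[1] != model.n_features:
        raise ContractError(
            f"model trained on {model.n_features} features, got {x.shape[1]}"
        )
    if model._scaler_mean is not None:
        x = (x - model._scaler_mean) / model._scaler_scale
    if model.spec.kind == "knn":
        return _knn_predict(model, x)
    return np.asarray(model._estimator.predict(x))


@dataclass
class CVResult:
    """Per-fold accuracies, their mean and dispersion, and the pooled
    confusion matrix over all held-out predictions."""

    fold_accuracies: tuple[float, ...]
    mean_accuracy: float
    std_accuracy: float
    k: int
    classes: tuple
    confusion: np.ndarray  # rows true, cols predicted, pooled over folds

    @property
    def total_correct(self) -> int:
        return int(np.trace(self.confusion))

    @property
    def total_count(self) -> int:
        return int(self.confusion.sum())


def make_folds(
    labels: np.ndarray,
    k: int,
    seed: int,
    stratified: bool = True,
    groups: np.ndarray | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Build a k-fold partition (list of train/test index pairs).

    Stratified folds keep per-fold class proportions within one sample
    of the global proportions.  With ``groups`` given, no group (e.g.
    subject) is split across train and test of any fold.
    """
    from sklearn.model_selection import KFold, StratifiedGroupKFold, StratifiedKFold

    labels = np.asarray(labels)
    if k < 2:
        raise FoldError(f"k must be >= 2, got {k}")
    if len(labels) < k:
        raise FoldError(f"cannot make {k} folds from {len(labels)} rows")
    seed = int(seed) % (2**31)
    if groups is not None:
        if len(np.unique(groups)) < k:
            raise FoldError(
                f"group-aware folding needs >= {k} distinct groups, got "
                f"{len(np.unique(groups))}; reduce k or disable --group-folds"
            )
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in splitter.split(labels[:, None], labels, groups)]
    if stratified:
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() < k:
            raise FoldError(
                f"stratified {k}-fold needs >= {k} members per class; smallest "
                f"class has {counts.min()} — reduce k or disable stratification"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(labels[:, None], labels)]


def cross_validate_folds(
    data: LabeledFeatures,
    spec: ClassifierSpec,
    folds: Sequence[tuple[np.ndarray, np.ndarray]],
) -> CVResult:
    """Evaluate a classifier on a pre-built fold partition."""
    classes = tuple(sorted(np.unique(data.labels).tolist()))
    class_idx = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    fold_acc: list[float] = []
    for tr, te in folds:
        train_data = LabeledFeatures(
            matrix=data.matrix[tr], labels=data.labels[tr]
        )
        model = train(spec, train_data)
        pred = predict(model, data.matrix[te])
        truth = data.labels[te]
        correct = int(np.sum(pred == truth))
        fold_acc.append(100.0 * correct / len(te))
        for t, p in zip(truth, pred):
            confusion[class_idx[t], class_idx[p]] += 1
    accs = tuple(fold_acc)
    return CVResult(
        fold_accuracies=accs,
        mean_accuracy=float(sum(accs) / len(accs)),
        std_accuracy=float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        k=len(folds),
        classes=classes,
        confusion=confusion,
    )


def kfold_cross_validate(
    data: LabeledFeatures,
    spec: ClassifierSpec,
    k: int = 10,
    seed: int = 0,
    stratified: bool = True,
    group_folds: bool = False,
) -> CVResult:
    """Stratified k-fold cross-validation of one classifier.

    Every row is held out exactly once; the overall accuracy is the
    arithmetic mean of the per-fold accuracies.  ``group_folds`` keeps
    all segments of one subject on the same side of every split.
    """
    folds = make_folds(
        data.labels, k, seed,
        stratified=stratified,
        groups=data.groups if group_folds else None,
    )
    return cross_validate_folds(data, spec, folds)


def run_grid(
    data: LabeledFeatures,
    statistics: Sequence[str],
    classifiers: Sequence[str],
    k: int = 10,
    seed: int = 0,
    stratified: bool = True,
    group_folds: bool = False,
    spec_overrides: dict | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], CVResult]]:
    """Cross-validate every (statistic, classifier) combination.

    ``data`` must carry column ordering metadata so each cell can be
    restricted to one statistic's columns.  The identical fold
    partition is reused for every cell, so cells are comparable.

    Returns a tidy summary DataFrame (statistic, classifier, mean, std,
    k, seed) and the full per-cell CVResult map.
    """
    from .dwt_features import STATISTICS

    for s in statistics:
        if s not in STATISTICS:
            raise ParameterError(f"unknown statistic {s!r}; valid: {STATISTICS}")
    for c in classifiers:
        if c not in CLASSIFIER_KINDS:
            raise ParameterError(f"unknown classifier {c!r}; valid: {CLASSIFIER_KINDS}")
    folds = make_folds(
        data.labels, k, seed,
        stratified=stratified,
        groups=data.groups if group_folds else None,
    )
    rows = []
    results: dict[tuple[str, str], CVResult] = {}
    for stat in statistics:
        sub = data.select_statistic(stat)
        for clf in classifiers:
            spec = ClassifierSpec(kind=clf, seed=seed, **(spec_overrides or {}))
            res = cross_validate_folds(sub, spec, folds)
            results[(stat, clf)] = res
            rows.append(
                {
                    "statistic": stat,
                    "classifier": clf,
                    "mean_accuracy": res.mean_accuracy,
                    "std_accuracy": res.std_accuracy,
                    "k": k,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows), results
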