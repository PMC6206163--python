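"""PCA preprocessing, tree ensembles, evaluation and persistence.

Training pipeline: PCA is fitted on the (unstandardized) training
feature matrix and truncated at the smallest component count explaining
95% of variance; 30 full-depth decision trees are then grown either on
bootstrap resamples (bagging, positive score = fraction of trees voting
positive) or by RUSBoost — AdaBoost-style rounds in which the majority
class is randomly undersampled to the minority count before each tree
is fitted, with learner weights scaled by a learning rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import joblib
import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import roc_curve
from sklearn.tree import DecisionTreeClassifier

from . import __version__
from .dataset import FEATURE_NAMES, LabeledDataset
from .errors import DegenerateSeriesError, EnhwalkError, SchemaError

DEFAULT_N_LEARNERS = 30
DEFAULT_LEARNING_RATE = 0.1
DEFAULT_VARIANCE_TARGET = 0.95
DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class PCATransform:
    mean_vector: np.ndarray
    components: np.ndarray  # (n_kept, n_features)
    explained_variance_ratios: np.ndarray  # all available ratios, descending
    n_kept: int
    scale_vector: Optional[np.ndarray] = None  # set when standardized

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = X - self.mean_vector
        if self.scale_vector is not None:
            Z = Z / self.scale_vector
        return Z @ self.components.T

    def inverse_transform(self, T: np.ndarray) -> np.ndarray:
        Z = T @ self.components
        if self.scale_vector is not None:
            Z = Z * self.scale_vector
        return Z + self.mean_vector


@dataclass
class TrainedModel:
    kind: str  # "bagged" | "rusboost"
    pca: PCATransform
    learners: list[DecisionTreeClassifier]
    seed: int
    feature_names: tuple[str, ...] = field(default=FEATURE_NAMES)
    learner_weights: Optional[np.ndarray] = None  # boosting only
    learning_rate: Optional[float] = None  # boosting only
    round_class_counts: Optional[list[tuple[int, int]]] = None  # boosting only
    n_learners_requested: int = DEFAULT_N_LEARNERS


@dataclass(frozen=True)
class EvaluationReport:
    auc: float
    accuracy: float
    roc_points: list[tuple[float, float]]  # (FPR, TPR), both non-decreasing
    threshold: float


def fit_pca(
    X: np.ndarray,
    variance_target: float = DEFAULT_VARIANCE_TARGET,
    standardize: bool = False,
) -> PCATransform:
    """PCA of the raw feature matrix, keeping the minimal number of
    components whose cumulative explained-variance ratio reaches
    ``variance_target``.

    By default columns are centered but *not* scaled, so high-count
    k-mer columns dominate the leading components.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise EnhwalkError("fit_pca needs a 2-D matrix with >= 2 samples")
    scale = None
    if standardize:
        scale = X.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0
        X = X / scale
    if np.allclose(X.var(axis=0), 0):
        raise DegenerateSeriesError("all rows identical: covariance is rank-zero")
    p = PCA(svd_solver="full", random_state=0)
    p.fit(X)
    ratios = p.explained_variance_ratio_
    n_kept = int(np.searchsorted(np.cumsum(ratios), variance_target) + 1)
    n_kept = min(n_kept, len(ratios))
    return PCATransform(
        mean_vector=p.mean_,
        components=p.components_[:n_kept],
        explained_variance_ratios=ratios,
        n_kept=n_kept,
        scale_vector=scale,
    )


def _check_two_classes(ds: LabeledDataset):
    pos, neg = ds.class_counts
    if pos == 0 or neg == 0:
        raise EnhwalkError("training data must contain both classes")


def train_bagged(
    train: LabeledDataset,
    n_learners: int = DEFAULT_N_LEARNERS,
    seed: int = 0,
    variance_target: float = DEFAULT_VARIANCE_TARGET,
    standardize: bool = False,
) -> TrainedModel:
    """Bootstrap-aggregated full-depth trees on the PCA-reduced matrix.

    Each tree sees an n-sized resample drawn uniformly with replacement;
    the ensemble score is the fraction of trees voting positive.
    """
    _check_two_classes(train)
    pca = fit_pca(train.X, variance_target, standardize)
    T = pca.transform(train.X)
    y = train.labels.astype(int)
    rng = np.random.default_rng(seed)
    n = len(y)
    learners = []
    for t in range(n_learners):
        idx = rng.integers(n, size=n)
        while len(np.unique(y[idx])) < 2:  # a usable tree needs both classes
            idx = rng.integers(n, size=n)
        tree = DecisionTreeClassifier(criterion="gini", random_state=int(seed + t))
        tree.fit(T[idx], y[idx])
        learners.append(tree)
    return TrainedModel(kind="bagged", pca=pca, learners=learners, seed=seed,
                        feature_names=train.feature_names,
                        n_learners_requested=n_learners)


def train_rusboost(
    train: LabeledDataset,
    n_learners: int = DEFAULT_N_LEARNERS,
    learning_rate: float = DEFAULT_LEARNING_RATE,
    seed: int = 0,
    variance_target: float = DEFAULT_VARIANCE_TARGET,
    standardize: bool = False,
) -> TrainedModel:
    """RUSBoost: AdaBoost.M1 rounds on randomly undersampled data.

    Each round draws all minority-class samples plus an equally sized
    uniform subsample of the majority class (exact 1:1 balance), fits a
    tree under the current sample weights, and updates weights with the
    usual multiplicative rule; learner weights alpha are scaled by
    ``learning_rate``. Boosting halts early if a round's weighted error
    reaches 0.5 (remaining learners unused).
    """
    _check_two_classes(train)
    pca = fit_pca(train.X, variance_target, standardize)
    T = pca.transform(train.X)
    y = train.labels.astype(int)
    rng = np.random.default_rng(seed)
    n = len(y)
    w = np.full(n, 1.0 / n)

    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    minority, majority = (pos_idx, neg_idx) if len(pos_idx) <= len(neg_idx) else (neg_idx, pos_idx)

    learners: list[DecisionTreeClassifier] = []
    alphas: list[float] = []
    round_counts: list[tuple[int, int]] = []
    for t in range(n_learners):
        sampled_maj = rng.choice(majority, size=len(minority), replace=False)
        idx = np.concatenate([minority, sampled_maj])
        tree = DecisionTreeClassifier(criterion="gini", random_state=int(seed + t))
        sw = w[idx]
        tree.fit(T[idx], y[idx], sample_weight=sw / sw.sum())
        pred = tree.predict(T)
        mis = pred != y
        err = float(w[mis].sum() / w.sum())
        if err >= 0.5:
            break
        err = max(err, 1e-10)
        alpha = learning_rate * float(np.log((1 - err) / err))
        w = w * np.exp(alpha * mis)
        w = w / w.sum()
        learners.append(tree)
        alphas.append(alpha)
        n_pos_round = int((y[idx] == 1).sum())
        round_counts.append((n_pos_round, len(idx) - n_pos_round))
    if not learners:
        raise EnhwalkError("boosting produced no usable learner (first round error >= 0.5)")
    return TrainedModel(
        kind="rusboost", pca=pca, learners=learners, seed=seed,
        feature_names=train.feature_names, learner_weights=np.array(alphas),
        learning_rate=learning_rate, round_class_counts=round_counts,
        n_learners_requested=n_learners,
    )


def _resolve_matrix(
    model: TrainedModel, X: Union[LabeledDataset, np.ndarray],
    feature_names: Optional[Sequence[str]] = None,
) -> np.ndarray:
    if isinstance(X, LabeledDataset):
        feature_names = X.feature_names
        X = X.X
    X = np.asarray(X, dtype=float)
    if feature_names is not None and tuple(feature_names) != tuple(model.feature_names):
        extra = set(feature_names) - set(model.feature_names)
        missing = set(model.feature_names) - set(feature_names)
        raise SchemaError(
            f"feature registry mismatch: missing {sorted(missing)[:5]}..., "
            f"unexpected {sorted(extra)[:5]}..."
            if missing or extra
            else "feature columns are in the wrong order"
        )
    if X.shape[1] != len(model.feature_names):
        raise SchemaError(
            f"expected {len(model.feature_names)} feature columns, got {X.shape[1]}"
        )
    return X


def predict_proba(
    model: TrainedModel,
    X: Union[LabeledDataset, np.ndarray],
    feature_names: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Positive-class score per sample.

    Bagging: fraction of trees voting positive. Boosting: alpha-weighted
    vote share. Hard labels come from thresholding at 0.5 (see
    :func:`predict_label`).
    """
    Xm = _resolve_matrix(model, X, feature_names)
    T = model.pca.transform(Xm)
    votes = np.stack([tree.predict(T) for tree in model.learners])  # (n_trees, n)
    if model.kind == "bagged":
        return votes.mean(axis=0)
    wts = model.learner_weights
    return (wts[:, None] * votes).sum(axis=0) / wts.sum()


def predict_label(
    model: TrainedModel,
    X: Union[LabeledDataset, np.ndarray],
    threshold: float = DEFAULT_THRESHOLD,
    feature_names: Optional[Sequence[str]] = None,
) -> np.ndarray:
    return (predict_proba(model, X, feature_names) >= threshold).astype(int)


def evaluate(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float = DEFAULT_THRESHOLD,
) -> EvaluationReport:
    """ROC over all distinct score thresholds, trapezoidal AUC, and
    accuracy of the thresholded labels."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    if len(np.unique(y)) < 2:
        raise EnhwalkError("AUC undefined: labels contain a single class")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    accuracy = float(np.mean((s >= threshold).astype(int) == y))
    return EvaluationReport(
        auc=auc,
        accuracy=accuracy,
        roc_points=[(float(a), float(b)) for a, b in zip(fpr, tpr)],
        threshold=threshold,
    )


def cross_validate(
    ds: LabeledDataset,
    kind: str = "bagged",
    n_folds: int = 10,
    seed: int = 0,
    **train_kwargs,
) -> list[float]:
    """Stratified k-fold AUC with PCA refit inside every fold."""
    from sklearn.model_selection import StratifiedKFold

    trainer = {"bagged": train_bagged, "rusboost": train_rusboost}[kind]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aucs = []
    for fold, (tr, te) in enumerate(skf.split(ds.X, ds.labels)):
        m = trainer(ds.subset(tr), seed=seed + fold, **train_kwargs)
        rep = evaluate(predict_proba(m, ds.subset(te)), ds.labels[te])
        aucs.append(rep.auc)
    return aucs


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a model bundle plus a JSON sidecar of its metadata."""
    path = Path(path)
    joblib.dump(model, path)
    sidecar = {
        "kind": model.kind,
        "n_learners": len(model.learners),
        "seed": model.seed,
        "pca_n_kept": model.pca.n_kept,
        "learning_rate": model.learning_rate,
        "n_features": len(model.feature_names),
        "feature_name_hash": f"{hash(model.feature_names) & 0xFFFFFFFF:08x}",
        "package_version": __version__,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> TrainedModel:
    try:
        model = joblib.load(path)
    except Exception as exc:  # corrupted archive -> clean error
        raise EnhwalkError(f"cannot load model from {path}: {exc}") from exc
    if not isinstance(model, TrainedModel):
        raise EnhwalkError(f"{path} does not contain a TrainedModel")
    return model
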