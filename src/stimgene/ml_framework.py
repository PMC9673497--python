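"""Normalization, class balancing, SVM training, feature selection, evaluation.

Features are clamp-and-scaled to [0,1] between their 5th and 95th training
percentiles.  The core classifier is an RBF-kernel SVM; KNN and random
forest serve as comparators.  Feature selection offers a forward pass (FFS)
and the AUC-driven subtractive iteration (ASI): repeatedly evaluate, on
frozen cross-validation folds, the AUC obtained by dropping each feature
alone and simultaneously remove every feature whose removal does not
decrease the baseline AUC.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

__all__ = [
    "CVPlan",
    "ClassifierSpec",
    "EvalReport",
    "ModelBundle",
    "fit_normalizer",
    "apply_normalizer",
    "fit_normalizer_table",
    "apply_normalizer_table",
    "undersample",
    "make_cv_plan",
    "cross_val_scores",
    "asi_select",
    "ffs_select",
    "metrics",
    "sn_n",
    "max_mcc_threshold",
    "rf_repeated_auc",
    "train_model",
    "predict_scores",
    "save_bundle",
    "load_bundle",
]


# --- normalization (5th/95th percentile clamp-and-scale) --------------------


def fit_normalizer(train_values: Sequence[float]) -> tuple[float, float]:
    """Lower/upper bounds (5th and 95th percentiles) from training values."""
    values = np.asarray(train_values, dtype=float)
    if values.size == 0:
        raise ValueError("no training values")
    return (float(np.percentile(values, 5)), float(np.percentile(values, 95)))


def apply_normalizer(value, lb: float, ub: float):
    """Clamp to [lb, ub] then scale linearly to [0, 1]; constant feature -> 0."""
    value = np.asarray(value, dtype=float)
    if ub <= lb:
        return np.zeros_like(value)
    return np.clip((value - lb) / (ub - lb), 0.0, 1.0)


def fit_normalizer_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-column bounds as a DataFrame with rows ``lb`` and ``ub``."""
    return pd.DataFrame(
        {col: fit_normalizer(frame[col].to_numpy()) for col in frame.columns},
        index=["lb", "ub"],
    )


def apply_normalizer_table(frame: pd.DataFrame, bounds: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for col in frame.columns:
        out[col] = apply_normalizer(
            frame[col].to_numpy(), bounds.at["lb", col], bounds.at["ub", col]
        )
    return pd.DataFrame(out, index=frame.index)


# --- balancing and cross-validation ----------------------------------------


def undersample(
    samples: pd.DataFrame, labels: Sequence[int], seed: int
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Downsample the majority class (without replacement) to the minority size.

    Returns ``(subset, subset_labels, kept_positional_indices)``;
    deterministic for a given seed and input order.
    """
    labels = np.asarray(labels).astype(int)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    rng = np.random.default_rng(seed)
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    keep = np.nonzero(labels == minority)[0]
    maj_idx = np.nonzero(labels == majority)[0]
    chosen = rng.choice(maj_idx, size=keep.size, replace=False)
    kept = np.sort(np.concatenate([keep, chosen]))
    return samples.iloc[kept], labels[kept], kept


@dataclass(frozen=True)
class CVPlan:
    """Frozen stratified fold assignment, reproducible from its seed."""

    k_folds: int
    fold: np.ndarray  # fold index per sample
    seed: int

    def splits(self):
        for k in range(self.k_folds):
            yield np.nonzero(self.fold != k)[0], np.nonzero(self.fold == k)[0]


def make_cv_plan(labels: Sequence[int], k_folds: int = 5, seed: int = 0) -> CVPlan:
    labels = np.asarray(labels).astype(int)
    splitter = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold = np.empty(labels.size, dtype=int)
    for k, (_, val) in enumerate(splitter.split(np.zeros(labels.size), labels)):
        fold[val] = k
    return CVPlan(k_folds=k_folds, fold=fold, seed=seed)


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier kind plus hyperparameters; ``svm``, ``knn`` or ``rf``."""

    kind: str = "svm"
    params: tuple = ()  # sorted (name, value) pairs, hashable

    @classmethod
    def svm(cls, C: float = 1.0, gamma="scale"):
        return cls("svm", (("C", C), ("gamma", gamma)))

    @classmethod
    def knn(cls, k: int = 20):
        return cls("knn", (("k", k),))

    @classmethod
    def rf(cls, n_trees: int = 50):
        return cls("rf", (("n_trees", n_trees),))

    def build(self, seed: int = 0):
        params = dict(self.params)
        if self.kind == "svm":
            # scores come from the squashed decision margin, so Platt-style
            # probability calibration is not needed
            return SVC(
                kernel="rbf",
                C=params.get("C", 1.0),
                gamma=params.get("gamma", "scale"),
                random_state=seed,
            )
        if self.kind == "knn":
            return KNeighborsClassifier(n_neighbors=params.get("k", 20))
        if self.kind == "rf":
            return RandomForestClassifier(
                n_estimators=params.get("n_trees", 50), random_state=seed
            )
        raise ValueError(f"unknown classifier kind {self.kind!r}")


def _score_samples(estimator, X: np.ndarray) -> np.ndarray:
    """Prediction scores in [0, 1] (probabilities, or squashed margins)."""
    if hasattr(estimator, "predict_proba"):
        try:
            return estimator.predict_proba(X)[:, 1]
        except AttributeError:  # SVC(probability=False)
            pass
    return expit(estimator.decision_function(X))


def cross_val_scores(
    features: pd.DataFrame,
    labels: Sequence[int],
    plan: CVPlan,
    classifier_spec: ClassifierSpec | None = None,
) -> tuple[np.ndarray, float]:
    """Out-of-fold scores (aligned to input order) and their pooled AUC.

    The percentile normalizer is fitted inside each training fold only.
    """
    spec = classifier_spec or ClassifierSpec.svm()
    labels = np.asarray(labels).astype(int)
    X = features.to_numpy(dtype=float)
    scores = np.empty(labels.size, dtype=float)
    for train_idx, val_idx in plan.splits():
        if np.unique(labels[train_idx]).size < 2 or np.unique(labels[val_idx]).size < 2:
            raise ValueError("a fold contains a single class")
        lb = np.percentile(X[train_idx], 5, axis=0)
        ub = np.percentile(X[train_idx], 95, axis=0)
        span = np.where(ub > lb, ub - lb, 1.0)
        zero = ub <= lb
        X_train = np.clip((X[train_idx] - lb) / span, 0.0, 1.0)
        X_val = np.clip((X[val_idx] - lb) / span, 0.0, 1.0)
        X_train[:, zero] = 0.0
        X_val[:, zero] = 0.0
        est = spec.build(seed=plan.seed)
        est.fit(X_train, labels[train_idx])
        scores[val_idx] = _score_samples(est, X_val)
    return scores, float(roc_auc_score(labels, scores))


# --- feature selection ------------------------------------------------------


def asi_select(
    features: pd.DataFrame,
    labels: Sequence[int],
    plan: CVPlan,
    classifier_spec: ClassifierSpec | None = None,
    max_iter: int = 50,
) -> tuple[list[str], pd.DataFrame]:
    """AUC-driven subtractive iteration over a frozen fold plan.

    Each iteration computes the baseline out-of-fold AUC of the current
    feature set, then the AUC obtained by dropping each feature alone; all
    features whose removal does not decrease the baseline are removed
    simultaneously.  Stops when no feature qualifies, one feature remains,
    or ``max_iter`` iterations have run.  The baseline AUC trajectory is
    non-decreasing by construction.
    """
    if features.shape[1] < 2:
        raise ValueError("at least 2 features required")
    current = list(features.columns)
    rows = []
    for iteration in range(1, max_iter + 1):
        scores, baseline = cross_val_scores(features[current], labels, plan, classifier_spec)
        threshold = max_mcc_threshold(scores, labels)
        mcc = metrics(scores, labels, threshold).mcc
        disruptive = []
        for name in current:
            remaining = [f for f in current if f != name]
            _, auc_without = cross_val_scores(
                features[remaining], labels, plan, classifier_spec
            )
            if auc_without >= baseline:
                disruptive.append(name)
        if len(disruptive) >= len(current):  # keep at least one feature
            disruptive = disruptive[:-1]
        rows.append(
            {"iteration": iteration, "auc": baseline, "mcc": mcc,
             "n_features": len(current), "n_removed": len(disruptive)}
        )
        if not disruptive or len(current) - len(disruptive) < 1:
            break
        current = [f for f in current if f not in disruptive]
        if len(current) == 1:
            break
    return current, pd.DataFrame(rows)


def ffs_select(
    features: pd.DataFrame,
    labels: Sequence[int],
    plan: CVPlan,
    classifier_spec: ClassifierSpec | None = None,
) -> list[str]:
    """Forward selection: rank by single-feature AUC, keep strict improvers."""
    if features.shape[1] < 1:
        raise ValueError("no features")
    singles = []
    for name in features.columns:
        _, auc = cross_val_scores(features[[name]], labels, plan, classifier_spec)
        singles.append((name, auc))
    singles.sort(key=lambda item: -item[1])
    selected = [singles[0][0]]
    _, best = cross_val_scores(features[selected], labels, plan, classifier_spec)
    for name, _ in singles[1:]:
        _, auc = cross_val_scores(features[selected + [name]], labels, plan, classifier_spec)
        if auc > best:
            selected.append(name)
            best = auc
    return selected


# --- evaluation -------------------------------------------------------------


@dataclass
class EvalReport:
    sensitivity: float
    specificity: float
    mcc: float
    auc: float
    sn_n: float
    n: int
    threshold: float


def _mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def sn_n(scores: Sequence[float], labels: Sequence[int], n: int) -> float:
    """Fraction of positives among the ``n`` highest-scoring samples.

    Ties are broken by descending score then stable input order.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if n > scores.size:
        raise ValueError("n exceeds sample count")
    order = np.argsort(-scores, kind="stable")
    return float(labels[order[:n]].sum() / n) if n else 0.0


def metrics(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> EvalReport:
    """Threshold-dependent and threshold-free evaluation of scores.

    The top-n sensitivity uses n = number of positive samples.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = scores >= threshold
    tp = int(((labels == 1) & pred).sum())
    fn = int(((labels == 1) & ~pred).sum())
    tn = int(((labels == 0) & ~pred).sum())
    fp = int(((labels == 0) & pred).sum())
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    auc = float(roc_auc_score(labels, scores)) if np.unique(labels).size == 2 else 0.0
    n = int((labels == 1).sum())
    return EvalReport(
        sensitivity=sensitivity,
        specificity=specificity,
        mcc=_mcc(tp, fp, tn, fn),
        auc=auc,
        sn_n=sn_n(scores, labels, n),
        n=n,
        threshold=threshold,
    )


def max_mcc_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Threshold (midpoint of consecutive distinct scores) maximising MCC.

    Ties are broken toward the smaller threshold.  A single distinct score
    yields 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    distinct = np.unique(scores)
    if distinct.size < 2:
        return 0.5
    candidates = list((distinct[:-1] + distinct[1:]) / 2)
    if distinct[0] > 0:  # predict everything positive
        candidates.insert(0, distinct[0] / 2)
    if distinct[-1] < 1:  # predict everything negative
        candidates.append((distinct[-1] + 1) / 2)
    best_thr, best_mcc = candidates[0], -2.0
    for thr in candidates:
        pred = scores >= thr
        tp = int(((labels == 1) & pred).sum())
        fn = int(((labels == 1) & ~pred).sum())
        tn = int(((labels == 0) & ~pred).sum())
        fp = int(((labels == 0) & pred).sum())
        value = _mcc(tp, fp, tn, fn)
        if value > best_mcc:
            best_mcc, best_thr = value, thr
    return float(best_thr)


def rf_repeated_auc(
    features: pd.DataFrame,
    labels: Sequence[int],
    k_folds: int = 5,
    n_trees: int = 50,
    repeats: int = 10,
    seed: int = 0,
) -> tuple[float, float, list[float]]:
    """Random-forest comparator: mean and sd of AUC over repeated CV runs."""
    aucs = []
    for r in range(repeats):
        plan = make_cv_plan(labels, k_folds=k_folds, seed=seed + r)
        _, auc = cross_val_scores(
            features, labels, plan, ClassifierSpec.rf(n_trees=n_trees)
        )
        aucs.append(auc)
    arr = np.asarray(aucs)
    return float(arr.mean()), float(arr.std(ddof=1)), aucs


# --- model bundle -----------------------------------------------------------


@dataclass
class ModelBundle:
    """Trained classifier plus everything needed to score new genes."""

    spec: ClassifierSpec
    feature_names: list[str]
    bounds: pd.DataFrame  # rows lb/ub, columns = feature_names
    threshold: float
    seed: int
    estimator: object = field(repr=False, default=None)


def train_model(
    features: pd.DataFrame,
    labels: Sequence[int],
    classifier_spec: ClassifierSpec | None = None,
    k_folds: int = 5,
    seed: int = 0,
) -> tuple[ModelBundle, EvalReport]:
    """Fit a final model on all data; pick the threshold from OOF scores."""
    spec = classifier_spec or ClassifierSpec.svm()
    labels = np.asarray(labels).astype(int)
    plan = make_cv_plan(labels, k_folds=k_folds, seed=seed)
    oof_scores, _ = cross_val_scores(features, labels, plan, spec)
    threshold = max_mcc_threshold(oof_scores, labels)
    report = metrics(oof_scores, labels, threshold)
    bounds = fit_normalizer_table(features)
    est = spec.build(seed=seed)
    est.fit(apply_normalizer_table(features, bounds).to_numpy(), labels)
    bundle = ModelBundle(
        spec=spec,
        feature_names=list(features.columns),
        bounds=bounds,
        threshold=threshold,
        seed=seed,
        estimator=est,
    )
    return bundle, report


def predict_scores(bundle: ModelBundle, features: pd.DataFrame) -> np.ndarray:
    """Scores in [0,1] for new samples using the bundle's bounds and model."""
    X = apply_normalizer_table(features[bundle.feature_names], bundle.bounds)
    return _score_samples(bundle.estimator, X.to_numpy())


def save_bundle(bundle: ModelBundle, directory) -> None:
    """Serialize a bundle as a directory (manifest, bounds, blob, metadata)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.Series(bundle.feature_names, name="feature").to_csv(
        directory / "features.tsv", sep="\t", index=False
    )
    bundle.bounds.to_csv(directory / "bounds.tsv", sep="\t")
    joblib.dump(bundle.estimator, directory / "classifier.joblib")
    meta = {
        "kind": bundle.spec.kind,
        "params": list(bundle.spec.params),
        "threshold": bundle.threshold,
        "seed": bundle.seed,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def load_bundle(directory) -> ModelBundle:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    names = pd.read_csv(directory / "features.tsv", sep="\t")["feature"].tolist()
    bounds = pd.read_csv(directory / "bounds.tsv", sep="\t", index_col=0)
    return ModelBundle(
        spec=ClassifierSpec(meta["kind"], tuple(tuple(p) for p in meta["params"])),
        feature_names=names,
        bounds=bounds,
        threshold=meta["threshold"],
        seed=meta["seed"],
        estimator=joblib.load(directory / "classifier.joblib"),
    )
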