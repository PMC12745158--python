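"""Glioma grade classification from per-region cfDNA fragment-count features.

WHO grades II and III are the low-grade class, grade IV the high-grade class.
Features are CPM-normalized fragment counts in a fixed set of marker regions.
The cohort is split 7:3 stratified by class; an XGBoost gradient-boosted tree
model is tuned by stratified 10-fold cross-validation over a small fixed grid
on the training split, refit on the full training split, and evaluated by AUC
with a stratified-bootstrap percentile confidence interval on both splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .genomic_io import (
    CountMatrix,
    FragmentsLike,
    GenomicInterval,
    ValidationError,
    count_overlaps,
)
from .subtype_differential import normalize_cpm
from .stats import auc_score

LOW_GRADES = frozenset({"II", "III"})
HIGH_GRADES = frozenset({"IV"})

DEFAULT_GRID = {
    "max_depth": (2, 3),
    "learning_rate": (0.1, 0.3),
    "n_estimators": (50, 150),
}


@dataclass
class LabeledCohort:
    samples: list[str]
    features: pd.DataFrame  # samples x regions (CPM)
    grade: dict[str, str]
    label: dict[str, str]  # low | high


@dataclass
class ClassifierReport:
    auc_train: float
    auc_train_ci: tuple[float, float]
    auc_test: float
    auc_test_ci: tuple[float, float]
    split_seed: int
    fold_count: int
    best_params: dict = field(default_factory=dict)
    importance: pd.Series | None = None

    def to_dict(self) -> dict:
        return {
            "auc_train": self.auc_train,
            "auc_train_ci": list(self.auc_train_ci),
            "auc_test": self.auc_test,
            "auc_test_ci": list(self.auc_test_ci),
            "split_seed": self.split_seed,
            "fold_count": self.fold_count,
            "best_params": self.best_params,
            "importance": None
            if self.importance is None
            else self.importance.to_dict(),
        }


def label_grades(grades: Mapping[str, str]) -> dict[str, str]:
    """Map WHO grades to binary labels: II/III -> low, IV -> high."""
    out = {}
    for sample, grade in grades.items():
        if grade in LOW_GRADES:
            out[sample] = "low"
        elif grade in HIGH_GRADES:
            out[sample] = "high"
        else:
            raise ValidationError(f"unknown WHO grade {grade!r} for sample {sample}")
    return out


def build_feature_matrix(
    regions: Sequence[GenomicInterval],
    fragments: FragmentsLike,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """CPM feature matrix (samples x regions) from fragment overlap counts."""
    if not regions:
        raise ValidationError("region list is empty")
    if len(set(regions)) != len(regions):
        raise ValidationError("duplicate regions in feature region list")
    cm = count_overlaps(regions, fragments, samples=samples)
    cpm = normalize_cpm(cm)
    return pd.DataFrame(
        cpm.T, index=cm.samples, columns=[r.region_id() for r in regions]
    )


def stratified_split(
    labels: Mapping[str, str], train_fraction: float = 0.7, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Random class-stratified train/test split, reproducible given seed."""
    by_class: dict[str, list[str]] = {}
    for sample, lab in labels.items():
        by_class.setdefault(lab, []).append(sample)
    if len(by_class) < 2:
        raise ValidationError("both classes must be present")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for lab in sorted(by_class):
        members = sorted(by_class[lab])
        if len(members) < 2:
            raise ValidationError(f"class {lab!r} has fewer than 2 samples")
        perm = rng.permutation(len(members))
        n_train = int(np.floor(train_fraction * len(members) + 0.5))
        n_train = min(max(n_train, 1), len(members) - 1)
        train.extend(members[i] for i in perm[:n_train])
        test.extend(members[i] for i in perm[n_train:])
    return sorted(train), sorted(test)


def _encode(labels: Sequence[str]) -> np.ndarray:
    return np.asarray([1 if l == "high" else 0 for l in labels])


def train_gbdt(
    features: pd.DataFrame,
    labels: Sequence[str],
    folds: int = 10,
    seed: int = 0,
    grid: Mapping[str, Sequence] = None,
) -> tuple[XGBClassifier, dict]:
    """Fit a gradient-boosted tree classifier with CV-chosen hyperparameters.

    A small fixed grid (depth, learning rate, boosting rounds) is scored by
    mean validation AUC over stratified `folds`-fold CV; the best setting is
    refit on the full training data. All randomness is seeded.
    """
    y = _encode(labels)
    if len(np.unique(y)) < 2:
        raise ValidationError("training labels contain a single class")
    grid = dict(grid or DEFAULT_GRID)
    X = features.to_numpy()
    folds = min(folds, int(np.bincount(y).min()))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best = None
    for depth in grid["max_depth"]:
        for lr in grid["learning_rate"]:
            for n_est in grid["n_estimators"]:
                aucs = []
                for tr, va in splits:
                    if len(np.unique(y[va])) < 2:
                        continue
                    model = _make_model(depth, lr, n_est, seed)
                    model.fit(X[tr], y[tr])
                    s = model.predict_proba(X[va])[:, 1]
                    aucs.append(auc_score(s[y[va] == 1], s[y[va] == 0]))
                mean_auc = float(np.mean(aucs))
                key = (mean_auc, -depth, -lr, -n_est)
                if best is None or key > best[0]:
                    best = (key, {"max_depth": depth, "learning_rate": lr,
                                  "n_estimators": n_est}, mean_auc)
    params = best[1]
    model = _make_model(params["max_depth"], params["learning_rate"],
                        params["n_estimators"], seed)
    model.fit(X, y)
    return model, {**params, "cv_auc": best[2], "folds": folds}


def _make_model(depth: int, lr: float, n_est: int, seed: int) -> XGBClassifier:
    return XGBClassifier(
        max_depth=depth,
        learning_rate=lr,
        n_estimators=n_est,
        random_state=seed,
        n_jobs=1,
        eval_metric="logloss",
        tree_method="hist",
        verbosity=0,
    )


def evaluate_auc(
    model,
    features: pd.DataFrame,
    labels: Sequence[str],
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """AUC with a stratified-bootstrap percentile 95% confidence interval."""
    y = _encode(labels)
    if len(np.unique(y)) < 2:
        raise ValidationError("evaluation labels contain a single class")
    scores = model.predict_proba(features.to_numpy())[:, 1]
    pos, neg = scores[y == 1], scores[y == 0]
    point = auc_score(pos, neg)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bp = pos[rng.integers(0, len(pos), len(pos))]
        bn = neg[rng.integers(0, len(neg), len(neg))]
        boots[b] = auc_score(bp, bn)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return point, (float(lo), float(hi))


def run_grade_classifier(
    features: pd.DataFrame,
    grades: Mapping[str, str],
    train_fraction: float = 0.7,
    folds: int = 10,
    seed: int = 0,
    n_boot: int = 2000,
) -> ClassifierReport:
    """End-to-end: label grades, 7:3 stratified split, CV-tuned fit, AUC report."""
    labels = label_grades(grades)
    train_ids, test_ids = stratified_split(labels, train_fraction, seed)
    X_train = features.loc[train_ids]
    X_test = features.loc[test_ids]
    y_train = [labels[s] for s in train_ids]
    y_test = [labels[s] for s in test_ids]
    model, fit_info = train_gbdt(X_train, y_train, folds=folds, seed=seed)
    auc_tr, ci_tr = evaluate_auc(model, X_train, y_train, n_boot=n_boot, seed=seed)
    auc_te, ci_te = evaluate_auc(model, X_test, y_test, n_boot=n_boot, seed=seed + 1)
    importance = pd.Series(
        model.feature_importances_, index=features.columns
    ).sort_values(ascending=False)
    return ClassifierReport(
        auc_train=auc_tr,
        auc_train_ci=ci_tr,
        auc_test=auc_te,
        auc_test_ci=ci_te,
        split_seed=seed,
        fold_count=fit_info["folds"],
        best_params={k: fit_info[k] for k in ("max_depth", "learning_rate", "n_estimators")},
        importance=importance,
    )
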