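"""Scoring functions S(c) used as the reinforcement-learning reward.

Two scorers behind one contract (a callable mapping a MoleculeRecord to a
ScoreResult in [0, 1]):

* the LogP range score — 1.0 for Crippen AlogP inside [2, 3], falling off as
  1 - tanh(distance to the interval) outside it;
* a calibrated SVM bioactivity model — a MinMax-kernel SVC on folded ECFP6
  count fingerprints, hyperparameters grid-searched for validation MCC, with
  Platt-scaled probabilistic output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import (
    balanced_accuracy_score,
    f1_score,
    matthews_corrcoef,
    roc_auc_score,
)
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC

from .chem import MoleculeRecord, canonicalize, crippen_logp, ecfp6_count_matrix

__all__ = [
    "ScoreResult",
    "score_from_alogp",
    "logp_range_score",
    "LogPRangeScorer",
    "minmax_kernel",
    "ActivityModel",
    "train_activity_model",
    "activity_score",
    "ActivityScorer",
    "evaluate_classifier",
]

LOGP_LOW = 2.0
LOGP_HIGH = 3.0


@dataclass(frozen=True)
class ScoreResult:
    value: float
    raw: Optional[float] = None


def score_from_alogp(alogp: float) -> float:
    """Piecewise range score: 1.0 on [2, 3], 1 - tanh(d) at distance d outside."""
    if LOGP_LOW <= alogp <= LOGP_HIGH:
        return 1.0
    d = min(abs(LOGP_LOW - alogp), abs(LOGP_HIGH - alogp))
    return 1.0 - math.tanh(d)


def logp_range_score(mol: MoleculeRecord) -> ScoreResult:
    """Score a molecule by its Crippen AlogP; invalid molecules score 0."""
    if not mol.is_valid:
        return ScoreResult(0.0, None)
    alogp = crippen_logp(mol)
    return ScoreResult(score_from_alogp(alogp), alogp)


class LogPRangeScorer:
    """Scorer-contract wrapper around :func:`logp_range_score`."""

    name = "logp_range"

    def __call__(self, mol: MoleculeRecord) -> ScoreResult:
        return logp_range_score(mol)


def minmax_kernel(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise MinMax kernel sum(min)/sum(max) between rows of count matrices.

    Uses the identity sum(min) = (|a| + |b| - L1(a, b)) / 2 for non-negative
    vectors. A pair of all-zero vectors has kernel value 0.
    """
    sa = a.sum(axis=1)
    sb = b.sum(axis=1)
    l1 = cdist(a, b, metric="cityblock")
    num = (sa[:, None] + sb[None, :] - l1) / 2.0
    den = (sa[:, None] + sb[None, :] + l1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(den > 0, num / den, 0.0)
    return k


@dataclass
class ActivityModel:
    """A trained, Platt-calibrated MinMax-kernel SVM bioactivity classifier."""

    svc: CalibratedClassifierCV
    train_features: np.ndarray
    regularization_c: float
    class_weighting: str  # "uniform" | "balanced"
    validation_mcc: float
    grid: list = field(default_factory=list, repr=False)

    def predict_proba_active(self, features: np.ndarray) -> np.ndarray:
        kernel = minmax_kernel(features, self.train_features)
        proba = self.svc.predict_proba(kernel)
        active_col = list(self.svc.classes_).index(1)
        return proba[:, active_col]


def _featurize(smiles: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Folded ECFP6 count matrix plus validity mask; invalids get zero rows."""
    records = [canonicalize(s) for s in smiles]
    valid = np.array([r.is_valid for r in records])
    mats = ecfp6_count_matrix([r if r.is_valid else canonicalize("C") for r in records])
    mats[~valid] = 0.0
    return mats, valid


def train_activity_model(
    train_smiles: Sequence[str],
    train_labels: Sequence[int],
    val_smiles: Sequence[str],
    val_labels: Sequence[int],
) -> ActivityModel:
    """Grid-search a MinMax-kernel SVC and Platt-calibrate the winner.

    The grid covers C in 10^-5 ... 10^5 (exponent step 1) crossed with uniform
    and frequency-balanced class weights; the model with the highest
    validation MCC wins, ties resolved toward uniform weights then smaller C.
    The winner is refit on the training set with probability estimates
    (Platt scaling on an internal 5-fold split).
    """
    y_train = np.asarray(train_labels, dtype=int)
    y_val = np.asarray(val_labels, dtype=int)
    if len(set(y_train.tolist())) < 2:
        raise ValueError("training set must contain both classes")
    if len(y_train) != len(train_smiles) or len(y_val) != len(val_smiles):
        raise ValueError("labels and SMILES must have equal lengths")
    x_train, _ = _featurize(train_smiles)
    x_val, _ = _featurize(val_smiles)
    k_train = minmax_kernel(x_train, x_train)
    k_val = minmax_kernel(x_val, x_train)

    best = None  # (mcc, weight_order, c) maximized lexicographically
    grid_records = []
    for class_weight in (None, "balanced"):
        for exponent in range(-5, 6):
            c = 10.0**exponent
            svc = SVC(kernel="precomputed", C=c, class_weight=class_weight)
            svc.fit(k_train, y_train)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mcc = matthews_corrcoef(y_val, svc.predict(k_val))
            grid_records.append({"C": c, "class_weight": class_weight or "uniform", "mcc": mcc})
            if best is None or mcc > best[0]:
                best = (mcc, class_weight, c)
    best_mcc, best_weight, best_c = best
    # Platt scaling on an internal 5-fold split of the training set
    final = CalibratedClassifierCV(
        SVC(kernel="precomputed", C=best_c, class_weight=best_weight),
        method="sigmoid",
        cv=5,
        ensemble=False,
    )
    final.fit(k_train, y_train)
    return ActivityModel(
        svc=final,
        train_features=x_train,
        regularization_c=best_c,
        class_weighting=best_weight or "uniform",
        validation_mcc=best_mcc,
        grid=grid_records,
    )


def activity_score(model: ActivityModel, mol: MoleculeRecord) -> ScoreResult:
    """Calibrated probability of the active class; invalid molecules score 0."""
    if not mol.is_valid:
        return ScoreResult(0.0, None)
    features, _ = _featurize([mol.canonical_smiles])
    proba = float(model.predict_proba_active(features)[0])
    return ScoreResult(proba, proba)


class ActivityScorer:
    """Scorer-contract wrapper around a trained :class:`ActivityModel`."""

    name = "activity"

    def __init__(self, model: ActivityModel) -> None:
        self.model = model

    def __call__(self, mol: MoleculeRecord) -> ScoreResult:
        return activity_score(self.model, mol)


def evaluate_classifier(
    model: ActivityModel, test_smiles: Sequence[str], test_labels: Sequence[int]
) -> dict:
    """balanced_accuracy, roc_auc, f1, mcc on a labeled test set.

    A single-class test set leaves roc_auc as NaN (undefined) with a warning;
    the other metrics are still computed.
    """
    y = np.asarray(test_labels, dtype=int)
    if len(y) == 0:
        raise ValueError("empty test set")
    x, _ = _featurize(test_smiles)
    proba = model.predict_proba_active(x)
    pred = (proba >= 0.5).astype(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        metrics = {
            "balanced_accuracy": balanced_accuracy_score(y, pred),
            "f1": f1_score(y, pred, zero_division=0),
            "mcc": matthews_corrcoef(y, pred),
        }
    if len(set(y.tolist())) < 2:
        warnings.warn("single-class test set: roc_auc is undefined")
        metrics["roc_auc"] = float("nan")
    else:
        metrics["roc_auc"] = roc_auc_score(y, proba)
    return {k: float(v) for k, v in metrics.items()}
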