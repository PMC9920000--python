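"""Classifier comparison under record-wise and patient-wise splits.

Six tree-ensemble classifiers are trained to detect claudication-modified
walking from the 155-feature windows, evaluated with stratified (record-wise)
or grouped (patient-wise) 10-fold cross-validation on the training side plus
a held-out test side, reporting accuracy, ROC-AUC, recall, precision and F1.

The two split strategies answer different questions: a record-wise split
mixes every patient's windows across train and test, so models may exploit
patient-specific idiosyncrasies; a patient-wise split holds out whole
patients and measures generalization to unseen subjects.  Each model uses a
fixed, documented hyperparameter set so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import GroupKFold, StratifiedKFold
from xgboost import XGBClassifier

METRIC_NAMES = ("accuracy", "auc", "recall", "precision", "f1")


def _make_xgboost(seed):
    return XGBClassifier(
        n_estimators=300, max_depth=6, learning_rate=0.1, subsample=0.9,
        colsample_bytree=0.9, eval_metric="logloss", random_state=seed,
        n_jobs=1, verbosity=0,
    )


def _make_lightgbm(seed):
    return LGBMClassifier(
        n_estimators=300, num_leaves=31, learning_rate=0.1, subsample=0.9,
        colsample_bytree=0.9, random_state=seed, n_jobs=1, verbose=-1,
    )


def _make_hist_gradient_boosting(seed):
    return HistGradientBoostingClassifier(
        max_iter=300, learning_rate=0.1, max_leaf_nodes=31, random_state=seed,
    )


def _make_random_forest(seed):
    return RandomForestClassifier(n_estimators=300, random_state=seed, n_jobs=1)


def _make_extra_trees(seed):
    return ExtraTreesClassifier(n_estimators=300, random_state=seed, n_jobs=1)


def _make_gradient_boosting(seed):
    return GradientBoostingClassifier(
        n_estimators=100, learning_rate=0.1, max_depth=3, random_state=seed,
    )


MODEL_REGISTRY = {
    "xgboost": _make_xgboost,
    "lightgbm": _make_lightgbm,
    "hist_gradient_boosting": _make_hist_gradient_boosting,
    "random_forest": _make_random_forest,
    "extra_trees": _make_extra_trees,
    "gradient_boosting": _make_gradient_boosting,
}


def make_model(name: str, seed: int = 0):
    """Instantiate a registry model with its fixed hyperparameters."""
    try:
        factory = MODEL_REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; registry: {sorted(MODEL_REGISTRY)}"
        ) from None
    return factory(seed)


@dataclass
class SplitPlan:
    """Train/test row indices under one split strategy."""

    strategy: str  # "records" | "patients"
    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int

    def __post_init__(self):
        tr, te = set(self.train_indices.tolist()), set(self.test_indices.tolist())
        if tr & te:
            raise ValueError("train and test indices overlap")

    @property
    def test_fraction(self) -> float:
        n = len(self.train_indices) + len(self.test_indices)
        return len(self.test_indices) / n


def split_records(ds, test_frac: float = 0.2, seed: int = 0) -> SplitPlan:
    """Uniform random row split, stratified by label."""
    y = np.asarray(ds.labels)
    if len(y) < 10:
        raise ValueError("need at least 10 rows")
    if len(np.unique(y)) < 2:
        raise ValueError("dataset contains a single class")
    rng = np.random.default_rng(seed)
    test_idx = []
    for cls in np.unique(y):
        rows = np.flatnonzero(y == cls)
        rng.shuffle(rows)
        n_test = int(round(test_frac * len(rows)))
        test_idx.append(rows[:n_test])
    test_idx = np.sort(np.concatenate(test_idx))
    train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
    return SplitPlan("records", train_idx, test_idx, seed)


def split_patients(ds, test_frac: float = 0.2, seed: int = 0) -> SplitPlan:
    """Assign whole patients to train or test.

    Best-first greedy assignment: repeatedly move the patient whose windows
    bring the realized test fraction closest to ``test_frac``, stopping when
    no move improves it; ties follow a seed-shuffled patient order.
    """
    pids = np.asarray(ds.patient_ids)
    patients = np.unique(pids)
    if len(patients) < 5:
        raise ValueError("need at least 5 patients for a patient-wise split")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(patients))
    sizes = {p: int(np.sum(pids == p)) for p in patients}
    total = len(pids)
    target = test_frac * total
    test_patients, n_test = [], 0
    while order:
        best = min(order, key=lambda p: abs(n_test + sizes[p] - target))
        if abs(n_test + sizes[best] - target) >= abs(n_test - target):
            break
        test_patients.append(best)
        order.remove(best)
        n_test += sizes[best]
    if not test_patients:  # degenerate sizes: hold out at least one patient
        test_patients = [order[0]]
    test_mask = np.isin(pids, test_patients)
    plan = SplitPlan("patients", np.flatnonzero(~test_mask), np.flatnonzero(test_mask), seed)
    assert not (set(pids[plan.train_indices]) & set(pids[plan.test_indices]))
    return plan


def compute_metrics(y_true, y_pred, y_proba) -> dict:
    """The five reported metrics; AUC is NaN on a single-class side."""
    out = {
        "accuracy": accuracy_score(y_true, y_pred),
        "recall": recall_score(y_true, y_pred, zero_division=0),
        "precision": precision_score(y_true, y_pred, zero_division=0),
        "f1": f1_score(y_true, y_pred, zero_division=0),
    }
    if len(np.unique(y_true)) < 2:
        out["auc"] = float("nan")
    else:
        out["auc"] = roc_auc_score(y_true, y_proba)
    return {k: float(out[k]) for k in METRIC_NAMES}


def evaluate(model, X, y) -> dict:
    """Evaluate a fitted model on one side (probability threshold 0.5)."""
    import warnings as _warnings

    with _warnings.catch_warnings():
        # lightgbm's sklearn wrapper invents feature names for ndarray input
        # and then warns when predicting on the same ndarray type
        _warnings.filterwarnings("ignore", message=".*does not have valid feature names.*")
        proba = model.predict_proba(X)[:, 1]
    pred = (proba >= 0.5).astype(int)
    return compute_metrics(y, pred, proba)


def crossval_train(
    model_name: str,
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray | None = None,
    K: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """K-fold cross-validation with per-fold metric rows.

    Stratified folds for record-wise data; grouped folds (no patient in both
    a training fold and its validation fold) when ``groups`` is given.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y)
    if groups is None and K > counts.min():
        raise ValueError(f"K={K} exceeds the minority-class count {counts.min()}")
    if groups is not None:
        K = min(K, len(np.unique(groups)))
        splitter = GroupKFold(n_splits=K)
        folds = splitter.split(X, y, groups)
    else:
        splitter = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
        folds = splitter.split(X, y)
    rows = []
    for fold, (tr, va) in enumerate(folds):
        if groups is not None:
            assert not (set(groups[tr]) & set(groups[va])), "group leakage across folds"
        model = make_model(model_name, seed=seed)
        model.fit(X[tr], y[tr])
        row = evaluate(model, X[va], y[va])
        row["fold"] = fold
        rows.append(row)
    return pd.DataFrame(rows).set_index("fold")


def compare_models(
    ds,
    plan: SplitPlan,
    models=None,
    K: int = 10,
    seed: int = 0,
    group_cv: bool = True,
) -> pd.DataFrame:
    """Train-CV and held-out-test metric rows per model.

    In patient-wise mode the cross-validation folds are also grouped by
    patient (``group_cv``), so no patient leaks between a training fold and
    its validation fold.
    """
    models = list(models) if models is not None else sorted(MODEL_REGISTRY)
    X = ds.features.to_numpy(dtype=float)
    y = np.asarray(ds.labels, dtype=int)
    tr, te = plan.train_indices, plan.test_indices
    groups = None
    if plan.strategy == "patients" and group_cv:
        groups = np.asarray(ds.patient_ids)[tr]
    rows = []
    for name in models:
        cv = crossval_train(name, X[tr], y[tr], groups=groups, K=K, seed=seed)
        row = {"model": name, "side": "train_cv"}
        row.update(cv[list(METRIC_NAMES)].mean().to_dict())
        rows.append(row)
        model = make_model(name, seed=seed)
        model.fit(X[tr], y[tr])
        row = {"model": name, "side": "test"}
        row.update(evaluate(model, X[te], y[te]))
        rows.append(row)
    return pd.DataFrame(rows, columns=["model", "side", *METRIC_NAMES])
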