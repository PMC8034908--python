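"""SVM diagnostic model on the final markers with the balanced split scheme.

The training cohort balances the classes by drawing as many acute-stage MI
samples as there are CAD controls; the later MI stages (paired with the same
controls) form internal test sets, and a second cohort provides external
validation sets per stage.  Performance is summarized by the ROC curve swept
over the decision values, its trapezoid AUC (checked against the tie-corrected
Mann-Whitney identity on every evaluation) and the accuracy at decision
value 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .datasets import ExpressionDataset

__all__ = ["SplitScheme", "make_splits", "train_svm", "evaluate", "auc_mann_whitney"]


@dataclass
class SplitScheme:
    """Sample ids per split; CAD controls are reused across internal splits."""

    train: list[str]
    internal_tests: dict[str, list[str]]  # stage -> sample ids
    external_validations: dict[str, list[str]]
    seed: int = 0
    labels: dict[str, pd.Series] = field(default_factory=dict)  # split -> 0/1 labels


def _balanced_draw(samples: list[str], n: int, rng: np.random.Generator) -> list[str]:
    if len(samples) < n:
        warnings.warn(
            f"requested {n} samples but only {len(samples)} available; using all",
            stacklevel=3,
        )
        return list(samples)
    idx = rng.choice(len(samples), size=n, replace=False)
    return [samples[i] for i in sorted(idx)]


def make_splits(expr: ExpressionDataset, external: ExpressionDataset | None = None,
                seed: int = 0) -> SplitScheme:
    """Balanced train/internal-test/external-validation splits, deterministic.

    Train: as many MI_S1 samples as CAD controls (drawn at random) plus all
    controls.  Internal test per later stage: the same number of MI samples
    drawn from that stage plus the same controls.  External validation per
    stage of the second cohort: all its MI samples of that stage plus its
    controls.
    """
    rng = np.random.default_rng(seed)
    cad = expr.samples_in("CAD")
    n = len(cad)
    labels: dict[str, pd.Series] = {}

    def split_labels(mi_samples: list[str], controls: list[str]) -> pd.Series:
        ids = mi_samples + controls
        return pd.Series([1] * len(mi_samples) + [0] * len(controls), index=ids)

    train_mi = _balanced_draw(expr.samples_in("MI_S1"), n, rng)
    train = train_mi + cad
    labels["train"] = split_labels(train_mi, cad)

    internal: dict[str, list[str]] = {}
    for stage in ("MI_S2", "MI_S3", "MI_S4"):
        pool = expr.samples_in(stage)
        if not pool:
            continue
        mi = _balanced_draw(pool, n, rng)
        internal[stage] = mi + cad
        labels[f"test_{stage}"] = split_labels(mi, cad)

    external_splits: dict[str, list[str]] = {}
    if external is not None:
        ext_cad = external.samples_in("CAD")
        for stage in ("MI_S1", "MI_S2", "MI_S3", "MI_S4"):
            pool = external.samples_in(stage)
            if not pool:
                continue
            external_splits[stage] = pool + ext_cad
            labels[f"validation_{stage}"] = split_labels(pool, ext_cad)

    return SplitScheme(train=train, internal_tests=internal,
                       external_validations=external_splits, seed=seed,
                       labels=labels)


def train_svm(expr: ExpressionDataset, split: SplitScheme, markers: list[str],
              kernel: str = "linear", c_param: float = 1.0,
              n_folds: int = 10, seed: int = 0):
    """Fit the marker SVM on the training split; returns (model, cv_auc).

    Features are standardized by training mean/sd inside the model pipeline;
    cv_auc is the stratified ten-fold cross-validated AUC on the training
    split.
    """
    if not markers:
        raise ValueError("markers must be nonempty")
    if kernel not in ("linear", "rbf"):
        raise ValueError("kernel must be 'linear' or 'rbf'")
    y = split.labels["train"]
    if y.nunique() < 2:
        raise ValueError("training labels contain a single class")
    x = expr.values.loc[markers, y.index].to_numpy().T

    def fresh() -> Pipeline:
        return Pipeline([
            ("scale", StandardScaler()),
            ("svm", SVC(kernel=kernel, C=c_param, random_state=seed)),
        ])

    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aucs = []
    yv = y.to_numpy()
    for tr, te in cv.split(x, yv):
        fold = fresh().fit(x[tr], yv[tr])
        scores = fold.decision_function(x[te])
        aucs.append(auc_mann_whitney(yv[te], scores))
    model = fresh().fit(x, yv)
    model.marker_features_ = list(markers)
    return model, float(np.mean(aucs))


def auc_mann_whitney(y_true, scores) -> float:
    """AUC via the tie-corrected Mann-Whitney identity U / (n1 * n0)."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required for AUC")
    u = _sps.mannwhitneyu(s[y == 1], s[y == 0], alternative="two-sided").statistic
    return float(u / (n1 * n0))


def evaluate(model, expr: ExpressionDataset, labels: pd.Series) -> dict:
    """ROC/AUC/accuracy of a fitted model on one split.

    ROC sweeps every unique decision value; AUC is the trapezoid area and is
    asserted (1e-12) against the Mann-Whitney identity.  Accuracy uses the
    decision boundary at 0.  A one-class split yields auc = None with a flag.
    """
    x = expr.values.loc[model.marker_features_, labels.index].to_numpy().T
    y = labels.to_numpy()
    scores = model.decision_function(x)
    accuracy = float((np.where(scores > 0, 1, 0) == y).mean())
    if len(np.unique(y)) < 2:
        return {"roc": None, "auc": None, "accuracy": accuracy,
                "flag": "single-class split"}
    if np.ptp(scores) == 0:
        fpr, tpr = np.array([0.0, 1.0]), np.array([0.0, 1.0])
    else:
        fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    mw = auc_mann_whitney(y, scores)
    assert abs(auc - mw) < 1e-12, f"AUC {auc} != Mann-Whitney {mw}"
    return {
        "roc": pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        "auc": auc,
        "accuracy": accuracy,
        "n": int(len(y)),
    }
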