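"""Per-node and per-pair LDA screening of network features as MI markers.

Every lncRNA, mRNA and lncRNA-mRNA edge of the ceRNA network is scored with a
stratified cross-validated linear-discriminant-analysis accuracy on two tasks:
diagnosis (acute MI vs stable CAD) and prognosis (heart failure vs no heart
failure after MI).  Units exceeding the accuracy threshold on BOTH tasks are
candidate markers; the final markers are candidates whose nodes are also
network hubs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .cerna import CeRNANetwork
from .datasets import ExpressionDataset

__all__ = ["MarkerReport", "lda_accuracy", "accuracy_distributions", "select_markers",
           "diagnosis_labels", "prognosis_labels"]

log = logging.getLogger(__name__)


@dataclass
class MarkerReport:
    candidates: pd.DataFrame  # unit_id, unit_kind, diagnosis, prognosis
    hubs: set[str]
    final_markers: list[str]
    threshold: float = 0.7
    notes: list[str] = field(default_factory=list)


def diagnosis_labels(expr: ExpressionDataset,
                     stage: str = "MI_S1") -> pd.Series:
    """0/1 labels for acute-stage MI vs stable CAD samples."""
    samples = expr.samples_in(stage, "CAD")
    grp = expr.group.loc[samples]
    return (grp == stage).astype(int)


def prognosis_labels(expr: ExpressionDataset,
                     stage: str = "MI_S1") -> pd.Series:
    """0/1 labels for HF vs noHF among acute-stage MI samples."""
    if expr.prognosis is None:
        raise ValueError("dataset carries no prognosis annotation")
    samples = [s for s in expr.samples_in(stage) if s in expr.prognosis.index]
    prog = expr.prognosis.loc[samples].dropna()
    return (prog == "HF").astype(int)


def lda_accuracy(expr: ExpressionDataset, unit, labels: pd.Series,
                 n_folds: int = 10, seed: int = 0) -> float:
    """Stratified k-fold cross-validated LDA accuracy of one node or pair.

    ``unit`` is a feature id or a tuple of feature ids (a pair uses the 2-D
    feature vector).  A unit whose pooled within-class variance vanishes is
    scored by the majority-class rule (flagged in the log).
    """
    features = [unit] if isinstance(unit, str) else list(unit)
    counts = labels.value_counts()
    if len(counts) != 2:
        raise ValueError("labels must contain exactly two classes")
    if counts.min() < n_folds:
        raise ValueError(
            f"both classes need >= n_folds={n_folds} samples, got {counts.to_dict()}"
        )
    x = expr.values.loc[features, labels.index].to_numpy().T
    y = labels.to_numpy()
    pooled_sd = np.concatenate(
        [x[y == cls] - x[y == cls].mean(axis=0) for cls in (0, 1)]
    ).std(axis=0)
    if np.any(pooled_sd == 0):
        log.info("lda_accuracy: degenerate unit %s scored by majority rule", features)
        return float(counts.max() / counts.sum())
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collinear pair features are tolerated
        scores = cross_val_score(LinearDiscriminantAnalysis(), x, y, cv=cv,
                                 scoring="accuracy")
    return float(scores.mean())


def accuracy_distributions(network: CeRNANetwork, expr: ExpressionDataset,
                           labels_by_task: dict[str, pd.Series],
                           n_folds: int = 10, seed: int = 0) -> pd.DataFrame:
    """Accuracy of every network lncRNA, mRNA and edge on every task.

    Returns a tidy frame (unit_id, unit_kind, task, accuracy, n_folds, seed);
    empty network -> empty frame.
    """
    units: list[tuple[str, str, object]] = []
    units += [(l, "lncRNA", l) for l in network.lnc_ids]
    units += [(m, "mRNA", m) for m in network.mrna_ids]
    units += [
        (f"{r.lnc_id}|{r.mrna_id}", "pair", (r.lnc_id, r.mrna_id))
        for r in network.edges.itertuples(index=False)
    ]
    rows = []
    for unit_id, kind, unit in units:
        for task, labels in labels_by_task.items():
            acc = lda_accuracy(expr, unit, labels, n_folds=n_folds, seed=seed)
            rows.append((unit_id, kind, task, acc, n_folds, seed))
    return pd.DataFrame(
        rows, columns=["unit_id", "unit_kind", "task", "accuracy", "n_folds", "seed"]
    )


def select_markers(records: pd.DataFrame, hubs: set[str],
                   threshold: float = 0.7) -> MarkerReport:
    """Candidates exceed ``threshold`` on both tasks; final markers are hub nodes.

    Pair units contribute their member nodes to the final marker set.
    """
    tasks = set(records["task"])
    if not {"diagnosis", "prognosis"} <= tasks:
        raise ValueError("records must cover both the diagnosis and prognosis tasks")
    wide = records.pivot_table(index=["unit_id", "unit_kind"], columns="task",
                               values="accuracy").reset_index()
    candidates = wide[(wide["diagnosis"] > threshold)
                      & (wide["prognosis"] > threshold)].reset_index(drop=True)
    final: list[str] = []
    for row in candidates.itertuples(index=False):
        nodes = row.unit_id.split("|") if row.unit_kind == "pair" else [row.unit_id]
        final += [n for n in nodes if n in hubs]
    final = sorted(set(final))
    notes = []
    if not final:
        notes.append("empty hub/candidate intersection")
        warnings.warn("no candidate marker is a network hub", stacklevel=2)
    return MarkerReport(candidates=candidates, hubs=set(hubs),
                        final_markers=final, threshold=threshold, notes=notes)
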