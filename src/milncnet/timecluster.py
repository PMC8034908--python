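"""Temporal trend clustering of stage-mean expression profiles.

Each feature is reduced to its mean expression per MI stage, standardized, and
the 4-point profiles are grouped into trend clusters by fuzzy c-means — the
soft analogue of k-means minimizing sum_ij u_ij^m d_ij^2 with row-stochastic
membership degrees u and fuzzifier m > 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .datasets import ExpressionDataset

__all__ = ["standardize_profiles", "FuzzyCMeans", "fuzzy_cmeans", "monotone_clusters"]

log = logging.getLogger(__name__)


def standardize_profiles(expr: ExpressionDataset,
                         stages: list[str]) -> pd.DataFrame:
    """Per-feature stage means, z-scored across stages (features x stages).

    Features whose stage means are constant carry no trend and are dropped
    (their count is logged).
    """
    if len(stages) < 2:
        raise ValueError("need at least 2 stages")
    means = {}
    for stage in stages:
        samples = expr.samples_in(stage)
        if not samples:
            raise ValueError(f"stage {stage!r} has no samples")
        means[stage] = expr.values[samples].mean(axis=1)
    profile = pd.DataFrame(means)
    sd = profile.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = int((~keep).sum())
    if dropped:
        log.info("standardize_profiles: dropped %d constant features", dropped)
    profile = profile[keep]
    return profile.sub(profile.mean(axis=1), axis=0).div(sd[keep], axis=0)


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Fuzzy c-means clustering with k-means++-style seeding.

    Alternating updates until the centroid shift falls below ``tol``:
    u_ij = 1 / sum_k (d_ij / d_ik)^(2/(m-1)),
    c_j = sum_i u_ij^m x_i / sum_i u_ij^m.
    The objective sum_ij u_ij^m d_ij^2 is nonincreasing across iterations.

    Parameters
    ----------
    n_clusters : number of clusters c.
    m : fuzzifier (> 1); 1.25 keeps memberships close to hard assignment.
    n_init : independent seedings; the run with the lowest objective is kept.

    Attributes (after fit)
    ----------------------
    cluster_centers_ : (c, p) centroid matrix.
    membership_ : (n, c) row-stochastic membership degrees.
    labels_ : argmax hard labels.
    objective_path_ : objective value per iteration of the winning run.
    """

    def __init__(self, n_clusters: int = 12, m: float = 1.25,
                 max_iter: int = 300, tol: float = 1e-6, n_init: int = 5,
                 random_state: int | None = 0):
        self.n_clusters = n_clusters
        self.m = m
        self.max_iter = max_iter
        self.tol = tol
        self.n_init = n_init
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _memberships(self, d2: np.ndarray) -> np.ndarray:
        """Membership update from squared distances, singularity-safe."""
        exact = d2 <= 1e-300
        power = 1.0 / (self.m - 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-power)
            u = inv / inv.sum(axis=1, keepdims=True)
        hit = exact.any(axis=1)
        if hit.any():
            u[hit] = exact[hit] / exact[hit].sum(axis=1, keepdims=True)
        return u

    def _init_centers(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """k-means++ seeding: spread initial centroids by squared distance."""
        n = x.shape[0]
        centers = [x[rng.integers(n)]]
        for _ in range(1, self.n_clusters):
            d2 = np.min(
                ((x[:, None, :] - np.array(centers)[None, :, :]) ** 2).sum(-1),
                axis=1,
            )
            total = d2.sum()
            if total <= 0:
                centers.append(x[rng.integers(n)])
                continue
            centers.append(x[rng.choice(n, p=d2 / total)])
        return np.array(centers)

    def _run(self, x: np.ndarray, rng: np.random.Generator):
        centers = self._init_centers(x, rng)
        path = []
        iters = 0
        for iters in range(1, self.max_iter + 1):
            d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
            u = self._memberships(d2)
            um = u**self.m
            path.append(float((um * d2).sum()))
            new_centers = (um.T @ x) / um.sum(axis=0)[:, None]
            shift = np.abs(new_centers - centers).max()
            centers = new_centers
            if shift < self.tol:
                break
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        u = self._memberships(d2)
        path.append(float((u**self.m * d2).sum()))
        return centers, u, path, iters

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y=None):
        if self.m <= 1.0:
            raise ValueError("fuzzifier m must be > 1")
        x = validate_data(self, X, ensure_min_samples=2)
        if x.shape[0] < self.n_clusters:
            raise ValueError(
                f"n_samples={x.shape[0]} < n_clusters={self.n_clusters}"
            )
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(max(1, self.n_init)):
            centers, u, path, iters = self._run(x, rng)
            if best is None or path[-1] < best[2][-1]:
                best = (centers, u, path, iters)
        (self.cluster_centers_, self.membership_,
         self.objective_path_, self.n_iter_) = best
        self.labels_ = self.membership_.argmax(axis=1)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def predict(self, X):
        check_is_fitted(self)
        x = validate_data(self, X, reset=False)
        d2 = ((x[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(-1)
        return self._memberships(d2).argmax(axis=1)


def fuzzy_cmeans(profiles: pd.DataFrame, c: int = 12, m: float = 1.25,
                 max_iter: int = 300, tol: float = 1e-6,
                 seed: int | None = 0) -> tuple[FuzzyCMeans, pd.Series]:
    """Cluster standardized trend profiles; returns the fitted model and
    hard labels ("Cluster1".."Clusterc") indexed by feature."""
    model = FuzzyCMeans(n_clusters=c, m=m, max_iter=max_iter, tol=tol,
                        random_state=seed)
    model.fit(profiles.to_numpy())
    labels = pd.Series(
        [f"Cluster{k + 1}" for k in model.labels_], index=profiles.index
    )
    return model, labels


def monotone_clusters(model: FuzzyCMeans) -> list[str]:
    """Cluster labels whose centroid is strictly monotone over the stages.

    These are the sustained up- and down-regulation patterns singled out for
    downstream network contexts.
    """
    out = []
    for k, center in enumerate(model.cluster_centers_):
        diffs = np.diff(center)
        if np.all(diffs > 0) or np.all(diffs < 0):
            out.append(f"Cluster{k + 1}")
    return out
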