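"""Weighted co-expression network construction and module detection.

The network is unsigned: adjacency a_mn = |cor(m, n)|^beta with beta chosen by
the scale-free topology criterion.  The adjacency is converted into the
topological overlap matrix (TOM); modules are clusters of the average-linkage
dendrogram of the 1-TOM dissimilarity, cut at a fixed height, with small
clusters left unassigned and near-duplicate modules merged by eigengene
correlation.  A module eigengene (ME) is the first principal component of the
module's standardized expression submatrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps
from scipy.cluster import hierarchy as _hier
from scipy.spatial.distance import squareform

from .datasets import ExpressionDataset
from .stats import holm_adjust, hypergeom_lower_tail, hypergeom_upper_tail

__all__ = [
    "UNASSIGNED",
    "ModuleAssignment",
    "adjacency",
    "tom_similarity",
    "scale_free_fit",
    "pick_soft_threshold",
    "detect_modules",
    "module_eigengenes",
    "module_trait_correlation",
    "lnc_proportion_test",
]

log = logging.getLogger(__name__)

UNASSIGNED = "grey"


@dataclass
class ModuleAssignment:
    """Feature -> module map plus eigengenes and linkage tree."""

    module_of: pd.Series  # feature -> label (UNASSIGNED for no module)
    eigengenes: pd.DataFrame  # samples x modules
    var_explained: dict[str, float]
    linkage: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def module_sizes(self) -> pd.Series:
        assigned = self.module_of[self.module_of != UNASSIGNED]
        return assigned.value_counts()

    @property
    def modules(self) -> list[str]:
        return sorted(self.module_sizes.index.tolist())


def _correlation_matrix(values: np.ndarray, feature_ids) -> np.ndarray:
    sd = values.std(axis=1, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [feature_ids[i] for i in zero[:5]]
        raise ValueError(f"zero-variance features: {names}")
    return np.corrcoef(values)


def adjacency(expr: ExpressionDataset, beta: int) -> pd.DataFrame:
    """Unsigned power adjacency |Pearson cor|^beta with unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    corr = _correlation_matrix(expr.values.to_numpy(), expr.feature_ids)
    adj = np.abs(corr) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=expr.feature_ids, columns=expr.feature_ids)


def tom_similarity(adj: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Unsigned topological overlap.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), where
    L_ij = sum_u a_iu a_uj over u != i, j and k_i = sum_u a_iu over u != i.
    """
    a = np.asarray(adj, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be a symmetric square matrix")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # zero diagonal already excludes u == i and u == j terms
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / denom
    tom = np.where(denom > 0, tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    if isinstance(adj, pd.DataFrame):
        return pd.DataFrame(tom, index=adj.index, columns=adj.columns)
    return tom


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """R^2 and slope of the log10(freq) ~ log10(mean k) fit over equal log-width bins."""
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 3:
        raise ValueError("too few positive connectivities to bin")
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(logk, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 3:
        raise ValueError("too few occupied bins for the scale-free fit")
    fit = _sps.linregress(xs, ys)
    return float(fit.rvalue**2), float(fit.slope)


DEFAULT_UNSIGNED_POWER = 6


def pick_soft_threshold(expr: ExpressionDataset,
                        powers=tuple(range(1, 21)),
                        r2_cut: float = 0.85) -> tuple[pd.DataFrame, int]:
    """Scale-free topology criterion for the soft-thresholding power.

    Returns the per-power table (beta, scale_free_r2, slope, mean_connectivity)
    and the smallest beta whose fit reaches ``r2_cut`` with a negative slope.
    If no power qualifies (connectivity not scale-free, common for strongly
    modular data), the conventional unsigned-network default power 6 is
    returned with a warning, following standard co-expression practice.
    """
    if len(powers) == 0:
        raise ValueError("powers must be nonempty")
    if expr.values.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if expr.values.shape[0] < 3:
        raise ValueError("too few features to bin connectivities")
    values = expr.values.to_numpy()
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = int((~keep).sum())
    if dropped:
        log.info("pick_soft_threshold: removed %d constant features", dropped)
        values = values[keep]
    abscorr = np.abs(np.corrcoef(values))
    np.fill_diagonal(abscorr, 0.0)
    rows = []
    for beta in powers:
        k = (abscorr**beta).sum(axis=1)
        r2, slope = scale_free_fit(k)
        rows.append((int(beta), r2, slope, float(k.mean())))
    table = pd.DataFrame(
        rows, columns=["beta", "scale_free_r2", "slope", "mean_connectivity"]
    )
    ok = table[(table["scale_free_r2"] >= r2_cut) & (table["slope"] < 0)]
    if len(ok):
        chosen = int(ok["beta"].iloc[0])
    else:
        in_range = [int(b) for b in powers if b == DEFAULT_UNSIGNED_POWER]
        chosen = in_range[0] if in_range else int(
            table.loc[table["scale_free_r2"].idxmax(), "beta"]
        )
        warnings.warn(
            f"no power reached scale-free R^2 >= {r2_cut}; "
            f"falling back to beta={chosen}",
            stacklevel=2,
        )
    return table, chosen


def module_eigengenes(expr: ExpressionDataset,
                      module_of: pd.Series) -> tuple[pd.DataFrame, dict[str, float]]:
    """First principal component per module, unit variance, sign-anchored.

    The eigengene sign is chosen so that it correlates positively with the
    module's mean standardized profile; var_explained is the share of the
    leading eigenvalue.
    """
    eigengenes = {}
    var_explained = {}
    for mod in sorted(set(module_of) - {UNASSIGNED}):
        members = module_of.index[module_of == mod]
        sub = expr.values.loc[members].to_numpy()
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError(f"module {mod} contains a zero-variance feature")
        z = (sub - mu) / sd
        if z.shape[0] == 1:
            warnings.warn(f"module {mod} has a single member", stacklevel=2)
            me, ve = z[0], 1.0
        else:
            u, s, vt = np.linalg.svd(z, full_matrices=False)
            me = vt[0]
            ve = float(s[0] ** 2 / (s**2).sum())
        me = me / me.std(ddof=1)
        anchor = z.mean(axis=0)
        if anchor.std() == 0:  # perfectly anti-correlated halves: anchor on row 1
            anchor = z[0]
        if np.corrcoef(me, anchor)[0, 1] < 0:
            me = -me
        eigengenes[mod] = me
        var_explained[mod] = ve
    frame = pd.DataFrame(eigengenes, index=expr.sample_ids)
    return frame, var_explained


def _relabel_by_size(module_of: pd.Series) -> pd.Series:
    sizes = module_of[module_of != UNASSIGNED].value_counts()
    mapping = {old: f"M{i + 1}" for i, old in enumerate(sizes.index)}
    mapping[UNASSIGNED] = UNASSIGNED
    return module_of.map(mapping)


def detect_modules(dissim: pd.DataFrame, expr: ExpressionDataset,
                   min_size: int = 30, cut_height: float | None = None,
                   merge_cut: float = 0.25) -> ModuleAssignment:
    """Average-linkage clustering of 1-TOM with static cut and eigengene merge.

    Clusters below ``min_size`` get the unassigned label; modules whose
    eigengenes satisfy 1 - cor(ME_i, ME_j) < ``merge_cut`` are merged
    iteratively until stable.  The default cut height is 0.99 on the
    dissimilarity scale, below which background features (pairwise TOM ~ 0)
    remain singletons.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if cut_height is None:
        cut_height = 0.99
    features = dissim.index
    d = np.asarray(dissim, dtype=float)
    linkage = _hier.linkage(squareform(d, checks=False), method="average")
    raw = _hier.fcluster(linkage, t=cut_height, criterion="distance")

    notes: list[str] = []
    labels = pd.Series([f"raw{c}" for c in raw], index=features)
    sizes = labels.value_counts()
    small = sizes.index[sizes < min_size]
    labels[labels.isin(small)] = UNASSIGNED
    if (labels == UNASSIGNED).all():
        notes.append("static cut produced no module of the minimum size")
        warnings.warn(notes[-1], stacklevel=2)
        empty = pd.DataFrame(index=expr.sample_ids)
        return ModuleAssignment(labels, empty, {}, linkage, notes)

    # iterative eigengene merge
    while True:
        mes, _ = module_eigengenes(expr, labels)
        mods = mes.columns.tolist()
        if len(mods) < 2:
            break
        corr = np.corrcoef(mes.to_numpy().T)
        np.fill_diagonal(corr, -np.inf)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if 1.0 - corr[i, j] >= merge_cut:
            break
        keep, drop = sorted((mods[i], mods[j]),
                            key=lambda m: -(labels == m).sum())
        labels[labels == drop] = keep
        notes.append(f"merged module {drop} into {keep}")

    labels = _relabel_by_size(labels)
    mes, ve = module_eigengenes(expr, labels)
    return ModuleAssignment(labels, mes, ve, linkage, notes)


def module_trait_correlation(eigengenes: pd.DataFrame, group: pd.Series,
                             traits: list[str],
                             significance: float = 1e-4) -> pd.DataFrame:
    """Pearson correlation of each eigengene with each 0/1 trait indicator.

    p follows the t-transform t = r sqrt((n-2)/(1-r^2)) with n-2 df, two-sided.
    """
    group = group.reindex(eigengenes.index)
    rows = []
    n = len(eigengenes)
    for trait in traits:
        indicator = (group == trait).to_numpy(dtype=float)
        if indicator.std() == 0:
            raise ValueError(f"trait {trait!r} is constant over the samples")
        for mod in eigengenes.columns:
            me = eigengenes[mod].to_numpy()
            r = float(np.corrcoef(me, indicator)[0, 1])
            if abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * np.sqrt((n - 2) / (1.0 - r**2))
                p = float(2.0 * _sps.t.sf(abs(t), df=n - 2))
            rows.append((mod, trait, r, p, p < significance))
    return pd.DataFrame(rows, columns=["module", "trait", "r", "p", "significant"])


def lnc_proportion_test(counts: pd.DataFrame, background_lnc: int = 1138,
                        background_pcg: int = 14099,
                        alternative: str = "lower") -> pd.DataFrame:
    """lncRNA depletion test per module/cluster against the platform background.

    Each row draws (lnc_count + pcg_count) features from an urn of
    ``background_lnc`` lncRNAs and ``background_pcg`` coding genes;
    the lower tail P(X <= lnc_count) tests for lncRNA depletion.  Rows with
    zero members are rejected; the adjusted column is Holm step-down over all
    finite rows.
    """
    required = {"tag", "lnc_count", "pcg_count"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts table must have columns {sorted(required)}")
    total = background_lnc + background_pcg
    out = counts.copy()
    pvals = []
    for _, row in counts.iterrows():
        lnc, pcg = int(row["lnc_count"]), int(row["pcg_count"])
        draw = lnc + pcg
        if draw < 1:
            raise ValueError(f"row {row['tag']!r} has zero members")
        if lnc > background_lnc or pcg > background_pcg:
            raise ValueError(f"row {row['tag']!r} exceeds the background universe")
        lower = hypergeom_lower_tail(lnc, total, background_lnc, draw)
        if alternative == "lower":
            p = lower
        elif alternative == "two-sided":
            upper = hypergeom_upper_tail(lnc, total, background_lnc, draw)
            p = min(1.0, 2.0 * min(lower, upper))
        else:
            raise ValueError("alternative must be 'lower' or 'two-sided'")
        pvals.append(p)
    out["p"] = pvals
    out["p_adjusted"] = holm_adjust(out["p"].to_numpy())
    return out
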