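"""Shared statistical primitives: multiple-testing adjustment and hypergeometric tails.

Both the familywise step-down (Holm) and the FDR step-up (Benjamini-Hochberg)
adjusters live here because different pipeline stages use different columns:
the module lncRNA-proportion table is adjusted step-down, while the enrichment
and ceRNA stages use FDR.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _sps

__all__ = [
    "holm_adjust",
    "bh_adjust",
    "hypergeom_lower_tail",
    "hypergeom_upper_tail",
]


def _validated(pvalues) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    finite = np.isfinite(p)
    if np.any((p[finite] <= 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return p, finite


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjustment, NaN entries passed through and excluded from m.

    Sorted ascending, adj_(i) = min(1, max_{j<=i} p_(j) * (m - j + 1)); the
    cumulative maximum enforces monotonicity and the original order is restored.
    """
    p, finite = _validated(pvalues)
    adjusted = np.full_like(p, np.nan)
    pf = p[finite]
    m = pf.size
    if m == 0:
        return adjusted
    order = np.argsort(pf, kind="mergesort")
    stepdown = pf[order] * (m - np.arange(m))
    stepdown = np.minimum(1.0, np.maximum.accumulate(stepdown))
    out = np.empty(m)
    out[order] = stepdown
    adjusted[finite] = out
    return adjusted


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, NaN entries passed through."""
    p, finite = _validated(pvalues)
    adjusted = np.full_like(p, np.nan)
    pf = p[finite]
    m = pf.size
    if m == 0:
        return adjusted
    order = np.argsort(pf, kind="mergesort")
    stepup = pf[order] * m / (np.arange(m) + 1)
    stepup = np.minimum(1.0, np.minimum.accumulate(stepup[::-1])[::-1])
    out = np.empty(m)
    out[order] = stepup
    adjusted[finite] = out
    return adjusted


def hypergeom_lower_tail(k: int, total: int, successes: int, draws: int) -> float:
    """P(X <= k) for X ~ Hypergeometric(total, successes, draws)."""
    return float(_sps.hypergeom.cdf(k, total, successes, draws))


def hypergeom_upper_tail(k: int, total: int, successes: int, draws: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(total, successes, draws)."""
    return float(_sps.hypergeom.sf(k - 1, total, successes, draws))
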