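"""Entity-level aggregation and group statistics.

The aggregation order of the assay is fixed: every parameter is measured on
each tissue section, section values are averaged per entity (one sponge or
lymph node; two specimens from the same mouse count as independent
entities), and groups are compared on the per-entity means — never on pooled
sections. Group results are reported as mean ± SEM, and between-group
comparisons use the two-sided Wilcoxon–Mann–Whitney rank-sum test.
"""
from __future__ import annotations

import math
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .errors import InsufficientDataError
from .types import ComparisonResult, GroupSummary, SpatialDensity
from .spatial import density_at

#: largest pooled sample size for which the exact permutation p-value is
#: enumerated; beyond it the tie-corrected normal approximation is used.
EXACT_ENUMERATION_LIMIT = 12


def entity_average(values: Sequence[float]) -> float:
    """Arithmetic mean of one entity's per-section values."""
    vals = np.asarray(list(values), float)
    if vals.size == 0:
        raise InsufficientDataError("entity has no section values")
    return float(vals.mean())


def average_curves(curves: Sequence[SpatialDensity],
                   support: np.ndarray) -> np.ndarray:
    """Pointwise mean of density curves resampled onto a common grid."""
    if len(curves) == 0:
        raise InsufficientDataError("no curves to average")
    support = np.asarray(support, float)
    resampled = np.stack([
        np.array([density_at(c, d) for d in support]) for c in curves
    ])
    return resampled.mean(axis=0)


def summarize_group(group: str, entity_values: Sequence[float]) -> GroupSummary:
    """Mean ± SEM (sample sd over sqrt(n)); SEM undefined for n = 1."""
    vals = [float(v) for v in entity_values]
    if len(vals) == 0:
        raise InsufficientDataError(f"group {group!r} has no entities")
    arr = np.asarray(vals, float)
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size >= 2 else None
    return GroupSummary(group=group, values=vals, n=arr.size,
                        mean=float(arr.mean()), sem=sem)


def _significance(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def mann_whitney_u(a: Sequence[float], b: Sequence[float],
                   labels: tuple[str, str] = ("a", "b")) -> ComparisonResult:
    """Two-sided Wilcoxon–Mann–Whitney test.

    U is computed from rank sums with midranks for ties. For pooled sizes up
    to :data:`EXACT_ENUMERATION_LIMIT` the two-sided p-value is exact, by
    enumerating all C(n1+n2, n1) group labelings and counting those whose U
    deviates from n1*n2/2 at least as much as observed. Larger samples use
    the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(list(a), float)
    y = np.asarray(list(b), float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise InsufficientDataError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    obs_dev = abs(u1 - mu)

    n = n1 + n2
    if n <= EXACT_ENUMERATION_LIMIT:
        hits = 0
        total = 0
        offs = n1 * (n1 + 1) / 2.0
        for idx in combinations(range(n), n1):
            u = ranks[list(idx)].sum() - offs
            if abs(u - mu) >= obs_dev - 1e-12:
                hits += 1
            total += 1
        p = hits / total
    else:
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts ** 3 - tie_counts).sum())) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            diff = u1 - mu
            cc = 0.5 * np.sign(diff)
            z = (diff - cc) / math.sqrt(sigma2)
            p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return ComparisonResult(groups=labels, U=u1, p_value=p,
                            significance=_significance(p))
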