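"""Cohort-level occurrence rates of variability categories.

Counts of subjects per category are treated as Poisson (variance equal to
the count), giving sqrt-count error bars on the fractions. Subjects
contributing several nights are down-weighted so each subject's weights sum
to one. Binary comparisons between proportions use a one-degree-of-freedom
chi-square on the 2x2 table, without continuity correction (switchable).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = ["category_fractions", "chi2_1df"]

CATEGORIES = ("a", "b", "c", "d")


def category_fractions(
    labels: Sequence[str],
    weights: Sequence[float] | None = None,
) -> dict[str, dict[str, float]]:
    """Weighted fraction of each category with a 1-s.d. Poisson error.

    ``weights`` defaults to 1 per label; with multiple nights per subject
    pass 1/n_nights per night so each subject sums to unity. The error on
    category k is sqrt(effective count_k) / total weight.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("empty cohort")
    if weights is None:
        weights = np.ones(len(labels))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(labels),):
        raise ValueError("weights must match labels")
    for lab in labels:
        if lab not in CATEGORIES:
            raise ValueError(f"unknown category {lab!r}")
    total = weights.sum()
    out: dict[str, dict[str, float]] = {}
    for cat in CATEGORIES:
        eff = float(sum(w for lab, w in zip(labels, weights) if lab == cat))
        out[cat] = {
            "fraction": eff / total,
            "sd": float(np.sqrt(eff)) / total,
            "effective_count": eff,
        }
    return out


def chi2_1df(count1: float, n1: float, count2: float, n2: float,
             correction: bool = False) -> tuple[float, float]:
    """One-df chi-square comparing two proportions (category vs rest).

    Returns ``(chi2, p)``; a degenerate table (zero marginal) gives
    ``(0, 1)``.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    table = np.array([[count1, n1 - count1], [count2, n2 - count2]], float)
    if np.any(table < 0):
        raise ValueError("counts cannot exceed group sizes")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return 0.0, 1.0
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)
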