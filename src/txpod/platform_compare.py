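"""Cross-platform concordance statistics and filtering-effect tests.

Fold-change regressions are performed on the log2 effect scale (signed fold
changes are mapped back to log2 differences to avoid the discontinuity at
+/-1); overlap statistics use case-normalized unique symbols; the
filtered-versus-unfiltered location test is a Welch two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .io_formats import TxpodError


@dataclass
class RegressionSummary:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def signed_fc_to_log2(fc) -> np.ndarray:
    """Invert the signed fold-change convention back to log2 differences."""
    fc = np.asarray(fc, dtype=float)
    if (np.abs(fc) < 1).any():
        raise TxpodError("signed fold changes have magnitude >= 1 by construction")
    with np.errstate(invalid="ignore"):
        return np.where(fc >= 0, np.log2(fc), -np.log2(-fc))


def fc_regression(fc_a: dict[str, float], fc_b: dict[str, float],
                  universe=None) -> RegressionSummary:
    """OLS of platform B on platform A log2 fold changes over shared genes.

    ``universe`` (typically the union of the two platforms' DEG lists)
    restricts the comparison; genes must be measured on both platforms.
    """
    keys = set(fc_a) & set(fc_b)
    if universe is not None:
        keys &= set(universe)
    genes = sorted(keys)
    if len(genes) < 3:
        raise TxpodError("need at least 3 shared genes for regression")
    x = signed_fc_to_log2([fc_a[g] for g in genes])
    y = signed_fc_to_log2([fc_b[g] for g in genes])
    res = stats.linregress(x, y)
    return RegressionSummary(slope=float(res.slope),
                             intercept=float(res.intercept),
                             r_squared=float(res.rvalue**2),
                             p_value=float(res.pvalue), n=len(genes))


def overlap_stats(lists_by_platform: dict[str, list[str]]) -> dict:
    """Pairwise (and overall) overlap counts and Jaccard indices.

    Symbols are case-normalized and deduplicated before comparison.
    """
    if len(lists_by_platform) < 2:
        raise TxpodError("need at least 2 platforms for overlap statistics")
    sets = {k: {g.upper() for g in v} for k, v in lists_by_platform.items()}
    out: dict = {"sizes": {k: len(v) for k, v in sets.items()}, "pairwise": {}}
    for a, b in combinations(sorted(sets), 2):
        inter = len(sets[a] & sets[b])
        union = len(sets[a] | sets[b])
        out["pairwise"][(a, b)] = {
            "intersection": inter,
            "union": union,
            "jaccard": inter / union if union else 0.0,
        }
    common = set.intersection(*sets.values())
    out["all_platforms_intersection"] = len(common)
    return out


def percent_in_pod_range(bmds, low: float = 2.6, high: float = 5.13) -> float:
    """Percent of BMDs inside the apical cancer PoD range (inclusive)."""
    arr = np.asarray(list(bmds), dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise TxpodError("empty BMD list")
    return float(100.0 * np.mean((arr >= low) & (arr <= high)))


def filtering_shift_test(values_a, values_b) -> float:
    """Welch two-sample t-test p between two BMD collections.

    Identical collections return p = 1 (t = 0) by convention.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 3 or len(b) < 3:
        raise TxpodError("each collection needs at least 3 values")
    if a.std() == 0 and b.std() == 0:
        if np.allclose(a.mean(), b.mean()):
            return 1.0
        raise TxpodError("degenerate zero-variance collections with unequal means")
    if len(a) == len(b) and np.allclose(np.sort(a), np.sort(b)):
        return 1.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)
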