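"""Immunohistochemistry marker statistics.

Marker values arrive already scored (semiquantitative 0-3 scales, absolute
counts, binary flags, H-scores); this module builds analysis variables from
them: H-score arithmetic, cutoff binarization, 2x2 cross-tabulations with
chi-square and Fisher tests, and rank-sum group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MARKER_SCALES",
    "MarkerMeasurement",
    "CrossTab",
    "h_score",
    "binarize",
    "round_half_up",
    "crosstab",
    "crosstab_from_counts",
    "frequency_table",
    "group_compare_continuous",
]

MARKER_SCALES = ("semiquant_0_3", "count", "binary", "hscore", "percent")


@dataclass(frozen=True)
class MarkerMeasurement:
    patient_id: str
    marker: str
    scale: str
    value: float

    def __post_init__(self) -> None:
        if self.scale not in MARKER_SCALES:
            raise ValueError(f"unknown marker scale {self.scale!r}")
        v = self.value
        ok = {
            "semiquant_0_3": v in (0, 1, 2, 3),
            "count": v >= 0,
            "binary": v in (0, 1),
            "hscore": 0 <= v <= 300,
            "percent": 0 <= v <= 100,
        }[self.scale]
        if not ok:
            raise ValueError(f"value {v} outside the {self.scale} scale")


def h_score(pct_neg: float, pct_low: float, pct_mod: float, pct_high: float) -> float:
    """H-score: 0*neg + 1*low + 2*moderate + 3*high staining percentages."""
    parts = (pct_neg, pct_low, pct_mod, pct_high)
    if any(p < 0 for p in parts):
        raise ValueError("percentages must be >= 0")
    if abs(sum(parts) - 100.0) > 1e-6:
        raise ValueError(f"percentages must sum to 100, got {sum(parts)}")
    return pct_low + 2.0 * pct_mod + 3.0 * pct_high


def binarize(values: Sequence[float], cutoff: float, rule: str = "ge") -> np.ndarray:
    """Dichotomize marker values at a cutoff; high = 1.

    ``rule='ge'`` calls value >= cutoff high (the convention for a 0-3 scale
    dichotomized at 2, i.e. scores 2-3 are 'high'); ``rule='gt'`` uses strict
    inequality.
    """
    arr = np.asarray(values, dtype=float)
    if rule == "ge":
        return (arr >= cutoff).astype(int)
    if rule == "gt":
        return (arr > cutoff).astype(int)
    raise ValueError(f"rule must be 'ge' or 'gt', got {rule!r}")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (matches typical report rounding, unlike banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CrossTab:
    counts: np.ndarray  # 2x2, rows = strata, cols = (positive, negative)
    row_labels: tuple[str, str]
    col_labels: tuple[str, str]
    row_percent: np.ndarray  # row percentages, half-up to one decimal
    chi2_p: float
    fisher_p: float
    n: int
    low_expected: bool  # any expected count < 5

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        df = pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)
        return (
            f"{df}\nchi2 p={self.chi2_p:.4g}  fisher p={self.fisher_p:.4g}"
            f"{'  (expected <5)' if self.low_expected else ''}"
        )


def crosstab_from_counts(
    counts,
    row_labels: tuple[str, str] = ("high", "low"),
    col_labels: tuple[str, str] = ("positive", "negative"),
    continuity: bool = False,
) -> CrossTab:
    """Cross-tabulation statistics from an explicit 2x2 count table."""
    table = np.asarray(counts, dtype=int)
    if table.shape != (2, 2):
        raise ValueError("counts must be 2x2")
    if (table < 0).any():
        raise ValueError("counts must be >= 0")
    n = int(table.sum())
    if n == 0:
        raise ValueError("empty table")
    row_tot = table.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * table / row_tot
    pct = np.vectorize(lambda v: round_half_up(v, 1) if np.isfinite(v) else np.nan)(pct)
    expected = row_tot * table.sum(axis=0, keepdims=True) / n
    low_expected = bool((expected < 5).any())
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        chi2_p = np.nan
    else:
        chi2_p = float(stats.chi2_contingency(table, correction=continuity)[1])
    fisher_p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return CrossTab(table, row_labels, col_labels, pct, chi2_p, fisher_p, n, low_expected)


def crosstab(
    strata: Sequence[float],
    outcome: Sequence[float],
    row_labels: tuple[str, str] = ("high", "low"),
    col_labels: tuple[str, str] = ("positive", "negative"),
    continuity: bool = False,
) -> CrossTab:
    """2x2 cross-tabulation of two binary vectors with pairwise NA deletion.

    Row 0 is ``strata == 1``; column 0 is ``outcome == 1``.
    """
    a = np.asarray(strata, dtype=float)
    b = np.asarray(outcome, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size == 0:
        raise ValueError("no complete pairs after deletion")
    if not set(np.unique(a)) <= {0.0, 1.0} or not set(np.unique(b)) <= {0.0, 1.0}:
        raise ValueError("inputs must be binary (0/1)")
    table = np.array(
        [
            [int(np.sum((a == 1) & (b == 1))), int(np.sum((a == 1) & (b == 0)))],
            [int(np.sum((a == 0) & (b == 1))), int(np.sum((a == 0) & (b == 0)))],
        ]
    )
    return crosstab_from_counts(table, row_labels, col_labels, continuity)


def frequency_table(values: Sequence[float]) -> pd.DataFrame:
    """Counts and round-half-up one-decimal percentages of a binary vector,
    with NA values dropped (the 'assessable' samples)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no assessable values")
    n = arr.size
    n_high = int(np.sum(arr == 1))
    n_low = int(np.sum(arr == 0))
    if n_high + n_low != n:
        raise ValueError("values must be binary (0/1)")
    return pd.DataFrame(
        {
            "group": ["high", "low"],
            "n": [n_high, n_low],
            "percent": [round_half_up(100.0 * n_high / n, 1), round_half_up(100.0 * n_low / n, 1)],
        }
    )


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumeration of all group assignments.

    Uses midranks, so ties are handled; the p-value is the fraction of
    assignments whose rank-sum deviates from its mean by at least as much as
    the observed one.
    """
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    n1 = x.size
    w_obs = ranks[:n1].sum()
    mu = ranks.sum() * n1 / ranks.size
    dev = abs(w_obs - mu)
    count = 0
    total = 0
    for idx in combinations(range(ranks.size), n1):
        w = ranks[list(idx)].sum()
        if abs(w - mu) >= dev - 1e-12:
            count += 1
        total += 1
    return count / total


def group_compare_continuous(values: Sequence[float], groups: Sequence[int]) -> float:
    """Two-sided Wilcoxon rank-sum p comparing values between two groups.

    Exact enumeration when both groups have <= 10 observations, otherwise a
    tie-corrected normal approximation.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    keep = ~np.isnan(v)
    v, g = v[keep], g[keep]
    levels = np.unique(g)
    if levels.size != 2:
        raise ValueError(f"need exactly two groups, got {levels.size}")
    x = v[g == levels[0]]
    y = v[g == levels[1]]
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if x.size <= 10 and y.size <= 10:
        return _exact_ranksum_p(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=False)
    return float(res.pvalue)
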