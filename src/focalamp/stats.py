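"""Association statistics: median splits of window element content,
breakpoint-frequency fold ratios with rank-sum tests, and Fisher exact
contingency tests for regional element enrichment.

Conventions: the two-sided Fisher p-value uses the probability-mass rule
(sum of hypergeometric probabilities of all tables, with the observed
margins, no more likely than the observed one). Ties at a median go to the
"below" stratum (strict > defines "above"). The Mann-Whitney U statistic is
reported for the first sample (U1, midranks for ties); the p-value is from
full enumeration when that is cheap and from the tie-corrected normal
approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "AssociationResult",
    "MedianSplit",
    "split_by_median",
    "breakpoint_fold_and_test",
    "fisher_exact_two_sided",
    "region_element_enrichment",
    "mann_whitney",
]


@dataclass
class ContingencyTable2x2:
    """2x2 count table; rows and columns carry labels for reporting."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("row1", "row2")
    col_labels: tuple[str, str] = ("col1", "col2")

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("contingency counts must be non-negative "
                                 "integers")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass
class AssociationResult:
    """Breakpoint frequency contrast between element-rich and element-poor
    windows."""

    element: str
    fold: float  # mean breakpoints per above-median window / below-median
    p_value: float
    n_above: int
    n_below: int
    infinite_fold: bool = False


@dataclass
class MedianSplit:
    element: str
    median: float
    above: np.ndarray  # boolean over the windows in scope
    degenerate: bool = False


def split_by_median(table: pd.DataFrame, element: str,
                    scope: np.ndarray | None = None) -> MedianSplit:
    """Label eligible windows as above (> median, strict) or below (<=)
    the median content of ``element`` within ``scope``.

    ``scope`` is a boolean mask over the table rows (default: all eligible
    windows). The returned ``above`` mask is False outside the scope. An
    all-equal content vector yields a degenerate split (flagged).
    """
    eligible = table["eligible"].to_numpy() if "eligible" in table else \
        np.ones(len(table), dtype=bool)
    mask = eligible if scope is None else (eligible & np.asarray(scope))
    if mask.sum() < 2:
        raise ValueError("need at least 2 eligible windows in scope")
    content = table[element].to_numpy(dtype=float)
    med = float(np.median(content[mask]))
    above = mask & (content > med)
    degenerate = np.ptp(content[mask]) == 0
    return MedianSplit(element=element, median=med, above=above,
                       degenerate=degenerate)


def breakpoint_fold_and_test(counts: np.ndarray, split: MedianSplit,
                             scope: np.ndarray | None = None,
                             eligible: np.ndarray | None = None
                             ) -> AssociationResult:
    """Fold ratio of breakpoint frequency between above- and below-median
    windows, with a two-sided rank-sum test of the per-window counts."""
    counts = np.asarray(counts, dtype=float)
    if eligible is None:
        eligible = np.ones(counts.size, dtype=bool)
    mask = eligible if scope is None else (eligible & np.asarray(scope))
    above = split.above & mask
    below = mask & ~split.above
    if not above.any() or not below.any():
        raise ValueError("both strata must be non-empty")
    xa, xb = counts[above], counts[below]
    mean_b = xb.mean()
    if mean_b == 0:
        fold, infinite = np.inf, True
    else:
        fold, infinite = float(xa.mean() / mean_b), False
    _, p = mann_whitney(xa, xb)
    return AssociationResult(element=split.element, fold=fold, p_value=p,
                             n_above=int(above.sum()),
                             n_below=int(below.sum()),
                             infinite_fold=infinite)


def fisher_exact_two_sided(t: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher exact test (probability-mass rule) and the
    conditional (sample) odds ratio. Returns (p, odds_ratio)."""
    arr = t.as_array()
    if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
        raise ValueError("all margins must be positive")
    odds, p = sps.fisher_exact(arr, alternative="two-sided")
    return float(p), float(odds)


def region_element_enrichment(table: pd.DataFrame, element: str,
                              region_a: np.ndarray,
                              region_b: np.ndarray,
                              median_scope: np.ndarray | None = None,
                              labels: tuple[str, str] = ("A", "B")
                              ) -> tuple[ContingencyTable2x2, float, float]:
    """Compare above/below-median window counts between two regions.

    The median is computed over ``median_scope`` (default: the whole
    eligible table, i.e. genome scope). Returns (table, p, odds ratio);
    table rows are regions, columns (above, below).
    """
    eligible = table["eligible"].to_numpy() if "eligible" in table else \
        np.ones(len(table), dtype=bool)
    region_a = np.asarray(region_a) & eligible
    region_b = np.asarray(region_b) & eligible
    if not region_a.any() or not region_b.any():
        raise ValueError("both regions must contain eligible windows")
    split = split_by_median(table, element, scope=median_scope)
    above = split.above
    ct = ContingencyTable2x2(
        a=int((region_a & above).sum()),
        b=int((region_a & ~above).sum()),
        c=int((region_b & above).sum()),
        d=int((region_b & ~above).sum()),
        row_labels=labels, col_labels=("above_median", "below_median"))
    if min(ct.a + ct.c, ct.b + ct.d) == 0:
        # all windows on one side of the median in both regions: the
        # table carries no association information
        return ct, 1.0, 1.0
    p, odds = fisher_exact_two_sided(ct)
    return ct, p, odds


# ---------------------------------------------------------------------------
# Mann-Whitney

_EXACT_MAX_TABLES = 200_000


def mann_whitney(xs, ys) -> tuple[float, float]:
    """Two-sided Mann-Whitney test. Returns (U1, p).

    U1 counts, with midranks for ties, how often an x precedes a y. The
    p-value is exact (full enumeration of group assignments of the pooled
    midranks) when min(n, m) <= 8 and the enumeration is small; otherwise
    the tie-corrected normal approximation on U is used.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    n, m = xs.size, ys.size
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([xs, ys])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n].sum()
    u1 = float(r1 - n * (n + 1) / 2)
    small = min(n, m)
    if small <= 8 and comb(n + m, small) <= _EXACT_MAX_TABLES:
        # exact permutation null of the rank sum of the smaller group
        k = small
        target = ranks[:n] if n <= m else ranks[n:]
        s_obs = target.sum()
        es = k * (n + m + 1) / 2.0
        dev = abs(s_obs - es)
        count = 0
        total = 0
        for idx in combinations(range(n + m), k):
            s = ranks[list(idx)].sum()
            if abs(s - es) >= dev - 1e-9:
                count += 1
            total += 1
        return u1, count / total
    # tie-corrected normal approximation
    mu = n * m / 2.0
    nm = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (nm * (nm - 1))
    sigma2 = n * m / 12.0 * ((nm + 1) - tie_term)
    if sigma2 <= 0:
        return u1, 1.0
    z = (u1 - mu) / np.sqrt(sigma2)
    return u1, float(2 * sps.norm.sf(abs(z)))
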