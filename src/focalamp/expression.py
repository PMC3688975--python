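"""Copy-number / expression integration.

Per gene, the copy-number dosage effect is summarized by a midrank
Spearman correlation between gene-level copy number and expression across
matched samples, with Benjamini-Hochberg control of the false discovery
rate across all tested genes, and by a two-sided Mann-Whitney comparison
of expression between amplified samples and the remainder of the
expression cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _permutations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix
from .stats import mann_whitney

__all__ = [
    "CorrelationResult",
    "GroupTestResult",
    "spearman_correlation",
    "spearman_cn_expression",
    "bh_fdr",
    "amplified_vs_rest_test",
    "rank_order_profile",
]

_EXACT_N_MAX = 9


@dataclass
class CorrelationResult:
    gene: str
    rho: float
    p_value: float
    q_value: float | None
    n: int
    degenerate: bool = False  # constant copy number or expression


@dataclass
class GroupTestResult:
    gene: str
    n_amplified: int
    n_rest: int
    p_value: float
    direction: str  # 'up' if amplified median higher, else 'down'/'none'


def spearman_correlation(x, y) -> tuple[float, float]:
    """Midrank Spearman rho with a p-value that is exact (full permutation
    enumeration) for n <= 9 and a t-approximation otherwise. Returns
    (rho, p); rho is NaN for constant inputs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= _EXACT_N_MAX:
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
        obs = abs(rx_c @ ry_c)
        count = 0
        total = 0
        for perm in _permutations(range(n)):
            if abs(rx_c @ ry_c[list(perm)]) >= obs - 1e-9:
                count += 1
            total += 1
        return rho, count / total
    t = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
    p = float(2 * sps.t.sf(abs(t), df=n - 2))
    return rho, min(1.0, p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def spearman_cn_expression(gene_cn: pd.DataFrame, expr: ExpressionMatrix,
                           min_samples: int = 3) -> list[CorrelationResult]:
    """Correlate gene copy number with expression, gene by gene.

    ``gene_cn`` is gene x sample (NaN = no copy-number estimate); samples
    are matched by id, missing cells excluded pairwise. q-values are BH
    over all genes that produced a p-value.
    """
    shared = [s for s in gene_cn.columns if s in expr.values.columns]
    results: list[CorrelationResult] = []
    for gene in gene_cn.index:
        if gene not in expr.values.index:
            continue
        cn = gene_cn.loc[gene, shared].to_numpy(dtype=float)
        ex = expr.values.loc[gene, shared].to_numpy(dtype=float)
        ok = np.isfinite(cn) & np.isfinite(ex)
        n = int(ok.sum())
        if n < min_samples:
            continue
        rho, p = spearman_correlation(cn[ok], ex[ok])
        results.append(CorrelationResult(
            gene=gene, rho=rho, p_value=p, q_value=None, n=n,
            degenerate=not np.isfinite(rho)))
    tested = [r for r in results if np.isfinite(r.p_value)]
    if tested:
        q = bh_fdr([r.p_value for r in tested])
        for r, qv in zip(tested, q):
            r.q_value = float(qv)
    return results


def amplified_vs_rest_test(expr: ExpressionMatrix,
                           amplified: dict[str, list[str]]
                           ) -> list[GroupTestResult]:
    """Per gene, compare expression in amplified samples vs the remainder
    of the expression cohort (two-sided Mann-Whitney).

    ``amplified`` maps gene id -> list of amplified sample ids. Genes
    whose amplified group is empty, or covers the whole cohort, are
    skipped.
    """
    results: list[GroupTestResult] = []
    cols = list(expr.values.columns)
    for gene, amp_samples in amplified.items():
        if gene not in expr.values.index:
            continue
        flags = np.array([s in set(amp_samples) for s in cols])
        vals = expr.values.loc[gene].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        flags, vals = flags[ok], vals[ok]
        if flags.sum() == 0 or flags.all():
            continue
        xs, ys = vals[flags], vals[~flags]
        _, p = mann_whitney(xs, ys)
        if np.median(xs) > np.median(ys):
            direction = "up"
        elif np.median(xs) < np.median(ys):
            direction = "down"
        else:
            direction = "none"
        results.append(GroupTestResult(gene=gene,
                                       n_amplified=int(flags.sum()),
                                       n_rest=int((~flags).sum()),
                                       p_value=p, direction=direction))
    return results


def rank_order_profile(expr: ExpressionMatrix, gene: str,
                       amplified_samples: list[str]) -> pd.DataFrame:
    """Samples ordered by expression of one gene (descending), flagged by
    amplification status — the data behind a waterfall panel."""
    vals = expr.values.loc[gene].astype(float).sort_values(ascending=False)
    amp = set(amplified_samples)
    return pd.DataFrame({
        "sample": vals.index,
        "expression": vals.to_numpy(),
        "amplified": [s in amp for s in vals.index],
    }).reset_index(drop=True)
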