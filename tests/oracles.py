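"""Independent brute-force oracles shared by the unit and acceptance
suites. Each re-derives its quantity from first principles (enumeration
or exhaustive scan) without touching the implementation under test."""

from __future__ import annotations

from itertools import combinations, permutations
from math import comb

import numpy as np
from scipy.stats import rankdata


def brute_force_best_arc(x: np.ndarray, min_probes: int = 5):
    """Exhaustive scan over every admissible circular arc (i, j): the arc
    maximizing |sum - k * total / n| * sqrt(n / (k (n - k)))."""
    n = len(x)
    total = x.sum()
    best, best_ij = -1.0, None
    for i in range(n + 1):
        for j in range(i + min_probes, n + 1):
            k = j - i
            if n - k < min_probes:
                continue
            if (0 < i < min_probes) or (n - min_probes < j < n):
                continue
            s = x[i:j].sum()
            z = abs(s - k * total / n) * np.sqrt(n / (k * (n - k)))
            if z > best + 1e-12:
                best, best_ij = z, (i, j)
    return best, best_ij


def brute_force_g4(seq: str, run_char: str = "G"):
    """Minimal-match quadruplex scan: at each position try loop lengths in
    lexicographic order, consume non-overlapping matches left to right."""

    def match_at(pos):
        def rec(p, runs_left):
            if seq[p:p + 3] != run_char * 3:
                return None
            p += 3
            if runs_left == 0:
                return p
            for loop in range(1, 8):
                chunk = seq[p:p + loop]
                if len(chunk) < loop or "N" in chunk:
                    break
                end = rec(p + loop, runs_left - 1)
                if end is not None:
                    return end
            return None

        return rec(pos, 3)

    hits = []
    i = 0
    while i <= len(seq) - 15:
        end = match_at(i)
        if end is not None:
            hits.append((i, end))
            i = end
        else:
            i += 1
    return hits


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by full enumeration over all tables with the
    observed margins, using exact integer hypergeometric masses."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    masses = {x: comb(r1, x) * comb(r2, c1 - x)
              for x in range(max(0, c1 - r2), min(r1, c1) + 1)}
    obs = masses[a]
    return sum(m for m in masses.values() if m <= obs) / denom


def mw_enumeration_oracle(xs, ys):
    """U (pairwise-comparison form) and exact two-sided p over every
    assignment of the pooled values to the two groups."""
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    pooled = np.concatenate([xs, ys])
    n, m = len(xs), len(ys)

    def u_stat(x_idx):
        xset = set(x_idx)
        x = pooled[list(x_idx)]
        y = pooled[[i for i in range(n + m) if i not in xset]]
        return float((x[:, None] > y[None, :]).sum()
                     + 0.5 * (x[:, None] == y[None, :]).sum())

    u_obs = u_stat(range(n))
    dev = abs(u_obs - n * m / 2)
    hits = total = 0
    for idx in combinations(range(n + m), n):
        total += 1
        hits += abs(u_stat(idx) - n * m / 2) >= dev - 1e-9
    return u_obs, hits / total


def spearman_enumeration_oracle(x, y):
    """Midrank Spearman rho and exact two-sided p by enumerating every
    pairing of the two vectors."""
    rx, ry = rankdata(x), rankdata(y)
    rho_obs = np.corrcoef(rx, ry)[0, 1]
    hits = total = 0
    for perm in permutations(range(len(y))):
        rho = np.corrcoef(rx, ry[list(perm)])[0, 1]
        total += 1
        hits += abs(rho) >= abs(rho_obs) - 1e-9
    return rho_obs, hits / total


def bh_stepup_oracle(pvalues):
    """Hand application of the step-up rule:
    q_(i) = min_{j >= i} p_(j) * m / j, mapped back to input order."""
    p = np.asarray(pvalues, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
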