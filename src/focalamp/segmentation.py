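"""Profile centering, circular binary segmentation (CBS), and the
sample-adaptive threshold (SAT).

Each array sample is processed independently: log2 ratios are centered so
the copy-neutral bulk of probes sits at zero, then partitioned per
chromosome into constant-mean segments by recursive CBS with a permutation
test for change-point acceptance. The SAT is a per-sample gain/loss cutoff
that scales with the sample's probe-to-probe noise, floored at 0.15; noisy
hybridizations therefore need a larger segment mean before a call is made.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ProbeMatrix

__all__ = [
    "SegmentProfile",
    "SatThreshold",
    "center_profile",
    "cbs_segment",
    "cbs_segment_values",
    "estimate_sat",
    "segment_cohort",
    "segment_values_at_probes",
]

#: consistency factor making the MAD match the SD under normality
_MAD_SCALE = 1.4826


@dataclass
class SegmentProfile:
    """Per-sample piecewise-constant fit (the segmentation line).

    ``segments`` has columns chrom, start, end, n_probes, mean; segments
    tile the probe-covered span of each chromosome.
    """

    sample: str
    segments: pd.DataFrame
    settings: dict = field(default_factory=dict)

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        return self.segments[self.segments["chrom"] == chrom]


@dataclass
class SatThreshold:
    """Sample-adaptive threshold: segment means above +tau are gains,
    below -tau losses."""

    sample: str
    tau: float
    noise: float  # robust probe-level noise estimate (log2 units)

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("SAT must be positive")


# ---------------------------------------------------------------------------
# centering

def center_profile(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Center a ratio vector so its modal (copy-neutral) level is zero.

    The shift is the argmax of a Gaussian kernel density estimate of the
    ratio distribution, which tracks the copy-neutral bulk rather than the
    mean, so large amplifications do not drag the baseline. Falls back to
    the median for (near-)degenerate inputs. Returns (centered, shift).
    """
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 10:
        raise ValueError("need at least 10 finite ratios to center")
    if np.ptp(finite) < 1e-12:
        shift = float(finite[0])
    else:
        try:
            kde = stats.gaussian_kde(finite)
            lo, hi = finite.min(), finite.max()
            grid = np.linspace(lo, hi, 512)
            shift = float(grid[np.argmax(kde(grid))])
        except np.linalg.LinAlgError:
            shift = float(np.median(finite))
    return x - shift, shift


# ---------------------------------------------------------------------------
# CBS internals

def _arc_scale(n: int, k: np.ndarray) -> np.ndarray:
    return np.sqrt(n / (k * (n - k)))


def _max_arc_stat(x: np.ndarray, min_probes: int):
    """Maximal circular arc statistic.

    For an arc (i, j) of length k the two-sample contrast between the arc
    and its complement is proportional to |S_ij - k*T/n| * sqrt(n/(k(n-k)))
    where S_ij is the arc sum and T the total; the noise scale is constant
    across arcs (and across permutations of x), so it cancels from the
    permutation comparison and is omitted. Only arcs whose induced pieces
    all have >= min_probes probes are considered. Ties are broken by the
    smallest left index, then the smallest arc length.

    Returns (stat, i, j) or (0.0, None, None) if no admissible arc exists.
    """
    n = x.size
    m = min_probes
    if n < 2 * m:
        return 0.0, None, None
    c = np.concatenate(([0.0], np.cumsum(x)))
    total = c[-1]
    best = -1.0
    best_i = best_j = None
    for k in range(m, n - m + 1):
        d = np.abs(c[k:] - c[:-k] - k * total / n) * _arc_scale(n, np.array(k))
        i = np.arange(n - k + 1)
        j = i + k
        ok = ((i == 0) | (i >= m)) & ((j == n) | (j <= n - m))
        if not ok.any():
            continue
        d = np.where(ok, d, -np.inf)
        idx = int(np.argmax(d))
        if d[idx] > best + 1e-15:
            best, best_i, best_j = float(d[idx]), idx, idx + k
    return (best, best_i, best_j) if best_i is not None else (0.0, None, None)


def _perm_max_stats(x: np.ndarray, min_probes: int, n_perm: int,
                    rng: np.random.Generator, observed: float,
                    stop_count: int, alpha: float | None = None,
                    accept_conf: float = 0.999) -> tuple[int, int]:
    """Count permutations whose max arc statistic >= observed.

    Works in batches, vectorized across permutations. Sequential early
    stopping in both directions: once the exceedance count makes the
    split non-significant the scan stops; conversely, once the
    Clopper-Pearson upper bound (at ``accept_conf``) on the exceedance
    probability falls below ``alpha`` the split is clearly significant
    and the scan stops (at least 100 permutations are always run).
    Returns (exceedances, permutations actually run).
    """
    n = x.size
    m = min_probes
    exceed = 0
    done = 0
    batch = 128  # grows geometrically so early stopping stays cheap
    batch_cap = max(16, min(n_perm, 1024, int(2e6 / max(n, 1))))
    while done < n_perm:
        b = min(batch, batch_cap, n_perm - done)
        batch *= 2
        perm = np.tile(x, (b, 1))
        # independent row-wise shuffles
        ridx = np.argsort(rng.random((b, n)), axis=1)
        perm = np.take_along_axis(perm, ridx, axis=1)
        c = np.zeros((b, n + 1))
        np.cumsum(perm, axis=1, out=c[:, 1:])
        total = c[:, -1:]
        best = np.zeros(b)
        for k in range(m, n - m + 1):
            i = np.arange(n - k + 1)
            ok = ((i == 0) | (i >= m)) & ((i + k == n) | (i + k <= n - m))
            if not ok.any():
                continue
            d = np.abs(c[:, k:] - c[:, :-k] - k * total / n)
            d *= _arc_scale(n, np.array(k))
            d[:, ~ok] = -np.inf
            np.maximum(best, d.max(axis=1), out=best)
        exceed += int((best >= observed - 1e-12).sum())
        done += b
        if exceed >= stop_count:
            break
        if alpha is not None and done >= 100:
            ucb = stats.beta.ppf(accept_conf, exceed + 1,
                                 max(done - exceed, 1))
            if ucb < alpha:
                break
    return exceed, done


def cbs_segment_values(x: np.ndarray, alpha: float = 0.01,
                       permutations: int = 10_000, min_probes: int = 5,
                       rng: np.random.Generator | None = None) -> list[int]:
    """Segment one chromosome's ratio vector; return interior change-point
    indices (a boundary b means probes [.., b) | [b, ..) belong to
    different segments).

    Recursive CBS: find the arc maximizing the contrast statistic, accept
    the split if its permutation p-value (+1-corrected, p=(b+1)/(B+1), from
    random shuffles of the tested stretch) is below ``alpha``, recurse on
    the pieces. No undo/pruning pass is applied afterwards.
    """
    if rng is None:
        rng = np.random.default_rng()
    x = np.asarray(x, dtype=float)
    n = x.size
    boundaries: list[int] = []
    # early-stop threshold: once exceedances reach this, p >= alpha
    stop = int(np.ceil(alpha * (permutations + 1) - 1))
    stop = max(stop, 1)
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        seg = x[lo:hi]
        stat, i, j = _max_arc_stat(seg, min_probes)
        if i is None or stat <= 0:
            continue
        exceed, done = _perm_max_stats(seg, min_probes, permutations, rng,
                                       stat, stop, alpha=alpha)
        if exceed >= stop:  # early or full: p >= alpha guaranteed
            continue
        if done >= permutations and \
                (exceed + 1) / (permutations + 1) >= alpha:
            continue
        # else: significant (full-run p < alpha, or early accept with
        # exceedance-rate upper bound below alpha)
        cuts = [b for b in (i, j) if 0 < b < hi - lo]
        pieces = [lo] + [lo + b for b in cuts] + [hi]
        for b in cuts:
            boundaries.append(lo + b)
        for a, b in zip(pieces[:-1], pieces[1:]):
            if b - a >= 2 * min_probes:
                stack.append((a, b))
    return sorted(boundaries)


def cbs_segment(pm: ProbeMatrix, sample: str, alpha: float = 0.01,
                permutations: int = 10_000, min_probes: int = 5,
                rng: np.random.Generator | None = None,
                center: bool = True) -> SegmentProfile:
    """Run CBS on one sample of a probe matrix, per chromosome.

    Probes with non-finite ratios are excluded from that sample's fit.
    Segment coordinates tile the probe-covered span: a segment starts at
    its first probe's start (or the previous boundary) and ends where the
    next segment begins; the last segment ends at the last probe's end.
    """
    if rng is None:
        rng = np.random.default_rng()
    values = pm.sample_ratios(sample).astype(float)
    if center:
        values, _ = center_profile(values)
    rows = []
    for chrom in pm.chromosomes():
        mask = (pm.probes["chrom"] == chrom).to_numpy()
        starts = pm.probes["start"].to_numpy()[mask]
        ends = pm.probes["end"].to_numpy()[mask]
        vals = values[mask]
        finite = np.isfinite(vals)
        if not finite.all():
            starts, ends, vals = starts[finite], ends[finite], vals[finite]
        if vals.size == 0:
            continue
        if vals.size < min_probes:
            bnds: list[int] = []
        else:
            bnds = cbs_segment_values(vals, alpha, permutations, min_probes,
                                      rng)
        edges = [0] + bnds + [vals.size]
        for a, b in zip(edges[:-1], edges[1:]):
            seg_start = int(starts[a]) if a > 0 else int(starts[0])
            seg_end = int(starts[b]) if b < vals.size else int(ends[-1])
            rows.append((chrom, seg_start, seg_end, b - a,
                         float(np.mean(vals[a:b]))))
    segments = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                           "n_probes", "mean"])
    return SegmentProfile(sample=sample, segments=segments,
                          settings={"alpha": alpha,
                                    "permutations": permutations,
                                    "min_probes": min_probes,
                                    "centered": center})


def segment_values_at_probes(profile: SegmentProfile,
                             pm: ProbeMatrix) -> np.ndarray:
    """Expand the segmentation line to per-probe values (NaN where a probe
    is not covered by any segment)."""
    out = np.full(pm.n_probes, np.nan)
    p_chrom = pm.probes["chrom"].to_numpy()
    p_start = pm.probes["start"].to_numpy()
    for chrom in profile.segments["chrom"].unique():
        segs = profile.for_chrom(chrom)
        mask = p_chrom == chrom
        pos = p_start[mask]
        starts = segs["start"].to_numpy()
        ends = segs["end"].to_numpy()
        means = segs["mean"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        vals = np.full(pos.size, np.nan)
        valid = idx >= 0
        inside = np.zeros(pos.size, bool)
        inside[valid] = pos[valid] < ends[idx[valid]]
        vals[inside] = means[idx[inside]]
        out[mask] = vals
    return out


# ---------------------------------------------------------------------------
# SAT

def estimate_sat(values: np.ndarray, sample: str = "",
                 floor: float = 0.15, k: float = 3.0) -> SatThreshold:
    """Estimate the sample-adaptive threshold.

    Noise is the scaled MAD of first differences of consecutive probe
    ratios divided by sqrt(2) (differencing doubles the variance of i.i.d.
    noise but cancels slow copy-number structure); tau = max(floor,
    k * noise). With the defaults (floor 0.15, k = 3) a quiet array gets
    the floor and noisier arrays scale up.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError("need at least 10 finite ratios for SAT")
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d))) * _MAD_SCALE
    noise = float(mad / np.sqrt(2.0))
    return SatThreshold(sample=sample, tau=float(max(floor, k * noise)),
                        noise=noise)


# ---------------------------------------------------------------------------
# convenience

def segment_cohort(pm: ProbeMatrix, alpha: float = 0.01,
                   permutations: int = 10_000, min_probes: int = 5,
                   seed: int | None = None, center: bool = True,
                   sat_floor: float = 0.15, sat_k: float = 3.0):
    """Center, segment and estimate the SAT for every sample.

    Returns (list of SegmentProfile, list of SatThreshold), in sample
    order. One child RNG per sample is spawned from ``seed`` so results do
    not depend on sample processing order.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(pm.n_samples)
    profiles, sats = [], []
    for sample, child in zip(pm.samples, children):
        values = pm.sample_ratios(sample)
        centered, _ = center_profile(values) if center else (values, 0.0)
        pm_view = ProbeMatrix(pm.probes, pm.ratios, list(pm.samples))
        rng = np.random.default_rng(child)
        prof = cbs_segment(pm_view, sample, alpha, permutations, min_probes,
                           rng, center=center)
        profiles.append(prof)
        sats.append(estimate_sat(centered, sample, floor=sat_floor, k=sat_k))
    return profiles, sats
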