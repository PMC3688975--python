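"""Gain/loss calling against the SAT, frequency and amplitude maps, gene
copy number, and amplicon architecture (co-occurrence and gene exclusion).

Calls are strict: a probe is a gain iff its segmentation-line value
exceeds +tau for that sample, a loss iff it is below -tau. The gain
frequency of a probe is the fraction of the cohort calling it gained;
its conditional amplitude is the mean segmentation-line value over those
gained samples only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ProbeMatrix
from .segmentation import SegmentProfile, SatThreshold, segment_values_at_probes

__all__ = [
    "CallMatrix",
    "AmpliconDefinition",
    "AmpliconCallMatrix",
    "GeneExclusionEvent",
    "call_aberrations",
    "gain_frequency",
    "gene_copy_number",
    "gene_inclusion_status",
    "call_amplicon_events",
    "cooccurrence_summary",
    "find_gene_excluding_amplifications",
    "promoter_span",
]

GAIN, NEUTRAL, LOSS = 1, 0, -1


@dataclass
class CallMatrix:
    """Probe-level segmentation values and gain/neutral/loss calls.

    ``segvals[i, s]`` is the segmentation line at probe i for sample s;
    ``calls[i, s]`` is +1 (gain), 0 (neutral) or -1 (loss). Probes not
    covered by any segment are neutral with NaN segmentation value.
    """

    probes: pd.DataFrame
    samples: list[str]
    segvals: np.ndarray
    calls: np.ndarray
    taus: dict[str, float] = field(default_factory=dict)

    def sample_calls(self, sample: str) -> np.ndarray:
        return self.calls[:, self.samples.index(sample)]

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def call_aberrations(profiles: list[SegmentProfile] | SegmentProfile,
                     sats: list[SatThreshold] | SatThreshold,
                     pm: ProbeMatrix) -> CallMatrix:
    """Expand segmentation lines to probe level and call against the SAT."""
    if isinstance(profiles, SegmentProfile):
        profiles = [profiles]
    if isinstance(sats, SatThreshold):
        sats = [sats]
    if len(profiles) != len(sats):
        raise ValueError("profiles and SATs differ in length")
    samples = []
    segvals = np.full((pm.n_probes, len(profiles)), np.nan)
    calls = np.zeros((pm.n_probes, len(profiles)), dtype=np.int8)
    taus = {}
    for s, (prof, sat) in enumerate(zip(profiles, sats)):
        if prof.sample != sat.sample:
            raise ValueError(
                f"profile sample {prof.sample!r} != SAT sample {sat.sample!r}")
        samples.append(prof.sample)
        taus[prof.sample] = sat.tau
        v = segment_values_at_probes(prof, pm)
        if np.isnan(v).any():
            warnings.warn(f"{prof.sample}: {int(np.isnan(v).sum())} probes "
                          "not covered by any segment; called neutral")
        segvals[:, s] = v
        with np.errstate(invalid="ignore"):
            calls[v > sat.tau, s] = GAIN
            calls[v < -sat.tau, s] = LOSS
    return CallMatrix(probes=pm.probes, samples=samples,
                      segvals=segvals, calls=calls, taus=taus)


def gain_frequency(cm: CallMatrix) -> pd.DataFrame:
    """Per-probe gain frequency and conditional mean amplitude.

    frequency = gained samples / all samples in the run; amplitude = mean
    segmentation-line value over the gained samples (NaN where no sample
    is gained).
    """
    if cm.n_samples == 0:
        raise ValueError("no samples")
    gained = cm.calls == GAIN
    n_gain = gained.sum(axis=1)
    freq = n_gain / cm.n_samples
    amp = np.full(len(freq), np.nan)
    has = n_gain > 0
    vals = np.where(gained, cm.segvals, 0.0)
    amp[has] = vals[has].sum(axis=1) / n_gain[has]
    out = cm.probes[["probe_id", "chrom", "start", "end"]].copy()
    out["gain_freq"] = freq
    out["gain_amp"] = amp
    return out


def gene_copy_number(profiles: list[SegmentProfile] | SegmentProfile,
                     genes: pd.DataFrame) -> pd.DataFrame:
    """Gene-level copy number: length-weighted mean segmentation value over
    each gene span. Genes with no overlapping segment get NaN.

    ``genes`` needs columns gene, chrom, start, end. Returns a gene x
    sample DataFrame.
    """
    if isinstance(profiles, SegmentProfile):
        profiles = [profiles]
    out = pd.DataFrame(index=genes["gene"],
                       columns=[p.sample for p in profiles], dtype=float)
    for prof in profiles:
        for g in genes.itertuples():
            segs = prof.for_chrom(g.chrom)
            if not len(segs):
                continue
            ov = np.minimum(segs["end"].to_numpy(), g.end) - \
                np.maximum(segs["start"].to_numpy(), g.start)
            ov = np.clip(ov, 0, None)
            if ov.sum() == 0:
                continue
            out.loc[g.gene, prof.sample] = float(
                (segs["mean"].to_numpy() * ov).sum() / ov.sum())
    return out


# ---------------------------------------------------------------------------
# amplicon architecture

@dataclass(frozen=True)
class AmpliconDefinition:
    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"amplicon {self.name}: start >= end")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class AmpliconCallMatrix:
    """Sample x amplicon boolean calls plus per-sample pattern labels."""

    calls: pd.DataFrame          # index samples, columns amplicon names, bool
    patterns: pd.Series          # per-sample label, e.g. "1+2+3" or "none"
    gene_status: pd.DataFrame | None = None  # gene x sample inclusion labels


def _pattern_label(row: pd.Series) -> str:
    names = [c for c in row.index if row[c]]
    return "+".join(names) if names else "none"


def call_amplicon_events(profiles: list[SegmentProfile],
                         sats: list[SatThreshold],
                         amplicons: list[AmpliconDefinition],
                         min_overlap_fraction: float = 0.25,
                         cm: CallMatrix | None = None,
                         genes: pd.DataFrame | None = None
                         ) -> AmpliconCallMatrix:
    """Call amplicons per sample from the segmentation line.

    An amplicon is called in a sample iff its gained span (union of
    segments with mean > tau, clipped to the amplicon) covers at least
    ``min_overlap_fraction`` of the amplicon. When a probe-level call
    matrix and a gene table are supplied, per-gene inclusion status is
    attached (see :func:`gene_inclusion_status`).
    """
    names = [a.name for a in amplicons]
    rows = {}
    for prof, sat in zip(profiles, sats):
        flags = []
        for amp in amplicons:
            segs = prof.for_chrom(amp.chrom)
            gained = segs[segs["mean"] > sat.tau]
            cov = 0
            if len(gained):
                ov = np.minimum(gained["end"].to_numpy(), amp.end) - \
                    np.maximum(gained["start"].to_numpy(), amp.start)
                cov = int(np.clip(ov, 0, None).sum())  # segments never overlap
            flags.append(cov >= min_overlap_fraction * amp.span)
        rows[prof.sample] = flags
    calls = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    patterns = calls.apply(_pattern_label, axis=1)
    gene_status = None
    if cm is not None and genes is not None:
        gene_status = gene_inclusion_status(cm, genes)
    return AmpliconCallMatrix(calls=calls, patterns=patterns,
                              gene_status=gene_status)


def gene_inclusion_status(cm: CallMatrix, genes: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-sample amplification inclusion.

    'full' iff every probe overlapping the gene span is gained, 'excluded'
    iff none is, 'partial' otherwise, 'no_probes' when the array has no
    probe over the gene.
    """
    out = pd.DataFrame(index=genes["gene"], columns=cm.samples, dtype=object)
    ps = cm.probes["start"].to_numpy()
    pe = cm.probes["end"].to_numpy()
    pc = cm.probes["chrom"].to_numpy()
    for g in genes.itertuples():
        sel = (pc == g.chrom) & (ps < g.end) & (pe > g.start)
        if not sel.any():
            out.loc[g.gene, :] = "no_probes"
            continue
        sub = cm.calls[sel] == GAIN
        frac = sub.mean(axis=0)
        out.loc[g.gene, :] = np.select(
            [frac == 1.0, frac == 0.0], ["full", "excluded"], "partial")
    return out


def cooccurrence_summary(acm: AmpliconCallMatrix,
                         exclusion_rule: tuple[str, str, str] | None = None
                         ) -> tuple[dict[str, int], list[str]]:
    """Pattern counts plus samples violating an exclusion rule.

    ``exclusion_rule=(a, b, via)`` flags samples where amplicons a and b
    are both called without the intervening amplicon ``via`` (the pattern
    the cohort architecture is expected to forbid). Default: the first and
    last amplicon require the middle one, when there are exactly three.
    """
    if len(acm.calls) < 1:
        raise ValueError("need at least one sample")
    counts = acm.patterns.value_counts().to_dict()
    violations: list[str] = []
    names = list(acm.calls.columns)
    if exclusion_rule is None and len(names) == 3:
        exclusion_rule = (names[0], names[2], names[1])
    if exclusion_rule is not None:
        a, b, via = exclusion_rule
        bad = acm.calls[a] & acm.calls[b] & ~acm.calls[via]
        violations = list(acm.calls.index[bad])
    return counts, violations


# ---------------------------------------------------------------------------
# gene-exclusion events

@dataclass(frozen=True)
class GeneExclusionEvent:
    """An amplification that keeps the auxiliary gene intact, excludes the
    canonical target, and breaks inside the intervening gene."""

    sample: str
    boundary_pos: int
    boundary_class: str  # 'coding' or 'promoter'


def promoter_span(gene: pd.Series | dict, length: int = 2000
                  ) -> tuple[int, int]:
    """Promoter interval: ``length`` bp upstream of the transcription start
    on the annotated strand (half-open, clipped at 0)."""
    strand = gene.get("strand", "+") if isinstance(gene, dict) else \
        getattr(gene, "strand", "+")
    start, end = int(gene["start"]), int(gene["end"])
    if strand == "-":
        return end, end + length
    return max(0, start - length), start


def find_gene_excluding_amplifications(
        cm: CallMatrix,
        profiles: list[SegmentProfile],
        sats: list[SatThreshold],
        target: pd.Series | dict,
        auxiliary: pd.Series | dict,
        intervening: pd.Series | dict,
        promoter_length: int = 2000) -> list[GeneExclusionEvent]:
    """Detect amplifications that include the auxiliary gene but not the
    canonical target, breaking within the intervening gene.

    An event requires, per sample: (1) every probe over the auxiliary gene
    gained, (2) no probe over the target gained, (3) the gained-segment
    boundary proximal to the target falling inside the intervening gene
    body ('coding') or its promoter ('promoter'). The three genes must be
    ordered and non-overlapping on one chromosome.
    """
    t, x, a = (dict(target), dict(intervening), dict(auxiliary))
    chroms = {t["chrom"], x["chrom"], a["chrom"]}
    if len(chroms) != 1:
        raise ValueError("genes must be on one chromosome")
    trio = sorted([t, x, a], key=lambda g: g["start"])
    if trio[1]["gene"] != x["gene"]:
        raise ValueError("intervening gene must lie between target and "
                         "auxiliary")
    for g1, g2 in zip(trio[:-1], trio[1:]):
        if g1["end"] > g2["start"]:
            raise ValueError("genes must be non-overlapping and ordered")
    target_left = t["start"] < a["start"]

    status = gene_inclusion_status(
        cm, pd.DataFrame([t, a])[["gene", "chrom", "start", "end"]])
    prom = promoter_span(x, promoter_length)
    body = (int(x["start"]), int(x["end"]))

    events: list[GeneExclusionEvent] = []
    for prof, sat in zip(profiles, sats):
        s = prof.sample
        if status.loc[a["gene"], s] != "full":
            continue
        if status.loc[t["gene"], s] != "excluded":
            continue
        segs = prof.for_chrom(a["chrom"]).reset_index(drop=True)
        gained = (segs["mean"] > sat.tau).to_numpy()
        # maximal run of gained segments covering the auxiliary gene
        cover = gained & (segs["start"].to_numpy() < a["end"]) & \
            (segs["end"].to_numpy() > a["start"])
        if not cover.any():
            continue
        i = int(np.flatnonzero(cover)[0])
        lo = hi = i
        while lo > 0 and gained[lo - 1]:
            lo -= 1
        while hi < len(segs) - 1 and gained[hi + 1]:
            hi += 1
        boundary = int(segs.loc[lo, "start"]) if target_left else \
            int(segs.loc[hi, "end"])
        if body[0] <= boundary < body[1]:
            cls = "coding"
        elif prom[0] <= boundary < prom[1]:
            cls = "promoter"
        else:
            continue
        events.append(GeneExclusionEvent(sample=s, boundary_pos=boundary,
                                         boundary_class=cls))
    return events
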