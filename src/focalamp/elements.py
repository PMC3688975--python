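"""G-quadruplex motif scanning and per-window sequence-element content.

The motif scanner looks for the canonical quadruplex-forming pattern
G3 N1-7 G3 N1-7 G3 N1-7 G3 (four runs of three guanines separated by
loops of 1-7 nucleotides) with lazy loops, reporting non-overlapping
minimal matches left to right; the complementary C-run pattern captures
motifs on the minus strand. Repeat-element content (LINE/SINE/LTR) is the
fraction of each window covered by the union of that class's intervals;
G4 content is base pairs of motif sequence per window.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .breakpoints import WindowGrid
from .io import IntervalTrack, ProbeMatrix

__all__ = [
    "MotifHit",
    "find_g4_motifs",
    "scan_genome_g4",
    "motif_hits_to_track",
    "window_element_content",
    "eligible_windows",
    "union_length",
]

# N is permitted in input but never matches (loops exclude it)
_G4_RE = re.compile("G{3}(?:[ACGT]{1,7}?G{3}){3}")
_C4_RE = re.compile("C{3}(?:[ACGT]{1,7}?C{3}){3}")
_G4_ALL_RE = re.compile("(?=(G{3}(?:[ACGT]{1,7}?G{3}){3}))")
_C4_ALL_RE = re.compile("(?=(C{3}(?:[ACGT]{1,7}?C{3}){3}))")
_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class MotifHit:
    chrom: str
    start: int
    end: int
    strand: str  # '+' = G-pattern, '-' = C-pattern

    def __post_init__(self):
        if not 15 <= self.end - self.start <= 45:
            raise ValueError("G4 motif length must be in [15, 45]")


def find_g4_motifs(sequence: str, chrom: str = "",
                   both_strands: bool = True,
                   overlapping: bool = False) -> list[MotifHit]:
    """Scan a sequence for quadruplex motifs.

    Default behaviour is the reference one: minimal (lazy-loop) matches,
    non-overlapping, scanning left to right and resuming after each match
    end; the G-pattern and (when ``both_strands``) the C-pattern are
    scanned independently, so a G-hit and a C-hit may overlap. With
    ``overlapping=True`` every start position yielding a minimal match is
    reported instead (sensitivity-analysis mode).
    """
    seq = sequence.upper()
    invalid = set(seq) - _VALID
    if invalid:
        raise ValueError(f"invalid sequence characters: {sorted(invalid)}")
    hits: list[MotifHit] = []
    patterns = [(_G4_ALL_RE if overlapping else _G4_RE, "+")]
    if both_strands:
        patterns.append((_C4_ALL_RE if overlapping else _C4_RE, "-"))
    for pat, strand in patterns:
        for m in pat.finditer(seq):
            if overlapping:
                start, end = m.start(1), m.end(1)
            else:
                start, end = m.start(), m.end()
            hits.append(MotifHit(chrom, start, end, strand))
    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return hits


def scan_genome_g4(genome: dict[str, str],
                   both_strands: bool = True) -> list[MotifHit]:
    hits = []
    for chrom, seq in genome.items():
        hits.extend(find_g4_motifs(seq, chrom, both_strands))
    return hits


def motif_hits_to_track(hits: list[MotifHit]) -> IntervalTrack:
    df = pd.DataFrame([(h.chrom, h.start, h.end, h.strand) for h in hits],
                      columns=["chrom", "start", "end", "name"])
    return IntervalTrack("G4", df)


# ---------------------------------------------------------------------------
# interval coverage

def union_length(starts: np.ndarray, ends: np.ndarray,
                 clip_start: int, clip_end: int) -> int:
    """Total bp covered by the union of intervals, clipped to a window."""
    s = np.clip(np.asarray(starts), clip_start, clip_end)
    e = np.clip(np.asarray(ends), clip_start, clip_end)
    keep = e > s
    s, e = s[keep], e[keep]
    if s.size == 0:
        return 0
    order = np.argsort(s)
    s, e = s[order], e[order]
    total = 0
    cur_s, cur_e = int(s[0]), int(e[0])
    for a, b in zip(s[1:], e[1:]):
        if a > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = int(a), int(b)
        else:
            cur_e = max(cur_e, int(b))
    return total + (cur_e - cur_s)


def _per_window_coverage(grid: WindowGrid, track_df: pd.DataFrame) -> np.ndarray:
    """Union-covered bp of each grid window by a set of intervals."""
    out = np.zeros(len(grid), dtype=int)
    w = grid.windows
    for chrom, wsub in w.groupby("chrom", sort=False):
        isub = track_df[track_df["chrom"] == chrom]
        if not len(isub):
            continue
        ist = isub["start"].to_numpy()
        ien = isub["end"].to_numpy()
        wst = wsub["start"].to_numpy()
        wen = wsub["end"].to_numpy()
        # candidate intervals per window via sorted sweep
        for row_i, (a, b) in zip(wsub.index, zip(wst, wen)):
            sel = (ist < b) & (ien > a)
            if sel.any():
                out[row_i] = union_length(ist[sel], ien[sel], a, b)
    return out


def window_element_content(grid: WindowGrid,
                           tracks: dict[str, IntervalTrack],
                           motif_hits: list[MotifHit] | None = None
                           ) -> pd.DataFrame:
    """Per-window element content table.

    For every track class a ``<class>_frac`` column gives the fraction of
    the window covered by the union of that class's intervals (clipped to
    the window; double-covered bases count once). When motif hits are
    supplied a ``g4_bp`` column gives union base pairs of motif sequence
    per window. Carries the grid's ``eligible`` flag.
    """
    table = grid.windows[["chrom", "start", "end", "eligible"]].copy()
    width = (table["end"] - table["start"]).to_numpy()
    for name, track in tracks.items():
        cov = _per_window_coverage(grid, track.intervals)
        table[f"{name.lower()}_frac"] = cov / width
    if motif_hits is not None:
        g4df = pd.DataFrame(
            [(h.chrom, h.start, h.end) for h in motif_hits],
            columns=["chrom", "start", "end"])
        table["g4_bp"] = _per_window_coverage(grid, g4df)
    return table


def eligible_windows(grid: WindowGrid, pm: ProbeMatrix | None = None,
                     cnv_track: IntervalTrack | None = None,
                     min_probes: int = 1) -> WindowGrid:
    """Return a grid with the eligibility mask updated.

    A window is eligible iff it has array coverage (at least ``min_probes``
    probes overlap it) and it overlaps no CNV interval (any overlap
    disqualifies — germline variants would confound somatic breakpoints).
    """
    w = grid.windows.copy()
    eligible = w["eligible"].to_numpy().copy()
    if pm is not None:
        pcount = np.zeros(len(w), dtype=int)
        for chrom, wsub in w.groupby("chrom", sort=False):
            probes = pm.probes[pm.probes["chrom"] == chrom]
            if not len(probes):
                continue
            ps = probes["start"].to_numpy()
            pe = probes["end"].to_numpy()
            for row_i, (a, b) in zip(wsub.index,
                                     zip(wsub["start"], wsub["end"])):
                pcount[row_i] = int(((ps < b) & (pe > a)).sum())
        eligible &= pcount >= min_probes
    if cnv_track is not None:
        for chrom, wsub in w.groupby("chrom", sort=False):
            cnv = cnv_track.for_chrom(chrom)
            if not len(cnv):
                continue
            cs = cnv["start"].to_numpy()
            ce = cnv["end"].to_numpy()
            for row_i, (a, b) in zip(wsub.index,
                                     zip(wsub["start"], wsub["end"])):
                if ((cs < b) & (ce > a)).any():
                    eligible[row_i] = False
    w["eligible"] = eligible
    return WindowGrid(grid.window_size, w)
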