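"""Readers and writers for the tabular and genomic formats the pipeline touches.

All coordinates are 0-based half-open internally (BED convention). Probe
tables are tab-separated with columns ``probe_id, chrom, start, end``
followed by one ratio column per sample; an optional ``qc_pass`` column
(0/1) carries the array quality flag. Lines starting with ``#`` are ignored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("focalamp")

__all__ = [
    "ProbeMatrix",
    "IntervalTrack",
    "ExpressionMatrix",
    "FormatError",
    "read_probe_table",
    "write_probe_table",
    "merge_replicate_probes",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "write_segments_seg",
    "read_segments_seg",
    "write_window_bedgraph",
    "read_expression_table",
    "write_expression_table",
]

_RESERVED_COLS = ("probe_id", "chrom", "start", "end", "qc_pass")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ProbeMatrix:
    """Probe coordinates plus per-sample log2 ratios.

    Attributes
    ----------
    probes : pandas.DataFrame
        Columns ``probe_id, chrom, start, end``, sorted by (chrom, start).
    ratios : numpy.ndarray
        Shape (n_probes, n_samples); NaN marks a missing/filtered cell.
    samples : list of str
    qc_pass : numpy.ndarray or None
        Boolean per probe; False marks control/failed probes.
    """

    probes: pd.DataFrame
    ratios: np.ndarray
    samples: list[str]
    qc_pass: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.probes = self.probes.reset_index(drop=True)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.ratios.shape != (len(self.probes), len(self.samples)):
            raise ValueError(
                f"ratio matrix shape {self.ratios.shape} does not match "
                f"{len(self.probes)} probes x {len(self.samples)} samples"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_ratios(self, sample: str) -> np.ndarray:
        return self.ratios[:, self.samples.index(sample)]

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.probes["chrom"]))

    def sorted(self) -> "ProbeMatrix":
        order = np.lexsort((self.probes["start"].to_numpy(),
                            self.probes["chrom"].to_numpy()))
        if np.array_equal(order, np.arange(len(order))):
            return self
        qc = self.qc_pass[order] if self.qc_pass is not None else None
        return ProbeMatrix(self.probes.iloc[order], self.ratios[order],
                           list(self.samples), qc)


@dataclass
class IntervalTrack:
    """A labelled, sorted, strand-agnostic set of genomic intervals."""

    label: str
    intervals: pd.DataFrame  # chrom, start, end[, name]

    def __post_init__(self) -> None:
        df = self.intervals.reset_index(drop=True)
        if len(df) and (df["start"] >= df["end"]).any():
            bad = df.index[df["start"] >= df["end"]][0]
            raise FormatError(
                f"track {self.label!r}: interval {bad} has start >= end")
        order = np.lexsort((df["start"].to_numpy(), df["chrom"].to_numpy()))
        self.intervals = df.iloc[order].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.intervals)

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        return self.intervals[self.intervals["chrom"] == chrom]


@dataclass
class ExpressionMatrix:
    """Gene-by-sample real-valued expression table."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()]
            raise FormatError(f"duplicate gene ids: {list(dupes[:3])}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# probe tables

def read_probe_table(path, quality_filter: bool = True) -> ProbeMatrix:
    """Read a tab-separated probe log2-ratio table.

    When ``quality_filter`` is set and a ``qc_pass`` column is present,
    probes with ``qc_pass == 0`` (controls / failed spots) are dropped and
    the count is logged, emulating the array platform's quality condition.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    for col in ("probe_id", "chrom", "start", "end"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    for col in ("start", "end"):
        if not np.issubdtype(df[col].dtype, np.integer):
            raise FormatError(f"{path}: column {col!r} is not integer")
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise FormatError(
            f"{path}: start >= end at data line {bad[0] + 1} "
            f"(probe {df.loc[bad[0], 'probe_id']!r})")
    dup = df[df.duplicated("probe_id", keep=False)]
    if len(dup):
        coords = dup.groupby("probe_id")[["chrom", "start", "end"]].nunique()
        conflicting = coords[(coords > 1).any(axis=1)]
        if len(conflicting):
            raise FormatError(
                f"{path}: probe id {conflicting.index[0]!r} appears with "
                "different coordinates")

    qc = None
    if "qc_pass" in df.columns:
        qc = df["qc_pass"].to_numpy().astype(bool)
        if quality_filter:
            n_drop = int((~qc).sum())
            if n_drop:
                logger.info("dropped %d control/failed probes", n_drop)
            df = df[qc]
            qc = None
    sample_cols = [c for c in df.columns if c not in _RESERVED_COLS]
    probes = df[["probe_id", "chrom", "start", "end"]]
    pm = ProbeMatrix(probes, df[sample_cols].to_numpy(dtype=float),
                     sample_cols, qc)
    resorted = pm.sorted()
    if resorted is not pm:
        warnings.warn(f"{path}: probes were not coordinate-sorted; sorting")
    return resorted


def write_probe_table(pm: ProbeMatrix, path) -> None:
    df = pm.probes.copy()
    if pm.qc_pass is not None:
        df["qc_pass"] = pm.qc_pass.astype(int)
    for i, s in enumerate(pm.samples):
        df[s] = pm.ratios[:, i]
    df.to_csv(path, sep="\t", index=False)


def merge_replicate_probes(pm: ProbeMatrix) -> ProbeMatrix:
    """Merge replicate probes (identical chrom/start/end) to their per-sample
    median ratio, keeping the first probe id of each replicate group."""
    key = pd.MultiIndex.from_frame(pm.probes[["chrom", "start", "end"]])
    if key.is_unique:
        return pm
    df = pm.probes.copy()
    for i, s in enumerate(pm.samples):
        df[s] = pm.ratios[:, i]
    grouped = df.groupby(["chrom", "start", "end"], sort=True, as_index=False)
    agg = {"probe_id": "first"} | {s: "median" for s in pm.samples}
    merged = grouped.agg(agg)
    probes = merged[["probe_id", "chrom", "start", "end"]]
    return ProbeMatrix(probes, merged[pm.samples].to_numpy(dtype=float),
                       list(pm.samples)).sorted()


# ---------------------------------------------------------------------------
# BED / bedGraph / SEG

def read_bed(path, label: str | None = None) -> IntervalTrack:
    """Read a BED3/BED4 file (0-based half-open) into an IntervalTrack."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            rows.append((parts[0], start, end,
                         parts[3] if len(parts) > 3 else ""))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return IntervalTrack(label or str(path), df)


def write_bed(track: IntervalTrack, path) -> None:
    cols = ["chrom", "start", "end"]
    if "name" in track.intervals.columns:
        cols.append("name")
    track.intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def write_segments_seg(profiles, path) -> None:
    """Write SEG format: sample, chrom, start, end, num_probes, seg_mean."""
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tnum_probes\tseg_mean\n")
        for prof in profiles:
            for seg in prof.segments.itertuples():
                fh.write(f"{prof.sample}\t{seg.chrom}\t{seg.start}\t"
                         f"{seg.end}\t{seg.n_probes}\t{seg.mean:.6g}\n")


def read_segments_seg(path):
    """Read a SEG file back into a list of SegmentProfile objects."""
    from .segmentation import SegmentProfile

    df = pd.read_csv(path, sep="\t")
    required = {"sample", "chrom", "start", "end", "num_probes", "seg_mean"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: SEG header missing {required - set(df.columns)}")
    profiles = []
    for sample, sub in df.groupby("sample", sort=False):
        segs = sub.rename(columns={"num_probes": "n_probes",
                                   "seg_mean": "mean"})
        profiles.append(SegmentProfile(
            sample=str(sample),
            segments=segs[["chrom", "start", "end", "n_probes", "mean"]]
            .reset_index(drop=True),
            settings={}))
    return profiles


def write_window_bedgraph(windows: pd.DataFrame, column: str, path,
                          track_name: str | None = None) -> None:
    """Write one numeric column of a window table as bedGraph (0-based
    half-open). Rows with missing values are skipped."""
    with open(path, "w") as fh:
        if track_name:
            fh.write(f"track type=bedGraph name={track_name}\n")
        for row in windows.itertuples():
            val = getattr(row, column)
            if pd.isna(val):
                continue
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{val:.6g}\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} dict (upper-cased)."""
    genome = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise FormatError(f"{path}: no FASTA records found")
    return genome


def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# expression

def read_expression_table(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return ExpressionMatrix(df)


def write_expression_table(em: ExpressionMatrix, path) -> None:
    em.values.to_csv(path, sep="\t", index_label="gene")
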