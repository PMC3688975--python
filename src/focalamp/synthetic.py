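"""Synthetic aCGH study generator with known ground truth.

Emulates the statistical structure of a zoom-in array-CGH cohort of
urothelial-carcinoma-like tumors: per-sample piecewise-constant log2
profiles with focal amplicons at configurable loci, i.i.d. Gaussian probe
noise, amplicon boundaries optionally drawn from hotspot windows (which
clusters breakpoints), repeat-element and CNV interval tracks, planted
quadruplex motifs, and expression values monotonically coupled to gene
copy number. Every planted quantity is recorded in a truth object so each
downstream stage can be scored against it.

All randomness flows from a single seed through named child generators in
a fixed order, so outputs are reproducible and independent of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, IntervalTrack, ProbeMatrix

__all__ = [
    "AmpliconSpec",
    "SimulationConfig",
    "SimulationTruth",
    "SimulatedStudy",
    "simulate_genome",
    "simulate_cohort",
    "simulate_expression",
    "simulate_study",
    "default_config",
    "true_exclusion_events",
]

_G4_MOTIF = "GGGATAGGGATAGGGATAGGG"  # minimal pattern, A/T loops


@dataclass(frozen=True)
class AmpliconSpec:
    """A focal amplification locus.

    Per sample, membership is Bernoulli(``prob``) unless a membership
    matrix is supplied in the config. The realized boundaries are the
    span edges, except where ``start_window``/``end_window`` give an
    interval from which the edge is drawn uniformly — this is how
    breakpoint hotspots are planted.
    """

    name: str
    chrom: str
    start: int
    end: int
    amplitude: float = 1.0
    prob: float = 0.5
    start_window: tuple[int, int] | None = None
    end_window: tuple[int, int] | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"amplicon {self.name}: start >= end")
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError(f"amplicon {self.name}: prob outside [0,1]")


@dataclass
class SimulationConfig:
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    probe_spacing: int = 10_000
    probe_length: int = 60
    n_samples: int = 68
    amplicons: list[AmpliconSpec] = field(default_factory=list)
    noise_sd: float = 0.065
    # sequence / tracks
    g_free_backbone: bool = False  # A/C/T backbone: no chance G-motifs
    n_g4_motifs: int = 100
    g4_positions: list[tuple[str, int]] | None = None
    element_densities: dict[str, float] = field(
        default_factory=lambda: {"LINE": 0.192, "SINE": 0.108, "LTR": 0.075})
    element_mean_lengths: dict[str, int] = field(
        default_factory=lambda: {"LINE": 3000, "SINE": 300, "LTR": 1000})
    cnv_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    # genes
    genes: pd.DataFrame | None = None  # override auto layout
    gene_spacing: int = 400_000
    gene_length: int = 40_000
    # expression
    expression_slope: float = 1.0
    expression_noise: float = 0.5
    n_expression_matched: int = 58
    n_expression_extra: int = 154
    # forced membership (samples x amplicon names, bool); None = Bernoulli
    membership: pd.DataFrame | None = None
    seed: int = 0

    def __post_init__(self):
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"{chrom}: non-positive length")
        if self.probe_spacing <= 0 or self.probe_length <= 0:
            raise ValueError("probe spacing/length must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.expression_noise < 0:
            raise ValueError("expression noise must be >= 0")
        for amp in self.amplicons:
            if amp.chrom not in self.chrom_lengths:
                raise ValueError(f"amplicon {amp.name}: unknown chromosome")
            if amp.end > self.chrom_lengths[amp.chrom]:
                raise ValueError(f"amplicon {amp.name}: outside chromosome")
            n_probes = (amp.end - amp.start) // self.probe_spacing
            if n_probes < 5:
                import warnings
                warnings.warn(f"amplicon {amp.name} spans fewer than 5 "
                              "probes; unsegmentable at these settings")
        if self.n_expression_matched > self.n_samples:
            raise ValueError("matched expression samples exceed cohort")

    def rng(self, stream: str) -> np.random.Generator:
        """Named child generator; streams are independent given the seed."""
        import zlib

        key = zlib.crc32(stream.encode())  # stable across processes
        child = np.random.SeedSequence(entropy=self.seed, spawn_key=(key,))
        return np.random.default_rng(child)


@dataclass
class SimulationTruth:
    """Everything the generator planted, for scoring downstream stages."""

    segments: pd.DataFrame      # sample, chrom, start, end, mean
    breakpoints: pd.DataFrame   # sample, chrom, pos
    membership: pd.DataFrame    # samples x amplicon names (bool)
    boundaries: pd.DataFrame    # sample, amplicon, start, end (realized)
    motif_intervals: pd.DataFrame  # chrom, start, end
    genes: pd.DataFrame
    expression_slope: float = 1.0
    expression_noise: float = 0.0

    def sample_segments(self, sample: str, chrom: str) -> pd.DataFrame:
        sel = (self.segments["sample"] == sample) & \
            (self.segments["chrom"] == chrom)
        return self.segments[sel]


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genome: dict[str, str]
    tracks: dict[str, IntervalTrack]
    genes: pd.DataFrame
    probe_matrix: ProbeMatrix
    truth: SimulationTruth
    expression: ExpressionMatrix


# ---------------------------------------------------------------------------
# genome, tracks, genes

def _auto_genes(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    i = 0
    for chrom, length in config.chrom_lengths.items():
        pos = config.gene_spacing // 2
        while pos + config.gene_length < length:
            rows.append((f"g{i:04d}", chrom, pos, pos + config.gene_length,
                         "+" if i % 2 == 0 else "-"))
            i += 1
            pos += config.gene_spacing
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end",
                                       "strand"])


def _element_track(name: str, chrom_lengths: dict[str, int], density: float,
                   mean_len: int, rng: np.random.Generator) -> IntervalTrack:
    """Alternating gap/element renewal process; expected coverage = density,
    intervals non-overlapping within the class by construction."""
    rows = []
    if density <= 0:
        return IntervalTrack(name, pd.DataFrame(
            columns=["chrom", "start", "end", "name"]))
    mean_gap = mean_len * (1 - density) / density
    for chrom, length in chrom_lengths.items():
        pos = 0.0
        while True:
            pos += rng.exponential(mean_gap)
            start = int(pos)
            span = max(50, int(rng.exponential(mean_len)))
            end = min(start + span, length)
            if start >= length:
                break
            rows.append((chrom, start, end, name))
            pos = end
    return IntervalTrack(name, pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name"]))


def simulate_genome(config: SimulationConfig):
    """Generate the genome sequence, element/CNV tracks and gene table.

    Returns (genome, tracks, genes, motif_intervals). Motifs are planted
    at recorded positions; with a G-free (A/C/T) backbone the planted
    motifs are the only quadruplex patterns present, so a scan recovers
    exactly the planted count.
    """
    rng = config.rng("genome")
    alphabet = np.frombuffer(b"ACT" if config.g_free_backbone else b"ACGT",
                             dtype=np.uint8)
    genome: dict[str, np.ndarray] = {}
    for chrom, length in config.chrom_lengths.items():
        genome[chrom] = alphabet[rng.integers(0, alphabet.size, size=length)]

    motif = np.frombuffer(_G4_MOTIF.encode(), dtype=np.uint8)
    placements: list[tuple[str, int]] = []
    if config.g4_positions is not None:
        placements = list(config.g4_positions)
    else:
        chroms = list(config.chrom_lengths)
        weights = np.array([config.chrom_lengths[c] for c in chroms], float)
        weights /= weights.sum()
        occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
        for k in range(config.n_g4_motifs):
            for _ in range(200):
                chrom = chroms[rng.choice(len(chroms), p=weights)]
                pos = int(rng.integers(
                    0, config.chrom_lengths[chrom] - motif.size))
                if all(pos + motif.size <= s or pos >= e
                       for s, e in occupied[chrom]):
                    occupied[chrom].append((pos, pos + motif.size))
                    placements.append((chrom, pos))
                    break
            else:
                raise RuntimeError(
                    f"could not place G4 motif {k} without collision "
                    f"after 200 retries (last locus {chrom}:{pos})")
    for chrom, pos in placements:
        if pos + motif.size > config.chrom_lengths[chrom]:
            raise ValueError(f"G4 motif at {chrom}:{pos} exceeds chromosome")
        genome[chrom][pos:pos + motif.size] = motif
    motif_intervals = pd.DataFrame(
        [(c, p, p + motif.size) for c, p in placements],
        columns=["chrom", "start", "end"])

    tracks: dict[str, IntervalTrack] = {}
    for name, density in config.element_densities.items():
        tracks[name] = _element_track(
            name, config.chrom_lengths, density,
            config.element_mean_lengths.get(name, 1000), config.rng(f"elem:{name}"))
    tracks["CNV"] = IntervalTrack("CNV", pd.DataFrame(
        config.cnv_intervals, columns=["chrom", "start", "end"]))

    genes = config.genes if config.genes is not None else _auto_genes(config)
    for g in genes.itertuples():
        if g.chrom not in config.chrom_lengths:
            raise ValueError(f"gene {g.gene}: unknown chromosome {g.chrom}")
        if g.end > config.chrom_lengths[g.chrom]:
            raise ValueError(f"gene {g.gene}: outside chromosome")
    genome_str = {c: seq.tobytes().decode() for c, seq in genome.items()}
    return genome_str, tracks, genes, motif_intervals


# ---------------------------------------------------------------------------
# cohort

def _sample_names(config: SimulationConfig) -> tuple[list[str], list[str]]:
    arrays = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    extra = [f"E{i + 1:03d}" for i in range(config.n_expression_extra)]
    return arrays, extra


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[ProbeMatrix, SimulationTruth]:
    """Simulate per-sample copy-number truth and the probe-level matrix.

    Truth (membership, realized boundaries, true segments) is generated
    for the array cohort and the expression-only cohort alike; probe
    ratios — true segment mean plus N(0, noise_sd) — only for the array
    samples.
    """
    rng = config.rng("cohort")
    arrays, extra = _sample_names(config)
    all_samples = arrays + extra
    amp_names = [a.name for a in config.amplicons]

    if config.membership is not None:
        membership = config.membership.astype(bool)
        missing = [s for s in all_samples if s not in membership.index]
        if missing:
            raise ValueError(f"membership matrix missing samples {missing[:3]}")
    else:
        data = {a.name: rng.random(len(all_samples)) < a.prob
                for a in config.amplicons}
        membership = pd.DataFrame(data, index=all_samples, dtype=bool)

    bound_rows = []
    for amp in config.amplicons:
        for s in all_samples:
            if not membership.loc[s, amp.name]:
                continue
            start = amp.start if amp.start_window is None else \
                int(rng.integers(*amp.start_window))
            end = amp.end if amp.end_window is None else \
                int(rng.integers(*amp.end_window))
            if start >= end:
                raise ValueError(f"amplicon {amp.name}, sample {s}: drawn "
                                 "boundaries collapsed")
            bound_rows.append((s, amp.name, start, end, amp.amplitude,
                               amp.chrom))
    boundaries = pd.DataFrame(
        bound_rows,
        columns=["sample", "amplicon", "start", "end", "amplitude", "chrom"])

    seg_rows, bp_rows = [], []
    for s in all_samples:
        for chrom, length in config.chrom_lengths.items():
            events = boundaries[(boundaries["sample"] == s)
                                & (boundaries["chrom"] == chrom)]
            events = events.sort_values("start")
            pos = 0
            for ev in events.itertuples():
                if ev.start < pos:
                    raise ValueError(
                        f"overlapping amplicons for sample {s} on {chrom}")
                if ev.start > pos:
                    seg_rows.append((s, chrom, pos, ev.start, 0.0))
                seg_rows.append((s, chrom, ev.start, ev.end, ev.amplitude))
                bp_rows.append((s, chrom, ev.start))
                bp_rows.append((s, chrom, ev.end))
                pos = ev.end
            if pos < length:
                seg_rows.append((s, chrom, pos, length, 0.0))
    segments = pd.DataFrame(
        seg_rows, columns=["sample", "chrom", "start", "end", "mean"])
    breakpoints = pd.DataFrame(bp_rows, columns=["sample", "chrom", "pos"])

    # probes
    probe_rows = []
    for chrom, length in config.chrom_lengths.items():
        for j, pos in enumerate(
                range(0, length - config.probe_length, config.probe_spacing)):
            probe_rows.append((f"{chrom}_p{j:06d}", chrom, pos,
                               pos + config.probe_length))
    probes = pd.DataFrame(probe_rows,
                          columns=["probe_id", "chrom", "start", "end"])

    ratios = np.zeros((len(probes), len(arrays)))
    p_chrom = probes["chrom"].to_numpy()
    p_start = probes["start"].to_numpy()
    for si, s in enumerate(arrays):
        mean = np.zeros(len(probes))
        for ev in boundaries[boundaries["sample"] == s].itertuples():
            sel = (p_chrom == ev.chrom) & (p_start >= ev.start) & \
                (p_start < ev.end)
            mean[sel] = ev.amplitude
        noise = rng.normal(0.0, config.noise_sd, size=len(probes)) \
            if config.noise_sd > 0 else 0.0
        ratios[:, si] = mean + noise

    genes = config.genes if config.genes is not None else _auto_genes(config)
    # canonical row order: (chrom, start) lexicographic, as the readers emit
    pm = ProbeMatrix(probes, ratios, arrays).sorted()
    truth = SimulationTruth(
        segments=segments, breakpoints=breakpoints, membership=membership,
        boundaries=boundaries, motif_intervals=pd.DataFrame(
            columns=["chrom", "start", "end"]),
        genes=genes, expression_slope=config.expression_slope,
        expression_noise=config.expression_noise)
    return pm, truth


def true_gene_copy(truth: SimulationTruth, genes: pd.DataFrame,
                   samples: list[str]) -> pd.DataFrame:
    """Length-weighted true copy value of each gene per sample."""
    out = pd.DataFrame(0.0, index=genes["gene"], columns=samples)
    for s in samples:
        ssub = truth.segments[truth.segments["sample"] == s]
        for g in genes.itertuples():
            segs = ssub[ssub["chrom"] == g.chrom]
            if not len(segs):
                raise ValueError(
                    f"gene {g.gene}: chromosome {g.chrom} not simulated")
            ov = np.minimum(segs["end"].to_numpy(), g.end) - \
                np.maximum(segs["start"].to_numpy(), g.start)
            ov = np.clip(ov, 0, None)
            if ov.sum() == 0:
                raise ValueError(f"gene {g.gene}: outside simulated span")
            out.loc[g.gene, s] = float(
                (segs["mean"].to_numpy() * ov).sum() / ov.sum())
    return out


def simulate_expression(truth: SimulationTruth, genes: pd.DataFrame,
                        config: SimulationConfig,
                        samples: list[str] | None = None) -> ExpressionMatrix:
    """Expression coupled to true gene copy number:
    expr = slope * copy + N(0, noise); monotone in copy at zero noise.

    Default sample set mirrors a two-denominator design: the first
    ``n_expression_matched`` array samples plus all expression-only
    samples.
    """
    rng = config.rng("expression")
    if samples is None:
        arrays, extra = _sample_names(config)
        samples = arrays[:config.n_expression_matched] + extra
    cn = true_gene_copy(truth, genes, samples)
    noise = rng.normal(0.0, config.expression_noise,
                       size=cn.shape) if config.expression_noise > 0 else 0.0
    values = config.expression_slope * cn + noise
    return ExpressionMatrix(pd.DataFrame(values, index=cn.index,
                                         columns=samples))


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Run the full generator: genome, tracks, cohort, expression."""
    genome, tracks, genes, motifs = simulate_genome(config)
    pm, truth = simulate_cohort(config)
    truth.motif_intervals = motifs
    expr = simulate_expression(truth, genes, config)
    return SimulatedStudy(config=config, genome=genome, tracks=tracks,
                          genes=genes, probe_matrix=pm, truth=truth,
                          expression=expr)


# ---------------------------------------------------------------------------
# planted-truth helpers

def true_exclusion_events(truth: SimulationTruth, amplicon: str,
                          target: dict, intervening: dict,
                          promoter_length: int = 2000) -> pd.DataFrame:
    """Samples whose realized amplicon start excludes the target gene and
    falls inside the intervening gene body or promoter — the planted
    analog of a gene-exclusion amplification event."""
    from .calls import promoter_span

    prom = promoter_span(intervening, promoter_length)
    body = (int(intervening["start"]), int(intervening["end"]))
    rows = []
    b = truth.boundaries
    for ev in b[b["amplicon"] == amplicon].itertuples():
        if ev.start < target["end"]:
            continue  # target included (or partially covered)
        if body[0] <= ev.start < body[1]:
            rows.append((ev.sample, ev.start, "coding"))
        elif prom[0] <= ev.start < prom[1]:
            rows.append((ev.sample, ev.start, "promoter"))
    return pd.DataFrame(rows, columns=["sample", "pos", "class"])


# ---------------------------------------------------------------------------
# default study conditions

def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Scaled-down default study: a 6p22-like chromosome with one amplicon
    and a gene trio supporting target-exclusion events, and a 1q21-24-like
    chromosome with three amplicons whose proximal boundary is drawn from
    a hotspot window.

    Cohort structure mirrors a 68-array zoom-in study with 58 matched and
    154 additional expression-only samples; probe noise 0.065 log2 units
    puts the median sample-adaptive threshold near 0.20.
    """
    genes6 = [
        ("TGT", "chr6s", 1_900_000, 1_960_000, "+"),   # E2F3-like target
        ("INT", "chr6s", 2_000_000, 2_060_000, "+"),   # CDKAL1-like
        ("AUX", "chr6s", 2_400_000, 2_430_000, "+"),   # SOX4-like auxiliary
    ]
    defaults = dict(
        chrom_lengths={"chr6s": 6_400_000, "chr1s": 12_800_000},
        probe_spacing=10_000,
        n_samples=68,
        amplicons=[
            AmpliconSpec("6p", "chr6s", 1_700_000, 4_500_000, amplitude=1.2,
                         prob=29 / 68,
                         start_window=(1_700_000, 2_062_000)),
            AmpliconSpec("1", "chr1s", 1_500_000, 3_000_000, amplitude=1.0,
                         prob=19 / 68, start_window=(1_500_000, 1_700_000)),
            AmpliconSpec("2", "chr1s", 4_000_000, 5_500_000, amplitude=1.0,
                         prob=25 / 68),
            AmpliconSpec("3", "chr1s", 8_000_000, 9_000_000, amplitude=1.0,
                         prob=35 / 68),
        ],
        noise_sd=0.065,
        n_g4_motifs=100,
        cnv_intervals=[("chr6s", 5_400_000, 5_500_000),
                       ("chr1s", 11_000_000, 11_120_000)],
        seed=seed,
    )
    gene_override = overrides.pop("genes", None)
    defaults.update(overrides)
    overrides = {}
    base = SimulationConfig(**defaults)
    if gene_override is not None:
        return replace(base, genes=gene_override)
    genes = _auto_genes(base)
    if base.chrom_lengths.get("chr6s", 0) >= 2_430_000:
        trio = pd.DataFrame(
            genes6, columns=["gene", "chrom", "start", "end", "strand"])
        # drop auto genes colliding with the trio, then append it
        drop = np.zeros(len(genes), dtype=bool)
        for t in trio.itertuples():
            drop |= ((genes["chrom"] == t.chrom) & (genes["start"] < t.end)
                     & (genes["end"] > t.start)).to_numpy()
        genes = pd.concat([genes[~drop], trio], ignore_index=True)
        genes = genes.sort_values(["chrom", "start"]).reset_index(drop=True)
    return replace(base, genes=genes)
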