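"""End-to-end orchestration: simulate (or load) -> segment -> call ->
breakpoints -> elements -> associate -> express -> report.

A run is fully determined by one config and one seed; every run writes a
manifest (parameter hash, seed, package versions, stage counts) so
permutation-heavy analyses can be reproduced and audited.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .breakpoints import (WindowGrid, bin_breakpoints, breakpoint_enrichment,
                          call_breakpoints)
from .calls import (AmpliconDefinition, call_aberrations, call_amplicon_events,
                    cooccurrence_summary, find_gene_excluding_amplifications,
                    gain_frequency, gene_copy_number, gene_inclusion_status)
from .elements import (eligible_windows, motif_hits_to_track, scan_genome_g4,
                       window_element_content)
from .expression import amplified_vs_rest_test, spearman_cn_expression
from .segmentation import segment_cohort
from .stats import breakpoint_fold_and_test, region_element_enrichment, split_by_median
from .synthetic import SimulationConfig, default_config, simulate_study

logger = logging.getLogger("focalamp")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """One config object driving the whole analysis.

    Either ``simulation`` is set (synthetic study) or the input paths are.
    ``regions`` maps a name to (chrom, start, end); ``enrich_regions``
    names the regions in which breakpoint clustering is permutation-
    tested; ``element_regions`` names the two regions compared in the
    element-enrichment contingency table.
    """

    simulation: SimulationConfig | None = None
    probes_path: str | None = None
    genome_path: str | None = None
    expression_path: str | None = None
    track_paths: dict[str, str] = field(default_factory=dict)
    genes_path: str | None = None

    regions: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    amplicons: list[AmpliconDefinition] = field(default_factory=list)
    enrich_regions: list[str] = field(default_factory=list)
    element_regions: tuple[str, str] | None = None
    exclusion_genes: tuple[str, str, str] | None = None  # target, aux, interv

    alpha: float = 0.01
    cbs_permutations: int = 10_000
    min_probes: int = 5
    sat_floor: float = 0.15
    sat_k: float = 3.0
    window_size: int = 50_000
    enrich_permutations: int = 10_000
    min_overlap_fraction: float = 0.25
    promoter_length: int = 2000
    quality_filter: bool = True
    seed: int = 0

    @classmethod
    def default_synthetic(cls, seed: int = 0,
                          simulation: SimulationConfig | None = None,
                          **overrides) -> "PipelineConfig":
        """Synthetic study with scaled 6p22-like and 1q21-24-like regions."""
        sim = simulation or default_config(seed=seed)
        cfg = cls(
            simulation=sim,
            regions={
                "6p_region": ("chr6s", 1_000_000, 5_000_000),
                "peak_6p": ("chr6s", 1_500_000, 4_600_000),
                "peak_1q": ("chr1s", 1_000_000, 9_500_000),
            },
            amplicons=[AmpliconDefinition(a.name, a.chrom, a.start, a.end)
                       for a in sim.amplicons if a.chrom == "chr1s"],
            enrich_regions=["6p_region", "peak_1q"],
            element_regions=("peak_6p", "peak_1q"),
            exclusion_genes=("TGT", "AUX", "INT"),
            seed=seed,
        )
        return dataclasses.replace(cfg, **overrides) if overrides else cfg

    def parameter_hash(self) -> str:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: encode(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, pd.DataFrame):
                return obj.to_csv()
            if isinstance(obj, dict):
                return {str(k): encode(v) for k, v in sorted(obj.items())}
            if isinstance(obj, (list, tuple)):
                return [encode(v) for v in obj]
            return obj

        blob = json.dumps(encode(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            from .synthetic import AmpliconSpec
            amps = [AmpliconSpec(**a) for a in sim.pop("amplicons", [])]
            sim = SimulationConfig(amplicons=amps, **sim)
        amps = [AmpliconDefinition(**a) for a in raw.pop("amplicons", [])]
        regions = {k: tuple(v) for k, v in raw.pop("regions", {}).items()}
        er = raw.pop("element_regions", None)
        eg = raw.pop("exclusion_genes", None)
        return cls(simulation=sim, amplicons=amps, regions=regions,
                   element_regions=tuple(er) if er else None,
                   exclusion_genes=tuple(eg) if eg else None, **raw)


@dataclass
class PipelineResult:
    config: PipelineConfig
    probe_matrix: object
    profiles: list
    sats: list
    call_matrix: object
    frequency: pd.DataFrame
    gene_cn: pd.DataFrame | None
    breakpoint_sets: list
    window_grid: object
    window_table: pd.DataFrame | None
    enrichment: dict
    associations: list
    element_enrichment: dict
    amplicon_calls: object | None
    cooccurrence: tuple | None
    exclusion_events: list
    correlations: list
    group_tests: list
    truth: object | None
    manifest: dict


def _stage(name):
    logger.info("stage: %s", name)


def run_pipeline(config: PipelineConfig,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Run every stage the config enables and optionally write the report
    bundle (TSV tables, BED/bedGraph tracks, JSON manifest) to ``outdir``.

    Identical config + seed gives identical outputs. A stage failure
    raises with the stage name; outputs written so far are retained.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameter_hash": config.parameter_hash(),
        "versions": _versions(),
        "counts": {},
    }

    def fail(stage, exc):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---- inputs -----------------------------------------------------------
    _stage("inputs")
    truth = genome = None
    tracks: dict = {}
    genes = None
    expr = None
    try:
        if config.simulation is not None:
            study = simulate_study(config.simulation)
            pm, truth = study.probe_matrix, study.truth
            genome, tracks, genes = study.genome, study.tracks, study.genes
            expr = study.expression
            chrom_lengths = dict(config.simulation.chrom_lengths)
        else:
            if config.probes_path is None:
                raise ValueError("need simulation config or probes_path")
            pm = fio.read_probe_table(config.probes_path,
                                      config.quality_filter)
            pm = fio.merge_replicate_probes(pm)
            if config.genome_path:
                genome = fio.read_fasta(config.genome_path)
            for name, path in config.track_paths.items():
                tracks[name.upper()] = fio.read_bed(path, label=name.upper())
            if config.genes_path:
                genes = pd.read_csv(config.genes_path, sep="\t")
            if config.expression_path:
                expr = fio.read_expression_table(config.expression_path)
            if genome is not None:
                chrom_lengths = {c: len(s) for c, s in genome.items()}
            else:
                ends = pm.probes.groupby("chrom")["end"].max()
                chrom_lengths = {c: int(e) for c, e in ends.items()}
        manifest["counts"]["probes"] = pm.n_probes
        manifest["counts"]["samples"] = pm.n_samples
    except Exception as exc:  # noqa: BLE001
        fail("inputs", exc)

    # ---- segmentation -----------------------------------------------------
    _stage("segmentation")
    try:
        profiles, sats = segment_cohort(
            pm, alpha=config.alpha, permutations=config.cbs_permutations,
            min_probes=config.min_probes, seed=config.seed,
            sat_floor=config.sat_floor, sat_k=config.sat_k)
        manifest["counts"]["segments"] = int(
            sum(len(p.segments) for p in profiles))
        if out is not None:
            fio.write_segments_seg(profiles, out / "segments.seg")
            pd.DataFrame([(s.sample, s.tau, s.noise) for s in sats],
                         columns=["sample", "tau", "noise"]).to_csv(
                out / "sat.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        fail("segmentation", exc)

    # ---- calls ------------------------------------------------------------
    _stage("calls")
    try:
        cm = call_aberrations(profiles, sats, pm)
        freq = gain_frequency(cm)
        gene_cn = gene_copy_number(profiles, genes) if genes is not None \
            else None
        manifest["counts"]["gain_calls"] = int((cm.calls == 1).sum())
        if out is not None:
            freq.to_csv(out / "gain_frequency.tsv", sep="\t", index=False)
            if gene_cn is not None:
                gene_cn.to_csv(out / "gene_copy_number.tsv", sep="\t")
    except Exception as exc:  # noqa: BLE001
        fail("calls", exc)

    # ---- breakpoints ------------------------------------------------------
    _stage("breakpoints")
    try:
        bp_sets = [call_breakpoints(p, s) for p, s in zip(profiles, sats)]
        grid = WindowGrid.from_chrom_lengths(chrom_lengths,
                                             config.window_size)
        grid = eligible_windows(grid, pm, tracks.get("CNV"))
        counts, dropped = bin_breakpoints(bp_sets, grid)
        manifest["counts"]["breakpoints"] = int(
            sum(len(b.events) for b in bp_sets))
        manifest["counts"]["breakpoints_dropped"] = dropped
        enrichment = {}
        rng_seeds = np.random.SeedSequence(config.seed).spawn(
            max(1, len(config.enrich_regions)))
        for region_name, child in zip(config.enrich_regions, rng_seeds):
            region = config.regions[region_name]
            enrichment[region_name] = breakpoint_enrichment(
                counts, grid, region, config.enrich_permutations,
                seed=int(child.generate_state(1)[0] % (2**31)))
        if out is not None:
            frames = [b.events.assign(sample=b.sample)
                      for b in bp_sets if len(b.events)]
            ev = pd.concat(frames, ignore_index=True) if frames else \
                pd.DataFrame(columns=["chrom", "pos", "left_mean",
                                      "right_mean", "sample"])
            ev.to_csv(out / "breakpoints.tsv", sep="\t", index=False)
            for name, res in enrichment.items():
                res.table.to_csv(out / f"enrichment_{name}.tsv", sep="\t",
                                 index=False)
    except Exception as exc:  # noqa: BLE001
        fail("breakpoints", exc)

    # ---- sequence elements ------------------------------------------------
    _stage("elements")
    window_table = None
    try:
        element_tracks = {k: v for k, v in tracks.items() if k != "CNV"}
        hits = scan_genome_g4(genome) if genome is not None else None
        if element_tracks or hits is not None:
            window_table = window_element_content(grid, element_tracks, hits)
            window_table["breakpoints"] = counts
            if out is not None:
                window_table.to_csv(out / "windows.tsv", sep="\t",
                                    index=False)
                if hits is not None:
                    fio.write_bed(motif_hits_to_track(hits),
                                  out / "g4_motifs.bed")
        manifest["counts"]["g4_motifs"] = len(hits) if hits else 0
        manifest["counts"]["eligible_windows"] = int(
            grid.windows["eligible"].sum())
    except Exception as exc:  # noqa: BLE001
        fail("elements", exc)

    # ---- association ------------------------------------------------------
    _stage("association")
    associations = []
    element_enr = {}
    try:
        if window_table is not None:
            content_cols = [c for c in window_table.columns
                            if c.endswith("_frac") or c == "g4_bp"]
            for col in content_cols:
                split = split_by_median(window_table, col)
                if split.degenerate:
                    continue
                associations.append(breakpoint_fold_and_test(
                    counts, split,
                    eligible=window_table["eligible"].to_numpy()))
            if config.element_regions is not None:
                ra = grid.region_mask(*config.regions[config.element_regions[0]])
                rb = grid.region_mask(*config.regions[config.element_regions[1]])
                for col in content_cols:
                    ct, p, odds = region_element_enrichment(
                        window_table, col, ra, rb,
                        labels=config.element_regions)
                    element_enr[col] = {"table": ct, "p": p, "odds": odds}
            if out is not None and associations:
                pd.DataFrame([dataclasses.asdict(a) for a in associations]
                             ).to_csv(out / "associations.tsv", sep="\t",
                                      index=False)
            if out is not None and element_enr:
                rows = [(k, v["table"].a, v["table"].b, v["table"].c,
                         v["table"].d, v["p"], v["odds"])
                        for k, v in element_enr.items()]
                pd.DataFrame(rows, columns=[
                    "element", "a_above", "a_below", "b_above", "b_below",
                    "p", "odds_ratio"]).to_csv(
                    out / "element_enrichment.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        fail("association", exc)

    # ---- amplicon architecture -------------------------------------------
    _stage("amplicons")
    acm = cooc = None
    exclusion_events = []
    try:
        if config.amplicons:
            acm = call_amplicon_events(profiles, sats, config.amplicons,
                                       config.min_overlap_fraction,
                                       cm=cm, genes=genes)
            cooc = cooccurrence_summary(acm)
            if out is not None:
                acm.calls.to_csv(out / "amplicon_calls.tsv", sep="\t")
        if config.exclusion_genes is not None and genes is not None:
            tgt, aux, inter = config.exclusion_genes
            gidx = genes.set_index("gene")
            events = find_gene_excluding_amplifications(
                cm, profiles, sats,
                target=gidx.loc[tgt].to_dict() | {"gene": tgt},
                auxiliary=gidx.loc[aux].to_dict() | {"gene": aux},
                intervening=gidx.loc[inter].to_dict() | {"gene": inter},
                promoter_length=config.promoter_length)
            exclusion_events = events
            manifest["counts"]["exclusion_events"] = len(events)
        if out is not None and (cooc or exclusion_events):
            report = {
                "cooccurrence": cooc[0] if cooc else {},
                "exclusion_rule_violations": cooc[1] if cooc else [],
                "gene_exclusion_events": [dataclasses.asdict(e)
                                          for e in exclusion_events],
            }
            (out / "events.json").write_text(json.dumps(report, indent=2))
    except Exception as exc:  # noqa: BLE001
        fail("amplicons", exc)

    # ---- expression -------------------------------------------------------
    _stage("expression")
    correlations = []
    group_tests = []
    try:
        if expr is not None and gene_cn is not None:
            correlations = spearman_cn_expression(gene_cn, expr)
            status = gene_inclusion_status(cm, genes)
            amplified = {g: [s for s in cm.samples
                             if status.loc[g, s] in ("full", "partial")]
                         for g in genes["gene"]}
            group_tests = amplified_vs_rest_test(expr, amplified)
            if out is not None:
                pd.DataFrame([dataclasses.asdict(r) for r in correlations]
                             ).to_csv(out / "correlations.tsv", sep="\t",
                                      index=False)
                pd.DataFrame([dataclasses.asdict(r) for r in group_tests]
                             ).to_csv(out / "group_tests.tsv", sep="\t",
                                      index=False)
        else:
            logger.info("expression inputs absent; stage skipped")
    except Exception as exc:  # noqa: BLE001
        fail("expression", exc)

    if out is not None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(
        config=config, probe_matrix=pm, profiles=profiles, sats=sats,
        call_matrix=cm, frequency=freq, gene_cn=gene_cn,
        breakpoint_sets=bp_sets, window_grid=grid,
        window_table=window_table, enrichment=enrichment,
        associations=associations, element_enrichment=element_enr,
        amplicon_calls=acm, cooccurrence=cooc,
        exclusion_events=exclusion_events, correlations=correlations,
        group_tests=group_tests, truth=truth, manifest=manifest)


def _versions() -> dict:
    import scipy

    from . import __version__

    return {"focalamp": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scipy": scipy.__version__}
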