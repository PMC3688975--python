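"""Ground-truth fidelity of the synthetic study generator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from focalamp.elements import find_g4_motifs
from focalamp.synthetic import (AmpliconSpec, SimulationConfig,
                                default_config, simulate_cohort,
                                simulate_expression, simulate_genome,
                                simulate_study, true_gene_copy)


def small_config(**overrides) -> SimulationConfig:
    base = dict(
        chrom_lengths={"chrA": 500_000},
        probe_spacing=5000,
        n_samples=4,
        amplicons=[AmpliconSpec("amp", "chrA", 100_000, 300_000,
                                amplitude=1.0, prob=1.0)],
        noise_sd=0.0,
        n_g4_motifs=0,
        n_expression_matched=2,
        n_expression_extra=2,
        seed=1,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_rejects_bad_lengths_and_probabilities(self):
        with pytest.raises(ValueError):
            small_config(chrom_lengths={"chrA": 0})
        with pytest.raises(ValueError):
            small_config(noise_sd=-0.1)
        with pytest.raises(ValueError):
            small_config(amplicons=[AmpliconSpec("a", "chrA", 0, 1000,
                                                 prob=1.5)])
        with pytest.raises(ValueError):
            small_config(amplicons=[AmpliconSpec("a", "chrA", 0, 900_000)])

    def test_narrow_amplicon_warns(self):
        with pytest.warns(UserWarning, match="fewer than 5"):
            small_config(amplicons=[AmpliconSpec("a", "chrA", 0, 20_000)])


class TestGenome:
    def test_g_free_backbone_yields_exactly_planted_motifs(self):
        cfg = small_config(g_free_backbone=True, n_g4_motifs=7)
        genome, tracks, genes, motifs = simulate_genome(cfg)
        hits = find_g4_motifs(genome["chrA"], "chrA", both_strands=False)
        assert len(hits) == 7
        assert len(motifs) == 7
        found = {(h.start, h.end) for h in hits}
        planted = {(r.start, r.end) for r in motifs.itertuples()}
        assert found == planted

    def test_zero_planted_motifs_on_g_free_backbone(self):
        cfg = small_config(g_free_backbone=True, n_g4_motifs=0)
        genome, *_ = simulate_genome(cfg)
        assert find_g4_motifs(genome["chrA"], "chrA",
                              both_strands=False) == []

    def test_collision_error_names_the_locus(self):
        cfg = small_config(chrom_lengths={"chrA": 60}, n_g4_motifs=3,
                           probe_spacing=5, amplicons=[])
        with pytest.raises(RuntimeError, match="chrA"):
            simulate_genome(cfg)

    def test_element_tracks_non_overlapping_within_class(self):
        cfg = small_config()
        _, tracks, _, _ = simulate_genome(cfg)
        for name in ("LINE", "SINE", "LTR"):
            df = tracks[name].intervals
            assert (df["start"].to_numpy()[1:]
                    >= df["end"].to_numpy()[:-1]).all()

    def test_element_coverage_calibrated_to_density(self):
        """Realized LINE coverage tracks the configured density (0.44
        over a 6.25-Mb chromosome) across seeds."""
        covs = []
        for seed in range(20):
            cfg = small_config(
                chrom_lengths={"chrA": 6_250_000}, seed=seed,
                amplicons=[],
                element_densities={"LINE": 0.44},
                element_mean_lengths={"LINE": 3000})
            _, tracks, _, _ = simulate_genome(cfg)
            df = tracks["LINE"].intervals
            covs.append((df["end"] - df["start"]).sum() / 6_250_000)
        assert np.mean(covs) == pytest.approx(0.44, abs=0.02)


class TestCohort:
    def test_noise_free_probes_reproduce_truth_exactly(self):
        pm, truth = simulate_cohort(small_config())
        inside = (pm.probes["start"] >= 100_000) & \
            (pm.probes["start"] < 300_000)
        assert (pm.ratios[inside.to_numpy()] == 1.0).all()
        assert (pm.ratios[~inside.to_numpy()] == 0.0).all()

    def test_same_seed_identical_matrix(self):
        cfg = small_config(noise_sd=0.1)
        pm1, _ = simulate_cohort(cfg)
        pm2, _ = simulate_cohort(small_config(noise_sd=0.1))
        np.testing.assert_array_equal(pm1.ratios, pm2.ratios)
        pd.testing.assert_frame_equal(pm1.probes, pm2.probes)

    def test_different_seed_differs(self):
        pm1, _ = simulate_cohort(small_config(noise_sd=0.1, seed=1))
        pm2, _ = simulate_cohort(small_config(noise_sd=0.1, seed=2))
        assert not np.array_equal(pm1.ratios, pm2.ratios)

    def test_membership_is_binomial(self):
        cfg = small_config(
            n_samples=200, n_expression_matched=0, n_expression_extra=0,
            amplicons=[AmpliconSpec("amp", "chrA", 100_000, 300_000,
                                    prob=0.5)])
        _, truth = simulate_cohort(cfg)
        count = int(truth.membership["amp"].sum())
        sd = np.sqrt(200 * 0.25)
        assert abs(count - 100) <= 3 * sd

    def test_truth_segments_tile_without_gaps(self):
        _, truth = simulate_cohort(small_config(noise_sd=0.05))
        for s, sub in truth.segments.groupby("sample"):
            sub = sub.sort_values("start")
            assert sub.iloc[0]["start"] == 0
            assert sub.iloc[-1]["end"] == 500_000
            assert (sub["start"].to_numpy()[1:]
                    == sub["end"].to_numpy()[:-1]).all()
            # every true breakpoint separates segments of different means
            means = sub["mean"].to_numpy()
            assert (np.diff(means) != 0).all()

    def test_residuals_are_gaussian_across_seeds(self):
        """Probe ratios minus planted means: KS against N(0, sigma) is
        non-significant at alpha = 0.01 in >= 95% of 100 seeds."""
        sigma = 0.08
        passed = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cfg = small_config(noise_sd=sigma, seed=seed, n_samples=1,
                               n_expression_matched=0,
                               n_expression_extra=0)
            pm, truth = simulate_cohort(cfg)
            inside = ((pm.probes["start"] >= 100_000)
                      & (pm.probes["start"] < 300_000)).to_numpy()
            resid = pm.ratios[:, 0] - np.where(inside, 1.0, 0.0)
            p = stats.kstest(resid, "norm", args=(0, sigma)).pvalue
            passed += p > 0.01
        assert passed / n_seeds >= 0.95

    def test_hotspot_window_controls_boundary_draws(self):
        cfg = small_config(
            n_samples=50, noise_sd=0.0, n_expression_matched=0,
            n_expression_extra=0,
            amplicons=[AmpliconSpec("amp", "chrA", 100_000, 300_000,
                                    prob=1.0,
                                    start_window=(100_000, 150_000))])
        _, truth = simulate_cohort(cfg)
        starts = truth.boundaries["start"]
        assert starts.between(100_000, 150_000 - 1).all()
        assert starts.nunique() > 1


class TestExpression:
    def test_perfect_coupling_gives_rho_one(self):
        cfg = small_config(expression_slope=1.0, expression_noise=0.0)
        pm, truth = simulate_cohort(cfg)
        expr = simulate_expression(truth, truth.genes, cfg)
        cn = true_gene_copy(truth, truth.genes, expr.samples)
        for gene in truth.genes["gene"]:
            x = cn.loc[gene].to_numpy()
            if np.ptp(x) == 0:
                continue
            rho = stats.spearmanr(x, expr.values.loc[gene]).statistic
            assert rho == pytest.approx(1.0)

    def test_zero_slope_decouples(self):
        cfg = small_config(
            chrom_lengths={"chrA": 25_000_000}, gene_spacing=500_000,
            expression_slope=0.0, expression_noise=1.0,
            n_samples=30, n_expression_matched=30, n_expression_extra=0,
            amplicons=[AmpliconSpec("amp", "chrA", 1_000_000, 20_000_000,
                                    prob=0.5)])
        pm, truth = simulate_cohort(cfg)
        expr = simulate_expression(truth, truth.genes, cfg)
        cn = true_gene_copy(truth, truth.genes, expr.samples)
        rhos = []
        for gene in truth.genes["gene"]:
            x = cn.loc[gene].to_numpy()
            if np.ptp(x) == 0:
                continue
            rhos.append(stats.spearmanr(x, expr.values.loc[gene]).statistic)
        assert len(rhos) >= 30
        assert abs(np.mean(rhos)) < 0.1

    def test_gene_outside_simulated_chromosomes_rejected(self):
        cfg = small_config()
        _, truth = simulate_cohort(cfg)
        bad = pd.DataFrame([("gX", "chrZ", 0, 1000, "+")],
                           columns=["gene", "chrom", "start", "end",
                                    "strand"])
        with pytest.raises(ValueError, match="gX"):
            simulate_expression(truth, bad, cfg)


class TestStudyBundle:
    def test_default_study_round_trips_through_io(self, tmp_path):
        from focalamp import io as fio

        cfg = default_config(seed=3, n_samples=3, n_expression_matched=2,
                             n_expression_extra=2,
                             chrom_lengths={"chr6s": 3_000_000,
                                            "chr1s": 3_000_000},
                             amplicons=[AmpliconSpec(
                                 "6p", "chr6s", 1_700_000, 2_800_000,
                                 amplitude=1.2, prob=0.5,
                                 start_window=(1_700_000, 2_062_000))],
                             n_g4_motifs=20)
        study = simulate_study(cfg)
        fio.write_probe_table(study.probe_matrix, tmp_path / "p.tsv")
        back = fio.read_probe_table(tmp_path / "p.tsv")
        np.testing.assert_allclose(back.ratios, study.probe_matrix.ratios)
        fio.write_fasta(study.genome, tmp_path / "g.fa")
        assert fio.read_fasta(tmp_path / "g.fa") == study.genome
        for name, track in study.tracks.items():
            if not len(track):
                continue
            fio.write_bed(track, tmp_path / f"{name}.bed")
            back_track = fio.read_bed(tmp_path / f"{name}.bed", name)
            pd.testing.assert_frame_equal(
                back_track.intervals[["chrom", "start", "end"]],
                track.intervals[["chrom", "start", "end"]].reset_index(
                    drop=True))
        fio.write_expression_table(study.expression, tmp_path / "e.tsv")
        back_expr = fio.read_expression_table(tmp_path / "e.tsv")
        np.testing.assert_allclose(back_expr.values.to_numpy(),
                                   study.expression.values.to_numpy())
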