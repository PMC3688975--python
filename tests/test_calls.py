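"""Gain/loss calling, frequency/amplitude maps, gene copy number, amplicon
architecture and gene-exclusion events."""

import numpy as np
import pandas as pd
import pytest

from focalamp.calls import (AmpliconDefinition, call_aberrations,
                            call_amplicon_events, cooccurrence_summary,
                            find_gene_excluding_amplifications,
                            gain_frequency, gene_copy_number,
                            gene_inclusion_status, promoter_span)
from tests.conftest import make_pm, make_profile, make_sat


def _pm_ten_probes():
    return make_pm({"S1": np.zeros(10)}, spacing=1000)


class TestCallAberrations:
    @pytest.mark.parametrize("mean, expected", [
        (0.5, 1),    # above tau -> gain
        (0.2, 0),    # equal to tau -> neutral (strict inequality)
        (-0.5, -1),  # below -tau -> loss
    ])
    def test_threshold_rule_is_strict(self, mean, expected):
        pm = _pm_ten_probes()
        prof = make_profile("S1", [("chr1", 0, 10_000, 10, mean)])
        cm = call_aberrations(prof, make_sat("S1", 0.2), pm)
        assert (cm.calls[:, 0] == expected).all()

    def test_uncovered_probe_is_neutral_with_warning(self):
        pm = _pm_ten_probes()
        prof = make_profile("S1", [("chr1", 0, 5000, 5, 0.5)])
        with pytest.warns(UserWarning, match="not covered"):
            cm = call_aberrations(prof, make_sat("S1", 0.2), pm)
        assert (cm.calls[:5, 0] == 1).all()
        assert (cm.calls[5:, 0] == 0).all()
        assert np.isnan(cm.segvals[5:, 0]).all()

    def test_mismatched_sample_ids_rejected(self):
        pm = _pm_ten_probes()
        prof = make_profile("S1", [("chr1", 0, 10_000, 10, 0.0)])
        with pytest.raises(ValueError, match="S2"):
            call_aberrations(prof, make_sat("S2", 0.2), pm)


class TestGainFrequency:
    def test_frequency_and_conditional_amplitude(self):
        values = {"A": 0.5, "B": 0.7, "C": 0.9, "D": 0.0, "E": 0.1}
        pm = make_pm({s: np.full(10, v) for s, v in values.items()},
                     spacing=1000)
        profs = [make_profile(s, [("chr1", 0, 10_000, 10, v)])
                 for s, v in values.items()]
        sats = [make_sat(s, 0.2) for s in values]
        cm = call_aberrations(profs, sats, pm)
        fp = gain_frequency(cm)
        assert (fp["gain_freq"] == 0.6).all()
        np.testing.assert_allclose(fp["gain_amp"], 0.7)

    def test_no_gains_gives_zero_frequency_and_missing_amplitude(self):
        pm = make_pm({"S1": np.zeros(10)}, spacing=1000)
        prof = make_profile("S1", [("chr1", 0, 10_000, 10, 0.0)])
        fp = gain_frequency(call_aberrations(prof, make_sat("S1", 0.2), pm))
        assert (fp["gain_freq"] == 0).all()
        assert fp["gain_amp"].isna().all()

    def test_conservation_of_gain_calls(self, rng):
        n_samples, n_probes = 7, 40
        pms = {f"S{i}": rng.normal(0, 0.4, n_probes)
               for i in range(n_samples)}
        pm = make_pm(pms, spacing=1000)
        profs, sats = [], []
        for i in range(n_samples):
            # one segment per probe: segment value = probe value
            segs = [("chr1", j * 1000, (j + 1) * 1000, 1, pms[f"S{i}"][j])
                    for j in range(n_probes)]
            profs.append(make_profile(f"S{i}", segs))
            sats.append(make_sat(f"S{i}", 0.2))
        cm = call_aberrations(profs, sats, pm)
        fp = gain_frequency(cm)
        assert int(round(fp["gain_freq"].sum() * n_samples)) == \
            int((cm.calls == 1).sum())


class TestGeneCopyNumber:
    def test_gene_inside_single_segment(self):
        prof = make_profile("S1", [("chr1", 0, 100_000, 100, 0.8)])
        genes = pd.DataFrame([("g", "chr1", 10_000, 20_000)],
                             columns=["gene", "chrom", "start", "end"])
        cn = gene_copy_number(prof, genes)
        assert cn.loc["g", "S1"] == pytest.approx(0.8)

    @pytest.mark.parametrize("segs, span, expected", [
        # 40% of length at 1.0, 60% at 0.0
        ([("chr1", 0, 40_000, 40, 1.0), ("chr1", 40_000, 100_000, 60, 0.0)],
         (0, 100_000), 0.4),
        # three equal thirds at 0.3 / 0.6 / 0.9
        ([("chr1", 0, 10_000, 10, 0.3), ("chr1", 10_000, 20_000, 10, 0.6),
          ("chr1", 20_000, 30_000, 10, 0.9)], (0, 30_000), 0.6),
    ])
    def test_length_weighted_mean_matches_overlap_oracle(self, segs, span,
                                                         expected):
        prof = make_profile("S1", segs)
        genes = pd.DataFrame([("g", "chr1", span[0], span[1])],
                             columns=["gene", "chrom", "start", "end"])
        cn = gene_copy_number(prof, genes)
        # independent overlap-weighted oracle
        weights = [min(e, span[1]) - max(s, span[0])
                   for _, s, e, _, _ in segs]
        oracle = sum(w * m for w, (_, _, _, _, m) in zip(weights, segs)) / \
            sum(weights)
        assert cn.loc["g", "S1"] == pytest.approx(oracle)
        assert cn.loc["g", "S1"] == pytest.approx(expected)

    def test_gene_without_overlap_is_missing(self):
        prof = make_profile("S1", [("chr1", 0, 1000, 1, 0.5)])
        genes = pd.DataFrame([("g", "chr9", 0, 100)],
                             columns=["gene", "chrom", "start", "end"])
        assert np.isnan(gene_copy_number(prof, genes).loc["g", "S1"])


class TestAmpliconArchitecture:
    AMPS = [AmpliconDefinition("1", "chr1", 0, 100_000),
            AmpliconDefinition("2", "chr1", 200_000, 300_000),
            AmpliconDefinition("3", "chr1", 400_000, 500_000)]

    def _profile_with_gains(self, sample, gained):
        """gained: list of (start, end) spans amplified at 1.0."""
        segs = []
        pos = 0
        for s, e in sorted(gained):
            if s > pos:
                segs.append(("chr1", pos, s, 10, 0.0))
            segs.append(("chr1", s, e, 10, 1.0))
            pos = e
        if pos < 600_000:
            segs.append(("chr1", pos, 600_000, 10, 0.0))
        return make_profile(sample, segs)

    def test_single_full_amplicon_pattern(self):
        prof = self._profile_with_gains("S1", [(200_000, 300_000)])
        acm = call_amplicon_events([prof], [make_sat("S1", 0.2)], self.AMPS)
        assert acm.patterns["S1"] == "2"

    def test_all_three_amplified(self):
        prof = self._profile_with_gains("S1", [(0, 520_000)])
        acm = call_amplicon_events([prof], [make_sat("S1", 0.2)], self.AMPS)
        assert acm.patterns["S1"] == "1+2+3"

    def test_small_overlap_below_threshold_not_called(self):
        prof = self._profile_with_gains("S1", [(200_000, 210_000)])  # 10%
        acm = call_amplicon_events([prof], [make_sat("S1", 0.2)], self.AMPS)
        assert acm.patterns["S1"] == "none"

    def test_cooccurrence_counts_match_planted_patterns(self):
        planted = {"1+2+3": 17, "2+3": 6, "1+2": 2, "3": 12}
        profiles, sats = [], []
        spans = {"1": (0, 100_000), "2": (200_000, 300_000),
                 "3": (400_000, 500_000)}
        i = 0
        for pattern, count in planted.items():
            for _ in range(count):
                gained = [spans[a] for a in pattern.split("+")]
                profiles.append(self._profile_with_gains(f"S{i}", gained))
                sats.append(make_sat(f"S{i}", 0.2))
                i += 1
        acm = call_amplicon_events(profiles, sats, self.AMPS)
        counts, violations = cooccurrence_summary(acm)
        assert counts == planted
        assert violations == []

    def test_one_and_three_without_two_is_flagged(self):
        prof = self._profile_with_gains(
            "S9", [(0, 100_000), (400_000, 500_000)])
        acm = call_amplicon_events([prof], [make_sat("S9", 0.2)], self.AMPS)
        counts, violations = cooccurrence_summary(acm)
        assert counts == {"1+3": 1}
        assert violations == ["S9"]

    def test_empty_cohort_rejected(self):
        acm = call_amplicon_events([], [], self.AMPS)
        with pytest.raises(ValueError):
            cooccurrence_summary(acm)


class TestGeneExclusion:
    # layout (bp): target 1000-2000, intervening 3000-6000 (+ strand,
    # promoter 2800-3000), auxiliary 8000-9000; probes every 100 bp
    TARGET = {"gene": "TGT", "chrom": "chr1", "start": 1000, "end": 2000,
              "strand": "+"}
    INTER = {"gene": "INT", "chrom": "chr1", "start": 3000, "end": 6000,
             "strand": "+"}
    AUX = {"gene": "AUX", "chrom": "chr1", "start": 8000, "end": 9000,
           "strand": "+"}

    def _setup(self, gain_start):
        n = 100
        values = np.where(np.arange(n) * 100 >= gain_start, 1.0, 0.0)
        pm = make_pm({"S1": values}, spacing=100, probe_len=50)
        segs = [("chr1", 0, gain_start, int(gain_start // 100), 0.0),
                ("chr1", gain_start, 10_000, n - int(gain_start // 100), 1.0)]
        prof = make_profile("S1", segs)
        sat = make_sat("S1", 0.2)
        cm = call_aberrations(prof, sat, pm)
        return cm, [prof], [sat]

    def test_promoter_span_respects_strand(self):
        assert promoter_span(self.INTER, 200) == (2800, 3000)
        minus = dict(self.INTER, strand="-")
        assert promoter_span(minus, 200) == (6000, 6200)

    def test_boundary_in_coding_region(self):
        cm, profs, sats = self._setup(gain_start=4000)
        events = find_gene_excluding_amplifications(
            cm, profs, sats, self.TARGET, self.AUX, self.INTER,
            promoter_length=200)
        assert len(events) == 1
        assert events[0].boundary_class == "coding"
        assert events[0].boundary_pos == 4000

    def test_boundary_in_promoter(self):
        cm, profs, sats = self._setup(gain_start=2900)
        events = find_gene_excluding_amplifications(
            cm, profs, sats, self.TARGET, self.AUX, self.INTER,
            promoter_length=200)
        assert len(events) == 1
        assert events[0].boundary_class == "promoter"

    def test_no_event_when_target_also_gained(self):
        cm, profs, sats = self._setup(gain_start=0)
        events = find_gene_excluding_amplifications(
            cm, profs, sats, self.TARGET, self.AUX, self.INTER)
        assert events == []

    def test_unordered_genes_rejected(self):
        cm, profs, sats = self._setup(gain_start=4000)
        with pytest.raises(ValueError):
            find_gene_excluding_amplifications(
                cm, profs, sats, self.INTER, self.AUX, self.TARGET)

    def test_inclusion_status_labels(self):
        cm, _, _ = self._setup(gain_start=4000)
        genes = pd.DataFrame([self.TARGET, self.INTER, self.AUX])
        status = gene_inclusion_status(cm, genes)
        assert status.loc["TGT", "S1"] == "excluded"
        assert status.loc["INT", "S1"] == "partial"
        assert status.loc["AUX", "S1"] == "full"
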