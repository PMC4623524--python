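"""Plastid-fraction estimation, coverage-window subsampling, and contig
classification."""

import numpy as np
import pytest

from skim2organelle import skimsim, triage
from skim2organelle._util import random_dna, revcomp
from skim2organelle.seqio import Contig, CoveragePlan


class TestEstimateCpFraction:
    def test_pure_bait_reads_fraction_near_one(self, rng):
        bait = random_dna(rng, 10_000)
        reads = skimsim.simulate_reads({"cp": (bait, True)}, {"cp": 10}, seed=1)
        frac, (lo, hi) = triage.estimate_cp_fraction(reads, {"cp": bait})
        assert frac > 0.99
        assert hi <= 1.0

    def test_known_mixture_within_interval(self, rng):
        """5% plastid bases by construction: the interval covers 0.05."""
        bait = random_dna(rng, 5_000)
        nuc = random_dna(rng, 95_000)
        reads = skimsim.simulate_reads(
            {"cp": (bait, True), "nuc": (nuc, False)},
            {"cp": 4, "nuc": 4}, seed=2)
        frac, (lo, hi) = triage.estimate_cp_fraction(reads, {"cp": bait}, seed=3)
        assert lo <= 0.05 <= hi
        assert abs(frac - 0.05) < 0.02

    def test_zero_cp_reads(self, rng):
        nuc = random_dna(rng, 20_000)
        bait = random_dna(rng, 5_000)
        reads = skimsim.simulate_reads({"nuc": (nuc, False)}, {"nuc": 5}, seed=4)
        frac, _ = triage.estimate_cp_fraction(reads, {"cp": bait})
        assert frac == 0.0

    def test_empty_bait_rejected(self):
        with pytest.raises(ValueError, match="empty bait"):
            triage.estimate_cp_fraction([], {})


class TestSubsample:
    def _reads(self, rng, n=2_000, rl=100):
        seq = random_dna(rng, 50_000)
        return skimsim.simulate_reads(
            {"s": (seq, False)}, {"s": n * 2 * rl / 50_000}, read_len=rl, seed=5)

    def test_target_base_arithmetic(self, rng):
        """fraction=1, cp=30 kb, target 100x: 3.0 Mbp selected (one pair of
        slack); the pool is large enough here so selection is exact."""
        reads = self._reads(rng, n=20_000)
        plan = CoveragePlan(genome_size=10**7, cp_size_estimate=30_000,
                            cp_fraction=1.0, target_cp_coverage=100, seed=1)
        sub = triage.subsample(reads, plan)
        bases = sum(len(p.bases1) + len(p.bases2) for p in sub)
        assert abs(bases - 3_000_000) <= 200  # one pair

    def test_paper_scale_arithmetic(self, rng):
        """fraction 1.7%, cp 134,551 bp, target 150x: the plan asks for
        134,551 x 150 / 0.017 bases and the draw honours it to one pair."""
        plan = CoveragePlan(genome_size=430_000_000, cp_size_estimate=134_551,
                            cp_fraction=0.017, target_cp_coverage=150, seed=2)
        expected = 134_551 * 150 / 0.017
        assert plan.target_read_bases == pytest.approx(expected)
        reads = self._reads(rng, n=3_000)
        with pytest.warns(UserWarning, match="taking all"):
            sub = triage.subsample(reads, plan)  # pool far smaller: takes all
        assert len(sub) == len(reads)

    def test_determinism(self, rng):
        reads = self._reads(rng)
        plan = CoveragePlan(10**6, 30_000, 0.5, 50, seed=9)
        a = triage.subsample(reads, plan)
        b = triage.subsample(reads, plan)
        assert [p.id for p in a] == [p.id for p in b]

    def test_never_more_than_requested_plus_one_pair(self, rng):
        reads = self._reads(rng)
        plan = CoveragePlan(10**7, 10_000, 1.0, 10, seed=3)
        sub = triage.subsample(reads, plan)
        bases = sum(len(p.bases1) + len(p.bases2) for p in sub)
        assert bases <= plan.target_read_bases + 200

    def test_nmpt_interference_warning_over_20x(self, rng):
        reads = self._reads(rng)
        plan = CoveragePlan(genome_size=10_000, cp_size_estimate=3_000,
                            cp_fraction=0.5, target_cp_coverage=100, seed=4)
        with pytest.warns(UserWarning, match="NMPT"):
            triage.subsample(reads, plan)


class TestClassifyContigs:
    def test_exact_cp_slice_labeled_cp(self, mock_genome):
        contig = Contig("slice", mock_genome.cp[2_000:6_000])
        report = triage.classify_contigs([contig], {"cp": mock_genome.cp})
        assert report[0].label == "cp"
        assert report[0].fraction == pytest.approx(1.0)

    def test_random_sequence_labeled_other(self, mock_genome, rng):
        contig = Contig("rand", random_dna(rng, 4_000))
        report = triage.classify_contigs([contig], {"cp": mock_genome.cp})
        assert report[0].label == "other"

    def test_label_invariant_to_reverse_complement(self, mock_genome):
        seq = mock_genome.cp[5_000:8_000]
        fwd = triage.classify_contigs([Contig("f", seq)], {"cp": mock_genome.cp})
        rev = triage.classify_contigs([Contig("r", revcomp(seq))],
                                      {"cp": mock_genome.cp})
        assert fwd[0].label == rev[0].label == "cp"
        assert fwd[0].fraction == pytest.approx(rev[0].fraction)

    def test_mock_assembly_contigs_follow_true_source(self, mock_genome):
        """Assembled contigs >= 1 kb from a mixed library receive the label
        of their true source component (nuclear -> other); contigs born from
        NMPT tracts are genuinely plastid-homologous and are excluded."""
        from skim2organelle import kassembler
        reads = skimsim.simulate_reads(
            mock_genome,
            {"cp": 60, "nuclear": 20, "mt_0": 20, "rdna_45s": 20, "rdna_5s": 20},
            seed=6)
        contigs = kassembler.assemble(kassembler.build_graph(reads, 31, 3))
        panel = {
            "cp": mock_genome.cp,
            "mt": [mock_genome.components["mt_0"][0]],
            "nR": [mock_genome.components["rdna_45s"][0],
                   mock_genome.components["rdna_5s"][0]],
        }
        report = triage.classify_contigs(contigs, panel)
        nmpt_like = set()
        for f in mock_genome.truth:
            if f.kind in ("nmpt", "mono_decoy"):
                comp = mock_genome.components[f.component][0]
                nmpt_like.add(comp[f.start:f.end])
        checked = 0
        for r in report:
            if len(r.contig.seq) < 1_000:
                continue
            source = _true_source(mock_genome, r.contig.seq)
            if source is None or _overlaps_nmpt(mock_genome, r.contig.seq, source):
                continue
            expected = {"cp": "cp", "mt_0": "mt", "mt_1": "other",
                        "nuclear": "other", "rdna_45s": "nR",
                        "rdna_5s": "nR"}[source]
            assert r.label == expected, (source, r.label, len(r.contig.seq))
            checked += 1
        assert checked >= 3

    def test_report_sorted_longest_first(self, mock_genome, rng):
        contigs = [Contig(f"c{i}", random_dna(rng, n))
                   for i, n in enumerate((500, 3_000, 1_200))]
        report = triage.classify_contigs(contigs, {"cp": mock_genome.cp})
        lengths = [len(r.contig.seq) for r in report]
        assert lengths == sorted(lengths, reverse=True)


def _true_source(genome, seq):
    for name, (comp, _) in genome.components.items():
        if seq in comp or revcomp(seq) in comp:
            return name
    return None


def _overlaps_nmpt(genome, seq, source):
    comp = genome.components[source][0]
    pos = comp.find(seq)
    if pos < 0:
        pos = comp.find(revcomp(seq))
    end = pos + len(seq)
    for f in genome.truth:
        if f.component == source and f.kind in ("nmpt", "mono_decoy"):
            if pos < f.end and f.start < end:
                return True
    return False
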