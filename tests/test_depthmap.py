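"""Seed-and-extend mapping, pileups with linked-haplotype partitions, and
anomaly profiles."""

import numpy as np
import pytest

from skim2organelle import depthmap, skimsim
from skim2organelle._util import random_dna, revcomp
from skim2organelle.seqio import Contig, ReadPair


def _pair_from(seq, start, insert, rl=100, pid="p"):
    frag = seq[start:start + insert]
    return ReadPair(pid, frag[:rl], revcomp(frag[-rl:]), [40] * rl, [40] * rl)


class TestMapReads:
    def test_exact_substring_placed_at_truth(self, rng):
        ref = random_dna(rng, 5_000)
        pair = _pair_from(ref, 1_000, 500)
        res = depthmap.map_reads([pair], ref)
        placed = {p.mate: p for p in res.placements}
        assert placed[1].start == 1_000 and placed[1].edits == 0
        assert placed[2].end == 1_500 and placed[2].strand == "-"

    def test_one_mismatch_unplaced_at_zero_budget(self, rng):
        """With a 100%-identity requirement a single mismatch is fatal."""
        ref = random_dna(rng, 2_000)
        read = list(ref[500:600])
        read[50] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[50]]
        pair = ReadPair("p", "".join(read), revcomp(ref[900:1000]),
                        [40] * 100, [40] * 100)
        res = depthmap.map_reads([pair], ref, max_mismatch_rate=0.0)
        assert {p.mate for p in res.placements} == {2}

    def test_placements_match_brute_force_scan(self, rng):
        """Error-free reads on a random 20-kb reference: the mapper's
        placements equal an exhaustive all-positions Hamming scan."""
        ref = random_dna(rng, 20_000)
        ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
        reads = skimsim.simulate_reads({"r": (ref, False)}, {"r": 5}, seed=1)
        res = depthmap.map_reads(reads, ref)
        by_key = {(p.qname, p.mate): p for p in res.placements}
        assert len(by_key) == 2 * len(reads)
        for pair in reads[:150]:
            for mate, bases in ((1, pair.bases1), (2, pair.bases2)):
                hits = []
                for strand, s in (("+", bases), ("-", revcomp(bases))):
                    arr = np.frombuffer(s.encode(), dtype=np.uint8)
                    for i in range(len(ref) - len(s) + 1):
                        if (ref_arr[i:i + len(arr)] == arr).all():
                            hits.append((i, strand))
                p = by_key[(pair.id, mate)]
                assert (p.start, p.strand) == min(hits)
                assert p.unique == (len(hits) == 1)

    def test_reverse_complement_reference_mirrors_placements(self, rng):
        ref = random_dna(rng, 3_000)
        pair = _pair_from(ref, 700, 400)
        fwd = depthmap.map_reads([pair], ref)
        rev = depthmap.map_reads([pair], revcomp(ref))
        f = {p.mate: p for p in fwd.placements}
        r = {p.mate: p for p in rev.placements}
        for mate in (1, 2):
            assert r[mate].start == len(ref) - f[mate].end
            assert r[mate].strand != f[mate].strand

    def test_circular_reference_wraps(self, rng):
        ref = random_dna(rng, 2_000)
        doubled = ref + ref
        pair = _pair_from(doubled, 1_950, 400)  # spans the origin
        res = depthmap.map_reads([pair], Contig("c", ref, circular=True))
        placed = {p.mate: p for p in res.placements}
        assert placed[1].start == 1_950 and placed[1].end == 2_050

    def test_invalid_mismatch_rate(self, rng):
        with pytest.raises(ValueError, match="max_mismatch_rate"):
            depthmap.map_reads([], random_dna(rng, 100), max_mismatch_rate=0.5)


class TestPileup:
    def test_identical_reads_single_allele(self, rng):
        ref = random_dna(rng, 3_000)
        reads = skimsim.simulate_reads({"r": (ref, False)}, {"r": 40}, seed=2)
        pile = depthmap.pileup(depthmap.map_reads(reads, ref))
        assert pile.columns == []
        assert pile.clusters == []

    def test_aligned_base_conservation(self, rng):
        """Sum of depth equals total aligned read bases (weights included)."""
        ref = random_dna(rng, 3_000)
        reads = skimsim.simulate_reads({"r": (ref, False)}, {"r": 40}, seed=3)
        res = depthmap.map_reads(reads, ref)
        pile = depthmap.pileup(res)
        assert pile.depth.sum() == pytest.approx(pile.aligned_bases)

    def test_paper_worked_partition(self, rng):
        """Read groups of sizes 186 (T,A), 24 (G,T) and 2 (T,T) at two
        linked positions partition into exactly those groups, depth 212."""
        ref = random_dna(rng, 1_000)
        pos1, pos2 = 500, 504
        base = list(ref)
        base[pos1], base[pos2] = "G", "T"  # draft carries the minor alleles
        draft = "".join(base)

        def variant(a1, a2):
            s = list(ref)
            s[pos1], s[pos2] = a1, a2
            return "".join(s)

        reads = []
        for n, (a1, a2) in ((186, ("T", "A")), (24, ("G", "T")), (2, ("T", "T"))):
            src = variant(a1, a2)
            for i in range(n):
                start = 440 + (i % 60)  # all spanning both positions
                reads.append(ReadPair(f"{a1}{a2}{i}", src[start:start + 100],
                                      revcomp(src[start + 150:start + 250]),
                                      [40] * 100, [40] * 100))
        res = depthmap.map_reads(reads, draft)
        pile = depthmap.pileup(res)
        clusters = [c for c in pile.clusters if set(c.positions) == {pos1, pos2}]
        assert len(clusters) == 1
        groups = clusters[0].groups
        assert groups[("T", "A")] == 186
        assert groups[("G", "T")] == 24
        assert groups[("T", "T")] == 2
        assert clusters[0].total == 212

    def test_majority_haplotype_fraction_binomial(self, mock_genome):
        """cp in ~12-fold excess over an NMPT-bearing minor source (within
        the 8-100-fold band): the majority haplotype fraction at
        NMPT-homologous sites tracks the simulated source proportions."""
        nm = max(mock_genome.features("nmpt", "nuclear"),
                 key=lambda f: f.end - f.start)
        cp_lo = max(0, nm.attrs["cp_start"] - 1_000)
        cp_hi = min(len(mock_genome.cp), nm.attrs["cp_end"] + 1_000)
        region = mock_genome.cp[cp_lo:cp_hi]
        tract = mock_genome.nuclear[max(0, nm.start - 500):nm.end + 500]
        cov_cp, cov_minor = 200, 16
        reads = skimsim.simulate_reads(
            {"cp": (region, False), "nmpt": (tract, False)},
            {"cp": cov_cp, "nmpt": cov_minor}, seed=4)
        res = depthmap.map_reads(reads, region)
        pile = depthmap.pileup(res)
        fractions = [c.ranked()[0][1] / c.total for c in pile.clusters]
        assert fractions, "expected NMPT-induced variant clusters"
        exp = cov_cp / (cov_cp + cov_minor)
        n = sum(c.total for c in pile.clusters)
        sd = np.sqrt(exp * (1 - exp) / n)
        # slack absorbs the lower placement efficiency of diverged reads
        assert abs(np.mean(fractions) - exp) < max(3 * sd, 0.04)


class TestAnomalyProfile:
    def test_concordant_only_zero_discordance(self, rng):
        ref = random_dna(rng, 5_000)
        reads = skimsim.simulate_reads({"r": (ref, False)}, {"r": 40}, seed=5)
        track = depthmap.anomaly_profile(depthmap.map_reads(reads, ref))
        assert track.discord.sum() == 0

    def test_false_gap_fixture_discordance_localized(self, mock_genome):
        draft, truth, reads = skimsim.make_misassembly_fixture(
            "FALSE_GAP", mock_genome, seed=3)
        res = depthmap.map_reads(reads, draft)
        track = depthmap.anomaly_profile(res)
        import re
        gap = re.search(r"N+", draft.seq)
        signal = track.discord + track.clips
        hot = np.flatnonzero(signal >= max(3, signal.max() * 0.2))
        assert hot.size > 0
        # discordance/clip mass concentrates within an insert of the gap
        assert np.all(np.abs(hot - gap.start()) < 700)

    def test_tr_collapse_depth_ratio_near_two(self, mock_genome):
        """The 4-to-2 collapsed array shows about twice the flank depth."""
        draft, truth, reads = skimsim.make_misassembly_fixture(
            "TR_COLLAPSE", mock_genome, seed=3)
        res = depthmap.map_reads(reads, draft)
        track = depthmap.anomaly_profile(res)
        s, e = 3_000, 3_036
        ratio = track.depth[s:e].mean() / track.depth[s - 500:s].mean()
        assert 1.6 <= ratio <= 2.4

    def test_few_pairs_flags_unreliable_baseline(self, rng):
        ref = random_dna(rng, 2_000)
        reads = skimsim.simulate_reads({"r": (ref, False)}, {"r": 2}, seed=6)
        res = depthmap.map_reads(reads, ref)
        with pytest.warns(UserWarning, match="unreliable"):
            track = depthmap.anomaly_profile(res)
        assert not track.reliable
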