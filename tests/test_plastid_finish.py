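"""Contig joining, quadripartite detection, issue detection and the four
fixers, and the finishing loop."""

import re

import numpy as np
import pytest

from skim2organelle import depthmap, plastid_finish as pf, skimsim
from skim2organelle._util import random_dna, revcomp, same_circular
from skim2organelle.seqio import Contig


def _fragment_circle(seq, n_frags, overlap, rng):
    """Cut a circular sequence into fragments with terminal overlaps."""
    L = len(seq)
    cuts = sorted(int(c) for c in rng.choice(L, size=n_frags, replace=False))
    doubled = seq + seq
    frags = []
    for i, c in enumerate(cuts):
        nxt = cuts[(i + 1) % n_frags] + (L if i == n_frags - 1 else 0)
        frags.append(doubled[c:nxt + overlap])
    return frags


class TestJoinAndCircularize:
    def test_five_fragments_close_the_circle(self, rng):
        truth = random_dna(rng, 12_000)
        frags = _fragment_circle(truth, 5, 20, rng)
        contigs = [Contig(f"f{i}", s if i % 2 else revcomp(s), depth=100.0)
                   for i, s in enumerate(frags)]
        draft = pf.join_and_circularize(contigs)
        assert draft.circular
        assert same_circular(draft.seq, truth)

    def test_single_circular_contig_unchanged(self, rng):
        c = Contig("c", random_dna(rng, 5_000), circular=True, depth=50.0)
        assert pf.join_and_circularize([c]) is c

    def test_subthreshold_overlap_bridged_with_n(self, rng):
        truth = random_dna(rng, 9_000)
        frags = _fragment_circle(truth, 3, 20, rng)
        frags[1] = frags[1][10:]  # junction 0->1 now only ~10 bp
        contigs = [Contig(f"f{i}", s, depth=80.0) for i, s in enumerate(frags)]
        with pytest.warns(UserWarning, match="bridged"):
            draft = pf.join_and_circularize(contigs, min_overlap=15)
        assert "N" in draft.seq

    def test_quadripartite_multiplicity_layout(self, mock_genome, cp_reads):
        """The collapsed IR unitig (about twice the baseline depth) is
        traversed twice, once per orientation, recovering the circle."""
        from skim2organelle import kassembler
        contigs = kassembler.assemble(kassembler.build_graph(cp_reads, 31, 1))
        draft = pf.join_and_circularize(contigs)
        assert draft.circular
        assert same_circular(draft.seq, mock_genome.cp)


class TestDetectQuadripartite:
    def test_planted_regions_recovered(self, mock_genome):
        regions, canon = pf.detect_quadripartite(
            Contig("cp", mock_genome.cp, circular=True))
        truth = {f.attrs["name"]: (f.start, f.end)
                 for f in mock_genome.features("region", "cp")}
        assert canon == mock_genome.cp
        assert regions == truth

    def test_rotation_gives_identical_canonical_output(self, mock_genome):
        rot = mock_genome.cp[1_000:] + mock_genome.cp[:1_000]
        regions, canon = pf.detect_quadripartite(Contig("r", rot, circular=True))
        assert canon == mock_genome.cp

    def test_ir_free_circle_warns(self, rng):
        with pytest.warns(UserWarning, match="no inverted repeat"):
            regions, canon = pf.detect_quadripartite(
                Contig("r", random_dna(rng, 20_000), circular=True))
        assert regions is None

    def test_regions_tile_the_circle(self, mock_genome):
        regions, canon = pf.detect_quadripartite(
            Contig("cp", mock_genome.cp, circular=True))
        spans = sorted(regions.values())
        assert spans[0][0] == 0 and spans[-1][1] == len(canon)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 == s2
        ira = canon[slice(*regions["IRa"])]
        irb = canon[slice(*regions["IRb"])]
        assert ira == revcomp(irb)


class TestDetectIssues:
    def test_clean_draft_empty_list(self, mock_genome, cp_reads):
        issues = pf.detect_issues(
            Contig("cp", mock_genome.cp, circular=True), cp_reads)
        assert issues == []

    @pytest.mark.parametrize("kind", skimsim.ISSUE_KINDS)
    def test_each_fixture_yields_one_matching_issue(self, mock_genome, kind):
        draft, truth, reads = skimsim.make_misassembly_fixture(
            kind, mock_genome, seed=3)
        issues = pf.detect_issues(draft, reads)
        matching = [i for i in issues if i.kind == kind]
        assert len(matching) == 1
        assert len(issues) == 1
        issue = matching[0]
        # the planted defect lives at fixture offset 3000 +- insert sd
        assert abs(issue.start - 3_000) < 150

    def test_false_snp_partition_reproduces_groups(self, mock_genome):
        draft, truth, reads = skimsim.make_misassembly_fixture(
            "FALSE_SNP", mock_genome, seed=3)
        issues = pf.detect_issues(draft, reads)
        cluster = issues[0].evidence["cluster"]
        ranked = cluster.ranked()
        # dominant group carries the true alleles, a scarce group the draft's
        assert ranked[0][0] == tuple(truth.seq[p] for p in cluster.positions)
        assert ranked[0][1] > 20 * ranked[1][1]


class TestFixers:
    def test_false_gap_merges_duplication(self, mock_genome):
        draft, truth, reads = skimsim.make_misassembly_fixture(
            "FALSE_GAP", mock_genome, seed=3)
        issue = pf.detect_issues(draft, reads)[0]
        res = pf.fix_false_gap(draft.seq, issue, reads)
        assert res.resolved and res.sequence == truth.seq

    def test_false_gap_unrelated_flanks_unresolved(self, rng):
        seq = random_dna(rng, 2_000) + "N" * 50 + random_dna(rng, 2_000)
        issue = pf.AssemblyIssue(pf.FALSE_GAP, 2_000, 2_050)
        res = pf.fix_false_gap(seq, issue, None)
        assert not res.resolved and res.sequence == seq

    def test_false_gap_short_duplication_unresolved(self, rng):
        left = random_dna(rng, 1_500)
        right = left[-9:] + random_dna(rng, 1_500)  # 9 bp < 10 bp threshold
        seq = left + "N" * 30 + right
        issue = pf.AssemblyIssue(pf.FALSE_GAP, 1_500, 1_530)
        res = pf.fix_false_gap(seq, issue, None)
        assert not res.resolved

    def test_false_snp_paper_partition_applied(self, rng):
        """Partition {186:(T,A), 24:(G,T), 2:(T,T)} with draft (G,T) is
        corrected to the dominant haplotype (T,A)."""
        ref = random_dna(rng, 1_200)
        pos = [600, 604]
        draft = list(ref)
        draft[600], draft[604] = "G", "T"
        draft = "".join(draft)
        cluster = depthmap.HaplotypeCluster(
            pos, {("T", "A"): 186, ("G", "T"): 24, ("T", "T"): 2})
        issue = pf.AssemblyIssue(pf.FALSE_SNP, 600, 605,
                                 evidence={"cluster": cluster})
        res = pf.fix_false_snp(draft, issue)
        assert res.resolved
        assert res.sequence[600] == "T" and res.sequence[604] == "A"

    def test_false_snp_tie_unresolved(self, rng):
        ref = random_dna(rng, 500)
        cluster = depthmap.HaplotypeCluster([250], {("A",): 50, ("G",): 50})
        issue = pf.AssemblyIssue(pf.FALSE_SNP, 250, 251,
                                 evidence={"cluster": cluster})
        res = pf.fix_false_snp(ref, issue)
        assert not res.resolved and res.sequence == ref

    def test_false_snp_fixture_restores_truth(self, mock_genome):
        draft, truth, reads = skimsim.make_misassembly_fixture(
            "FALSE_SNP", mock_genome, seed=3)
        issue = pf.detect_issues(draft, reads)[0]
        res = pf.fix_false_snp(draft.seq, issue)
        assert res.sequence == truth.seq

    def test_tr_copy_local_reassembly_k64(self, mock_genome):
        draft, truth, reads = skimsim.make_misassembly_fixture(
            "TR_COLLAPSE", mock_genome, seed=3)
        issue = pf.detect_issues(draft, reads)[0]
        res = pf.fix_tr_copy(draft.seq, issue, reads)
        assert res.resolved and res.sequence == truth.seq
        assert "k=64" in res.note

    def test_tr_copy_depth_ratio_rewrite(self, mock_genome):
        """Strategy B arithmetic: depth ratio 2.0 over a 2-copy array gives
        4 copies."""
        draft, truth, reads = skimsim.make_misassembly_fixture(
            "TR_COLLAPSE", mock_genome, seed=3)
        issue = pf.detect_issues(draft, reads)[0]
        u = issue.payload["unit_len"]
        c = issue.payload["copies"]
        ratio = issue.evidence["depth_ratio"]
        assert c == 2 and abs(ratio - 2.0) < 0.4
        assert int(round(c * ratio)) == 4

    def test_monopolymer_candidate_selection(self, mock_genome):
        """Truth (T)17 among candidates {7,8,...,17}: the 17-tract variant
        attracts the highest perfect-match depth."""
        draft, truth, reads = skimsim.make_misassembly_fixture(
            "MONOPOLYMER", mock_genome, seed=3)
        issue = pf.detect_issues(draft, reads)[0]
        res = pf.fix_monopolymer(draft.seq, issue, reads,
                                 candidate_lengths=[7, 8, 9, 10, 11, 12, 15, 17])
        assert res.resolved and res.sequence == truth.seq

    def test_monopolymer_correct_length_confirmed(self, mock_genome, cp_reads):
        mono = next(f for f in mock_genome.features("monopolymer", "cp")
                    if f.attrs["planted"])
        issue = pf.AssemblyIssue(pf.MONOPOLYMER, mono.start, mono.end,
                                 payload={"base": mono.attrs["base"],
                                          "length": 17})
        res = pf.fix_monopolymer(mock_genome.cp, issue, cp_reads)
        assert res.sequence == mock_genome.cp


class TestFinish:
    def test_multi_defect_draft_restored(self, mock_genome):
        """A draft carrying a false gap, a false SNP, a collapsed TR and a
        wrong monopolymer is finished back to the truth exactly."""
        cp = mock_genome.cp
        tr = next(f for f in mock_genome.features("tr_array", "cp"))
        mono = next(f for f in mock_genome.features("monopolymer", "cp")
                    if f.attrs["planted"])
        unit = tr.attrs["unit"]
        edits = sorted([
            ("tr", tr.start, tr.end, unit * 2),
            ("mono", mono.start, mono.end, mono.attrs["base"] * 8),
        ], key=lambda e: -e[1])
        draft = cp
        for _, s, e, repl in edits:
            draft = draft[:s] + repl + draft[e:]
        reads = skimsim.simulate_reads({"cp": (cp, True)}, {"cp": 100}, seed=21)
        asm = pf.finish(Contig("d", draft, circular=True), reads)
        assert asm.sequence == cp
        applied = [e for e in asm.finishing_log if e["resolved"]]
        assert len(applied) >= 2
        assert asm.residual_issues == []

    def test_clean_assembly_idempotent(self, mock_genome, cp_reads):
        asm = pf.finish(Contig("cp", mock_genome.cp, circular=True), cp_reads)
        assert asm.sequence == mock_genome.cp
        changed = [e for e in asm.finishing_log
                   if e["resolved"] and "confirmed" not in e["note"]]
        assert changed == []
        again = pf.finish(Contig("cp", asm.sequence, circular=True), cp_reads)
        assert again.sequence == asm.sequence

    def test_unfixable_defect_reported_residual(self, mock_genome, rng):
        """An N gap whose content was never sequenced stays residual."""
        cp = mock_genome.cp
        draft = cp[:10_000] + "N" * 200 + random_dna(rng, 400) + cp[10_000:]
        reads = skimsim.simulate_reads({"cp": (cp, True)}, {"cp": 100}, seed=22)
        asm = pf.finish(Contig("d", draft, circular=True), reads, max_rounds=2)
        assert len(asm.residual_issues) >= 1

    def test_fix_reduces_anomaly_mass(self, mock_genome):
        """Each accepted fix lowers (or keeps) the discordance+clip mass."""
        for kind in skimsim.ISSUE_KINDS:
            draft, truth, reads = skimsim.make_misassembly_fixture(
                kind, mock_genome, seed=3)
            before = _mass(draft.seq, reads)
            issue = pf.detect_issues(draft, reads)[0]
            if kind == pf.FALSE_GAP:
                res = pf.fix_false_gap(draft.seq, issue, reads)
            elif kind == pf.FALSE_SNP:
                res = pf.fix_false_snp(draft.seq, issue)
            elif kind == pf.TR_COLLAPSE:
                res = pf.fix_tr_copy(draft.seq, issue, reads)
            else:
                res = pf.fix_monopolymer(draft.seq, issue, reads)
            after = _mass(res.sequence, reads)
            assert after <= before, kind


def _mass(seq, reads):
    res = depthmap.map_reads(reads, seq)
    track = depthmap.anomaly_profile(res)
    hot = np.abs(track.win_z) >= 3
    return (track.discord.sum() + track.clips.sum()
            + np.abs(track.win_z[hot]).sum())


class TestEndToEnd:
    def test_pipeline_recovers_truth_across_seeds(self):
        """Simulate -> assemble -> join -> finish equals the planted plastome
        exactly (canonical form) in at least 19 of 20 seeds."""
        from skim2organelle import kassembler
        ok = 0
        for seed in range(20):
            g = skimsim.build_mock_genome(skimsim.MockGenomeSpec(seed=seed))
            reads = skimsim.simulate_reads(g, {"cp": 100}, seed=seed + 100)
            contigs = kassembler.assemble(kassembler.build_graph(reads, 31, 1))
            draft = pf.join_and_circularize(contigs)
            asm = pf.finish(draft, reads)
            ok += asm.sequence == g.cp
        assert ok >= 19
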