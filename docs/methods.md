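# Methods

## The assembly model

The package targets the high-copy fraction of a genome skim.  Its working
assumptions are: (i) plastid and rDNA sequences are present at large
copy-number excess over single-copy nuclear DNA, so at any library size
their k-mer counts separate cleanly from the nuclear background; (ii) the
plastome is a circle with the quadripartite LSC–IRa–SSC–IRb architecture,
where the two IR copies are reverse complements at ≥99.9% identity;
(iii) rDNA units within one array are homogeneous enough that reads from
any copy inform every copy; and (iv) the dominant read support at any locus
is the true organellar base — diverged nuclear/mitochondrial plastid
insertions (NMPTs) contribute only minority evidence.

### Coverage planning

The plastid read fraction is estimated by mapping a 10,000-read sample
against any related plastome (Clopper–Pearson 95% interval on the mapped
read count).  The subsampler draws pairs uniformly (seeded) to hit
`target_cp_coverage × cp_size / fraction` read bases; the default target of
150× sits inside the empirically favourable 100–250× window.  When the
implied whole-genome coverage exceeds 20×, a warning is recorded: past that
point NMPT-derived reads are abundant enough to contaminate plastid contigs,
which is the motivation for subsampling at all.

### Assembly

Canonical k-mers (lexicographic minimum of a k-mer and its reverse
complement) are counted exactly; unitigs are maximal paths that are
unambiguous in both directions.  Defaults: k=31; the library-level count
floor (`min_count`) is 1 for error-free unit tests, and the pipeline raises
it adaptively to `0.08 × expected plastid coverage` (capped at 20).  The
floor is what keeps NMPT k-mers — present at a few × coverage, 39% of them
unmutated at 3% divergence — from branching and shattering the plastid
graph.  Tips (dead ends shorter than 2k with mean count below 25% of the
neighbour median) and bubbles (same terminal (k−1)-mers, ≤2 mismatches,
lower count) are removed over up to four rounds.  Repeat resolution is
deliberately *not* attempted in-graph: traversal stops at branches and
downstream joining handles layout, mirroring a finishing workflow in which
contigs are ordered and connected by their terminal overlaps.  k must be
odd (no palindromic self-canonical k-mers); k=64 is permitted as an explicit
override because arrays of short tandem repeats resolve exactly when k
exceeds the assembled array span.

### Joining and the canonical plastome form

Contigs are ordered and oriented by maximal exact terminal overlaps
(default ≥15 bp; observed joins in practice are the k−1=30 bp de Bruijn
overlaps).  A contig at about twice the length-weighted median depth — the
collapsed IR — may be traversed twice, once per orientation.  A depth-first
search over oriented contigs (bounded at total multiplicity 24) enumerates
closed layouts; layouts are deduplicated through the canonical plastome
form, and genuinely inequivalent layouts raise an error naming the joins.
With no closed layout, contigs are chained greedily and unjoinable
junctions bridged with (N)₁₀₀ inside a circular draft, which the finishing
loop then repairs.

Because the IR (~3.9 kb in the default mock, 20–30 kb in real plastomes)
exceeds any short-read insert size, the two SSC-orientation isomers cannot
be distinguished by read data — both are biologically real "flip-flop"
forms.  The package therefore defines one canonical presentation: rotate to
the LSC start and take the lexicographically smallest of the four
equivalent strings (two strands × two SSC orientations).  The synthetic
generator emits its planted plastome in the same canonical form, which is
what makes "equals the truth exactly" a well-posed test.

### Error detection thresholds

Evidence comes from remapping the reads to the draft (exact 15-mer seeds,
Hamming verification with an edlib fallback, mismatch budget 5%).  Reads
that fail full-length placement contribute *clipped fragments* (longest
exact prefix/suffix match ≥25 bp): counting these into the depth track
reproduces the read stacking that a local aligner shows over collapsed
repeats, and their breakpoints mark mis-assembly edges.

- **False gaps** are simply N runs; the fix merges the maximal exact flank
  duplication (≥10 bp) and is kept only when remapping clears the local
  discordance+clip mass.  Gaps without a duplication go to the paired-read
  gap closer.
- **False SNPs**: variant columns are clustered within a read length
  (alleles on one read are linked) and the covering unique reads
  partitioned by their joint allele vector.  A cluster is flagged when the
  majority haplotype disagrees with the draft (the primary correction
  signal) or the second group reaches 5% of depth (a contamination screen).
  The fix assigns the largest group's allele vector jointly; ties leave the
  draft unchanged; a majority below 50% warns of contamination but still
  applies.
- **TR collapse** requires a 50-bp depth window at z ≥ 3 *and* local tandem
  periodicity (smallest lag 4–100 with a match run ≥ max(u, 12)) *and* an
  array/flank depth ratio ≥ 1.25.  The ratio threshold splits two regimes
  measured on simulations: chance hot windows over correctly assembled
  arrays stay ≤ ~1.17, while the smallest real collapse signal is
  (c+1)/c ≈ 1.33 for a 4-copy array missing one.  Repair prefers local
  re-assembly at k = max(64, c·u+1) (capped at read length −1) when the
  read length spans the assembled array plus two units, else rewrites the
  array with round(c × depth_TR/depth_flank) copies; either way the fix
  must bring the remapped ratio into [0.8, 1.25].
- **Monopolymers**: homopolymer runs ≥8 nt with ≥3 clipped read ends at
  their edges.  The fix builds one hypothetical draft window per candidate
  length (default 5–25 plus the current length), maps reads at 100%
  identity, and keeps the length with maximal mean window depth; ties keep
  the draft's length.  A correct tract is "confirmed" (flagged, re-scored,
  unchanged) rather than skipped, so the log records the check.

The finishing loop applies fixes in positional order (structural kinds
before substitutional at equal positions), closes residual gaps with the
paired-read closer, and iterates detection up to 5 rounds.  Issues that
resolve to "no change" are remembered and not re-flagged; returning to a
previously seen sequence stops the loop with an oscillation report.
Residual issues are reported, never dropped.

### Gap closing

Each gap edge grows by frontier-consensus extension: reads containing the
current terminal 31-mer vote on the next base (majority, minimum support
2).  The edge budget equals the N-run length — the placeholder is treated
as the gap-size estimate — plus the merge-overlap allowance.  A gap closes
when an extension reaches the opposite flank or the two extensions overlap
by ≥20 bp at ≥99% identity, and every candidate fill must pass a junction
check: all 31-mers across the filled junction must occur in the reads.
The check rejects overlap-consistent but repeat-collapsed merges.  This
budget semantics is what produces the documented 45S behaviour: with the
true missing IGS span (~400 bp) exceeding the (N)₁₀₀ budget, closure
stalls; enlarging the placeholder (300, then 1000) lets the extensions
meet.

### rDNA units and copy number

The 45S unit is cut between the two 18S starts of the closed two-unit
construct and annotated by locating the packaged gene models (18S, 5.8S,
26S; ITS1/ITS2/IGS are the gaps between them).  The 5S unit is the minimal
rotation period (≥99% self-identity) of a 5S-model-bearing contig,
canonicalized to the gene start; secondary period candidates are reported
rather than suppressed.  Copy number is the mean per-base depth of the unit
(circular mapping, fractional multi-mapping weights) under a seeded
subsample of exactly `genome_size` read bases.  The estimator is exact for
a uniformly sampled library; a library enriched for one component (such as
a cp-heavy simulation) dilutes the others' estimates proportionally, which
the pipeline reports as-is.

## The synthetic generator

`skimsim` emulates, per seed: a 200-kb i.i.d. nuclear background; a 30-kb
canonical-form plastome (LSC 0.60 / IR 0.13×2 / SSC 0.14) carrying one
4-copy 18-bp tandem array and one (T)₁₇ tract padded so it stays maximal;
six NMPT insertions (cp fragments of 0.3–3 kb at 3% substitution
divergence) plus nuclear homopolymer decoys at 7–15 nt in near-identical
context; two ~15-kb mitochondrial fragments each carrying a ~1% diverged
plastid segment; a 100-copy 45S array (3,000-bp cistron from the packaged
models + 1,000-bp IGS with a GC-rich 60-bp sub-repeat triplet) and a
300-copy 5S array (320-bp unit).  Reads are paired-end 2×100 bp with a
Gaussian insert (500 ± 50, truncated to [2·read_len, 2·mean]), mate 2
reverse-complemented, substitution errors only (indel errors default to 0),
circular components sampled across the origin.  Truth tables record every
planted feature, including incidental homopolymer runs ≥9 nt.

Two deliberate regularities: the IGS sub-repeat copies carry diagnostic
substitutions every ~20 bp (≈5% divergence) instead of uniformly random
mutations, so every 31-mer window distinguishes the copies — with random
divergence, window-identical stretches occasionally make read-guided
traversal of the sub-repeat formally ambiguous (a real repeat-collapse
pathology no read-based closer can resolve); and the planted plastome is
emitted in the canonical quadripartite form (see above).

What passing the synthetic suite does *not* show about real data: quality
profiles (qualities are constant Q40; the trimming rule is exercised with
synthetic quality vectors separately), indel sequencing errors, PCR
duplicates, heteroplasmy and within-array rDNA heterogeneity, real NMPT age
structure, and real genome sizes (the mock nuclear background is 200 kb, so
plastid read fractions are unrealistically high; all depth *ratios* scale,
but absolute fractions do not).

## Numerical and interface choices

Internal coordinates are 0-based half-open; reported coordinates (TSV, VCF,
GFF-like) are 1-based inclusive.  Tie-breaks everywhere are lexicographic.
The quality-trimming rule (Phred ≤20 ends trimmed, then mean-quality ≤20
drops the read, a pair drops with either mate) is idempotent by
construction.  The homopolymer census threshold "more than 8 nt" is strict
(runs ≥9); the CLI exposes `--min-len` for the inclusive alternative.  A
multi-base alignment gap is one InDel event; same-kind gap events separated
by ≤10 matched columns are fused, since optimal alignments can split one
indel in a short tandem context.  The pairwise comparator refuses inputs
below 90% identity.  The `--threads` flag is accepted for interface
compatibility but execution is single-threaded.  Problem sizes in the test
suite and acceptance script (30-kb mock plastome, 20-seed recovery sweeps,
5-copy mini-arrays for 45S closure, ≥100-trial oracle cross-checks) were
chosen so the full suite completes in a few minutes while every planted
signal stays well above its detection threshold.

## Known limitations

Mitochondrial contigs are classified but not finished.  The mapper is
global per read (no gapped spliced alignment, no SAM/BAM emission);
clipped-fragment handling approximates local alignment only for evidence
purposes.  TR detection needs unit length ≥4 bp and at least two assembled
copies; collapses of arrays longer than the read span fall back to the
depth-ratio rewrite, which assumes the collapse preserved unit phase.
Copy-number estimates inherit the uniform-library assumption discussed
above.  The packaged rDNA gene models are synthetic stand-ins for curated
plant consensus sequences and should be replaced for real data.
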