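"""Seed-and-extend read mapping against small references, with pileups,
linked-haplotype partitions and discordance/depth anomaly profiles.

The mapper places each mate at its best-scoring location (exact 15-mer
seeds, Hamming verification, edlib fallback for indel-containing reads)
within a mismatch budget.  Multi-mapping policy follows the copy-number
logic of the pipeline: all equal-best placements contribute fractional
weight 1/n to the depth profile, while anomaly and false-SNP evidence use
unique placements only.  References up to ~250 kb are intended; circular
references wrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np

from .seqio import Contig
from ._util import revcomp, seq_to_array

SEED_LEN = 15


@dataclass
class Placement:
    qname: str
    mate: int  # 1 or 2
    start: int  # 0-based on the (unwrapped) reference; end may exceed L
    end: int
    strand: str  # '+' or '-'
    edits: int
    unique: bool
    weight: float  # 1/n over equal-best placements
    seq: str  # read bases oriented to the forward reference strand


@dataclass
class PileupColumn:
    position: int
    depth: int  # unique-placement depth at the column
    counts: dict  # base -> count, sums to depth


@dataclass
class HaplotypeCluster:
    """Reads partitioned by their joint alleles at linked variant columns."""

    positions: list
    groups: dict  # allele tuple -> read count

    @property
    def total(self) -> int:
        return sum(self.groups.values())

    def ranked(self) -> list:
        return sorted(self.groups.items(), key=lambda kv: (-kv[1], kv[0]))


@dataclass
class Pileup:
    columns: list  # PileupColumn at variant columns
    clusters: list  # HaplotypeCluster
    depth: np.ndarray  # fractional multi-mapping weights, all placements
    depth_unique: np.ndarray
    aligned_bases: float


@dataclass
class AnomalyTrack:
    discord: np.ndarray  # per-position discordant-pair count
    clips: np.ndarray  # per-position clipped-end count
    depth: np.ndarray
    window: int
    win_z: np.ndarray  # per-window depth z-score vs trimmed baseline
    baseline_mean: float
    baseline_sd: float
    reliable: bool = True

    def z_at(self, pos: int) -> float:
        return float(self.win_z[min(pos // self.window, len(self.win_z) - 1)])


@dataclass
class MappingResult:
    reference: str
    ref_id: str
    circular: bool
    placements: list  # primary Placement per placed mate
    alternates: dict  # (qname, mate) -> list of alternate starts (ties)
    clip_events: list  # (ref position, qname)
    n_pairs: int
    read_len: int

    @property
    def n_placed(self) -> int:
        return len(self.placements)


def _build_seed_index(ref2: str) -> dict:
    index: dict[str, list] = {}
    for i in range(len(ref2) - SEED_LEN + 1):
        index.setdefault(ref2[i:i + SEED_LEN], []).append(i)
    return index


def map_reads(reads, reference, max_mismatch_rate: float = 0.05,
              circular: bool | None = None) -> MappingResult:
    """Map both mates of every pair to a single reference sequence."""
    if isinstance(reference, Contig):
        ref, ref_id = reference.seq, reference.id
        if circular is None:
            circular = reference.circular
    else:
        ref, ref_id = reference, "ref"
        circular = bool(circular)
    if not ref:
        raise ValueError("empty reference")
    if not 0 <= max_mismatch_rate <= 0.2:
        raise ValueError("max_mismatch_rate must be in [0, 0.2]")

    reads = list(reads)
    max_rl = max((max(len(p.bases1), len(p.bases2)) for p in reads), default=0)
    L = len(ref)
    wrap = min(L, max_rl + 8) if circular else 0
    ref2 = ref + ref[:wrap]
    index = _build_seed_index(ref2)
    ref2_arr = seq_to_array(ref2)

    placements: list[Placement] = []
    alternates: dict = {}
    clip_events: list = []

    for pair in reads:
        for mate, bases in ((1, pair.bases1), (2, pair.bases2)):
            hit = _place_one(bases, ref2, ref2_arr, index, L, circular,
                             max_mismatch_rate)
            if hit is None:
                clip_events.extend(
                    (pos, pair.id, astart, aend)
                    for pos, astart, aend in _find_clips(bases, ref2, index, L)
                )
                continue
            starts, strand, edits, oriented = hit
            n = len(starts)
            placements.append(Placement(
                pair.id, mate, starts[0], starts[0] + len(bases), strand,
                edits, n == 1, 1.0 / n, oriented,
            ))
            if n > 1:
                alternates[(pair.id, mate)] = starts[1:]
    return MappingResult(ref, ref_id, circular, placements, alternates,
                         clip_events, len(reads), max_rl)


def _place_one(bases, ref2, ref2_arr, index, L, circular, mmr):
    rl = len(bases)
    budget = int(mmr * rl)
    best_edits = budget + 1
    best: list[tuple[int, str]] = []  # (start, strand)
    offsets = sorted({0, max(0, (rl - SEED_LEN) // 2), max(0, rl - SEED_LEN)})
    for strand, seq in (("+", bases), ("-", revcomp(bases))):
        if "N" in seq:
            seq_arr = None
        else:
            seq_arr = seq_to_array(seq)
        cands = set()
        for off in offsets:
            seed = seq[off:off + SEED_LEN]
            for pos in index.get(seed, ()):
                start = pos - off
                if start < 0:
                    if circular:
                        start += L
                    else:
                        continue
                if start + rl > len(ref2):
                    continue
                if not circular and start + rl > L:
                    continue
                cands.add(start)
        for start in cands:
            if seq_arr is not None:
                edits = int(np.count_nonzero(
                    ref2_arr[start:start + rl] != seq_arr))
            else:
                edits = budget + 1
            if edits > budget and budget > 0:
                # allow indel-containing alignments via edlib
                lo = max(0, start - 3)
                window = ref2[lo:start + rl + 3]
                res = edlib.align(seq, window, mode="HW", k=budget)
                if res["editDistance"] >= 0:
                    edits = res["editDistance"]
            if edits <= budget:
                norm = start % L if circular else start
                if edits < best_edits:
                    best_edits = edits
                    best = [(norm, strand)]
                elif edits == best_edits and (norm, strand) not in best:
                    best.append((norm, strand))
    if not best:
        return None
    best.sort()
    starts = [b[0] for b in best]
    strand = best[0][1]
    oriented = bases if strand == "+" else revcomp(bases)
    return starts, strand, best_edits, oriented


def _find_clips(bases, ref2, index, L, min_anchor: int = 25):
    """Clipped partial placements for a read that failed full-length
    placement: (clip position, aligned start, aligned end).  The aligned
    fragment is the longest exact prefix/suffix match; counting these
    fragments into the depth track reproduces the read *stacking* a local
    mapper shows over collapsed repeats."""
    events = []
    for seq in (bases, revcomp(bases)):
        # prefix anchor -> clip at the divergence point
        seed = seq[:SEED_LEN]
        best = 0
        best_pos = None
        for pos in index.get(seed, ())[:8]:
            m = SEED_LEN
            while pos + m < len(ref2) and m < len(seq) and ref2[pos + m] == seq[m]:
                m += 1
            if m > best:
                best, best_pos = m, pos
        if best >= min_anchor and best < len(seq) and best_pos is not None:
            events.append(((best_pos + best) % L, best_pos, best_pos + best))
        # suffix anchor -> clip at the divergence point (leftward)
        seed = seq[-SEED_LEN:]
        best = 0
        best_pos = None
        for pos in index.get(seed, ())[:8]:
            m = SEED_LEN
            while (pos + SEED_LEN - m - 1 >= 0 and m < len(seq)
                   and ref2[pos + SEED_LEN - m - 1] == seq[len(seq) - m - 1]):
                m += 1
            if m > best:
                best, best_pos = m, pos
        if best >= min_anchor and best < len(seq) and best_pos is not None:
            start = best_pos + SEED_LEN - best
            events.append((start % L, start, best_pos + SEED_LEN))
        if events:
            break  # one orientation suffices
    return events


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------


def pileup(mapres: MappingResult, reference=None, link_window: int | None = None,
           minor_floor: float = 0.05) -> Pileup:
    """Allele counts, depth profiles and linked-haplotype partitions.

    Depth uses fractional multi-mapping weights; allele/haplotype evidence
    uses unique placements only.  Variant columns are materialized where a
    unique placement disagrees with the reference.
    """
    ref = mapres.reference
    if reference is not None:
        given = reference.seq if isinstance(reference, Contig) else reference
        if given != ref:
            raise ValueError("pileup reference differs from mapping reference")
    L = len(ref)
    link_window = link_window or mapres.read_len
    ref_arr = seq_to_array(ref + ref[:mapres.read_len + 8] if mapres.circular else ref)

    depth_w = np.zeros(L)
    depth_u = np.zeros(L, dtype=np.int64)
    alt_counts: dict[int, dict] = {}
    aligned = 0.0

    def add_interval(arr, s, e, v):
        if e <= L:
            arr[s:e] += v
        else:  # wrapped placement
            arr[s:L] += v
            arr[: e - L] += v

    mismatch_cache: dict[int, list] = {}
    for pi, p in enumerate(mapres.placements):
        add_interval(depth_w, p.start, p.end, p.weight)
        aligned += (p.end - p.start) * p.weight
        if not p.unique:
            for alt in mapres.alternates.get((p.qname, p.mate), ()):
                add_interval(depth_w, alt, alt + (p.end - p.start), p.weight)
                aligned += (p.end - p.start) * p.weight
            continue
        add_interval(depth_u, p.start, p.end, 1)
        if p.edits:
            seg = ref_arr[p.start:p.end]
            if len(seg) == p.end - p.start:
                read_arr = seq_to_array(p.seq)
                mism = np.flatnonzero(seg != read_arr)
                mismatch_cache[pi] = mism
                for off in mism:
                    col = (p.start + int(off)) % L
                    alt_counts.setdefault(col, {}).setdefault(p.seq[int(off)], 0)
                    alt_counts[col][p.seq[int(off)]] += 1

    columns = []
    for col in sorted(alt_counts):
        d = int(depth_u[col])
        counts = dict(alt_counts[col])
        ref_n = d - sum(counts.values())
        if ref_n > 0:
            counts[ref[col]] = counts.get(ref[col], 0) + ref_n
        columns.append(PileupColumn(col, d, counts))

    # cluster variant columns within link_window, partition covering reads.
    # Only *significant* columns enter clustering: either the second allele
    # reaches the minor floor or the majority allele disagrees with the
    # draft base -- this keeps sporadic sequencing-error columns out.
    clusters = []
    var_pos = []
    for c in columns:
        ranked = sorted(c.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if not ranked or c.depth == 0:
            continue
        major = ranked[0][0]
        minor_frac = ranked[1][1] / c.depth if len(ranked) > 1 else 0.0
        if major != ref[c.position] or minor_frac >= minor_floor:
            var_pos.append(c.position)
    i = 0
    while i < len(var_pos):
        j = i + 1
        while j < len(var_pos) and var_pos[j] - var_pos[j - 1] <= link_window:
            j += 1
        positions = var_pos[i:j]
        groups: dict[tuple, int] = {}
        for p in mapres.placements:
            if not p.unique:
                continue
            if p.start <= positions[0] and positions[-1] < p.end:
                alleles = tuple(p.seq[pos - p.start] for pos in positions)
                groups[alleles] = groups.get(alleles, 0) + 1
        if groups:
            clusters.append(HaplotypeCluster(positions, groups))
        i = j
    return Pileup(columns, clusters, depth_w, depth_u, aligned)


# ---------------------------------------------------------------------------
# anomaly profile
# ---------------------------------------------------------------------------


def anomaly_profile(mapres: MappingResult, insert_model=(500.0, 50.0),
                    window: int = 50, z_sd_floor: float = 1.0) -> AnomalyTrack:
    """Discordant-pair and clipped-end counts plus windowed depth z-scores.

    A pair is discordant when its mates are not forward/reverse facing, or
    the observed insert deviates more than 4 sd from the model, or one mate
    is unplaced; counts are registered at the placed mate positions.
    """
    mean, sd = insert_model
    ref_len = len(mapres.reference)
    discord = np.zeros(ref_len, dtype=np.int64)
    clips = np.zeros(ref_len, dtype=np.int64)
    for pos, _, _, _ in mapres.clip_events:
        clips[pos % ref_len] += 1

    by_pair: dict[str, dict] = {}
    for p in mapres.placements:
        by_pair.setdefault(p.qname, {})[p.mate] = p
    n_full = 0
    for qname, mates in by_pair.items():
        p1, p2 = mates.get(1), mates.get(2)
        if p1 is None or p2 is None:
            placed = p1 or p2
            discord[placed.start % ref_len] += 1
            continue
        n_full += 1
        if not _concordant(p1, p2, mean, sd, ref_len, mapres.circular):
            discord[p1.start % ref_len] += 1
            discord[p2.start % ref_len] += 1

    # depth z-scores against a trimmed baseline (10% per tail)
    depth = np.zeros(ref_len)
    for p in mapres.placements:
        s, e = p.start, p.end
        if e <= ref_len:
            depth[s:e] += p.weight
        else:
            depth[s:ref_len] += p.weight
            depth[: e - ref_len] += p.weight
        if not p.unique:
            for alt in mapres.alternates.get((p.qname, p.mate), ()):
                e2 = alt + (e - s)
                if e2 <= ref_len:
                    depth[alt:e2] += p.weight
                else:
                    depth[alt:ref_len] += p.weight
                    depth[: e2 - ref_len] += p.weight
    # clipped partial placements stack onto the reference like a local
    # mapper's soft-clipped reads: the depth-excess signal over collapsed
    # tandem arrays comes from exactly these fragments
    for _, _, a0, a1 in mapres.clip_events:
        s = a0 % ref_len
        e = s + (a1 - a0)
        if e <= ref_len:
            depth[s:e] += 1.0
        else:
            depth[s:ref_len] += 1.0
            depth[: e - ref_len] += 1.0

    nwin = max(1, ref_len // window)
    wmeans = np.array([
        depth[i * window: (i + 1) * window].mean() for i in range(nwin)
    ])
    order = np.sort(wmeans)
    t = max(1, int(0.1 * len(order)))
    trimmed = order[t:-t] if len(order) > 2 * t else order
    base_mean = float(trimmed.mean())
    base_sd = max(float(trimmed.std()), z_sd_floor)
    win_z = (wmeans - base_mean) / base_sd

    reliable = n_full >= 100
    if not reliable:
        warnings.warn(
            f"only {n_full} fully placed pairs: anomaly baseline unreliable",
            stacklevel=2,
        )
    return AnomalyTrack(discord, clips, depth, window, win_z,
                        base_mean, base_sd, reliable)


def _concordant(p1: Placement, p2: Placement, mean: float, sd: float,
                ref_len: int, circular: bool) -> bool:
    if p1.strand == p2.strand:
        return False
    fwd, rev = (p1, p2) if p1.strand == "+" else (p2, p1)
    insert = rev.end - fwd.start
    if circular:
        insert %= ref_len
        if insert <= 0:
            insert += ref_len
        # take the closer interpretation around the circle
        insert = min(insert, ref_len - insert + (rev.end - rev.start) + (fwd.end - fwd.start))
    elif insert < 0:
        return False
    return abs(insert - mean) <= 4 * sd


def placements_to_tsv(mapres: MappingResult, path) -> None:
    """Placements as TSV (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("read\tmate\tref\tstart\tend\tstrand\tedits\tunique\tweight\n")
        for p in mapres.placements:
            fh.write(
                f"{p.qname}\t{p.mate}\t{mapres.ref_id}\t{p.start + 1}\t{p.end}\t"
                f"{p.strand}\t{p.edits}\t{int(p.unique)}\t{p.weight:.4g}\n"
            )


def depth_to_bed(mapres: MappingResult, path, window: int = 100) -> None:
    """Windowed mean depth as BED-like TSV (0-based half-open)."""
    pile = pileup(mapres)
    L = len(mapres.reference)
    with open(path, "w") as fh:
        for s in range(0, L, window):
            e = min(L, s + window)
            fh.write(f"{mapres.ref_id}\t{s}\t{e}\t{pile.depth[s:e].mean():.3f}\n")
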