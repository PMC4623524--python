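"""De Bruijn graph assembly over canonical k-mers.

The graph stores canonical k-mers (lexicographically smaller of a k-mer and
its reverse complement) with exact counts; unitigs are maximal unambiguous
paths after tip clipping and bubble popping.  Repeat resolution is
deliberately not attempted in-graph: traversal stops at every ambiguous
branch, and downstream finishing joins contigs by terminal overlaps instead.

Also hosts the iterative paired-read gap closer used both on plastome drafts
and on the two-unit 45S tandem construction.  The closer extends each gap
edge by frontier k-mer consensus over the reads; each edge's extension
budget equals the current N-run length, so the placeholder length acts as
the gap-size estimate -- a gap whose true content exceeds the budget stalls
until the caller enlarges the placeholder.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .seqio import Contig
from ._util import canonical_kmer, revcomp

_N_RUN = re.compile(r"N+")


@dataclass
class KmerGraph:
    k: int
    counts: dict  # canonical k-mer -> exact count

    def __post_init__(self) -> None:
        if self.k % 2 == 0 and self.k != 64:
            # even k admits palindromic self-canonical k-mers; permitted only
            # via the documented k=64 override used for short-TR resolution
            raise ValueError("k must be odd (k=64 permitted as explicit override)")

    def __contains__(self, kmer: str) -> bool:
        return canonical_kmer(kmer) in self.counts

    def __len__(self) -> int:
        return len(self.counts)


def _read_kmers(seq: str, k: int):
    """Canonical k-mers of one read, skipping windows containing N."""
    n = len(seq)
    if n < k:
        return
    rc = revcomp(seq)
    if "N" in seq:
        for i in range(n - k + 1):
            fwd = seq[i:i + k]
            if "N" in fwd:
                continue
            bwd = rc[n - k - i:n - i]
            yield fwd if fwd <= bwd else bwd
    else:
        for i in range(n - k + 1):
            fwd = seq[i:i + k]
            bwd = rc[n - k - i:n - i]
            yield fwd if fwd <= bwd else bwd


def build_graph(reads, k: int = 31, min_count: int = 1) -> KmerGraph:
    """Count canonical k-mers over both mates of every pair.

    Node set is exactly the k-mers occurring >= min_count times; counts are
    exact (not capped).
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: dict[str, int] = {}
    any_long = False
    for pair in reads:
        for seq in (pair.bases1, pair.bases2) if hasattr(pair, "bases1") else (pair,):
            if len(seq) >= k:
                any_long = True
            for km in _read_kmers(seq, k):
                counts[km] = counts.get(km, 0) + 1
    if not any_long:
        raise ValueError(f"no read is long enough for k={k}")
    if min_count > 1:
        counts = {km: c for km, c in counts.items() if c >= min_count}
    return KmerGraph(k, counts)


# ---------------------------------------------------------------------------
# unitig extraction
# ---------------------------------------------------------------------------


def _successors(counts, kmer: str) -> list[str]:
    suf = kmer[1:]
    out = []
    for b in "ACGT":
        cand = suf + b
        if canonical_kmer(cand) in counts:
            out.append(cand)
    return out


def _predecessors(counts, kmer: str) -> list[str]:
    pre = kmer[:-1]
    out = []
    for b in "ACGT":
        cand = b + pre
        if canonical_kmer(cand) in counts:
            out.append(cand)
    return out


def _unique_forward(counts, kmer: str) -> str | None:
    """The unique forward extension, when the step is unambiguous both ways."""
    succ = _successors(counts, kmer)
    if len(succ) != 1:
        return None
    nxt = succ[0]
    if len(_predecessors(counts, nxt)) != 1:
        return None
    return nxt


@dataclass
class _Unitig:
    seq: str
    nodes: list  # canonical k-mers, path order
    circular: bool = False
    mean_count: float = 0.0


def _extract_unitigs(counts: dict, k: int) -> list[_Unitig]:
    visited: set[str] = set()
    unitigs: list[_Unitig] = []

    def walk(start: str) -> _Unitig:
        path = [start]
        visited.add(canonical_kmer(start))
        cur = start
        circular = False
        while True:
            nxt = _unique_forward(counts, cur)
            if nxt is None:
                break
            if canonical_kmer(nxt) in visited:
                circular = nxt == start  # perfect cycle closes on itself
                break
            path.append(nxt)
            visited.add(canonical_kmer(nxt))
            cur = nxt
        seq = path[0] + "".join(p[-1] for p in path[1:])
        if circular:
            seq = seq[: len(path)]  # trim the duplicated k-1 terminal overlap
        nodes = [canonical_kmer(p) for p in path]
        mean = sum(counts[n] for n in nodes) / len(nodes)
        return _Unitig(seq, nodes, circular, mean)

    # pass 1: walks from genuine unitig starts (no unambiguous backward step)
    for km in sorted(counts):
        if km in visited:
            continue
        for orient in (km, revcomp(km)):
            if _unique_forward(counts, revcomp(orient)) is None:
                unitigs.append(walk(orient))
                break
    # pass 2: leftovers are interiors of perfect cycles
    for km in sorted(counts):
        if km not in visited:
            unitigs.append(walk(km))
    return unitigs


def _clean_graph(counts: dict, k: int, tip_len: int, tip_frac: float) -> dict:
    """Iterative tip clipping and bubble popping on the unitig level."""
    counts = dict(counts)
    for _ in range(4):
        unitigs = _extract_unitigs(counts, k)
        if len(unitigs) <= 1:
            break
        removable: set[int] = set()
        by_ends: dict = {}
        for idx, u in enumerate(unitigs):
            if u.circular:
                continue
            head1, tail1 = u.seq[:k - 1], u.seq[-(k - 1):]
            ends = frozenset((min(head1, revcomp(head1)), min(tail1, revcomp(tail1))))
            by_ends.setdefault(ends, []).append(idx)
        for idx, u in enumerate(unitigs):
            if u.circular:
                continue
            own = set(u.nodes)
            head, tail = u.seq[:k], u.seq[-k:]
            pred_ext = [p for p in _predecessors(counts, head)
                        if canonical_kmer(p) not in own]
            succ_ext = [s for s in _successors(counts, tail)
                        if canonical_kmer(s) not in own]
            dead_end = not pred_ext or not succ_ext
            if dead_end and len(u.seq) < tip_len and (pred_ext or succ_ext):
                # tip: compare against attached neighbours' counts
                neigh = []
                for node in pred_ext + succ_ext:
                    cn = canonical_kmer(node)
                    if cn in counts:
                        neigh.append(counts[cn])
                if neigh:
                    neigh.sort()
                    med = neigh[len(neigh) // 2]
                    if u.mean_count < tip_frac * med:
                        removable.add(idx)
        # bubbles: same end pair, near-equal sequence, drop lower count
        for ends, idxs in by_ends.items():
            if len(idxs) < 2:
                continue
            idxs = sorted(idxs, key=lambda i: (-unitigs[i].mean_count, unitigs[i].seq))
            keep = unitigs[idxs[0]]
            for other in idxs[1:]:
                u = unitigs[other]
                if abs(len(u.seq) - len(keep.seq)) <= 2 and _near(u.seq, keep.seq, 2):
                    removable.add(other)
        if not removable:
            break
        for idx in removable:
            for node in unitigs[idx].nodes:
                counts.pop(node, None)
    return counts


def _near(a: str, b: str, max_mm: int) -> bool:
    if len(a) != len(b):
        return False
    for x in (b, revcomp(b)):
        mm = sum(1 for p, q in zip(a, x) if p != q)
        if mm <= max_mm:
            return True
    return False


def assemble(graph: KmerGraph, reads=None, tip_len: int | None = None,
             tip_frac: float = 0.25) -> list[Contig]:
    """Unitigs of the cleaned graph as contigs, longest first.

    Contig sequences are strand-canonical (lexicographically smaller of the
    two strands); ties in length are broken lexicographically; contig depth
    is the mean k-mer count along the path.
    """
    if len(graph) == 0:
        return []
    k = graph.k
    counts = _clean_graph(graph.counts, k, tip_len or 2 * k, tip_frac)
    unitigs = _extract_unitigs(counts, k)
    unitigs.sort(key=lambda u: (-len(u.seq), min(u.seq, revcomp(u.seq))))
    contigs = []
    for i, u in enumerate(unitigs):
        seq = min(u.seq, revcomp(u.seq))
        contigs.append(Contig(
            f"ctg_{i + 1:04d}", seq, circular=u.circular, depth=u.mean_count,
            provenance=f"kassembler k={k}",
        ))
    return contigs


# ---------------------------------------------------------------------------
# gap closing
# ---------------------------------------------------------------------------


@dataclass
class GapCloseState:
    sequence: str
    gaps: list = field(default_factory=list)  # per-gap dicts (interval, exts)
    iterations: int = 0
    stalled: bool = False

    @property
    def n_gaps(self) -> int:
        return len(_N_RUN.findall(self.sequence))


class _ReadIndex:
    """k-mer -> occurrences over a read set, for consensus extension."""

    def __init__(self, reads, k: int = 31):
        self.k = k
        self.seqs: list[str] = []
        for pair in reads:
            if hasattr(pair, "bases1"):
                self.seqs.append(pair.bases1)
                self.seqs.append(pair.bases2)
            else:
                self.seqs.append(pair)
        self.index: dict[str, list] = {}
        for si, seq in enumerate(self.seqs):
            for i in range(len(seq) - k + 1):
                km = seq[i:i + k]
                if "N" in km:
                    continue
                self.index.setdefault(canonical_kmer(km), []).append((si, i))

    def vote_next(self, frontier: str) -> dict:
        """Votes for the base following the oriented `frontier` k-mer."""
        votes: dict[str, int] = {}
        rc_f = revcomp(frontier)
        for si, i in self.index.get(canonical_kmer(frontier), ()):
            seq = self.seqs[si]
            win = seq[i:i + self.k]
            if win == frontier:
                if i + self.k < len(seq):
                    b = seq[i + self.k]
                    votes[b] = votes.get(b, 0) + 1
            elif win == rc_f and i > 0:
                b = revcomp(seq[i - 1])
                votes[b] = votes.get(b, 0) + 1
        votes.pop("N", None)
        return votes


def _extend(index: _ReadIndex, seed: str, budget: int, min_support: int) -> str:
    """Grow a consensus extension to the right of `seed`, up to `budget`."""
    cur = seed
    ext = []
    while len(ext) < budget:
        frontier = cur[-index.k:]
        votes = index.vote_next(frontier)
        if not votes:
            break
        best = max(votes.values())
        winners = sorted(b for b, v in votes.items() if v == best)
        if best < min_support or len(winners) != 1:
            break
        ext.append(winners[0])
        cur += winners[0]
    return "".join(ext)


def close_gaps(draft: str | Contig, reads, max_iter: int = 5,
               min_merge_overlap: int = 20, min_support: int = 2,
               frontier_k: int = 31) -> GapCloseState:
    """Iteratively fill N runs by paired-read consensus extension.

    Per gap and iteration, both edges are extended by frontier-k-mer
    consensus (budget = current N-run length); the gap closes when (a) an
    extension reaches the opposite flank, or (b) the two extensions overlap
    by >= min_merge_overlap at >= 99% identity.  The stall flag is set when
    an iteration closes nothing and extends no edge.
    """
    seq = draft.seq if isinstance(draft, Contig) else draft
    if "N" not in seq:
        raise ValueError("nothing to close: draft contains no N run")
    index = _ReadIndex(reads, frontier_k)
    state = GapCloseState(seq)
    prev_ext_total = -1
    for iteration in range(1, max_iter + 1):
        state.iterations = iteration
        gaps = [(m.start(), m.end()) for m in _N_RUN.finditer(state.sequence)]
        if not gaps:
            break
        closed_any = False
        ext_total = 0
        new_gap_log = []
        # process right-to-left so earlier coordinates stay valid
        for s, e in reversed(gaps):
            left = state.sequence[:s]
            right = state.sequence[e:]
            budget = e - s
            w = min_merge_overlap
            anchor_l = left[-max(frontier_k, 40):]
            anchor_r = right[:max(frontier_k, 40)]
            if len(anchor_l) < frontier_k or len(anchor_r) < frontier_k:
                new_gap_log.append({"interval": (s, e), "note": "edge too short"})
                continue
            ext_l = _extend(index, anchor_l, budget + w, min_support)
            ext_r = revcomp(_extend(index, revcomp(anchor_r), budget + w, min_support))
            ext_total += len(ext_l) + len(ext_r)
            content = None
            for cand in _merge_candidates(ext_l, ext_r, anchor_r[:w],
                                          left[-w:] if len(left) >= w else left, w):
                # a correct fill leaves no junction k-mer unsupported by
                # reads; a repeat-collapsed merge creates novel k-mers
                if _junction_supported(index, left[-frontier_k:], cand,
                                       right[:frontier_k]):
                    content = cand
                    break
            if content is not None:
                state.sequence = left + content + right
                closed_any = True
            else:
                new_gap_log.append({
                    "interval": (s, e), "ext_left": ext_l, "ext_right": ext_r,
                })
        state.gaps = list(reversed(new_gap_log))
        if not closed_any:
            if state.gaps:
                state.stalled = True
            break
        if ext_total == prev_ext_total and not closed_any:
            state.stalled = True
            break
        prev_ext_total = ext_total
    if state.n_gaps and not state.stalled and state.iterations == max_iter:
        state.stalled = True
    return state


def _merge_candidates(ext_l: str, ext_r: str, right_head: str, left_tail: str,
                      w: int):
    """Gap-content candidates implied by the two edge extensions, best
    first.  The caller validates each against read support."""
    # (a) left extension reached the right flank
    if len(ext_l) >= w and right_head:
        pos = ext_l.find(right_head)
        if pos >= 0:
            yield ext_l[:pos]
    # (b) right extension reached the left flank
    if len(ext_r) >= w and left_tail:
        pos = ext_r.find(left_tail)
        if pos >= 0:
            yield ext_r[pos + len(left_tail):]
    # (c) the extensions themselves overlap
    for o in range(min(len(ext_l), len(ext_r)), w - 1, -1):
        a, b = ext_l[-o:], ext_r[:o]
        mm = sum(1 for x, y in zip(a, b) if x != y)
        if mm <= max(0, int(0.01 * o)):
            yield ext_l + ext_r[o:]


def _junction_supported(index: _ReadIndex, left_tail: str, content: str,
                        right_head: str) -> bool:
    """True when every k-mer across the filled junction occurs in the
    reads."""
    joined = left_tail + content + right_head
    k = index.k
    if len(joined) < k:
        return True
    for i in range(len(joined) - k + 1):
        km = joined[i:i + k]
        if "N" in km:
            return False
        if canonical_kmer(km) not in index.index:
            return False
    return True
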