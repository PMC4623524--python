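"""Post-assembly comparison utilities: homopolymer census and pairwise
SNP/InDel enumeration between near-identical plastomes.

The variant comparator is anchor-based: unique shared 31-mers chained
collinearly, inter-anchor segments aligned at edit distance (edlib), runs
of adjacent gap columns merged into single InDel events.  It is meant for
sequences >= 90% identical (plastomes of cultivars or congeners); anything
more diverged is refused.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from ._util import revcomp

ANCHOR_K = 31


def scan_monopolymers(sequence: str, min_len_exclusive: int = 8,
                      circular: bool = False) -> list:
    """Maximal single-base runs strictly longer than `min_len_exclusive`.

    Returns (base, start, length) with 0-based starts; N runs are never
    reported; for circular sequences a run spanning the origin is reported
    once, anchored at its start near the end of the sequence.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if min_len_exclusive < 1:
        raise ValueError("min_len_exclusive must be >= 1")
    n = len(sequence)
    runs = []
    i = 0
    while i < n:
        j = i + 1
        while j < n and sequence[j] == sequence[i]:
            j += 1
        runs.append((sequence[i], i, j - i))
        i = j
    if circular and len(runs) > 1 and runs[0][0] == runs[-1][0]:
        base, s, ln = runs[-1]
        first = runs[0]
        runs = runs[1:-1] + [(base, s, ln + first[2])]
    return [
        (b, s, ln) for b, s, ln in runs
        if ln > min_len_exclusive and b != "N"
    ]


@dataclass
class Snp:
    pos: int  # 1-based on sequence A
    ref: str
    alt: str


@dataclass
class Indel:
    pos: int  # 1-based on sequence A (base before the event, VCF-style)
    kind: str  # "ins" | "del"
    length: int
    seq: str


def _unique_kmers(seq: str, k: int) -> dict:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        km = seq[i:i + k]
        counts[km] = counts.get(km, 0) + 1
    first: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        km = seq[i:i + k]
        if counts[km] == 1 and km not in first:
            first[km] = i
    return first


def _lis_chain(pairs):
    """Longest increasing chain over (posA, posB), strictly increasing in B."""
    pairs = sorted(pairs)
    tails: list[int] = []
    tails_idx: list[int] = []
    prev = [-1] * len(pairs)
    import bisect
    for i, (_, b) in enumerate(pairs):
        j = bisect.bisect_left(tails, b)
        if j == len(tails):
            tails.append(b)
            tails_idx.append(i)
        else:
            tails[j] = b
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    chain = []
    i = tails_idx[-1] if tails_idx else -1
    while i >= 0:
        chain.append(pairs[i])
        i = prev[i]
    return chain[::-1]


def pairwise_variants(seq_a: str, seq_b: str, circular: bool = False,
                      anchor_k: int = ANCHOR_K):
    """SNP and InDel events between two near-identical sequences.

    Returns (snps, indels) with 1-based coordinates on `seq_a`.  For
    circular inputs, `seq_b` is first rotated (and strand-flipped if
    needed) onto `seq_a` via a shared unique anchor.
    """
    a, b = seq_a.upper(), seq_b.upper()
    ua = _unique_kmers(a, anchor_k)
    ub = _unique_kmers(b, anchor_k)

    def shared(bb):
        ubb = _unique_kmers(bb, anchor_k) if bb is not b else ub
        return [(ua[km], ubb[km]) for km in ua.keys() & ubb.keys()], ubb

    pairs, ubb = shared(b)
    if not pairs:
        b = revcomp(b)
        pairs, ubb = shared(b)
    if not pairs:
        raise ValueError("sequences too diverged for this comparator: no shared anchors")

    if circular:
        # rotate b so the first shared anchor aligns with its position in a
        pa, pb = min(pairs)
        shift = (pb - pa) % len(b)
        b = b[shift:] + b[:shift]
        ubb = _unique_kmers(b, anchor_k)
        pairs = [(ua[km], ubb[km]) for km in ua.keys() & ubb.keys()]

    chain = _lis_chain(pairs)
    snps: list[Snp] = []
    indels: list[Indel] = []

    # sparse anchor subset: anchor starts are exactly aligned columns, so
    # aligning the full inter-anchor segments (anchor interiors included)
    # cannot split or lose an event, even where repeats let dense anchors
    # slide across an indel
    spacing = 400
    sparse = []
    last_a, last_b = -spacing, -spacing
    for pa, pb in chain:
        if pa >= last_a + spacing and pb >= last_b + spacing:
            sparse.append((pa, pb))
            last_a, last_b = pa, pb

    total_ed = 0
    segments = []
    prev_a, prev_b = 0, 0
    for pa, pb in sparse + [(len(a), len(b))]:
        if pa > prev_a or pb > prev_b:
            segments.append((prev_a, pa, prev_b, pb))
        prev_a, prev_b = pa, pb

    for sa, ea, sb, eb in segments:
        seg_a, seg_b = a[sa:ea], b[sb:eb]
        if not seg_a and not seg_b:
            continue
        if not seg_a:
            indels.append(Indel(sa, "ins", len(seg_b), seg_b))
            continue
        if not seg_b:
            indels.append(Indel(sa, "del", len(seg_a), seg_a))
            continue
        res = edlib.align(seg_b, seg_a, mode="NW", task="path")
        total_ed += res["editDistance"]
        ia, ib = sa, sb
        for length, op in _parse_cigar(res["cigar"]):
            if op == "=":
                ia += length
                ib += length
            elif op == "X":
                for t in range(length):
                    snps.append(Snp(ia + t + 1, a[ia + t], b[ib + t]))
                ia += length
                ib += length
            elif op == "I":  # insertion in b relative to a
                indels.append(Indel(ia, "ins", length, b[ib:ib + length]))
                ib += length
            elif op == "D":  # deletion from a
                indels.append(Indel(ia, "del", length, a[ia:ia + length]))
                ia += length

    identity = 1.0 - total_ed / max(len(a), len(b))
    if identity < 0.90:
        raise ValueError(
            f"sequences too diverged for this comparator ({identity:.2%} identity)"
        )
    snps.sort(key=lambda s: s.pos)
    indels.sort(key=lambda d: d.pos)
    return snps, _merge_indels(indels)


def _merge_indels(indels, max_gap: int = 10):
    """Fuse same-kind gap events separated by <= max_gap matched columns:
    optimal alignments may split one indel in a short tandem context."""
    merged: list[Indel] = []
    for d in indels:
        if (merged and merged[-1].kind == d.kind
                and d.pos - (merged[-1].pos + (merged[-1].length if d.kind == "del" else 0)) <= max_gap):
            last = merged[-1]
            merged[-1] = Indel(last.pos, last.kind, last.length + d.length,
                               last.seq + d.seq)
        else:
            merged.append(d)
    return merged


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def variants_to_vcf(snps, indels, seq_a: str, chrom: str, path) -> None:
    """Minimal VCF 4.x (CHROM/POS/REF/ALT, no genotypes)."""
    rows = []
    for s in snps:
        rows.append((s.pos, s.ref, s.alt))
    for d in indels:
        if d.kind == "del":
            pos = max(1, d.pos)
            ref = seq_a[pos - 1:pos + d.length]
            rows.append((pos, ref, ref[0]))
        else:
            pos = max(1, d.pos)
            anchor = seq_a[pos - 1]
            rows.append((pos, anchor, anchor + d.seq))
    rows.sort()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for pos, ref, alt in rows:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\n")


def census_to_tsv(runs, path) -> None:
    """Monopolymer census as TSV with per-base and combined counts."""
    from collections import Counter
    by_base = Counter(b for b, _, _ in runs)
    with open(path, "w") as fh:
        fh.write("base\tstart_1based\tlength\n")
        for b, s, ln in runs:
            fh.write(f"{b}\t{s + 1}\t{ln}\n")
        fh.write(f"#combined\t{len(runs)}\t\n")
        for b in sorted(by_base):
            fh.write(f"#count_{b}\t{by_base[b]}\t\n")
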