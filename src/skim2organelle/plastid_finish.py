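"""Plastome finishing: contig joining and circularization, quadripartite
structure detection, and detection + repair of the four in-silico assembly
error classes (false gaps, false SNPs, tandem-repeat copy-number collapse,
monopolymer length errors).

The error model: a genome skim contains plastid reads in large excess over
nuclear/mitochondrial reads, so the true plastome base call always carries
the dominant read support.  Mis-assemblies betray themselves during read
remapping as accumulations of discordant pairs, clipped read ends, or
abnormally high depth; each fix is accepted only if remapping evidence
improves, and unresolved issues are reported rather than dropped.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import depthmap, kassembler
from .compare import scan_monopolymers
from .seqio import Contig
from ._util import revcomp, seq_to_array, same_circular

FALSE_GAP = "FALSE_GAP"
FALSE_SNP = "FALSE_SNP"
TR_COLLAPSE = "TR_COLLAPSE"
MONOPOLYMER = "MONOPOLYMER"

_N_RUN = re.compile(r"N+")

IR_MIN_LEN = 1_000
IR_KMER = 31


@dataclass
class AssemblyIssue:
    kind: str
    start: int  # 0-based half-open on the draft
    end: int
    evidence: dict = field(default_factory=dict)
    payload: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("issue interval must be non-empty")


@dataclass
class PlastomeAssembly:
    sequence: str
    circular: bool
    regions: dict | None  # name -> (start, end), tiling the circle
    finishing_log: list
    residual_issues: list

    def __len__(self) -> int:
        return len(self.sequence)

    def region_seq(self, name: str) -> str:
        s, e = self.regions[name]
        return self.sequence[s:e]


# ---------------------------------------------------------------------------
# inverted-repeat detection and the canonical plastome form
# ---------------------------------------------------------------------------


def find_inverted_repeat(seq: str, min_len: int = IR_MIN_LEN):
    """Longest inverted-repeat pair on the circle, as ((a0, a1), (b0, b1))
    intervals on `seq` (may wrap: taken mod len).  None if < min_len."""
    n = len(seq)
    if n < 2 * min_len:
        return None
    k = IR_KMER
    seq2 = seq + seq
    pos: dict[str, list] = {}
    for i in range(len(seq2) - k + 1):
        pos.setdefault(seq2[i:i + k], []).append(i)
    # anti-diagonal grouping of forward-vs-reverse-complement matches
    diags: dict[int, list] = {}
    rc2 = revcomp(seq2)
    m = len(seq2)
    for j in range(m - k + 1):
        km = rc2[j:j + k]
        for i in pos.get(km, ()):  # seq2[i:i+k] == rc of seq2 at j' (below)
            jj = m - j - k  # start of the partner copy on seq2
            if i > jj:
                continue  # keep one of each symmetric pair
            diags.setdefault(i + jj, []).append(i)
    best = None  # (length, a0, a1, b0, b1) in doubled coordinates, a before b
    for d, starts in diags.items():
        starts = sorted(set(starts))
        runs = []
        r0 = prev = starts[0]
        for x in starts[1:]:
            if x == prev + 1:
                prev = x
                continue
            runs.append((r0, prev))
            r0 = prev = x
        runs.append((r0, prev))
        for i0, i1 in runs:
            length = i1 - i0 + k
            if length < min_len:
                continue
            a0, a1 = i0, i1 + k
            b0, b1 = d - i1, d - i0 + k
            # distinct, non-overlapping copies that fit within one circle span
            if a0 >= n or a1 > b0 or b1 - a0 > n:
                continue
            cand = (length, a0, a1, b0, b1)
            if best is None or length > best[0] or (length == best[0]
                                                    and a0 < best[1]):
                best = cand
    if best is None:
        return None
    _, a0, a1, b0, b1 = best
    return (a0, a1), (b0, b1)


def canonical_plastome(seq: str):
    """Canonical representation of a circular quadripartite plastome.

    Rotates to the LSC start and picks the lexicographically smallest of the
    four equivalent presentations (two strands x two SSC orientations -- the
    SSC flip isomers are indistinguishable by read data whenever the IR
    exceeds the insert size, so a fixed convention is required for
    comparability).  Returns (canonical_seq, regions) or (seq, None) when no
    IR >= 1 kb is found.
    """
    n = len(seq)
    ir = find_inverted_repeat(seq)
    if ir is None:
        return seq, None
    (a0, a1), (b0, b1) = ir
    seq2 = seq + seq
    # single-copy gaps between the IR copies on the circle (doubled coords:
    # a precedes b, and the whole a..b span fits within one circle length)
    len1 = b0 - a1          # gap after copy A
    len2 = n - (b1 - a0)    # gap after copy B, wrapping to copy A
    if len1 <= 0 or len2 <= 0:
        return seq, None
    l_ir = a1 - a0
    if len1 >= len2:
        lsc_start, l_lsc, l_ssc = a1, len1, len2
    else:
        lsc_start, l_lsc, l_ssc = b1 % n, len2, len1

    linear = seq2[lsc_start: lsc_start + n]
    L = linear[:l_lsc]
    i1 = linear[l_lsc:l_lsc + l_ir]
    S = linear[l_lsc + l_ir:l_lsc + l_ir + l_ssc]
    i2 = linear[l_lsc + l_ir + l_ssc:]
    candidates = [
        L + i1 + S + i2,
        L + i1 + revcomp(S) + i2,
        revcomp(L) + revcomp(i2) + revcomp(S) + revcomp(i1),
        revcomp(L) + revcomp(i2) + S + revcomp(i1),
    ]
    best = min(candidates)
    regions = {
        "LSC": (0, l_lsc),
        "IRa": (l_lsc, l_lsc + l_ir),
        "SSC": (l_lsc + l_ir, l_lsc + l_ir + l_ssc),
        "IRb": (l_lsc + l_ir + l_ssc, n),
    }
    return best, regions


def detect_quadripartite(draft):
    """Region intervals plus the canonicalized draft (rotation/strand/SSC
    convention).  Works on circular drafts; warns when no IR >= 1 kb."""
    seq = draft.seq if isinstance(draft, Contig) else draft
    canon, regions = canonical_plastome(seq)
    if regions is None:
        warnings.warn("no inverted repeat >= 1 kb: quadripartite regions unset",
                      stacklevel=2)
    return regions, canon


# ---------------------------------------------------------------------------
# contig joining
# ---------------------------------------------------------------------------


def _max_overlap(a: str, b: str, min_overlap: int, cap: int = 500) -> int:
    """Largest exact suffix(a)==prefix(b) overlap in [min_overlap, cap]."""
    top = min(len(a), len(b) - 1, cap)
    for o in range(top, min_overlap - 1, -1):
        if a[-o:] == b[:o]:
            return o
    return 0


def join_and_circularize(cp_contigs, min_overlap: int = 15,
                         placeholder_n: int = 100) -> Contig:
    """Order and orient contigs by maximal exact terminal overlaps into a
    single circular draft.

    Contigs whose depth is about twice the baseline (the inverted repeat)
    may be traversed twice, once per orientation.  If no closed layout
    exists, contigs are chained greedily and unjoinable junctions bridged
    with an N run of `placeholder_n` (reported in the provenance).
    Ambiguous inequivalent closed layouts raise an error naming the joins.
    """
    contigs = list(cp_contigs)
    if not contigs:
        raise ValueError("no contigs to join")
    if len(contigs) == 1:
        c = contigs[0]
        if c.circular:
            return c
        o = _max_overlap(c.seq, c.seq, max(min_overlap, 1))
        if o and o < len(c.seq):
            return Contig(c.id, c.seq[:-o], circular=True, depth=c.depth,
                          provenance=c.provenance + " self-circularized")
        return c

    depths = [c.depth for c in contigs]
    if all(d is not None for d in depths):
        pairs_ld = sorted((len(c.seq), c.depth) for c in contigs)
        tot = sum(l for l, _ in pairs_ld)
        acc = 0
        baseline = pairs_ld[-1][1]
        for l, d in pairs_ld:
            acc += l
            if acc >= tot / 2:
                baseline = d
                break
        mult = [max(1, min(2, int(round(c.depth / baseline)))) for c in contigs]
    else:
        mult = [1] * len(contigs)

    oriented = {}
    for i, c in enumerate(contigs):
        oriented[(i, "+")] = c.seq
        oriented[(i, "-")] = revcomp(c.seq)
    nodes = sorted(oriented)
    edges: dict = {}
    for u in nodes:
        for v in nodes:
            if u[0] == v[0]:
                continue
            o = _max_overlap(oriented[u], oriented[v], min_overlap)
            if o:
                edges.setdefault(u, []).append((v, o))
    for u in edges:
        edges[u].sort()

    total = sum(mult)
    start_i = max(range(len(contigs)), key=lambda i: (len(contigs[i].seq), -i))
    start = (start_i, "+")
    if total > 24:
        warnings.warn(f"{len(contigs)} contigs (multiplicity {total}) is too "
                      "fragmented for exhaustive layout search: chaining "
                      "greedily", stacklevel=2)
        return _greedy_chain(contigs, oriented, edges, mult, start,
                             placeholder_n, min_overlap)
    solutions = []
    raw_layouts = []

    def dfs(node, used, path):
        if len(solutions) > 8 or len(path) > total:
            return
        if len(path) == total:
            for v, o in edges.get(node, ()):
                if v == start:
                    seqp = _walk_sequence(path, oriented)
                    circ = seqp[: len(seqp) - o]
                    solutions.append(circ)
                    raw_layouts.append(list(path))
            return
        for v, o in edges.get(node, ()):
            i = v[0]
            if used[i] >= mult[i]:
                continue
            used[i] += 1
            path.append((v, o))
            dfs(v, used, path)
            path.pop()
            used[i] -= 1

    used0 = [0] * len(contigs)
    used0[start_i] = 1
    dfs(start, used0, [(start, 0)])

    if solutions:
        canon_set = {}
        for sol, lay in zip(solutions, raw_layouts):
            key, _ = canonical_plastome(sol)
            canon_set.setdefault(key, lay)
        if len(canon_set) > 1:
            joins = [" -> ".join(f"{contigs[i].id}{o}" for (i, o), _ in lay)
                     for lay in canon_set.values()]
            raise ValueError(
                "multiple inconsistent overlap layouts: " + " | ".join(joins)
            )
        seq = next(iter(canon_set))
        depth = float(np.average([c.depth or 0 for c in contigs],
                                 weights=[len(c.seq) for c in contigs]))
        return Contig("cp_draft", seq, circular=True, depth=depth,
                      provenance="join_and_circularize closed layout")

    # fallback: greedy chain with N-gap bridges
    return _greedy_chain(contigs, oriented, edges, mult, start, placeholder_n,
                         min_overlap)


def _walk_sequence(path, oriented) -> str:
    seq = oriented[path[0][0]]
    for node, o in path[1:]:
        seq += oriented[node][o:]
    return seq


def _greedy_chain(contigs, oriented, edges, mult, start, placeholder_n,
                  min_overlap=15):
    used = {i: 0 for i in range(len(contigs))}
    used[start[0]] = 1
    path = [(start, 0)]
    cur = start
    gaps = 0
    while sum(used.values()) < sum(mult):
        nxt = None
        best_o = 0
        for v, o in edges.get(cur, ()):
            if used[v[0]] < mult[v[0]] and o > best_o:
                nxt, best_o = v, o
        if nxt is None:
            # weak ordering hint: try sub-threshold overlaps >= 8
            cand = None
            for v in sorted(oriented):
                if used[v[0]] >= mult[v[0]]:
                    continue
                o = _max_overlap(oriented[cur], oriented[v], 8)
                if o:
                    cand = v
                    break
            if cand is None:
                remaining = [i for i in used if used[i] < mult[i]]
                cand = (max(remaining, key=lambda i: len(contigs[i].seq)), "+")
            nxt, best_o = cand, -1  # -1 marks an N bridge
            gaps += 1
        used[nxt[0]] += 1
        path.append((nxt, best_o))
        cur = nxt
    # close the circle: last -> first, bridged with N when no strong overlap
    o_close = _max_overlap(oriented[cur], oriented[start], min_overlap)
    if o_close == 0:
        o_close = -1
    if o_close < 0:
        gaps += 1
    incoming = [o_close] + [o for _, o in path[1:]]
    seq = ""
    for (node, _), o_in in zip(path, incoming):
        s = oriented[node]
        seq += s[o_in:] if o_in >= 0 else "N" * placeholder_n + s
    if seq.startswith("N"):
        # rotate the circle so the closure bridge sits interior
        shift = placeholder_n + len(oriented[path[0][0]])
        seq = seq[shift:] + seq[:shift]
    layout = " -> ".join(f"{contigs[i].id}{o}" for (i, o), _ in path)
    warnings.warn(f"no closed overlap layout: {gaps} junction(s) bridged with "
                  f"(N){placeholder_n}", stacklevel=2)
    return Contig("cp_draft", seq, circular=True, depth=None,
                  provenance=f"join_and_circularize bridged chain [{layout}]")


# ---------------------------------------------------------------------------
# issue detection
# ---------------------------------------------------------------------------


@dataclass
class _Evidence:
    mapres: depthmap.MappingResult
    pile: depthmap.Pileup
    anomaly: depthmap.AnomalyTrack


def _gather_evidence(draft: Contig, reads, max_mismatch_rate=0.05,
                     insert_model=None) -> _Evidence:
    reads = list(reads)
    if insert_model is None and reads:
        insert_model = (reads[0].insert_mean, reads[0].insert_sd)
    mapres = depthmap.map_reads(reads, draft, max_mismatch_rate)
    pile = depthmap.pileup(mapres)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        anomaly = depthmap.anomaly_profile(mapres, insert_model or (500.0, 50.0))
    return _Evidence(mapres, pile, anomaly)


def _tandem_period(seq: str, lo: int, hi: int, max_unit: int = 100,
                   min_unit: int = 4):
    """Smallest period u with a contiguous match run >= max(u, 12) between
    seq[i] and seq[i+u] overlapping [lo, hi); returns (u, s, e) for the full
    array interval or None."""
    w0 = max(0, lo - 300)
    w1 = min(len(seq), hi + 300)
    region = seq_to_array(seq[w0:w1])
    m = len(region)
    for u in range(min_unit, min(max_unit, m // 2) + 1):
        eq = region[:-u] == region[u:]
        if not eq.any():
            continue
        # longest True run
        best_len, best_s = 0, -1
        run = 0
        for i, v in enumerate(eq):
            if v:
                run += 1
                if run > best_len:
                    best_len, best_s = run, i - run + 1
            else:
                run = 0
        if best_len >= max(u, 12):
            s = w0 + best_s
            e = s + best_len + u  # full array span
            if s < hi and e > lo:
                return u, s, e
    return None


def detect_issues(draft, reads, *, z_thresh: float = 3.0,
                  minor_floor: float = 0.05, clip_min: int = 3,
                  min_cluster_depth: int = 10, tr_min_ratio: float = 1.25,
                  evidence: _Evidence | None = None) -> list:
    """Scan a mapped draft for the four mis-assembly classes.

    Returns AssemblyIssues sorted by position.  Precedence on overlapping
    evidence: N runs (false gaps) first, then homopolymer length errors,
    then tandem-repeat collapses, then false SNPs.
    """
    if not isinstance(draft, Contig):
        draft = Contig("draft", draft)
    ev = evidence or _gather_evidence(draft, reads)
    seq = draft.seq
    issues: list[AssemblyIssue] = []
    blocked: list[tuple[int, int]] = []

    def overlaps_blocked(s, e, pad=10):
        return any(s - pad < be and bs < e + pad for bs, be in blocked)

    for mobj in _N_RUN.finditer(seq):
        s, e = mobj.start(), mobj.end()
        win = slice(max(0, s - 600), min(len(seq), e + 600))
        issues.append(AssemblyIssue(
            FALSE_GAP, s, e,
            evidence={"discordant": int(ev.anomaly.discord[win].sum()),
                      "clips": int(ev.anomaly.clips[win].sum())},
            payload={"n_len": e - s},
        ))
        blocked.append((s - 600, e + 600))

    for base, s, length in scan_monopolymers(seq, min_len_exclusive=7):
        e = s + length
        if overlaps_blocked(s, e):
            continue
        edge_clips = int(ev.anomaly.clips[max(0, s - 3):min(len(seq), e + 3)].sum())
        if edge_clips >= clip_min:
            issues.append(AssemblyIssue(
                MONOPOLYMER, s, e,
                evidence={"clips": edge_clips},
                payload={"base": base, "length": length},
            ))
            blocked.append((s, e))

    win = ev.anomaly.window
    hot = np.flatnonzero(ev.anomaly.win_z >= z_thresh)
    seen_arrays: set = set()
    for w in hot:
        lo, hi = w * win, min(len(seq), (w + 1) * win)
        if overlaps_blocked(lo, hi):
            continue
        found = _tandem_period(seq, lo, hi)
        if found is None:
            continue
        u, s, e = found
        if (s, e) in seen_arrays or overlaps_blocked(s, e):
            continue
        seen_arrays.add((s, e))
        flank_depth = _flank_depth(ev.anomaly.depth, s, e)
        tr_depth = float(ev.anomaly.depth[s:e].mean())
        # a collapsed array stacks the missing copies' reads on top of the
        # remaining ones: the smallest real signal is (c+1)/c (~1.33 for a
        # 4-copy array missing one); a correct array sits at flank depth,
        # so a hot window there is chance -- 1.25 splits the two regimes
        if flank_depth <= 0 or tr_depth / flank_depth < tr_min_ratio:
            continue
        issues.append(AssemblyIssue(
            TR_COLLAPSE, s, e,
            evidence={"z": float(ev.anomaly.win_z[w]),
                      "depth_ratio": tr_depth / flank_depth if flank_depth else 0.0},
            payload={"unit_len": u, "copies": (e - s) // u},
        ))
        blocked.append((s, e))

    for cluster in ev.pile.clusters:
        ranked = cluster.ranked()
        if cluster.total < min_cluster_depth:
            continue
        s, e = cluster.positions[0], cluster.positions[-1] + 1
        if overlaps_blocked(s, e):
            continue
        draft_alleles = tuple(seq[p] for p in cluster.positions)
        major_alleles, major_n = ranked[0]
        minor_frac = ranked[1][1] / cluster.total if len(ranked) > 1 else 0.0
        if major_alleles != draft_alleles or (len(ranked) >= 2
                                              and minor_frac >= minor_floor):
            issues.append(AssemblyIssue(
                FALSE_SNP, s, e,
                evidence={"cluster": cluster,
                          "groups": dict(cluster.groups)},
                payload={"positions": list(cluster.positions),
                         "draft_alleles": draft_alleles,
                         "consensus": major_alleles},
            ))

    issues.sort(key=lambda i: (i.start, i.kind))
    return issues


def _flank_depth(depth: np.ndarray, s: int, e: int, flank: int = 500) -> float:
    left = depth[max(0, s - flank):s]
    right = depth[e:e + flank]
    both = np.concatenate([left, right])
    return float(both.mean()) if both.size else 0.0


# ---------------------------------------------------------------------------
# fixers
# ---------------------------------------------------------------------------


@dataclass
class FixResult:
    sequence: str
    resolved: bool
    note: str


def _anomaly_mass_near(draft_seq, reads, pos, halfwin=600) -> float:
    ctg = Contig("check", draft_seq)
    ev = _gather_evidence(ctg, reads)
    lo, hi = max(0, pos - halfwin), min(len(draft_seq), pos + halfwin)
    return float(ev.anomaly.discord[lo:hi].sum() + ev.anomaly.clips[lo:hi].sum())


def fix_false_gap(draft, issue: AssemblyIssue, reads=None, min_dup: int = 10,
                  validate: bool = True) -> FixResult:
    """Collapse the duplicated flanks around an N run.

    The maximal exact duplication (suffix of the left flank == prefix of the
    right flank, >= min_dup) is merged and the N removed; the edit is kept
    only if remapping clears the local discordance, otherwise the draft is
    returned unchanged and the issue stays unresolved (to be handed to the
    gap closer).
    """
    if issue.kind != FALSE_GAP:
        raise ValueError("issue is not a FALSE_GAP")
    seq = draft.seq if isinstance(draft, Contig) else draft
    s, e = issue.start, issue.end
    left, right = seq[:s], seq[e:]
    o = _max_overlap(left, right, min_dup, cap=300)
    if o == 0:
        return FixResult(seq, False, "no flanking duplication >= "
                                     f"{min_dup} bp: routed to gap closing")
    candidate = left + right[o:]
    if validate and reads is not None:
        before = _anomaly_mass_near(seq, reads, s)
        after = _anomaly_mass_near(candidate, reads, s)
        if not (after < before and after <= max(2.0, 0.2 * before)):
            return FixResult(seq, False,
                             f"merge of {o} bp duplication rejected by "
                             f"remapping (anomaly {before:.0f} -> {after:.0f})")
    return FixResult(candidate, True, f"merged {o} bp duplicated flank, "
                                      f"removed (N){e - s}")


def fix_false_snp(draft, issue: AssemblyIssue, pile=None) -> FixResult:
    """Jointly set the linked positions to the highest-depth haplotype."""
    if issue.kind != FALSE_SNP:
        raise ValueError("issue is not a FALSE_SNP")
    seq = draft.seq if isinstance(draft, Contig) else draft
    cluster = issue.evidence["cluster"]
    ranked = cluster.ranked()
    if len(ranked) >= 2 and ranked[0][1] == ranked[1][1]:
        return FixResult(seq, False, "tied haplotype groups: draft unchanged")
    consensus, n = ranked[0]
    if n < 0.5 * cluster.total:
        warnings.warn(
            f"largest haplotype group is only {n}/{cluster.total} reads: "
            "possible contamination", stacklevel=2)
    out = list(seq)
    changed = False
    for pos, allele in zip(cluster.positions, consensus):
        if out[pos] != allele:
            out[pos] = allele
            changed = True
    note = (f"consensus {('->'.join(consensus))} applied at "
            f"{[p + 1 for p in cluster.positions]} (group {n}/{cluster.total})")
    if not changed:
        note = "draft already carries the consensus alleles"
    return FixResult("".join(out), True, note)


def fix_tr_copy(draft, issue: AssemblyIssue, reads, local_k: int = 64,
                evidence: _Evidence | None = None) -> FixResult:
    """Restore tandem-repeat copy number.

    Strategy A (read length >= array span + 2 units): re-assemble reads near
    the array with a k-mer longer than the assembled array span and splice
    the resolved array in.  Strategy B: rewrite with n* = round(c x
    depth_TR/depth_flank) copies.  Either way the fix must bring the
    remapped depth ratio at the array into [0.8, 1.25] of the flanks.
    """
    if issue.kind != TR_COLLAPSE:
        raise ValueError("issue is not a TR_COLLAPSE")
    seq = draft.seq if isinstance(draft, Contig) else draft
    reads = list(reads)
    s, e = issue.start, issue.end
    u = issue.payload["unit_len"]
    c = max(1, (e - s) // u)
    read_len = max(len(reads[0].bases1), len(reads[0].bases2)) if reads else 0

    candidates = []
    if read_len >= (e - s) + 2 * u:
        k = min(max(local_k, c * u + 1), read_len - 1)
        spliced = _local_reassembly(seq, s, e, reads, k)
        if spliced is not None:
            candidates.append((spliced, f"local re-assembly at k={k}"))
    ev = evidence
    if ev is None:
        ev = _gather_evidence(Contig("draft", seq), reads)
    flank = _flank_depth(ev.anomaly.depth, s, e)
    tr = float(ev.anomaly.depth[s:e].mean())
    if flank > 0:
        n_star = int(round(c * tr / flank))
        if n_star != c and n_star >= 1:
            unit = seq[s:s + u]
            rewritten = seq[:s] + unit * n_star + seq[e:]
            candidates.append(
                (rewritten, f"depth-ratio rewrite {c} -> {n_star} copies "
                            f"(ratio {tr / flank:.2f})"))

    for cand, note in candidates:
        ev2 = _gather_evidence(Contig("cand", cand), reads)
        ne = s + (len(cand) - len(seq)) + (e - s)
        flank2 = _flank_depth(ev2.anomaly.depth, s, ne)
        tr2 = float(ev2.anomaly.depth[s:ne].mean()) if ne > s else 0.0
        if flank2 > 0 and 0.8 <= tr2 / flank2 <= 1.25:
            return FixResult(cand, True, note + f" (post-fix ratio {tr2 / flank2:.2f})")
    return FixResult(seq, False, "no strategy passed the post-fix depth check")


def _local_reassembly(seq, s, e, reads, k, pad: int = 1_500):
    """Assemble reads near [s, e) at large k and splice the segment between
    the flank anchors back into the draft."""
    lo, hi = max(0, s - pad), min(len(seq), e + pad)
    probe = seq[lo:hi]
    probe_kmers = {probe[i:i + 21] for i in range(len(probe) - 20)}
    rc_kmers = {revcomp(p) for p in probe_kmers}
    probe_kmers |= rc_kmers
    local = []
    for pair in reads:
        for b in (pair.bases1, pair.bases2):
            for i in range(0, len(b) - 21, 10):
                if b[i:i + 21] in probe_kmers:
                    local.append(pair)
                    break
            else:
                continue
            break
    if len(local) < 10:
        return None
    try:
        graph = kassembler.build_graph(local, k=k, min_count=2)
    except ValueError:
        return None
    contigs = kassembler.assemble(graph)
    anchor_l = seq[max(0, s - 40):s]
    anchor_r = seq[e:e + 40]
    if len(anchor_l) < 20 or len(anchor_r) < 20:
        return None
    for ctg in contigs:
        for cseq in (ctg.seq, revcomp(ctg.seq)):
            il = cseq.find(anchor_l)
            if il < 0:
                continue
            ir = cseq.find(anchor_r, il + len(anchor_l))
            if ir < 0:
                continue
            middle = cseq[il + len(anchor_l):ir]
            return seq[:s] + middle + seq[e:]
    return None


def fix_monopolymer(draft, issue: AssemblyIssue, reads,
                    candidate_lengths=None) -> FixResult:
    """Select the tract length whose hypothetical sequence attracts the
    highest perfect-match (0 mismatch) read depth in a read-length window
    around the tract."""
    if issue.kind != MONOPOLYMER:
        raise ValueError("issue is not a MONOPOLYMER")
    seq = draft.seq if isinstance(draft, Contig) else draft
    reads = list(reads)
    s, e = issue.start, issue.end
    base = issue.payload["base"]
    current = e - s
    if candidate_lengths is None:
        candidate_lengths = sorted(set(range(5, 26)) | {current})
    read_len = max(len(reads[0].bases1), len(reads[0].bases2)) if reads else 100

    left = seq[max(0, s - read_len):s]
    right = seq[e:e + read_len]
    # pre-filter: only mates sharing a 15-mer with the flanks can contribute
    probes = set()
    for flank in (left, right):
        for i in range(len(flank) - 14):
            probes.add(flank[i:i + 15])
    probes |= {revcomp(p) for p in probes}
    subset = []
    for pair in reads:
        for b in (pair.bases1, pair.bases2):
            if any(b[i:i + 15] in probes for i in range(0, len(b) - 14, 7)):
                subset.append(pair)
                break

    best_len, best_depth = None, -1.0
    depths = {}
    for L in candidate_lengths:
        window = left + base * L + right
        res = depthmap.map_reads(subset, window, max_mismatch_rate=0.0)
        mean_depth = sum(p.end - p.start for p in res.placements) / len(window)
        depths[L] = mean_depth
        if mean_depth > best_depth + 1e-9:
            best_len, best_depth = L, mean_depth
    if best_depth <= 0:
        return FixResult(seq, False, "no candidate length has perfect-match support")
    ties = [L for L, d in depths.items() if abs(d - best_depth) < 1e-9]
    if len(ties) > 1:
        best_len = current if current in ties else min(ties)
    if best_len == current:
        return FixResult(seq, True, f"tract length {current} confirmed "
                                    f"(depth {best_depth:.2f})")
    fixed = seq[:s] + base * best_len + seq[e:]
    return FixResult(fixed, True,
                     f"({base}){current} -> ({base}){best_len} "
                     f"(depth {best_depth:.2f}, "
                     f"runner-up {sorted(depths.values())[-2]:.2f})")


# ---------------------------------------------------------------------------
# the finishing loop
# ---------------------------------------------------------------------------

_FIX_ORDER = {FALSE_GAP: 0, MONOPOLYMER: 1, FALSE_SNP: 2, TR_COLLAPSE: 3}


def finish(draft, reads, max_rounds: int = 5, reference: str | None = None,
           detect_kwargs: dict | None = None) -> PlastomeAssembly:
    """Iterate detect -> fix -> remap until the draft is evidence-clean.

    Fixes within a round are applied in positional order (structural kinds
    first at equal positions); a gap whose flanks carry no duplication is
    handed to the paired-read gap closer.  Oscillation (returning to a
    previously seen sequence) stops the loop with a report.  The finished
    draft is canonicalized to the quadripartite convention (or anchored to
    `reference` when given).
    """
    if not isinstance(draft, Contig):
        draft = Contig("draft", draft, circular=False)
    reads = list(reads)
    seq = draft.seq
    circular = draft.circular
    log: list[dict] = []
    seen = {seq}
    detect_kwargs = detect_kwargs or {}
    unresolved_keys: set = set()
    residual: list[AssemblyIssue] = []

    for rnd in range(1, max_rounds + 1):
        ev = _gather_evidence(Contig("draft", seq, circular=circular), reads)
        issues = detect_issues(Contig("draft", seq, circular=circular), reads,
                               evidence=ev, **detect_kwargs)
        issues = [i for i in issues if _issue_key(seq, i) not in unresolved_keys]
        if not issues:
            residual = []
            break
        issues.sort(key=lambda i: (i.start, _FIX_ORDER[i.kind]))
        delta = 0
        changed = False
        gap_backlog = []
        for issue in issues:
            shifted = AssemblyIssue(issue.kind, issue.start + delta,
                                    issue.end + delta, issue.evidence,
                                    issue.payload)
            before_len = len(seq)
            if issue.kind == FALSE_GAP:
                res = fix_false_gap(seq, shifted, reads)
                if not res.resolved:
                    gap_backlog.append(shifted)
            elif issue.kind == MONOPOLYMER:
                res = fix_monopolymer(seq, shifted, reads)
            elif issue.kind == FALSE_SNP:
                res = fix_false_snp(seq, shifted)
            else:
                res = fix_tr_copy(seq, shifted, reads, evidence=None)
            log.append({"round": rnd, "kind": issue.kind,
                        "interval": (shifted.start, shifted.end),
                        "resolved": res.resolved,
                        "changed": res.sequence != seq, "note": res.note})
            if res.sequence != seq:
                changed = True
                seq = res.sequence
                delta += len(seq) - before_len
            elif not res.resolved:
                unresolved_keys.add(_issue_key(seq, shifted))
                residual.append(shifted)
        if gap_backlog and "N" in seq:
            try:
                state = kassembler.close_gaps(seq, reads)
            except ValueError:
                state = None
            if state is not None and state.sequence != seq:
                closed = seq.count("N") - state.sequence.count("N")
                seq = state.sequence
                changed = True
                log.append({"round": rnd, "kind": FALSE_GAP,
                            "interval": None, "resolved": not state.stalled,
                            "changed": True,
                            "note": f"gap closer removed {closed} N bases "
                                    f"({state.iterations} iterations)"})
        if not changed:
            break
        if seq in seen:
            log.append({"round": rnd, "kind": "OSCILLATION", "interval": None,
                        "resolved": False,
                        "note": "fix re-created a previously seen sequence"})
            break
        seen.add(seq)
    else:
        # rounds exhausted: record whatever detection still finds
        residual = detect_issues(Contig("draft", seq, circular=circular), reads,
                                 **detect_kwargs)

    regions, canon = detect_quadripartite(Contig("final", seq, circular=True))
    if regions is not None:
        seq = canon
    if reference:
        seq = _anchor_to_reference(seq, reference)
        if regions is not None:
            regions, _ = detect_quadripartite(Contig("final", seq, circular=True))
            # keep the reference orientation; regions recomputed on it
            regions = _regions_on(seq) or regions
    if "N" in seq:
        for mobj in _N_RUN.finditer(seq):
            residual.append(AssemblyIssue(FALSE_GAP, mobj.start(), mobj.end(),
                                          payload={"unclosed": True}))
    if regions is not None:
        ira = seq[slice(*regions["IRa"])]
        irb = seq[slice(*regions["IRb"])]
        ident = _identity(ira, revcomp(irb))
        if ident < 0.999:
            warnings.warn(f"IR copies only {ident:.3%} identical", stacklevel=2)
    return PlastomeAssembly(seq, True, regions, log, residual)


def _regions_on(seq: str):
    ir = find_inverted_repeat(seq)
    if ir is None:
        return None
    canon, regions = canonical_plastome(seq)
    return regions if canon == seq else None


def _issue_key(seq: str, issue: AssemblyIssue):
    return (issue.kind, seq[max(0, issue.start - 20):issue.end + 20])


def _identity(a: str, b: str) -> float:
    if len(a) != len(b) or not a:
        return 0.0
    arr_a, arr_b = seq_to_array(a), seq_to_array(b)
    return float((arr_a == arr_b).mean())


def _anchor_to_reference(seq: str, reference: str) -> str:
    """Rotate/orient a circular sequence to match the reference start."""
    probe = reference[:40]
    for cand in (seq, revcomp(seq)):
        doubled = cand + cand
        i = doubled.find(probe)
        if 0 <= i < len(cand):
            return doubled[i:i + len(cand)]
    return seq


def finishing_log_to_tsv(assembly: PlastomeAssembly, path) -> None:
    with open(path, "w") as fh:
        fh.write("round\tkind\tstart\tend\tresolved\tchanged\tnote\n")
        for entry in assembly.finishing_log:
            iv = entry["interval"] or ("", "")
            fh.write(f"{entry['round']}\t{entry['kind']}\t{iv[0]}\t{iv[1]}\t"
                     f"{int(entry['resolved'])}\t"
                     f"{int(entry.get('changed', False))}\t{entry['note']}\n")


def regions_to_bed(assembly: PlastomeAssembly, path, name: str = "plastome") -> None:
    with open(path, "w") as fh:
        if assembly.regions:
            for rname, (s, e) in assembly.regions.items():
                strand = "-" if rname == "IRb" else "+"
                fh.write(f"{name}\t{s}\t{e}\t{rname}\t.\t{strand}\n")
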