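"""Nuclear ribosomal DNA unit reconstruction and copy-number estimation.

The 45S unit (18S-ITS1-5.8S-ITS2-26S cistron plus the intergenic spacer) is
completed with the two-unit tandem trick: because the units of an array are
highly homogeneous, an initial contig covering the cistron and part of the
IGS can be duplicated around a placeholder (N)n run and the gap closed with
the raw paired reads; when the placeholder length underestimates the
missing IGS span, gap closing stalls and the placeholder is enlarged on a
schedule before retrying.  The region between the two cistron starts of the
closed construct is one complete unit.

Copy numbers follow the 1x genome-equivalent rule: subsample the reads down
to exactly one haploid genome of bases, map them to the unit, and read the
mean per-base depth as the copy number.

Gene detection uses the packaged rDNA models (synthetic stand-in consensus
sequences shipped with the package).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np

from . import depthmap, kassembler
from .seqio import Contig
from .skimsim import load_rdna_models
from ._util import revcomp, seq_to_array

_N_RUN = re.compile(r"N+")

DEFAULT_N_SCHEDULE = (100, 300, 1000)


@dataclass
class RdnaUnit:
    unit_class: str  # "5S" | "45S"
    sequence: str  # one full unit, canonical rotation (gene/cistron start)
    sub_regions: dict | None = None  # 45S: name -> (start, end), tiles unit
    cistron_length: int | None = None
    igs_length: int | None = None
    copy_number_estimate: float | None = None
    copy_number_interval: tuple | None = None
    complete: bool = True
    secondary_periods: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


def _locate(model: str, seq: str, max_div: float = 0.15):
    """Best infix match of a gene model in seq (either strand).

    Returns (start, end, strand, edit_distance) or None.
    """
    k = int(max_div * len(model))
    best = None
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        res = edlib.align(model, s, mode="HW", task="locations", k=k)
        if res["editDistance"] < 0:
            continue
        loc = res["locations"][0]
        cand = (res["editDistance"], strand, loc[0], loc[1] + 1)
        if best is None or cand[0] < best[0]:
            best = cand
    if best is None:
        return None
    ed, strand, s, e = best
    if strand == "-":
        n = len(seq)
        s, e = n - e, n - s
    return s, e, strand, ed


def _locate_all(model: str, seq: str, max_div: float = 0.15):
    """All non-overlapping infix matches of a model (forward strand)."""
    k = int(max_div * len(model))
    res = edlib.align(model, seq, mode="HW", task="locations", k=k)
    if res["editDistance"] < 0:
        return []
    hits = []
    last_end = -1
    for s, e in sorted(res["locations"]):
        if s > last_end:
            hits.append((s, e + 1))
            last_end = e
    return hits


# ---------------------------------------------------------------------------
# 45S completion
# ---------------------------------------------------------------------------


def complete_45s(initial_contig, reads, n_len_schedule=DEFAULT_N_SCHEDULE,
                 models: dict | None = None) -> RdnaUnit:
    """Complete the 45S unit from an initial cistron-bearing contig.

    Builds contig + (N)n + contig, runs the gap closer, and on closure cuts
    one unit between the two 18S starts; a stall advances n along
    `n_len_schedule`.  If every schedule entry stalls, a partial unit with
    an explicit N gap is returned (complete=False).
    """
    models = models or load_rdna_models()
    m18 = models["18S_synthetic_consensus"]
    seq = initial_contig.seq if isinstance(initial_contig, Contig) else initial_contig
    hit = _locate(m18, seq)
    if hit is None:
        raise ValueError("initial contig does not contain the 45S cistron "
                         "(no 18S match)")
    if hit[2] == "-":
        seq = revcomp(seq)
        hit = _locate(m18, seq)

    closed = None
    stalls = []
    for n_len in n_len_schedule:
        construct = seq + "N" * n_len + seq
        state = kassembler.close_gaps(construct, reads)
        if "N" not in state.sequence:
            closed = state.sequence
            break
        stalls.append(n_len)
    if closed is None:
        warnings.warn(
            f"45S gap closing stalled at all N lengths {list(n_len_schedule)}: "
            "returning partial unit", stacklevel=2)
        partial = seq + "N" * n_len_schedule[-1] + seq
        unit = _cut_unit(partial, m18)
        return _annotate_45s(unit or partial, models, complete=False)

    unit = _cut_unit(closed, m18)
    if unit is None:
        raise ValueError("closed 45S construct lacks two cistron copies")
    return _annotate_45s(unit, models, complete=True, stalled_at=stalls)


def _cut_unit(closed: str, m18: str):
    """One unit = the span between the two 18S starts of the closed
    two-unit construct (canonical rotation: unit starts at 18S)."""
    hits = _locate_all(m18, closed)
    if len(hits) < 2:
        return None
    s1, s2 = hits[0][0], hits[1][0]
    if s2 <= s1:
        return None
    return closed[s1:s2]


def _annotate_45s(unit: str, models: dict, complete: bool = True,
                  stalled_at=None) -> RdnaUnit:
    m18 = models["18S_synthetic_consensus"]
    m58 = models["5.8S_synthetic_consensus"]
    m26 = models["26S_synthetic_consensus"]
    sub = {}
    h18 = _locate(m18, unit)
    h58 = _locate(m58, unit)
    h26 = _locate(m26, unit)
    cistron_len = igs_len = None
    if h18 and h58 and h26 and h18[0] == 0:
        sub["18S"] = (0, h18[1])
        sub["ITS1"] = (h18[1], h58[0])
        sub["5.8S"] = (h58[0], h58[1])
        sub["ITS2"] = (h58[1], h26[0])
        sub["26S"] = (h26[0], h26[1])
        sub["IGS"] = (h26[1], len(unit))
        cistron_len = h26[1]
        igs_len = len(unit) - h26[1]
    else:
        sub = None
        warnings.warn("could not tile 45S sub-regions on the unit", stacklevel=2)
    u = RdnaUnit("45S", unit, sub_regions=sub, cistron_length=cistron_len,
                 igs_length=igs_len, complete=complete and "N" not in unit)
    if stalled_at:
        u.secondary_periods = []  # populated by period analysis elsewhere
    return u


# ---------------------------------------------------------------------------
# 5S extraction
# ---------------------------------------------------------------------------


def _rotation_period(seq: str, min_period: int = 50, min_identity: float = 0.99):
    """Smallest p with seq[:-p] ~= seq[p:] at >= min_identity (and >= 50 bp
    of overlap), plus any secondary candidates (multiples, weaker periods)."""
    arr = seq_to_array(seq)
    n = len(arr)
    candidates = []
    for p in range(min_period, n - 49):
        a, b = arr[:-p], arr[p:]
        ident = float((a == b).mean())
        if ident >= min_identity:
            candidates.append((p, ident))
    if not candidates:
        return None, []
    primary = candidates[0][0]
    secondary = [p for p, _ in candidates[1:] if p % primary != 0][:3]
    return primary, secondary


def extract_5s(contigs, models: dict | None = None) -> RdnaUnit:
    """One full 5S unit from a tandem-spanning contig.

    The unit is the minimal rotation period of the contig, canonicalized to
    start at the 5S gene; a circular (collapsed-cycle) contig is itself one
    period.  Raises if no contig matches the 5S model or the match lies in
    an aperiodic contig shorter than one period.
    """
    models = models or load_rdna_models()
    m5s = models["5S_synthetic_consensus"]
    if isinstance(contigs, (str, Contig)):
        contigs = [contigs if isinstance(contigs, Contig) else Contig("c", contigs)]
    match = None
    for c in sorted(contigs, key=lambda c: -len(c.seq)):
        hit = _locate(m5s, c.seq)
        if hit is not None:
            match = (c, hit)
            break
    if match is None:
        raise ValueError("no contig matches the 5S gene model")
    contig, hit = match
    seq = contig.seq if hit[2] == "+" else revcomp(contig.seq)
    hit = _locate(m5s, seq)
    gene_start = hit[0]

    if contig.circular:
        unit = seq[gene_start:] + seq[:gene_start]
        return RdnaUnit("5S", unit, cistron_length=hit[1] - hit[0],
                        igs_length=len(unit) - (hit[1] - hit[0]))
    period, secondary = _rotation_period(seq)
    if period is None:
        # aperiodic: the contig itself must be (at least) one full unit
        if len(seq) - gene_start < (hit[1] - hit[0]):
            raise ValueError("incomplete unit: contig shorter than one period")
        unit = seq
        if gene_start:
            unit = seq[gene_start:] + seq[:gene_start]
        return RdnaUnit("5S", unit, cistron_length=hit[1] - hit[0],
                        igs_length=len(unit) - (hit[1] - hit[0]))
    if len(seq) < period:
        raise ValueError("incomplete unit: contig shorter than one period")
    if gene_start + period <= len(seq):
        unit = seq[gene_start:gene_start + period]
    else:
        base = seq[:period]
        g = gene_start % period
        unit = base[g:] + base[:g]
    return RdnaUnit("5S", unit, cistron_length=hit[1] - hit[0],
                    igs_length=period - (hit[1] - hit[0]),
                    secondary_periods=secondary)


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------


def estimate_copy_number(unit, reads, genome_size: int, seed: int = 0):
    """Copy number per 1x haploid genome equivalent.

    Subsamples the reads down to exactly `genome_size` bases (seeded), maps
    them to the unit treated as circular (a tandem unit wraps), and returns
    (mean depth, (lo, hi)) -- the mean per-base depth IS the copy number
    under a 1x genome equivalent.  Fractional multi-mapping weights apply.
    """
    useq = unit.sequence if isinstance(unit, RdnaUnit) else (
        unit.seq if isinstance(unit, Contig) else unit)
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    reads = list(reads)
    if not reads:
        raise ValueError("no reads")
    rl = max(len(reads[0].bases1), len(reads[0].bases2))
    if len(useq) < rl:
        raise ValueError("unit shorter than the read length")
    pair_bases = len(reads[0].bases1) + len(reads[0].bases2)
    n_1x = int(round(genome_size / pair_bases))
    if n_1x < len(reads):
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(reads), size=n_1x, replace=False))
        sample = [reads[i] for i in idx]
    else:
        if n_1x > len(reads):
            warnings.warn(
                f"fewer than 1x genome-equivalent reads available "
                f"({len(reads)} pairs < {n_1x}): estimate will be biased low",
                stacklevel=2)
        sample = reads
    mapres = depthmap.map_reads(sample, useq, max_mismatch_rate=0.05,
                                circular=True)
    pile = depthmap.pileup(mapres)
    mean_depth = float(pile.depth.mean())
    # sampling interval from window-mean dispersion
    win = 50
    wm = [pile.depth[i:i + win].mean() for i in range(0, len(useq) - win + 1, win)]
    se = float(np.std(wm) / max(1.0, np.sqrt(len(wm))))
    interval = (mean_depth - 1.96 * se, mean_depth + 1.96 * se)
    if isinstance(unit, RdnaUnit):
        unit.copy_number_estimate = mean_depth
        unit.copy_number_interval = interval
    return mean_depth, interval


def units_to_gff(unit: RdnaUnit, path, seqid: str | None = None) -> None:
    """45S sub-regions (or the 5S gene) as a GFF3-like TSV."""
    seqid = seqid or f"rdna_{unit.unit_class}"
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if unit.sub_regions:
            for name, (s, e) in unit.sub_regions.items():
                fh.write(f"{seqid}\tskim2organelle\tregion\t{s + 1}\t{e}\t.\t+\t.\t"
                         f"Name={name}\n")
        else:
            fh.write(f"{seqid}\tskim2organelle\tregion\t1\t{len(unit)}\t.\t+\t.\t"
                     f"Name={unit.unit_class}\n")


def copy_number_report(units, path) -> None:
    with open(path, "w") as fh:
        fh.write("unit_class\tlength\tcopy_number\tci_lo\tci_hi\tcomplete\n")
        for u in units:
            cn = u.copy_number_estimate
            lo, hi = u.copy_number_interval or ("", "")
            fh.write(f"{u.unit_class}\t{len(u)}\t"
                     f"{cn if cn is None else f'{cn:.1f}'}\t"
                     f"{lo if lo == '' else f'{lo:.1f}'}\t"
                     f"{hi if hi == '' else f'{hi:.1f}'}\t{int(u.complete)}\n")
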