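"""Skim triage: plastid read-fraction estimation, coverage-window
subsampling, and k-mer screening classification of contigs.

The subsampling logic implements the coverage-window optimization: the best
plastome assemblies come from read amounts giving roughly 100-250x plastid
coverage, while exceeding ~20x whole-genome coverage floods the assembly
with NMPT-derived reads and inflates error and contig counts -- so the
planner warns when the implied genome coverage crosses that threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import depthmap
from .seqio import Contig, CoveragePlan
from ._util import canonical_kmer, revcomp

CLASSIFY_K = 21
CLASSIFY_MIN_FRACTION = 0.3
GENOME_COVERAGE_WARN = 20.0


def estimate_cp_fraction(reads, bait_reference, sample_size: int = 10_000,
                         max_mismatch_rate: float = 0.1, seed: int = 0):
    """Fraction of read bases of plastid origin, from mapping a read sample
    against any related plastome bait.

    Returns (fraction, (lo, hi)): the point estimate with its 95%
    Clopper-Pearson interval over sampled reads.
    """
    if isinstance(bait_reference, dict):
        baits = list(bait_reference.values())
    elif isinstance(bait_reference, str):
        baits = [bait_reference]
    else:
        baits = [c.seq if isinstance(c, Contig) else c for c in bait_reference]
    if not baits or not any(baits):
        raise ValueError("empty bait reference")

    reads = list(reads)
    rng = np.random.default_rng(seed)
    if len(reads) > sample_size:
        idx = np.sort(rng.choice(len(reads), size=sample_size, replace=False))
        sample = [reads[i] for i in idx]
    else:
        sample = reads

    mapped_reads = 0
    mapped_bases = 0
    total_reads = 0
    total_bases = 0
    placed: set = set()
    for bait in baits:
        res = depthmap.map_reads(sample, bait, max_mismatch_rate, circular=True)
        for p in res.placements:
            placed.add((p.qname, p.mate))
    lengths = {}
    for pair in sample:
        lengths[(pair.id, 1)] = len(pair.bases1)
        lengths[(pair.id, 2)] = len(pair.bases2)
    total_reads = len(lengths)
    total_bases = sum(lengths.values())
    mapped_reads = len(placed)
    mapped_bases = sum(lengths[key] for key in placed)

    fraction = mapped_bases / total_bases if total_bases else 0.0
    lo, hi = _clopper_pearson(mapped_reads, total_reads)
    return fraction, (lo, hi)


def _clopper_pearson(k: int, n: int, alpha: float = 0.05):
    if n == 0:
        return 0.0, 1.0
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def subsample(reads, plan: CoveragePlan) -> list:
    """Seed-deterministic uniform draw of pairs hitting the plan's target
    read-base count (never more than one pair over)."""
    reads = list(reads)
    if not reads:
        return []
    target = plan.target_read_bases
    implied_genome_cov = target / plan.genome_size
    if implied_genome_cov > GENOME_COVERAGE_WARN:
        warnings.warn(
            f"subsample implies {implied_genome_cov:.1f}x whole-genome coverage "
            f"(> {GENOME_COVERAGE_WARN:.0f}x): NMPT-derived reads are likely to "
            "interfere with plastome assembly",
            stacklevel=2,
        )
    pair_bases = [len(p.bases1) + len(p.bases2) for p in reads]
    mean_pair = float(np.mean(pair_bases))
    n_pairs = int(round(target / mean_pair))
    if n_pairs >= len(reads):
        if n_pairs > len(reads):
            warnings.warn(
                f"requested {target:.0f} bases but only "
                f"{sum(pair_bases)} available: taking all", stacklevel=2,
            )
        return reads
    rng = np.random.default_rng(plan.seed)
    idx = np.sort(rng.choice(len(reads), size=n_pairs, replace=False))
    return [reads[i] for i in idx]


@dataclass
class ContigLabel:
    contig: Contig
    label: str  # cp | mt | nR | other
    fraction: float  # shared canonical 21-mer fraction with the best class
    best_class: str


def _kmer_set(seq: str, k: int = CLASSIFY_K) -> set:
    return {
        canonical_kmer(seq[i:i + k])
        for i in range(len(seq) - k + 1)
        if "N" not in seq[i:i + k]
    }


def classify_contigs(contigs, panel: dict, k: int = CLASSIFY_K,
                     min_fraction: float = CLASSIFY_MIN_FRACTION) -> list:
    """Label contigs by shared canonical k-mer fraction against a labeled
    reference panel ({label: sequence or [sequences]}).

    The winning class must share at least `min_fraction` of the contig's
    k-mers, otherwise the contig is labeled "other".  Report is sorted by
    contig length, longest first.  Labels are reverse-complement invariant
    by construction (canonical k-mers).
    """
    if not panel:
        raise ValueError("empty reference panel")
    panel_sets = {}
    for label, seqs in panel.items():
        if isinstance(seqs, str):
            seqs = [seqs]
        kset: set = set()
        for s in seqs:
            s = s.seq if isinstance(s, Contig) else s
            kset |= _kmer_set(s, k)
        panel_sets[label] = kset

    report = []
    for contig in sorted(contigs, key=lambda c: (-len(c.seq), c.id)):
        kmers = _kmer_set(contig.seq, k)
        best_label, best_frac = "other", 0.0
        if kmers:
            for label in sorted(panel_sets):
                frac = len(kmers & panel_sets[label]) / len(kmers)
                if frac > best_frac:
                    best_label, best_frac = label, frac
        label = best_label if best_frac >= min_fraction else "other"
        report.append(ContigLabel(contig, label, best_frac, best_label))
    return report


def classification_to_tsv(report, path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tlength\tlabel\tfraction\tbest_hit\n")
        for r in report:
            fh.write(
                f"{r.contig.id}\t{len(r.contig.seq)}\t{r.label}\t"
                f"{r.fraction:.3f}\t{r.best_class}\n"
            )
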