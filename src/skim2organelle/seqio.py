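"""Sequence I/O and the core domain types.

FASTQ/FASTA reading and writing go through Biopython; this module adds the
paired-end pairing logic, the quality-trimming rule applied before assembly
(drop a read when its mean Phred quality after end-trimming is at or below
the threshold; a pair is dropped when either mate drops), and the ``ReadPair``
/ ``Contig`` / ``CoveragePlan`` containers used throughout the pipeline.

Coordinates are 0-based half-open internally; user-facing reports are
1-based inclusive.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import ALPHABET

FASTA_WIDTH = 70

DEFAULT_INSERT_MEAN = 500.0
DEFAULT_INSERT_SD = 50.0


@dataclass
class ReadPair:
    """One paired-end read: mate 2 is sequenced from the opposite strand of
    the same fragment, so on the reference the mates face each other
    (forward/reverse) at roughly the expected insert size apart."""

    id: str
    bases1: str
    bases2: str
    quals1: Sequence[int]
    quals2: Sequence[int]
    insert_mean: float = DEFAULT_INSERT_MEAN
    insert_sd: float = DEFAULT_INSERT_SD

    def __post_init__(self) -> None:
        if len(self.bases1) != len(self.quals1) or len(self.bases2) != len(self.quals2):
            raise ValueError(f"read {self.id}: bases/quals length mismatch")
        for q in (*self.quals1, *self.quals2):
            if not 0 <= q <= 60:
                raise ValueError(f"read {self.id}: Phred score {q} outside [0, 60]")
        for b in (self.bases1, self.bases2):
            if set(b) - ALPHABET:
                raise ValueError(f"read {self.id}: non-ACGTN base")


@dataclass
class Contig:
    """An assembled sequence, possibly circular, possibly containing N gaps."""

    id: str
    seq: str
    circular: bool = False
    depth: float | None = None  # mean mapped (or k-mer) depth, once known
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"contig {self.id}: empty sequence")
        if self.circular and (self.seq.startswith("N") or self.seq.endswith("N")):
            raise ValueError(f"contig {self.id}: circular contig with terminal N run")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class CoveragePlan:
    """Subsampling plan: how many read bases to draw so that the plastid
    fraction of the skim yields the target fold-coverage of the plastome."""

    genome_size: int
    cp_size_estimate: int
    cp_fraction: float
    target_cp_coverage: float = 150.0  # within the favourable 100-250x window
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cp_fraction <= 1:
            raise ValueError("cp_fraction must be in (0, 1]")
        if self.target_cp_coverage <= 0:
            raise ValueError("target_cp_coverage must be positive")

    @property
    def target_read_bases(self) -> float:
        return self.target_cp_coverage * self.cp_size_estimate / self.cp_fraction


# ---------------------------------------------------------------------------
# FASTQ loading with quality trimming
# ---------------------------------------------------------------------------


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def trim_read(bases: str, quals: Sequence[int], qmin: int) -> tuple[str, list[int]] | None:
    """Apply the quality rule to one read.

    Trailing bases with Phred <= qmin are trimmed from both ends; the read
    is then dropped (None) when its mean Phred is <= qmin or nothing is
    left.  Idempotent by construction.
    """
    quals = list(quals)
    lo, hi = 0, len(quals)
    while hi > lo and quals[hi - 1] <= qmin:
        hi -= 1
    while lo < hi and quals[lo] <= qmin:
        lo += 1
    if hi <= lo:
        return None
    kept_q = quals[lo:hi]
    if sum(kept_q) / len(kept_q) <= qmin:
        return None
    return bases[lo:hi], kept_q


def load_reads(fastq1, fastq2, qmin: int = 20) -> Iterator[ReadPair]:
    """Stream quality-trimmed pairs from two synchronized FASTQ files.

    A pair survives only when both mates survive :func:`trim_read`.  Input
    order is preserved.  Desynchronized files (mismatched ids) raise with
    the first offending record named.
    """
    with _open_text(fastq1) as h1, _open_text(fastq2) as h2:
        it1 = SeqIO.parse(h1, "fastq")
        it2 = SeqIO.parse(h2, "fastq")
        for rec1 in it1:
            rec2 = next(it2, None)
            if rec2 is None:
                raise ValueError(f"pair files desynchronized: {rec1.id} has no mate")
            if _pair_stem(rec1.id) != _pair_stem(rec2.id):
                raise ValueError(
                    f"pair files desynchronized at {rec1.id} / {rec2.id}"
                )
            t1 = trim_read(str(rec1.seq).upper(), rec1.letter_annotations["phred_quality"], qmin)
            if t1 is None:
                continue
            t2 = trim_read(str(rec2.seq).upper(), rec2.letter_annotations["phred_quality"], qmin)
            if t2 is None:
                continue
            yield ReadPair(_pair_stem(rec1.id), t1[0], t2[0], t1[1], t2[1])
        extra = next(it2, None)
        if extra is not None:
            raise ValueError(f"pair files desynchronized: {extra.id} has no mate")


def _pair_stem(read_id: str) -> str:
    for suffix in ("/1", "/2"):
        if read_id.endswith(suffix):
            return read_id[: -len(suffix)]
    return read_id


def write_pairs(pairs: Iterable[ReadPair], fastq1, fastq2) -> int:
    """Write pairs as two synchronized FASTQ files; returns the pair count."""
    n = 0
    with open(fastq1, "w") as h1, open(fastq2, "w") as h2:
        for p in pairs:
            for handle, bases, quals, mate in (
                (h1, p.bases1, p.quals1, 1),
                (h2, p.bases2, p.quals2, 2),
            ):
                qstr = "".join(chr(q + 33) for q in quals)
                handle.write(f"@{p.id}/{mate}\n{bases}\n+\n{qstr}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """FASTA -> {id: uppercased sequence}.  Lowercase input is uppercased
    (a warning records the canonicalization); duplicate ids are an error."""
    records: dict[str, str] = {}
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate FASTA id: {rec.id}")
            seq = str(rec.seq)
            if seq != seq.upper():
                warnings.warn(f"{rec.id}: lowercase bases uppercased", stacklevel=2)
                seq = seq.upper()
            records[rec.id] = seq
    if not records:
        warnings.warn(f"{path}: empty FASTA", stacklevel=2)
    return records


def write_fasta(records, path) -> None:
    """Write {id: seq} (or an iterable of Contig) wrapped at 70 columns."""
    if isinstance(records, dict):
        items = records.items()
    else:
        items = [(c.id, c.seq) for c in records]
    recs = []
    for rid, seq in items:
        if not seq:
            raise ValueError(f"refusing to write empty sequence {rid}")
        recs.append(SeqRecord(Seq(seq), id=rid, description=""))
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=FASTA_WIDTH)
        writer.write_file(recs)


def constant_quals(length: int, q: int = 40) -> list[int]:
    return [q] * length


def mean_quality(quals: Sequence[int]) -> float:
    return float(np.mean(quals))
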