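"""Small shared sequence helpers used across the pipeline."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def canonical_rotation(seq: str) -> str:
    """Lexicographically smallest rotation over both strands of a circular
    sequence.  Used to compare circular sequences for equality up to
    rotation and strand."""
    best = None
    for s in (seq, revcomp(seq)):
        doubled = s + s
        n = len(s)
        # Booth's algorithm would be O(n); the simple scan with early
        # pruning is fast enough for the <~250 kb sequences handled here.
        cand = min(doubled[i : i + n] for i in _rotation_candidates(s))
        if best is None or cand < best:
            best = cand
    return best


def _rotation_candidates(seq: str):
    """Indices of rotations starting with the minimal character --
    restricts the O(n^2) rotation scan to a handful of candidates."""
    m = min(seq)
    # cap candidate count for pathological inputs (homopolymers)
    idx = [i for i, c in enumerate(seq) if c == m]
    if len(idx) > 64:
        doubled = seq + seq
        n = len(seq)
        # refine by the 16-mer following each candidate
        idx.sort(key=lambda i: doubled[i : i + 16])
        best16 = doubled[idx[0] : idx[0] + 16]
        idx = [i for i in idx if doubled[i : i + 16] == best16][:64]
    return idx or [0]


def same_circular(a: str, b: str) -> bool:
    """True when two circular sequences are equal up to rotation/strand."""
    if len(a) != len(b):
        return False
    return canonical_rotation(a) == canonical_rotation(b)


def seq_to_array(seq: str) -> np.ndarray:
    """DNA string as a uint8 byte array (for vectorised comparisons)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """I.i.d. random DNA with the given GC content."""
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    bases = rng.choice(
        np.frombuffer(b"ACGT", dtype=np.uint8),
        size=length,
        p=[p_at, p_gc, p_gc, p_at],
    )
    return bases.tobytes().decode("ascii")


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Apply i.i.d. substitutions at the given per-base rate."""
    if rate <= 0:
        return seq
    arr = seq_to_array(seq).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    if hits.size == 0:
        return seq
    others = {
        ord("A"): b"CGT",
        ord("C"): b"AGT",
        ord("G"): b"ACT",
        ord("T"): b"ACG",
    }
    picks = rng.integers(0, 3, size=hits.size)
    for i, pos in enumerate(hits):
        alt = others.get(int(arr[pos]))
        if alt is None:  # leave N untouched
            continue
        arr[pos] = alt[picks[i]]
    return arr.tobytes().decode("ascii")
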