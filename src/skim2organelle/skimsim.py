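"""Synthetic genome-skim generator.

Builds a mock plant genome with the features that make low-coverage
plastome/rDNA assembly hard in real data -- a circular quadripartite
plastome in large copy-number excess, NMPT tracts (diverged plastid copies
inserted into the nuclear and mitochondrial sequences), tandem 45S and 5S
rDNA arrays with a GC-rich IGS sub-repeat, a planted tandem repeat and
homopolymer tract inside the plastome plus nuclear homopolymer decoys --
and simulates paired-end reads from it.  It also constructs targeted
mis-assembly fixtures for the four error classes the finishing stage must
detect and repair.

Everything is a pure function of (spec, seed): no downloads, byte-stable.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import seqio
from ._util import mutate, random_dna, revcomp, seq_to_array

FALSE_GAP = "FALSE_GAP"
FALSE_SNP = "FALSE_SNP"
TR_COLLAPSE = "TR_COLLAPSE"
MONOPOLYMER = "MONOPOLYMER"
ISSUE_KINDS = (FALSE_GAP, FALSE_SNP, TR_COLLAPSE, MONOPOLYMER)


def load_rdna_models() -> dict[str, str]:
    """Packaged rDNA gene models (synthetic stand-in consensus sequences)
    used both to build mock rDNA units and to detect cistrons in contigs."""
    ref = importlib.resources.files("skim2organelle") / "data" / "synthetic_rdna_models.fasta"
    with importlib.resources.as_file(ref) as path:
        return seqio.read_fasta(path)


@dataclass
class MockGenomeSpec:
    """Parameters of the mock genome.

    Defaults emulate the study conditions: a plastome present at large
    excess over single-copy nuclear depth, a 4-copy 18-bp tandem repeat and
    a (T)17 homopolymer planted in the plastome, nuclear (T)n decoys at
    7-15 nt, ~3% diverged NMPT insertions, and homogeneous 45S (100 copies)
    and 5S (300 copies) tandem arrays.
    """

    nuclear_size: int = 200_000
    cp_size: int = 30_000
    lsc_fraction: float = 0.60
    ir_fraction: float = 0.13
    ssc_fraction: float = 0.14
    mt_fragment_count: int = 2
    mt_fragment_size: int = 15_000
    nmpt_count: int = 6
    nmpt_divergence: float = 0.03
    nmpt_length_range: tuple[int, int] = (300, 3_000)
    rdna_45s_unit: int = 4_000
    rdna_45s_copies: int = 100
    rdna_5s_unit: int = 320
    rdna_5s_copies: int = 300
    igs_subrepeat_len: int = 60
    igs_subrepeat_copies: int = 3
    tr_profile: tuple = ((18, 4, "cp"),)
    monopolymer_base: str = "T"
    monopolymer_length: int = 17
    decoy_lengths: tuple = (7, 8, 9, 10, 11, 12, 15)
    seed: int = 0

    def __post_init__(self) -> None:
        frac = self.lsc_fraction + 2 * self.ir_fraction + self.ssc_fraction
        if abs(frac - 1.0) > 1e-9:
            raise ValueError("quadripartite proportions must sum to 1")
        for name in ("nuclear_size", "cp_size", "mt_fragment_size",
                     "rdna_45s_unit", "rdna_5s_unit"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rdna_45s_unit < 3_300:
            raise ValueError("45S unit must exceed the cistron model length")


@dataclass
class Feature:
    """One planted (or incidental) feature in the truth table."""

    kind: str
    component: str
    start: int  # 0-based half-open on the component
    end: int
    attrs: dict = field(default_factory=dict)


@dataclass
class MockGenome:
    spec: MockGenomeSpec
    components: dict  # name -> (sequence, circular flag)
    truth: list  # list[Feature]

    @property
    def cp(self) -> str:
        return self.components["cp"][0]

    @property
    def nuclear(self) -> str:
        return self.components["nuclear"][0]

    @property
    def genome_size(self) -> int:
        return sum(len(s) for s, _ in self.components.values())

    def features(self, kind: str, component: str | None = None) -> list:
        return [
            f for f in self.truth
            if f.kind == kind and (component is None or f.component == component)
        ]

    def truth_table(self) -> list[dict]:
        rows = []
        for f in self.truth:
            rows.append({
                "kind": f.kind, "component": f.component,
                "start": f.start, "end": f.end, **f.attrs,
            })
        return rows


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------


def _scan_runs(seq: str, min_len: int = 9) -> list[tuple[str, int, int]]:
    """Maximal homopolymer runs of length >= min_len (linear scan)."""
    runs = []
    i, n = 0, len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len and seq[i] != "N":
            runs.append((seq[i], i, j - i))
        i = j
    return runs


def _plant(host: str, insert: str, pos: int) -> str:
    return host[:pos] + insert + host[pos:]


def build_mock_genome(spec: MockGenomeSpec) -> MockGenome:
    """Deterministically build the mock genome from its spec."""
    rng = np.random.default_rng(spec.seed)
    truth: list[Feature] = []

    # --- plastome: LSC + IRa + SSC + IRb(=rc IRa), then canonical isomer
    ir_len = int(round(spec.cp_size * spec.ir_fraction))
    ssc_len = int(round(spec.cp_size * spec.ssc_fraction))
    lsc_len = spec.cp_size - 2 * ir_len - ssc_len
    lsc = random_dna(rng, lsc_len)
    ira = random_dna(rng, ir_len)
    ssc = random_dna(rng, ssc_len)

    # plant TR array and homopolymer inside the LSC, well separated
    tr_unit_len, tr_copies, tr_loc = spec.tr_profile[0] if spec.tr_profile else (0, 0, None)
    tr_unit = ""
    if tr_loc is not None:
        while True:
            tr_unit = random_dna(rng, tr_unit_len)
            # reject units that are themselves periodic or homopolymeric
            if len(set(tr_unit)) >= 3 and tr_unit[: tr_unit_len // 2] != tr_unit[tr_unit_len - tr_unit_len // 2:]:
                break
        tr_array = tr_unit * tr_copies
        tr_pos = int(rng.integers(lsc_len // 8, lsc_len // 3))
        lsc = _plant(lsc, tr_array, tr_pos)

    mono = spec.monopolymer_base * spec.monopolymer_length
    # pad the tract so neighbouring random bases cannot extend it
    pad = {"A": "C", "C": "A", "G": "T", "T": "G"}[spec.monopolymer_base]
    mono_ctx = pad + mono + pad
    mono_pos = int(rng.integers(2 * lsc_len // 3, lsc_len - 200))
    lsc = _plant(lsc, mono_ctx, mono_pos)

    cp_raw = lsc + ira + ssc + revcomp(ira)
    # deferred import: plastid_finish also imports nothing from here
    from .plastid_finish import canonical_plastome

    cp, regions = canonical_plastome(cp_raw)
    if regions is None:  # degenerate spec (IR < 1 kb): keep raw sequence
        cp = cp_raw
    else:
        for name, (s, e) in regions.items():
            truth.append(Feature("region", "cp", s, e, {"name": name}))

    # locate the planted features on the canonical plastome
    if tr_loc is not None:
        tr_array = tr_unit * tr_copies
        pos = cp.find(tr_array)
        unit = tr_unit
        if pos < 0:
            pos = cp.find(revcomp(tr_array))
            unit = revcomp(tr_unit)
        if pos < 0:
            raise AssertionError("planted TR array lost during canonicalization")
        truth.append(Feature("tr_array", "cp", pos, pos + len(tr_array),
                             {"unit": unit, "unit_len": tr_unit_len,
                              "copies": tr_copies, "planted": True}))

    planted_mono = None
    mono_bases = {spec.monopolymer_base, revcomp(spec.monopolymer_base)}
    for base, start, length in _scan_runs(cp, min_len=9):
        planted = length == spec.monopolymer_length and base in mono_bases
        feat = Feature("monopolymer", "cp", start, start + length,
                       {"base": base, "length": length, "planted": planted})
        truth.append(feat)
        if planted and planted_mono is None:
            planted_mono = feat

    # --- nuclear background with NMPT insertions and homopolymer decoys
    nuclear = random_dna(rng, spec.nuclear_size)
    lo, hi = spec.nmpt_length_range
    nmpt_tracts = []
    for _ in range(spec.nmpt_count):
        length = int(rng.integers(lo, hi + 1))
        src = int(rng.integers(0, len(cp) - length))
        tract = mutate(rng, cp[src:src + length], spec.nmpt_divergence)
        nmpt_tracts.append((tract, src, length))

    # homopolymer decoys: diverged copies of the planted tract context with
    # other run lengths, mirroring NMPT-borne homopolymers
    decoys = []
    if planted_mono is not None:
        ctx_l = cp[max(0, planted_mono.start - 120):planted_mono.start]
        ctx_r = cp[planted_mono.end:planted_mono.end + 120]
        for L in spec.decoy_lengths:
            dec = (mutate(rng, ctx_l, 0.02)
                   + spec.monopolymer_base * L
                   + mutate(rng, ctx_r, 0.02))
            decoys.append((dec, L))

    inserts = [("nmpt", t) for t in nmpt_tracts] + [("decoy", d) for d in decoys]
    positions = sorted(
        int(p) for p in rng.choice(spec.nuclear_size - 1, size=len(inserts),
                                   replace=False)
    )
    # splice ascending, tracking the cumulative shift from earlier inserts
    parts = []
    prev = 0
    offset = 0
    for pos, (tag, payload) in zip(positions, inserts):
        parts.append(nuclear[prev:pos])
        if tag == "nmpt":
            tract, src, length = payload
            parts.append(tract)
            truth.append(Feature("nmpt", "nuclear", pos + offset,
                                 pos + offset + length,
                                 {"cp_start": src, "cp_end": src + length,
                                  "divergence": spec.nmpt_divergence}))
            offset += length
        else:
            dec, L = payload
            parts.append(dec)
            truth.append(Feature("mono_decoy", "nuclear", pos + offset,
                                 pos + offset + len(dec), {"length": L}))
            offset += len(dec)
        prev = pos
    parts.append(nuclear[prev:])
    nuclear = "".join(parts)

    # --- mitochondrial fragments sharing near-identical plastid segments
    components = {"nuclear": (nuclear, False), "cp": (cp, True)}
    for i in range(spec.mt_fragment_count):
        frag = random_dna(rng, spec.mt_fragment_size)
        length = int(rng.integers(lo, hi + 1))
        src = int(rng.integers(0, len(cp) - length))
        tract = mutate(rng, cp[src:src + length], spec.nmpt_divergence / 3)
        pos = int(rng.integers(0, len(frag)))
        frag = _plant(frag, tract, pos)
        name = f"mt_{i}"
        truth.append(Feature("nmpt", name, pos, pos + length,
                             {"cp_start": src, "cp_end": src + length,
                              "divergence": spec.nmpt_divergence / 3}))
        components[name] = (frag, False)

    # --- rDNA arrays from the packaged gene models
    models = load_rdna_models()
    m18 = models["18S_synthetic_consensus"]
    m58 = models["5.8S_synthetic_consensus"]
    m26 = models["26S_synthetic_consensus"]
    m5s = models["5S_synthetic_consensus"]

    its1 = random_dna(rng, 150)
    its2 = random_dna(rng, 190)
    cistron = m18 + its1 + m58 + its2 + m26
    igs_len = spec.rdna_45s_unit - len(cistron)
    if igs_len < 2 * spec.igs_subrepeat_len * spec.igs_subrepeat_copies // 2 + 100:
        raise ValueError("45S unit too short for the IGS sub-repeat")
    igs = random_dna(rng, igs_len, gc=0.45)
    sub = random_dna(rng, spec.igs_subrepeat_len, gc=0.78)
    # copies carry diagnostic substitutions every ~20 bp (≈5% divergence):
    # close enough to "highly homogeneous", dense enough that every k-mer
    # window distinguishes the copies (no window-identical stretches that
    # would make read-guided traversal of the sub-repeat ambiguous)
    sub_arr = sub
    swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
    for j in range(1, spec.igs_subrepeat_copies):
        copy = list(sub)
        for off in range(4 + j, spec.igs_subrepeat_len, 20):
            copy[off] = swap[copy[off]]
        sub_arr += "".join(copy)
    # plant the sub-repeat in the distal 40% of the IGS: outside the part an
    # initial 45S contig typically covers, so gap closing must cross it
    sub_pos = int(igs_len * 0.70)
    igs = igs[:sub_pos] + sub_arr + igs[sub_pos + len(sub_arr):]
    unit45 = cistron + igs
    if len(unit45) != spec.rdna_45s_unit:
        raise AssertionError("45S unit length bookkeeping error")

    off = 0
    for name, seg in (("18S", m18), ("ITS1", its1), ("5.8S", m58),
                      ("ITS2", its2), ("26S", m26), ("IGS", igs)):
        truth.append(Feature("rdna_subregion", "rdna_45s", off, off + len(seg),
                             {"name": name}))
        off += len(seg)
    truth.append(Feature("rdna_unit", "rdna_45s", 0, len(unit45),
                         {"unit_len": len(unit45), "copies": spec.rdna_45s_copies,
                          "cistron_len": len(cistron), "igs_len": igs_len,
                          "unit": unit45}))
    components["rdna_45s"] = (unit45 * spec.rdna_45s_copies, False)

    unit5 = m5s + random_dna(rng, spec.rdna_5s_unit - len(m5s))
    truth.append(Feature("rdna_unit", "rdna_5s", 0, len(unit5),
                         {"unit_len": len(unit5), "copies": spec.rdna_5s_copies,
                          "unit": unit5}))
    components["rdna_5s"] = (unit5 * spec.rdna_5s_copies, False)

    return MockGenome(spec, components, truth)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

_CONST_QUALS: dict[int, tuple] = {}


def _quals(length: int, q: int = 40) -> tuple:
    if length not in _CONST_QUALS:
        _CONST_QUALS[length] = tuple([q] * length)
    return _CONST_QUALS[length]


def simulate_reads(
    genome,
    per_component_coverage: dict,
    read_len: int = 100,
    insert_mean: float = 500.0,
    insert_sd: float = 50.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list:
    """Simulate paired-end reads.

    ``genome`` is a MockGenome or a {name: (seq, circular)} mapping.  Insert
    sizes are Gaussian truncated to [2*read_len, 2*insert_mean]; mate 2 is
    the reverse complement of the fragment's other end.  Circular components
    are sampled across the origin.  Substitution errors only.
    """
    components = genome.components if isinstance(genome, MockGenome) else genome
    rng = np.random.default_rng(seed)
    pairs: list[seqio.ReadPair] = []
    lo_ins, hi_ins = 2 * read_len, max(2 * read_len, int(2 * insert_mean))
    quals = _quals(read_len)

    for name in sorted(per_component_coverage):
        cov = per_component_coverage[name]
        if cov <= 0:
            continue
        seq, circular = components[name]
        L = len(seq)
        if read_len > L:
            raise ValueError(f"read length {read_len} exceeds component {name} ({L} bp)")
        n_pairs = int(round(cov * L / (2 * read_len)))
        if n_pairs == 0:
            continue
        inserts = np.clip(
            np.rint(rng.normal(insert_mean, insert_sd, size=n_pairs)).astype(int),
            lo_ins, min(hi_ins, L),
        )
        if circular:
            starts = rng.integers(0, L, size=n_pairs)
            doubled = seq + seq
        else:
            starts = np.array([
                int(rng.integers(0, max(1, L - ins + 1))) for ins in inserts
            ])
            doubled = seq
        flips = rng.random(n_pairs) < 0.5
        err_positions = None
        for i in range(n_pairs):
            s, ins = int(starts[i]), int(inserts[i])
            frag = doubled[s:s + ins]
            if flips[i]:
                frag = revcomp(frag)
            b1 = frag[:read_len]
            b2 = revcomp(frag[-read_len:])
            if error_rate > 0:
                b1 = mutate(rng, b1, error_rate)
                b2 = mutate(rng, b2, error_rate)
            strand = "-" if flips[i] else "+"
            pairs.append(seqio.ReadPair(
                f"sim|{name}|{s}|{strand}|{i}", b1, b2, quals, quals,
                insert_mean=insert_mean, insert_sd=insert_sd,
            ))
    return pairs


# ---------------------------------------------------------------------------
# mis-assembly fixtures
# ---------------------------------------------------------------------------


def _clear_interval(genome: MockGenome, rng, flank: int = 3_100,
                    separation: int = 1_200) -> int:
    """A plastome position with full `flank` context inside the sequence and
    at least `separation` away from the planted TR array and homopolymers --
    a quiet spot to plant a synthetic defect.  Correctly assembled features
    elsewhere in the slice are harmless; only evidence overlap matters."""
    cp = genome.cp
    blocked = [
        (f.start, f.end) for f in genome.truth
        if f.component == "cp" and f.kind in ("tr_array", "monopolymer")
    ]
    for _ in range(500):
        pos = int(rng.integers(flank, len(cp) - flank))
        if all(pos + separation < s or pos - separation > e for s, e in blocked):
            return pos
    raise RuntimeError("could not find a clear plastome interval")


def make_misassembly_fixture(kind: str, genome: MockGenome, seed: int = 0,
                             coverage: float = 100.0, read_len: int = 100):
    """Build (draft, truth, reads) exhibiting exactly one planted defect.

    FALSE_GAP: an N run whose flanks carry a duplicated segment.
    FALSE_SNP: draft carries minor-source alleles at two linked positions;
        reads mix the true (high-copy) source with the diverged minor source.
    TR_COLLAPSE: the planted 4-copy 18-bp array collapsed to 2 copies.
    MONOPOLYMER: the planted (T)17 tract replaced by a wrong candidate (T)8.
    """
    if kind not in ISSUE_KINDS:
        raise ValueError(f"unsupported fixture kind: {kind}")
    rng = np.random.default_rng(seed + 1_000_003)
    cp = genome.cp
    flank = 3_000

    if kind == TR_COLLAPSE:
        feat = next(f for f in genome.features("tr_array", "cp") if f.attrs["planted"])
        s, e = feat.start, feat.end
        unit = feat.attrs["unit"]
        truth_seq = cp[max(0, s - flank):min(len(cp), e + flank)]
        off = s - max(0, s - flank)
        draft_seq = truth_seq[:off] + unit * 2 + truth_seq[off + len(unit) * feat.attrs["copies"]:]
        meta = {"unit_len": feat.attrs["unit_len"], "truth_copies": feat.attrs["copies"],
                "draft_copies": 2, "draft_interval": (off, off + 2 * len(unit))}
    elif kind == MONOPOLYMER:
        feat = next(f for f in genome.features("monopolymer", "cp") if f.attrs["planted"])
        s, e = feat.start, feat.end
        truth_seq = cp[max(0, s - flank):min(len(cp), e + flank)]
        off = s - max(0, s - flank)
        base = feat.attrs["base"]
        wrong = 8
        draft_seq = truth_seq[:off] + base * wrong + truth_seq[off + feat.attrs["length"]:]
        meta = {"base": base, "truth_length": feat.attrs["length"], "draft_length": wrong,
                "draft_interval": (off, off + wrong)}
    elif kind == FALSE_GAP:
        pos = _clear_interval(genome, rng)
        truth_seq = cp[pos - flank:pos + flank]
        c, dup, n_len = flank, 30, 50
        draft_seq = truth_seq[:c] + "N" * n_len + truth_seq[c - dup:]
        meta = {"dup_len": dup, "n_len": n_len, "draft_interval": (c, c + n_len)}
    else:  # FALSE_SNP
        pos = _clear_interval(genome, rng)
        truth_seq = cp[pos - flank:pos + flank]
        c = flank
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}
        minor = list(truth_seq)
        minor[c] = alt[minor[c]]
        minor[c + 4] = alt[minor[c + 4]]
        minor_seq = "".join(minor)
        draft_seq = minor_seq  # draft took the minor-source alleles
        meta = {"positions": (c, c + 4),
                "truth_alleles": (truth_seq[c], truth_seq[c + 4]),
                "minor_alleles": (minor_seq[c], minor_seq[c + 4])}

    comp = {"truth": (truth_seq, False)}
    cov = {"truth": coverage}
    if kind == FALSE_SNP:
        comp["truth"] = (truth_seq, False)
        comp["minor"] = (minor_seq, False)
        cov = {"truth": max(coverage, 200.0), "minor": 4.0}
    reads = simulate_reads(comp, cov, read_len=read_len, seed=seed)

    draft = seqio.Contig(f"draft_{kind.lower()}", draft_seq,
                         provenance=f"fixture:{kind} seed={seed} {meta}")
    truth = seqio.Contig(f"truth_{kind.lower()}", truth_seq,
                         provenance=f"fixture:{kind} truth")
    return draft, truth, reads


# ---------------------------------------------------------------------------
# on-disk output for the CLI
# ---------------------------------------------------------------------------


def write_simulation(genome: MockGenome, pairs, outdir) -> dict:
    """Write genome FASTA, truth TSV and paired FASTQ; returns file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "genome.fasta"
    seqio.write_fasta({n: s for n, (s, _) in genome.components.items()}, fasta)
    truth_tsv = outdir / "truth.tsv"
    rows = genome.truth_table()
    keys = ["kind", "component", "start", "end"]
    extra = sorted({k for r in rows for k in r} - set(keys) - {"unit"})
    with open(truth_tsv, "w") as fh:
        fh.write("\t".join(keys + extra) + "\n")
        for r in rows:
            fh.write("\t".join(str(r.get(k, "")) for k in keys + extra) + "\n")
    fq1, fq2 = outdir / "reads_1.fastq", outdir / "reads_2.fastq"
    n = seqio.write_pairs(pairs, fq1, fq2)
    return {"genome": fasta, "truth": truth_tsv, "reads1": fq1, "reads2": fq2,
            "n_pairs": n}
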