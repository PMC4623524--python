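"""End-to-end pipeline orchestration: load or simulate reads, estimate the
plastid fraction, subsample into the favourable coverage window, assemble,
classify contigs, finish the plastome, complete the rDNA units and estimate
copy numbers.  A machine-readable manifest records every stage's parameters,
seeds and input digests so a run can be reproduced bit for bit."""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np

from . import depthmap, kassembler, plastid_finish, rdna, skimsim, triage
from . import seqio
from .seqio import Contig, CoveragePlan


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


DEFAULT_CONFIG = {
    "seed": 0,
    "qmin": 20,
    "k": 31,
    "min_count": 1,
    "target_cp_coverage": 150.0,
    "min_overlap": 15,
    "read_len": 100,
    "insert_mean": 500.0,
    "insert_sd": 50.0,
    "error_rate": 0.0,
}


def run_pipeline(config: dict, outdir, seed: int | None = None) -> dict:
    """Execute the full workflow; returns the manifest (also written to
    manifest.json in `outdir`).

    The config either points at FASTQ inputs (`reads1`/`reads2` plus
    `bait`/`panel` FASTAs) or carries a `simulate` section (MockGenomeSpec
    fields plus per-component coverages), in which case the mock genome
    itself provides bait and panel.  Completed stage outputs survive a later
    stage's failure.
    """
    cfg = {**DEFAULT_CONFIG, **config}
    if seed is not None:
        cfg["seed"] = seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _jsonable(cfg), "stages": [], "outputs": {}}
    t_start = time.time()

    def stage(name, fn):
        entry = {"stage": name, "status": "running", "t0": round(time.time() - t_start, 2)}
        manifest["stages"].append(entry)
        try:
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                result = fn()
            entry["warnings"] = [str(w.message) for w in wlist]
            entry["status"] = "ok"
            entry["seconds"] = round(time.time() - t_start - entry["t0"], 2)
            return result
        except Exception as exc:
            entry["status"] = "failed"
            entry["cause"] = repr(exc)
            _write_manifest(manifest, outdir)
            raise

    # ---- stage: inputs (load or simulate) --------------------------------
    genome = None
    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        coverage = sim.pop("coverage", {"cp": 100.0})
        spec_kwargs = {k: v for k, v in sim.items()
                       if k in skimsim.MockGenomeSpec.__dataclass_fields__}
        spec = skimsim.MockGenomeSpec(**{**spec_kwargs, "seed": cfg["seed"]})

        def _simulate():
            g = skimsim.build_mock_genome(spec)
            pairs = skimsim.simulate_reads(
                g, coverage, read_len=cfg["read_len"],
                insert_mean=cfg["insert_mean"], insert_sd=cfg["insert_sd"],
                error_rate=cfg["error_rate"], seed=cfg["seed"] + 1)
            return g, pairs

        genome, reads = stage("simulate", _simulate)
        bait = {"cp": genome.cp}
        panel = {
            "cp": genome.cp,
            "mt": [s for n, (s, _) in genome.components.items() if n.startswith("mt_")],
            "nR": [genome.components["rdna_45s"][0],
                   genome.components["rdna_5s"][0]],
        }
        genome_size = genome.genome_size
        manifest["outputs"]["simulated_components"] = {
            n: len(s) for n, (s, _) in genome.components.items()}
    else:
        for key in ("reads1", "reads2", "bait"):
            if key not in cfg or not Path(cfg[key]).exists():
                raise FileNotFoundError(f"missing input: {key}")
        reads = stage("load_reads", lambda: list(
            seqio.load_reads(cfg["reads1"], cfg["reads2"], cfg["qmin"])))
        bait = seqio.read_fasta(cfg["bait"])
        panel = {}
        for label, path in (cfg.get("panel") or {}).items():
            panel[label] = list(seqio.read_fasta(path).values())
        panel.setdefault("cp", list(bait.values()))
        genome_size = int(cfg["genome_size"])
        manifest["outputs"]["input_digests"] = {
            k: _sha256(cfg[k]) for k in ("reads1", "reads2", "bait")}
    manifest["outputs"]["n_pairs_input"] = len(reads)

    # ---- stage: cp fraction + subsample ----------------------------------
    def _fraction():
        return triage.estimate_cp_fraction(
            reads, bait, seed=cfg["seed"] + 2)

    fraction, ci = stage("estimate_cp_fraction", _fraction)
    manifest["outputs"]["cp_fraction"] = {"estimate": fraction, "ci95": list(ci)}

    cp_size_est = int(cfg.get("cp_size_estimate")
                      or sum(len(s) for s in ([bait] if isinstance(bait, str)
                                              else bait.values())))

    def _subsample():
        if fraction <= 0:
            raise ValueError("no plastid-derived reads detected: cannot plan "
                             "coverage subsampling")
        plan = CoveragePlan(genome_size, cp_size_est, fraction,
                            cfg["target_cp_coverage"], seed=cfg["seed"] + 3)
        return triage.subsample(reads, plan)

    sub = stage("subsample", _subsample)
    sub_entry = manifest["stages"][-1]
    if any("NMPT" in w for w in sub_entry.get("warnings", ())):
        manifest["outputs"]["nmpt_interference_warning"] = True
    manifest["outputs"]["n_pairs_subsampled"] = len(sub)

    # ---- stage: assembly --------------------------------------------------
    # k-mer count floor scaled to the expected plastid depth: low-copy
    # nuclear k-mers (including NMPT copies that would branch the plastid
    # graph) fall below it, while plastid/rDNA k-mers sit far above
    sub_bases = sum(len(p.bases1) + len(p.bases2) for p in sub)
    cov_cp_est = fraction * sub_bases / cp_size_est
    min_count = max(int(cfg["min_count"]), min(20, int(0.08 * cov_cp_est)))
    manifest["outputs"]["assembly_min_count"] = min_count
    manifest["outputs"]["estimated_cp_coverage"] = round(cov_cp_est, 1)

    def _assemble():
        graph = kassembler.build_graph(sub, k=cfg["k"], min_count=min_count)
        return kassembler.assemble(graph)

    contigs = stage("assemble", _assemble)
    manifest["outputs"]["n_contigs"] = len(contigs)
    seqio.write_fasta(contigs, outdir / "contigs.fasta")

    # ---- stage: classification --------------------------------------------
    report = stage("classify", lambda: triage.classify_contigs(contigs, panel))
    triage.classification_to_tsv(report, outdir / "classification.tsv")
    manifest["outputs"]["classification"] = {
        lab: sum(1 for r in report if r.label == lab)
        for lab in ("cp", "mt", "nR", "other")}

    # ---- stage: plastome finishing ----------------------------------------
    def _finish():
        cp_contigs = [r.contig for r in report if r.label == "cp"]
        if not cp_contigs:
            raise ValueError("no cp-labeled contigs")
        # high-copy filter: drop contigs far below the cp depth baseline
        # (NMPT-bearing low-copy contigs can share enough k-mers to classify
        # as cp but would poison the overlap layout)
        with_depth = [c for c in cp_contigs if c.depth]
        if with_depth:
            # length-weighted median depth: the long plastid backbone
            # contigs define the baseline, not the many short fragments
            order = sorted(with_depth, key=lambda c: c.depth)
            cum = np.cumsum([len(c.seq) for c in order])
            baseline = order[int(np.searchsorted(cum, cum[-1] / 2))].depth
            cp_contigs = [c for c in cp_contigs
                          if c.depth is None or c.depth >= 0.25 * baseline]
        draft = plastid_finish.join_and_circularize(
            cp_contigs, min_overlap=cfg["min_overlap"])
        return plastid_finish.finish(draft, sub)

    assembly = stage("finish_cp", _finish)
    seqio.write_fasta({"plastome": assembly.sequence}, outdir / "plastome.fasta")
    plastid_finish.finishing_log_to_tsv(assembly, outdir / "finishing_log.tsv")
    plastid_finish.regions_to_bed(assembly, outdir / "plastome_regions.bed")
    manifest["outputs"]["plastome"] = {
        "length": len(assembly.sequence),
        "regions": assembly.regions,
        "fixes_applied": sum(1 for e in assembly.finishing_log
                              if e.get("changed")),
        "sites_confirmed": sum(1 for e in assembly.finishing_log
                               if not e.get("changed")),
        "residual_issues": len(assembly.residual_issues),
    }

    # ---- stage: rDNA ------------------------------------------------------
    def _rdna():
        models = rdna.load_rdna_models()
        nr = [r.contig for r in report if r.label == "nR"]
        units = []
        c45 = None
        for c in nr:
            if rdna._locate(models["18S_synthetic_consensus"], c.seq) is not None:
                c45 = c
                break
        if c45 is not None:
            local = _filter_reads_by_kmers(reads, c45.seq)
            units.append(rdna.complete_45s(c45, local, models=models))
        try:
            units.append(rdna.extract_5s(nr, models=models))
        except ValueError:
            pass
        for u in units:
            rdna.estimate_copy_number(u, reads, genome_size,
                                      seed=cfg["seed"] + 4)
        return units

    units = stage("rdna", _rdna)
    for u in units:
        seqio.write_fasta({f"rdna_{u.unit_class}": u.sequence},
                          outdir / f"rdna_{u.unit_class.lower()}.fasta")
        rdna.units_to_gff(u, outdir / f"rdna_{u.unit_class.lower()}.gff")
    if units:
        rdna.copy_number_report(units, outdir / "copy_numbers.tsv")
    manifest["outputs"]["rdna_units"] = {
        u.unit_class: {"length": len(u), "complete": u.complete,
                       "copy_number": u.copy_number_estimate}
        for u in units}

    manifest["elapsed_seconds"] = round(time.time() - t_start, 2)
    _write_manifest(manifest, outdir)
    return manifest


def _filter_reads_by_kmers(reads, seq: str, k: int = 21, step: int = 7):
    """Pairs with at least one mate sharing a k-mer with `seq` (either
    strand) -- cheap pre-filter before local gap closing."""
    from ._util import revcomp

    probes = {seq[i:i + k] for i in range(0, len(seq) - k + 1)}
    probes |= {revcomp(p) for p in probes}
    out = []
    for pair in reads:
        hit = False
        for b in (pair.bases1, pair.bases2):
            if any(b[i:i + k] in probes for i in range(0, len(b) - k + 1, step)):
                hit = True
                break
        if hit:
            out.append(pair)
    return out


def _write_manifest(manifest, outdir) -> None:
    with open(Path(outdir) / "manifest.json", "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2, default=str)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
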