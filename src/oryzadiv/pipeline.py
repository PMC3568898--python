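"""Stage orchestration: each stage runs one slice of the comparative
analysis over a run directory and records a machine-readable manifest
(parameters, input/output checksums, package version) so every number in a
final report traces back to a stage run."""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict
from datetime import datetime, timezone

import numpy as np

from . import __version__

STAGES = [
    "simulate", "qc", "consensus", "windows", "codon", "splice", "ssr", "enrich",
    "report",
]


class UnknownStageError(ValueError):
    pass


class MissingInputError(FileNotFoundError):
    pass


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out_dir: str, stage: str, params: dict, inputs: list, outputs: list):
    manifest = {
        "stage": stage,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "params": params,
        "inputs": {p: _sha256(p) for p in inputs},
        "outputs": {p: _sha256(p) for p in outputs},
    }
    path = os.path.join(out_dir, f"manifest_{stage}.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def _require(out_dir: str, name: str, producer: str) -> str:
    path = os.path.join(out_dir, name)
    if not os.path.exists(path):
        raise MissingInputError(
            f"missing input {name!r}; run the {producer!r} stage first"
        )
    return path


def _load_dataset(out_dir: str, seed: int):
    # Stages after `simulate` rebuild the dataset deterministically from the
    # recorded seed rather than re-parsing every emitted file; the emitted
    # files carry the same content (checksummed in the manifest).
    from .simulate import SimulationConfig, simulate_genomes

    cfg_path = _require(out_dir, "simulation_config.json", "simulate")
    with open(cfg_path) as fh:
        d = json.load(fh)
    from .simulate import SpliceMutation, SSREvent

    d["planted_splice_mutations"] = [
        SpliceMutation(**m) for m in d.get("planted_splice_mutations", [])
    ]
    d["planted_ssr_events"] = [SSREvent(**e) for e in d.get("planted_ssr_events", [])]
    for key in ("exons_per_gene", "exon_codons", "intron_length", "read_length",
                "fragment_length"):
        if key in d:
            d[key] = tuple(d[key])
    return simulate_genomes(SimulationConfig(**d))


def run_stage(name: str, cfg, out_dir: str, seed: int = 0) -> dict:
    """Run one pipeline stage; returns its manifest.

    ``cfg`` is a dict of stage parameters (may be empty).  Outputs and a
    manifest land in ``out_dir``.
    """
    if name not in STAGES:
        raise UnknownStageError(f"unknown stage {name!r}; stages: {', '.join(STAGES)}")
    os.makedirs(out_dir, exist_ok=True)
    fn = globals()[f"_stage_{name}"]
    return fn(dict(cfg or {}), out_dir, seed)


def _stage_simulate(cfg: dict, out_dir: str, seed: int) -> dict:
    from .simulate import (
        SimulationConfig, simulate_genomes, simulate_reads, write_dataset,
        write_fastq,
    )

    sim_cfg = SimulationConfig(seed=seed, **cfg)
    dataset = simulate_genomes(sim_cfg)
    paths = write_dataset(dataset, out_dir)
    reads, _ = simulate_reads(dataset)
    fastq = os.path.join(out_dir, "og_reads.fastq")
    write_fastq(reads, fastq)
    cfg_path = os.path.join(out_dir, "simulation_config.json")
    with open(cfg_path, "w") as fh:
        json.dump(asdict(sim_cfg), fh, indent=1, default=str)
    outputs = list(paths.values()) + [fastq, cfg_path]
    return _write_manifest(out_dir, "simulate", asdict(sim_cfg), [], outputs)


def _stage_qc(cfg: dict, out_dir: str, seed: int) -> dict:
    from .reads import QCConfig, filter_reads, make_organelle_screen, read_fastq, trim_3prime

    fastq = _require(out_dir, "og_reads.fastq", "simulate")
    dataset = _load_dataset(out_dir, seed)
    qc_cfg = QCConfig(**cfg)
    reads = [trim_3prime(r, qc_cfg) for r in read_fastq(fastq)]
    kept, rejected = filter_reads(
        reads, qc_cfg, make_organelle_screen(dataset.organelle)
    )
    out = os.path.join(out_dir, "qc_summary.json")
    reasons: dict[str, int] = {}
    for r in rejected:
        reasons[r.reason] = reasons.get(r.reason, 0) + 1
    with open(out, "w") as fh:
        json.dump({"kept": len(kept), "rejected": reasons}, fh, indent=1)
    kept_path = os.path.join(out_dir, "qc_kept_reads.txt")
    with open(kept_path, "w") as fh:
        fh.writelines(r.id + "\n" for r in kept)
    return _write_manifest(out_dir, "qc", asdict(qc_cfg), [fastq], [out, kept_path])


def _stage_consensus(cfg: dict, out_dir: str, seed: int) -> dict:
    from .reads import (
        ConsensusConfig, KmerAligner, MappedRead, QCConfig, build_consensus,
        contig_stats, filter_reads, make_organelle_screen, read_fastq,
        select_best_hit, trim_3prime,
    )
    from .align import annotation_classes

    fastq = _require(out_dir, "og_reads.fastq", "simulate")
    dataset = _load_dataset(out_dir, seed)
    qc_cfg = QCConfig()
    con_cfg = ConsensusConfig(**cfg)
    reads = [trim_3prime(r, qc_cfg) for r in read_fastq(fastq)]
    kept, _ = filter_reads(reads, qc_cfg, make_organelle_screen(dataset.organelle))
    aligner = KmerAligner(dataset.genome("osj"))
    mapped = []
    for r in kept:
        best = select_best_hit(aligner.map_read(r, qc_cfg), qc_cfg)
        if best is not None:
            mapped.append(MappedRead(read=r, start=best.start, strand=best.strand))
    consensus = build_consensus(mapped, con_cfg)
    ann = annotation_classes(dataset.genes, dataset.aln.genome_length("osj"))
    stats = contig_stats(
        consensus.contigs, dataset.aln.genome_length("osj"), ann
    )
    stats["mapped_reads"] = len(mapped)
    out = os.path.join(out_dir, "contig_stats.json")
    with open(out, "w") as fh:
        json.dump(stats, fh, indent=1)
    bed = os.path.join(out_dir, "contigs.bed")
    with open(bed, "w") as fh:
        for s, e in consensus.contigs:
            fh.write(f"chr1\t{s}\t{e}\n")
    return _write_manifest(out_dir, "consensus", asdict(con_cfg), [fastq], [out, bed])


def _stage_windows(cfg: dict, out_dir: str, seed: int) -> dict:
    from .align import annotation_classes, build_columns
    from .windows import WindowConfig, tstv_ratio, window_counts, write_window_tsv

    dataset = _load_dataset(out_dir, seed)
    w_cfg = WindowConfig(**cfg)
    ann = annotation_classes(dataset.genes, dataset.aln.genome_length("osj"))
    columns = build_columns(dataset.aln, annotation=ann)
    win = window_counts(columns, w_cfg, pair=("osj", "og"))
    out_tsv = os.path.join(out_dir, "windows_osj_og.tsv")
    write_window_tsv(win, out_tsv)
    summary = {
        "tstv_osj_og": tstv_ratio(columns, ("osj", "og")),
        "tstv_osj_osi": tstv_ratio(columns, ("osj", "osi")),
    }
    out_json = os.path.join(out_dir, "divergence_summary.json")
    with open(out_json, "w") as fh:
        json.dump(summary, fh, indent=1)
    inputs = [os.path.join(out_dir, "threeway.aln.fasta")]
    return _write_manifest(out_dir, "windows", asdict(w_cfg), inputs, [out_tsv, out_json])


def _stage_codon(cfg: dict, out_dir: str, seed: int) -> dict:
    from .codons import CodonAlignment, MNGParams, lineage_dnds
    from .stats import BootstrapConfig

    dataset = _load_dataset(out_dir, seed)
    alns = [a for a in dataset.codon_alignments() if isinstance(a, CodonAlignment)]
    params = MNGParams(**cfg.pop("mng", {}))
    boot = BootstrapConfig(seed=seed, **cfg.pop("bootstrap", {}))
    res = lineage_dnds(alns, params, boot)
    out = os.path.join(out_dir, "dnds_summary.json")
    with open(out, "w") as fh:
        json.dump(
            {
                "n_genes": len(alns),
                "bN": res.bN, "bS": res.bS, "omega": res.omega,
                "omega_sd": res.omega_sd,
                "lineage_counts": {k: list(v) for k, v in res.lineage_counts.items()},
                "count_gtest": res.count_gtest.to_dict() if res.count_gtest else None,
            },
            fh, indent=1,
        )
    inputs = [os.path.join(out_dir, "osj.gff3")]
    return _write_manifest(out_dir, "codon", {"R": params.R}, inputs, [out])


def _stage_splice(cfg: dict, out_dir: str, seed: int) -> dict:
    from .splice import (
        assign_splice_lineage, extract_splice_contexts, flank_clean_filter,
        summarize_table4, write_records_tsv,
    )

    dataset = _load_dataset(out_dir, seed)
    records = extract_splice_contexts(dataset.genes, dataset.aln)
    for r in records:
        if r.gap_free:
            assign_splice_lineage(r)
    clean = flank_clean_filter(records)
    summary = {
        "all_gap_free": summarize_table4([r for r in records if r.gap_free]),
        "flank_clean": summarize_table4(clean),
    }
    tsv = os.path.join(out_dir, "splice_records.tsv")
    write_records_tsv(records, tsv)
    out = os.path.join(out_dir, "splice_summary.json")
    with open(out, "w") as fh:
        json.dump(summary, fh, indent=1)
    inputs = [os.path.join(out_dir, "osj.gff3")]
    return _write_manifest(out_dir, "splice", {}, inputs, [tsv, out])


def _stage_ssr(cfg: dict, out_dir: str, seed: int) -> dict:
    from .ssr import (
        SSRConfig, assign_region, classify_cluster, cluster_across_genomes,
        detect_ssrs, ssr_gtests, table5_counts, write_bed,
    )

    dataset = _load_dataset(out_dir, seed)
    ssr_cfg = SSRConfig()
    loci = {
        g: detect_ssrs(dataset.genome(g), genome=g, cfg=ssr_cfg)
        for g in ("osj", "osi", "og")
    }
    clusters = cluster_across_genomes(loci, dataset.aln, ssr_cfg)
    for c in clusters:
        classify_cluster(c)
        assign_region(c, dataset.genes)
    report = ssr_gtests(clusters)
    report["counts"] = {
        f"{k[0]}_unit{k[1]}": v for k, v in table5_counts(clusters).items()
    }
    bed = os.path.join(out_dir, "ssr_osj.bed")
    write_bed(loci["osj"], bed)
    out = os.path.join(out_dir, "ssr_summary.json")
    with open(out, "w") as fh:
        json.dump(report, fh, indent=1)
    inputs = [os.path.join(out_dir, "osj.fasta")]
    return _write_manifest(out_dir, "ssr", {}, inputs, [bed, out])


def _stage_enrich(cfg: dict, out_dir: str, seed: int) -> dict:
    from .stats import ContingencyTable2x2, gtest_2x2

    tables = cfg.get("tables")
    if not tables:
        raise MissingInputError("enrich stage needs cfg['tables'] = {label: [a,b,c,d]}")
    results = {}
    for label, (a, b, c, d) in tables.items():
        res = gtest_2x2(ContingencyTable2x2(a, b, c, d))
        results[label] = {"table": [a, b, c, d], **res.to_dict()}
    out = os.path.join(out_dir, "enrichment.json")
    with open(out, "w") as fh:
        json.dump(results, fh, indent=1)
    return _write_manifest(out_dir, "enrich", {"n_tables": len(tables)}, [], [out])


def _stage_report(cfg: dict, out_dir: str, seed: int) -> dict:
    pieces = {}
    for name in ("qc_summary", "contig_stats", "divergence_summary",
                 "dnds_summary", "splice_summary", "ssr_summary", "enrichment"):
        path = os.path.join(out_dir, f"{name}.json")
        if os.path.exists(path):
            with open(path) as fh:
                pieces[name] = json.load(fh)
    out = os.path.join(out_dir, "report.json")
    with open(out, "w") as fh:
        json.dump(pieces, fh, indent=1)
    return _write_manifest(out_dir, "report", {}, [], [out])
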