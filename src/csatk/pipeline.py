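"""End-to-end driver chaining simulate -> filter -> assemble -> merge ->
haplotype -> evaluate on a simulated region, with a manifest recording each
stage's parameters and output checksums.

Execution is single-process and deterministic: rerunning with an identical
configuration reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from dataclasses import asdict, replace
from pathlib import Path
from typing import Any

import pandas as pd

from csatk.config import RunConfig, config_to_dict
from csatk.core_io import SeqRecord, write_fasta, write_fastq_pairs
from csatk.csa_merge import (all_pairs_overlaps, build_layout,
                             build_superscaffolds, merge_site_clones)
from csatk.evaluate import gc_windows, global_identity
from csatk.haplotypes import partition_clones, summarize_separated_regions
from csatk.mini_assembly import ksweep_assemble
from csatk.read_filter import filter_pipeline
from csatk.simulate import (make_target_sites, simulate_clones,
                            simulate_pool_reads, simulate_reads,
                            simulate_region, write_simulation)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "filter", "assemble", "merge", "haplotype", "evaluate")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _params_hash(cfg: RunConfig) -> str:
    blob = json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> tuple[int, dict[str, Any]]:
    """Run all six stages; returns (exit_status, manifest).

    On a stage failure the manifest marks the last completed stage and the
    exit status is non-zero.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "params_hash": _params_hash(config),
        "seed": config.seed,
        "stages": [],
        "outputs": {},
    }
    state: dict[str, Any] = {}
    try:
        for stage in STAGES:
            logger.info("stage %s", stage)
            files = _RUNNERS[stage](config, outdir, state)
            manifest["stages"].append(stage)
            manifest["outputs"][stage] = {
                name: _sha256(outdir / name) for name in sorted(files)}
        manifest["summary"] = {
            "n_clones": len(state["clones"]),
            "n_second_class": len(state["second"]),
            "n_superscaffolds": len(state["supers"]),
            "best_identity_to_truth": state["best_identity"],
            "haplotype_assignment": {
                k: v for k, v in sorted(state["partition"].assignment.items())},
        }
        status = 0
    except Exception as exc:  # noqa: BLE001 — driver boundary
        logger.error("stage failed: %s", exc)
        manifest["failed_stage"] = (
            STAGES[len(manifest["stages"])] if len(manifest["stages"]) < len(STAGES)
            else "unknown")
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        logger.debug(traceback.format_exc())
        status = 1
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return status, manifest


def _stage_simulate(config: RunConfig, outdir: Path, state: dict) -> list[str]:
    sim = config.sim
    truth = simulate_region(sim)
    sites = make_target_sites(sim.region_len, config.n_sites)
    clones = simulate_clones(truth, sim, sites)
    write_simulation(outdir, truth, clones)
    files = ["haplotypes.fasta", "clones.fasta", "variants.tsv", "clones.tsv"]
    small: dict[str, list] = {}
    for rec, _meta in clones:
        pairs, _origins = simulate_reads(rec, sim, 500)
        small[rec.id] = pairs
        write_fastq_pairs(pairs, outdir / f"{rec.id}_500_1.fastq",
                          outdir / f"{rec.id}_500_2.fastq")
        files += [f"{rec.id}_500_1.fastq", f"{rec.id}_500_2.fastq"]
    pool: dict[int, list] = {}
    for lib in (2000, 5000):
        pool[lib], _ = simulate_pool_reads(
            [rec for rec, _m in clones], sim, lib, config.large_insert_coverage)
        write_fastq_pairs(pool[lib], outdir / f"pool_{lib}_1.fastq",
                          outdir / f"pool_{lib}_2.fastq")
        files += [f"pool_{lib}_1.fastq", f"pool_{lib}_2.fastq"]
    state.update(truth=truth, sites=sites, clones=clones, small=small, pool=pool)
    return files


def _stage_filter(config: RunConfig, outdir: Path, state: dict) -> list[str]:
    sim = config.sim
    params = replace(
        config.filter,
        adapter_seqs=[sim.adapter_seq] if sim.adapter_seq else [],
        contam_refs=[SeqRecord(id="vector", seq=sim.vector_seq)] if sim.vector_seq else [],
    )
    rows = []
    filtered_small: dict[str, list] = {}
    for clone_id, pairs in state["small"].items():
        kept, report = filter_pipeline(pairs, params)
        filtered_small[clone_id] = kept
        rows.append((clone_id, 500, report.input_pairs, report.surviving_pairs,
                     *(report.dropped_by_rule[r] for r in sorted(report.dropped_by_rule))))
    filtered_pool: dict[int, list] = {}
    for lib, pairs in state["pool"].items():
        kept, report = filter_pipeline(pairs, params)
        filtered_pool[lib] = kept
        rows.append(("pool", lib, report.input_pairs, report.surviving_pairs,
                     *(report.dropped_by_rule[r] for r in sorted(report.dropped_by_rule))))
    cols = ["sample", "library", "input_pairs", "surviving_pairs",
            "adapter_or_short", "contaminant", "duplicate", "low_quality", "too_many_n"]
    pd.DataFrame(rows, columns=cols).to_csv(outdir / "filter_report.tsv",
                                            sep="\t", index=False)
    state.update(filtered_small=filtered_small, filtered_pool=filtered_pool)
    return ["filter_report.tsv"]


def _stage_assemble(config: RunConfig, outdir: Path, state: dict) -> list[str]:
    meta_by_id = {m.clone_id: m for _r, m in state["clones"]}
    scaffolds = []
    stats_rows = []
    for clone_id in sorted(state["filtered_small"]):
        cs = ksweep_assemble(
            state["filtered_small"][clone_id], config.assembly,
            large_pairs_by_lib=state["filtered_pool"],
            clone_id=clone_id, site_id=meta_by_id[clone_id].site_id)
        scaffolds.append(cs)
        stats_rows.append((clone_id, cs.site_id, cs.k_used, len(cs.seq),
                           cs.stats["n_contigs"], cs.stats["scaffold_n50"],
                           len(cs.gaps)))
    write_fasta([SeqRecord(id=cs.clone_id, seq=cs.seq) for cs in scaffolds],
                outdir / "clone_scaffolds.fasta")
    pd.DataFrame(stats_rows, columns=[
        "clone_id", "site_id", "k_used", "scaffold_len", "n_contigs",
        "scaffold_n50", "n_gaps"]).to_csv(outdir / "assembly_stats.tsv",
                                          sep="\t", index=False)
    state["clone_scaffolds"] = scaffolds
    return ["clone_scaffolds.fasta", "assembly_stats.tsv"]


def _stage_merge(config: RunConfig, outdir: Path, state: dict) -> list[str]:
    by_site: dict[str, list[SeqRecord]] = {}
    for cs in state["clone_scaffolds"]:
        by_site.setdefault(cs.site_id, []).append(
            SeqRecord(id=cs.clone_id, seq=cs.seq))
    second, site_layouts = merge_site_clones(by_site, config.merge)
    supers, super_layouts = build_superscaffolds(second, config.merge)
    write_fasta([SeqRecord(id=m.id, seq=m.seq) for m in second],
                outdir / "second_class.fasta")
    write_fasta([SeqRecord(id=m.id, seq=m.seq) for m in supers],
                outdir / "super_scaffolds.fasta")
    with open(outdir / "provenance.bed", "w") as fh:
        for m in supers + second:
            for s, e, src in m.provenance:
                fh.write(f"{m.id}\t{s}\t{e}\t{src}\t0\t+\n")
    state.update(second=second, supers=supers)
    return ["second_class.fasta", "super_scaffolds.fasta", "provenance.bed"]


def _stage_haplotype(config: RunConfig, outdir: Path, state: dict) -> list[str]:
    records = [SeqRecord(id=cs.clone_id, seq=cs.seq)
               for cs in state["clone_scaffolds"]]
    edges = all_pairs_overlaps(records, config.merge)
    layouts = build_layout(records, edges, config.merge.offset_tol)
    partition = partition_clones([r.id for r in records], edges,
                                 config.haplotype.same_threshold)
    lens = {r.id: len(r.seq) for r in records}
    regions = summarize_separated_regions(partition, layouts, lens)
    pd.DataFrame(
        sorted(partition.assignment.items()),
        columns=["clone_id", "haplotype_group"],
    ).to_csv(outdir / "haplotype_assignment.tsv", sep="\t", index=False)
    regions.to_csv(outdir / "separated_regions.tsv", sep="\t", index=False)
    variant_rows = []
    for e in edges:
        for pos, vtype, a, b in e.variants:
            # VCF-like export: 1-based position on scaffold a
            variant_rows.append((e.id_a, pos + 1, vtype, a or "-", b or "-", e.id_b))
    pd.DataFrame(variant_rows, columns=[
        "CHROM", "POS", "TYPE", "REF", "ALT", "other_clone"]).to_csv(
        outdir / "clone_variants.tsv", sep="\t", index=False)
    state.update(partition=partition, clone_edges=edges)
    return ["haplotype_assignment.tsv", "separated_regions.tsv", "clone_variants.tsv"]


def _stage_evaluate(config: RunConfig, outdir: Path, state: dict) -> list[str]:
    truth = state["truth"]
    rows = []
    gc_rows = []
    best_identity = 0.0
    for m in state["supers"]:
        rep = global_identity(SeqRecord(id=m.id, seq=m.seq), truth.hapA,
                              anchor_k=config.evaluate.anchor_k)
        best_identity = max(best_identity, rep.identity)
        rows.append((m.id, len(m.seq), rep.identity, len(rep.blocks),
                     len(rep.differences), rep.orientation))
        prof = gc_windows(m.seq, config.evaluate.gc_window)
        gc_rows.extend((m.id, i, v if v is not None else "NA")
                       for i, v in enumerate(prof.per_window))
    pd.DataFrame(rows, columns=[
        "scaffold", "length", "identity_to_truth", "n_blocks",
        "n_differences", "orientation"]).to_csv(
        outdir / "evaluation.tsv", sep="\t", index=False)
    pd.DataFrame(gc_rows, columns=["scaffold", "window", "gc"]).to_csv(
        outdir / "gc_windows.tsv", sep="\t", index=False)
    state["best_identity"] = best_identity
    return ["evaluation.tsv", "gc_windows.tsv"]


_RUNNERS = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "assemble": _stage_assemble,
    "merge": _stage_merge,
    "haplotype": _stage_haplotype,
    "evaluate": _stage_evaluate,
}
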