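"""End-to-end orchestration: simulate -> seeds -> recruit -> assemble -> evaluate.

Stages communicate only via files under the output directory, and a manifest
records the configuration and a checksum of every output, so a rerun with the
same config and seed is byte-identical and resumable stage by stage.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import assemble as asm
from . import evaluate as ev
from . import recruit as rc
from . import seeds as sd
from . import simulate as sim
from .config import PipelineConfig
from .io_formats import (
    read_fasta,
    read_fastq_pair,
    write_fasta,
    write_hits_table,
    write_otu_table,
)
from .model import SeedBin, Seed, SeqRecord

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_amplicons(sim_dir: Path, sample_ids: list[str]):
    for sid in sample_ids:
        path = sim_dir / f"{sid}_amplicons.fastq"
        from .io_formats import read_fastq

        for rec in read_fastq(path):
            yield sid, rec


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the pipeline; returns the manifest (also written as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    # --- simulate -----------------------------------------------------------
    sim_params = dataclasses.replace(config.simulate, rng_seed=config.seed)
    sim_dir = outdir / "sim"
    if config.run_simulation:
        logger.info("stage simulate -> %s", sim_dir)
        files = sim.simulate_dataset(sim_params, sim_dir)
        written.extend(files.values())
    samples_df = pd.read_csv(sim_dir / "samples.tsv", sep="\t", dtype=str)
    sample_ids = list(samples_df["sample_id"])
    diversity = dict(zip(samples_df["sample_id"], samples_df["diversity"]))

    # --- seeds --------------------------------------------------------------
    seeds_dir = outdir / "seeds"
    seeds_dir.mkdir(exist_ok=True)
    all_seeds, otu_table = sd.cluster_otus(
        _read_amplicons(sim_dir, sample_ids), config.seeds.cluster_identity
    )
    all_seeds = sd.filter_length(all_seeds, (config.seeds.min_len, config.seeds.max_len))
    reference = read_fasta(config.seeds.reference) if config.seeds.reference else []
    n_sel = config.seeds.n_samples or len(sample_ids)
    selected_samples = sd.select_samples(otu_table, n_sel, config.seeds.rank_statistic)
    if config.seeds.filter_order == "before_topk":
        novel, known = sd.filter_known(all_seeds, reference, config.seeds.cluster_identity)
        seeds = sd.select_seeds(novel, otu_table, selected_samples, config.seeds.top_k,
                                config.seeds.rank_statistic)
    else:
        top = sd.select_seeds(all_seeds, otu_table, selected_samples, config.seeds.top_k,
                              config.seeds.rank_statistic)
        seeds, known = sd.filter_known(top, reference, config.seeds.cluster_identity)
    otu_path = seeds_dir / "otu_table.tsv"
    write_otu_table(otu_table, otu_path)
    seeds_path = seeds_dir / "seeds.fasta"
    write_fasta(
        [
            SeqRecord(
                id=s.id,
                sequence=s.sequence,
                description=f"rank={i + 1} max_abund={max(s.rel_abundance.values() or [0]):.5f}",
            )
            for i, s in enumerate(seeds)
        ],
        seeds_path,
    )
    sel_path = seeds_dir / "selection.tsv"
    pd.DataFrame(
        {"selected_sample": selected_samples}
    ).to_csv(sel_path, sep="\t", index=False)
    written += [otu_path, seeds_path, sel_path]
    logger.info("stage seeds: %d OTUs, %d seeds selected", len(otu_table.otu_ids), len(seeds))

    # --- recruit ------------------------------------------------------------
    recruit_dir = outdir / "recruit"
    recruit_dir.mkdir(exist_ok=True)
    assignments_by_sample: dict[str, list] = {}
    pairs_by_sample: dict[str, dict] = {}
    all_hits = []
    counters = []
    for sid in sample_ids:
        pairs = list(
            read_fastq_pair(sim_dir / f"{sid}_R1.fastq", sim_dir / f"{sid}_R2.fastq", sid)
        )
        assignments, ghits = rc.recruit_sample(pairs, seeds, sid, config.recruit)
        assignments_by_sample[sid] = assignments
        pairs_by_sample[sid] = {p.id: p for p in pairs}
        all_hits.extend(ghits)
        n_assigned = sum(a.assigned for a in assignments)
        by_reason = {}
        for a in assignments:
            if not a.assigned:
                by_reason[a.reason] = by_reason.get(a.reason, 0) + 1
        counters.append({"sample_id": sid, "n_pairs": len(pairs), "n_assigned": n_assigned, **by_reason})
        logger.info("stage recruit %s: %d/%d pairs assigned (%s)", sid, n_assigned, len(pairs), by_reason)
    hits_path = recruit_dir / "hits.tsv"
    write_hits_table(all_hits, hits_path)
    assign_path = recruit_dir / "assignments.tsv"
    rows = [
        {
            "read_id": a.read_id, "sample_id": a.sample_id,
            "matched_seeds": ",".join(sorted(a.matched_seed_ids)),
            "assigned": a.assigned_seed_id or "", "reason": a.reason or "",
        }
        for sid in sample_ids
        for a in assignments_by_sample[sid]
        if a.assigned or a.reason != "no_hit"
    ]
    pd.DataFrame(rows, columns=["read_id", "sample_id", "matched_seeds", "assigned", "reason"]).to_csv(
        assign_path, sep="\t", index=False
    )
    counters_path = recruit_dir / "counters.tsv"
    pd.DataFrame(counters).fillna(0).to_csv(counters_path, sep="\t", index=False)
    bins = rc.bin_pairs(assignments_by_sample, pairs_by_sample)
    bin_files = rc.write_bins(bins, recruit_dir / "bins")
    no_reads = sorted(set(s.id for s in seeds) - set(b.seed_id for b in bins))
    noreads_path = recruit_dir / "no_reads.tsv"
    pd.DataFrame({"seed_id": no_reads}).to_csv(noreads_path, sep="\t", index=False)
    written += [hits_path, assign_path, counters_path, noreads_path]
    for r1, r2 in bin_files.values():
        written += [r1, r2]

    # --- assemble -----------------------------------------------------------
    asm_dir = outdir / "assemble"
    asm_dir.mkdir(exist_ok=True)
    bin_by_seed = {b.seed_id: b for b in bins}
    results = []
    for s in seeds:
        b = bin_by_seed.get(s.id, SeedBin(seed_id=s.id))
        results.append(asm.assemble_seed(b, s, config.assemble))
    reported, short = asm.length_filter(results, config.assemble.min_report_len)
    # chimera parents: the seed set (every contig's own seed is excluded by id);
    # seeds share the amplicon window, so parent spans are comparable
    pool = [SeqRecord(id=s.id, sequence=s.sequence) for s in seeds]
    for r in results:
        if r.length > 0:
            r.chimera = asm.chimera_check(
                r, pool, config.evaluate.chimera_min_div, config.evaluate.chimera_min_improve
            )
    contigs_path = asm_dir / "contigs.fasta"
    write_fasta(
        [
            SeqRecord(
                id=r.seed_id, sequence=r.sequence,
                description=f"length={r.length} n_pairs={r.n_pairs_used} status={r.status}",
            )
            for r in results
            if r.length > 0
        ],
        contigs_path,
    )
    report_path = asm_dir / "assembly_report.tsv"
    pd.DataFrame(
        [
            {
                "seed_id": r.seed_id, "length": r.length, "n_pairs_used": r.n_pairs_used,
                "status": r.status, "chimera": r.chimera,
            }
            for r in results
        ]
    ).to_csv(report_path, sep="\t", index=False)
    written += [contigs_path, report_path]
    logger.info(
        "stage assemble: %d/%d reconstructed, %d >= %d nt",
        sum(r.length > 0 for r in results), len(results), len(reported),
        config.assemble.min_report_len,
    )

    # --- evaluate -----------------------------------------------------------
    if config.run_evaluation:
        eval_dir = outdir / "evaluate"
        eval_dir.mkdir(exist_ok=True)
        truth = read_fasta(sim_dir / "truth_16s.fasta")
        truth_map, unmapped = ev.build_seed_truth(seeds, truth, config.evaluate.seed_truth_identity)
        prov = {}
        for sid in sample_ids:
            for pid, p in pairs_by_sample[sid].items():
                if p.provenance:
                    prov[pid] = p.provenance
        scores = ev.score_recruitment(
            [a for sid in sample_ids for a in assignments_by_sample[sid]], truth_map, prov
        )
        scores_path = eval_dir / "recruitment_scores.tsv"
        scores.to_csv(scores_path, sep="\t", index=False)
        n_pairs = {b.seed_id: len(b.pairs) for b in bins}
        recon = ev.reconstruction_report(results, truth, n_pairs, config.evaluate.success_identity)
        recon_path = eval_dir / "reconstruction_report.tsv"
        recon.to_csv(recon_path, sep="\t", index=False)
        written += [scores_path, recon_path]
        logger.info(
            "stage evaluate: %d/%d successful reconstructions",
            int(recon["success"].sum()), len(recon),
        )

    # --- manifest -----------------------------------------------------------
    cfg_dict = dataclasses.asdict(config)
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(written))
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return manifest
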