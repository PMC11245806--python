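"""Ground-truth scoring for simulated runs.

Correctness is genome-level: a recruited pair is correct iff its provenance
tag names the same genome as the seed it was assigned to. Reconstruction
success uses an end-gap-free global identity of contig vs truth 16S at the
99% rule, distinct from the local identity used during recruitment.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .alignment import infix_identity, semiglobal_identity
from .io_formats import parse_provenance
from .model import PairAssignment, PairedRead, ReconstructedSeq, Seed, SeqRecord

logger = logging.getLogger(__name__)


@dataclass
class SeedTruth:
    seed_id: str
    genome_id: str
    truth_id: str
    identity: float


def build_seed_truth(
    seeds: Sequence[Seed], truth_16s: Sequence[SeqRecord], min_identity: float = 99.0
) -> tuple[dict[str, SeedTruth], list[str]]:
    """Map each seed to its genome by aligning it into the truth 16S set.

    A seed maps when its best infix alignment reaches ``min_identity`` (the
    whole seed is consumed, so coverage is complete); seeds whose best identity
    is tied between two different genomes are ambiguous and excluded. Returns
    (map, unmapped-or-ambiguous seed ids).
    """
    out: dict[str, SeedTruth] = {}
    unmapped: list[str] = []
    for seed in seeds:
        scored = []
        for rec in truth_16s:
            genome = parse_provenance(rec.description) or rec.id.split("_")[0]
            ident, _, _ = infix_identity(seed.sequence, rec.sequence)
            scored.append((ident, genome, rec.id))
        scored.sort(key=lambda t: (-t[0], t[1]))
        if not scored or scored[0][0] < min_identity:
            unmapped.append(seed.id)
            continue
        best = scored[0]
        tied_genomes = {g for i, g, _ in scored if abs(i - best[0]) < 1e-9}
        if len(tied_genomes) > 1:
            logger.warning("seed %s ambiguous between genomes %s; excluded", seed.id, sorted(tied_genomes))
            unmapped.append(seed.id)
            continue
        out[seed.id] = SeedTruth(seed.id, best[1], best[2], best[0])
    return out, unmapped


def score_recruitment(
    assignments: Sequence[PairAssignment],
    truth_map: Mapping[str, SeedTruth],
    provenance: Mapping[str, str],
) -> pd.DataFrame:
    """Correct/incorrect pair counts per (seed, sample).

    ``provenance`` maps pair id to genome id (from the simulator's read
    headers); an assigned pair without provenance is an error. Pairs assigned
    to seeds absent from the truth map are skipped (counted in the
    ``unmapped_seed`` column of the totals).
    """
    counts: dict[tuple[str, str], list[int]] = defaultdict(lambda: [0, 0])
    for a in assignments:
        if not a.assigned:
            continue
        if a.read_id not in provenance:
            raise ValueError(f"pair {a.read_id} has no provenance tag; cannot score")
        truth = truth_map.get(a.assigned_seed_id)
        if truth is None:
            continue
        correct = provenance[a.read_id] == truth.genome_id
        counts[(a.assigned_seed_id, a.sample_id)][0 if correct else 1] += 1
    rows = [
        {"seed_id": sid, "sample_id": smp, "n_correct": c, "n_incorrect": w}
        for (sid, smp), (c, w) in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["seed_id", "sample_id", "n_correct", "n_incorrect"])


def pair_provenance(pairs: Sequence[PairedRead], prefix_sample: bool = False) -> dict[str, str]:
    out = {}
    for p in pairs:
        if p.provenance is None:
            continue
        key = f"{p.sample_id}:{p.id}" if prefix_sample else p.id
        out[key] = p.provenance
    return out


def reconstruction_report(
    contigs: Sequence[ReconstructedSeq],
    truth_16s: Sequence[SeqRecord],
    n_pairs: Mapping[str, int],
    success_identity: float = 99.0,
) -> pd.DataFrame:
    """Per-contig best truth identity, coverage and success flag.

    Identity is end-gap-free global (the shorter sequence consumed entirely);
    coverage is the aligned fraction of the matched truth record. Failed
    contigs score identity 0 and appear at length 0 — the scatter of
    ``n_pairs`` vs ``length`` is the coverage-vs-length diagnostic.
    """
    rows = []
    for c in contigs:
        best_ident, best_cov, best_truth = 0.0, 0.0, ""
        if c.length > 0:
            for rec in truth_16s:
                ident, span, _ = semiglobal_identity(c.sequence, rec.sequence)
                if len(c.sequence) <= len(rec.sequence):
                    cov = (span[1] - span[0]) / len(rec.sequence)
                else:
                    cov = 1.0
                if ident > best_ident:
                    best_ident, best_cov, best_truth = ident, cov, rec.id
        rows.append(
            {
                "seed_id": c.seed_id,
                "length": c.length,
                "n_pairs": int(n_pairs.get(c.seed_id, 0)),
                "best_truth_id": best_truth,
                "truth_identity": round(best_ident, 3),
                "truth_coverage": round(100.0 * best_cov, 3),
                "success": bool(c.length > 0 and best_ident >= success_identity),
            }
        )
    return pd.DataFrame(rows)


def figure_tables(
    identity_sweeps: Mapping[str, pd.DataFrame],
    multiplicity_sweeps: Mapping[str, pd.DataFrame],
    scores_by_sample: Mapping[str, pd.DataFrame],
    diversity_mode: Mapping[str, str],
    reconstruction: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Long-format tables behind the identity-sweep, multiplicity-sweep and
    pairs-vs-length diagnostics, keyed by figure-style names."""
    out: dict[str, pd.DataFrame] = {}
    rows = []
    for sid, df in sorted(identity_sweeps.items()):
        for _, r in df.iterrows():
            rows.append(
                {"sample_id": sid, "diversity": diversity_mode.get(sid, ""),
                 "threshold": r["threshold"], "n_hits": r["n_hits"],
                 "n_assigned": r["n_assigned"]}
            )
    out["identity_sweep"] = pd.DataFrame(rows)
    rows = []
    for sid, df in sorted(multiplicity_sweeps.items()):
        for _, r in df.iterrows():
            rows.append(
                {"sample_id": sid, "diversity": diversity_mode.get(sid, ""),
                 "m": r["m"], "n_assigned": r["n_assigned"],
                 "n_discarded_multi": r["n_discarded_multi"]}
            )
    out["multiplicity_sweep"] = pd.DataFrame(rows)
    rows = []
    for sid, df in sorted(scores_by_sample.items()):
        for _, r in df.iterrows():
            rows.append(
                {"sample_id": r.get("sample_id", sid),
                 "diversity": diversity_mode.get(r.get("sample_id", sid), ""),
                 "seed_id": r["seed_id"], "n_correct": r["n_correct"],
                 "n_incorrect": r["n_incorrect"]}
            )
    out["recruitment_scores"] = pd.DataFrame(rows)
    if reconstruction is not None:
        out["pairs_vs_length"] = reconstruction[["seed_id", "n_pairs", "length"]].copy()
    return out
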