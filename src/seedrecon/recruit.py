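"""Recruitment of shotgun read pairs to seeds.

This is the heart of the method: each mate is locally aligned to the seeds
(an exact k-mer prefilter skips hopeless mate-seed combinations), hits must
pass an identity threshold and a geometry rule (the alignment covers the whole
read, or it runs into a seed terminus with the unaligned read overhanging that
end), and each surviving pair is assigned to a single seed. Pairs matching
more than ``max_matches`` seeds are discarded; among fewer, the seed with the
highest relative amplicon abundance in the read's own sample wins.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alignment import best_local
from .io_formats import write_fastq_pair
from .model import AlignmentHit, PairAssignment, PairedRead, Seed, SeedBin, revcomp


@dataclass
class RecruitParams:
    min_identity: float = 98.0  # percent
    max_matches: int = 3  # multiplicity cap m
    min_aln_len: int = 50  # nt; excludes spurious short local hits
    end_tolerance: int = 5  # nt slack at seed termini (delta)
    read_cover_tolerance: int = 5  # nt slack on unaligned read ends (epsilon)
    prefilter_k: int = 13  # 0 disables the exact k-mer prefilter

    def validate(self) -> list[str]:
        errs = []
        if not (90.0 <= self.min_identity <= 100.0):
            errs.append("min_identity must be in [90, 100]")
        if not (1 <= self.max_matches <= 10):
            errs.append("max_matches must be in [1, 10]")
        if self.end_tolerance < 0 or self.read_cover_tolerance < 0:
            errs.append("tolerances must be >= 0")
        if self.min_aln_len < 1:
            errs.append("min_aln_len must be >= 1")
        return errs


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


class SeedIndex:
    """Exact k-mer index over seed sequences for candidate prefiltering.

    A mate-seed combination is aligned only when the mate (on either strand)
    shares at least one exact k-mer with the seed. At the default identity
    threshold (98% over a 150 nt read, i.e. at most 3 mismatches) a shared
    13-mer is guaranteed by pigeonhole, so the prefilter loses nothing.
    """

    def __init__(self, seeds: Sequence[Seed], k: int):
        self.k = k
        self.by_kmer: dict[str, set[str]] = defaultdict(set)
        for s in seeds:
            for km in _kmer_set(s.sequence, k):
                self.by_kmer[km].add(s.id)

    def candidates(self, read_seq: str) -> dict[str, set[str]]:
        """seed id -> strands ('+'/'-') worth aligning for this mate."""
        out: dict[str, set[str]] = defaultdict(set)
        for strand, seq in (("+", read_seq), ("-", revcomp(read_seq))):
            for i in range(len(seq) - self.k + 1):
                for sid in self.by_kmer.get(seq[i : i + self.k], ()):
                    out[sid].add(strand)
        return out


def align_to_seeds(
    pairs: Iterable[PairedRead],
    seeds: Sequence[Seed],
    params: RecruitParams | None = None,
) -> list[AlignmentHit]:
    """Best local alignment of every mate x seed combination passing the filters.

    At most one hit is kept per mate-seed combination (best score); hits below
    ``min_identity`` or shorter than ``min_aln_len`` columns are dropped. With
    ``prefilter_k = 0`` the search is exhaustive.
    """
    params = params or RecruitParams()
    if not seeds:
        raise ValueError("no seeds to align against")
    index = SeedIndex(seeds, params.prefilter_k) if params.prefilter_k > 0 else None
    seed_by_id = {s.id: s for s in seeds}
    hits: list[AlignmentHit] = []
    for pair in pairs:
        for mate_no, rec in ((1, pair.mate1), (2, pair.mate2)):
            read = rec.sequence
            if index is not None:
                cand = index.candidates(read)
            else:
                cand = {s.id: {"+", "-"} for s in seeds}
            for sid in sorted(cand):
                best = None
                for strand in sorted(cand[sid]):
                    q = read if strand == "+" else revcomp(read)
                    aln = best_local(q, seed_by_id[sid].sequence)
                    if aln is None:
                        continue
                    if best is None or aln.score > best[0].score:
                        best = (aln, strand)
                if best is None:
                    continue
                aln, strand = best
                if aln.identity < params.min_identity - 1e-9 or aln.columns < params.min_aln_len:
                    continue
                qs, qe = aln.query_span
                if strand == "-":
                    qs, qe = len(read) - aln.query_span[1], len(read) - aln.query_span[0]
                hits.append(
                    AlignmentHit(
                        read_id=pair.id, mate=mate_no, seed_id=sid,
                        identity=aln.identity, aln_len=aln.columns,
                        read_span=(qs, qe), seed_span=aln.target_span,
                        strand=strand, score=aln.score,
                        mismatches=aln.mismatches, gap_opens=aln.gap_opens,
                    )
                )
    return hits


def geometry_pass(
    hit: AlignmentHit, read_len: int, seed_len: int, params: RecruitParams | None = None
) -> bool:
    """True iff the hit covers the whole read, or abuts a seed terminus with the
    unaligned read hanging off that terminus (never into the seed interior)."""
    params = params or RecruitParams()
    eps, delta = params.read_cover_tolerance, params.end_tolerance
    qs, qe = hit.read_span
    if qe - qs >= read_len - eps:
        return True
    # orient unaligned read ends onto the seed axis
    if hit.strand == "+":
        left_over, right_over = qs, read_len - qe
    else:
        left_over, right_over = read_len - qe, qs
    at_start = hit.seed_span[0] <= delta
    at_end = hit.seed_span[1] >= seed_len - delta
    if not (at_start or at_end):
        return False
    if left_over > eps and not at_start:
        return False
    if right_over > eps and not at_end:
        return False
    return True


def filter_geometry(
    hits: Iterable[AlignmentHit],
    read_lens: Mapping[tuple[str, int], int],
    seed_lens: Mapping[str, int],
    params: RecruitParams | None = None,
) -> list[AlignmentHit]:
    params = params or RecruitParams()
    return [
        h
        for h in hits
        if geometry_pass(h, read_lens[(h.read_id, h.mate)], seed_lens[h.seed_id], params)
    ]


def assign_pairs(
    hits: Iterable[AlignmentHit],
    sample_id: str,
    seed_abundance: Mapping[str, float],
    params: RecruitParams | None = None,
    all_pair_ids: Iterable[str] | None = None,
    geometry_failed_ids: Iterable[str] = (),
) -> list[PairAssignment]:
    """Assign each pair (union of both mates' geometry-passing seeds) to one seed.

    Pairs matching more than ``max_matches`` seeds are discarded; otherwise the
    matched seed with the highest relative abundance in this sample wins, ties
    broken by lexicographically smallest seed id. ``all_pair_ids`` (optional)
    adds explicit no-hit discards; ``geometry_failed_ids`` marks pairs whose
    every raw hit failed the geometry rule.
    """
    params = params or RecruitParams()
    matched: dict[str, set[str]] = defaultdict(set)
    for h in hits:
        matched[h.read_id].add(h.seed_id)
    geometry_failed = set(geometry_failed_ids) - set(matched)
    out: list[PairAssignment] = []
    universe = list(all_pair_ids) if all_pair_ids is not None else sorted(
        set(matched) | geometry_failed
    )
    for pid in universe:
        seeds_hit = matched.get(pid)
        if not seeds_hit:
            reason = "geometry_fail" if pid in geometry_failed else "no_hit"
            out.append(PairAssignment(pid, sample_id, None, reason=reason))
            continue
        if len(seeds_hit) > params.max_matches:
            out.append(
                PairAssignment(
                    pid, sample_id, None, reason="too_many_seeds",
                    matched_seed_ids=frozenset(seeds_hit),
                )
            )
            continue
        winner = min(seeds_hit, key=lambda s: (-seed_abundance.get(s, 0.0), s))
        out.append(
            PairAssignment(
                pid, sample_id, winner,
                matched_seed_ids=frozenset(seeds_hit),
                tie_break_used=len(seeds_hit) > 1,
            )
        )
    return out


def recruit_sample(
    pairs: Sequence[PairedRead],
    seeds: Sequence[Seed],
    sample_id: str,
    params: RecruitParams | None = None,
) -> tuple[list[PairAssignment], list[AlignmentHit]]:
    """Full per-sample recruitment: align, geometry-filter, assign.

    Returns assignments for every input pair (conservation: each pair is
    assigned or discarded with a reason) plus the geometry-passing hits.
    """
    params = params or RecruitParams()
    read_lens = {}
    for p in pairs:
        read_lens[(p.id, 1)] = len(p.mate1.sequence)
        read_lens[(p.id, 2)] = len(p.mate2.sequence)
    seed_lens = {s.id: len(s.sequence) for s in seeds}
    abundance = {s.id: s.rel_abundance.get(sample_id, 0.0) for s in seeds}
    raw = align_to_seeds(pairs, seeds, params)
    ghits = filter_geometry(raw, read_lens, seed_lens, params)
    raw_ids = {h.read_id for h in raw}
    assignments = assign_pairs(
        ghits, sample_id, abundance, params,
        all_pair_ids=[p.id for p in pairs], geometry_failed_ids=raw_ids,
    )
    return assignments, ghits


def sweep_identity(
    pairs: Sequence[PairedRead],
    seeds: Sequence[Seed],
    thresholds: Sequence[float],
    sample_id: str,
    params: RecruitParams | None = None,
) -> pd.DataFrame:
    """Recruitment counts per identity threshold on identical inputs.

    Hits are computed once at the lowest threshold; since thresholds only
    filter the best-scoring alignments, per-threshold results equal a full
    rerun. Columns: threshold, n_hits, n_assigned.
    """
    params = params or RecruitParams()
    if not thresholds:
        return pd.DataFrame(columns=["threshold", "n_hits", "n_assigned"])
    base = RecruitParams(**{**params.__dict__, "min_identity": min(thresholds)})
    read_lens = {}
    for p in pairs:
        read_lens[(p.id, 1)] = len(p.mate1.sequence)
        read_lens[(p.id, 2)] = len(p.mate2.sequence)
    seed_lens = {s.id: len(s.sequence) for s in seeds}
    abundance = {s.id: s.rel_abundance.get(sample_id, 0.0) for s in seeds}
    raw = align_to_seeds(pairs, seeds, base)
    rows = []
    for t in thresholds:
        sub = [h for h in raw if h.identity >= t - 1e-9]
        ghits = filter_geometry(sub, read_lens, seed_lens, params)
        assigned = [
            a for a in assign_pairs(ghits, sample_id, abundance, params) if a.assigned
        ]
        rows.append({"threshold": t, "n_hits": len(sub), "n_assigned": len(assigned)})
    return pd.DataFrame(rows)


def sweep_multiplicity(
    ghits: Sequence[AlignmentHit],
    sample_id: str,
    seed_abundance: Mapping[str, float],
    m_values: Sequence[int] = tuple(range(1, 11)),
    params: RecruitParams | None = None,
) -> pd.DataFrame:
    """Assignment counts as the multiplicity cap m varies on a fixed hit set."""
    params = params or RecruitParams()
    rows = []
    for m in m_values:
        p = RecruitParams(**{**params.__dict__, "max_matches": m})
        assigns = assign_pairs(ghits, sample_id, seed_abundance, p)
        rows.append(
            {
                "m": m,
                "n_assigned": sum(a.assigned for a in assigns),
                "n_discarded_multi": sum(a.reason == "too_many_seeds" for a in assigns),
            }
        )
    return pd.DataFrame(rows)


def bin_pairs(
    assignments_by_sample: Mapping[str, Sequence[PairAssignment]],
    pairs_by_sample: Mapping[str, Mapping[str, PairedRead]],
) -> list[SeedBin]:
    """Pool assigned pairs per seed across samples; ids prefixed by sample."""
    bins: dict[str, SeedBin] = {}
    seen: dict[str, set[str]] = defaultdict(set)
    for sample_id in sorted(assignments_by_sample):
        for a in assignments_by_sample[sample_id]:
            if not a.assigned:
                continue
            pair = pairs_by_sample[sample_id][a.read_id]
            new_id = f"{sample_id}:{a.read_id}"
            b = bins.setdefault(a.assigned_seed_id, SeedBin(seed_id=a.assigned_seed_id))
            if new_id in seen[a.assigned_seed_id]:
                raise ValueError(f"duplicate pair id {new_id} in bin {a.assigned_seed_id}")
            seen[a.assigned_seed_id].add(new_id)
            b.pairs.append(
                PairedRead(
                    id=new_id, mate1=pair.mate1, mate2=pair.mate2,
                    sample_id=sample_id, provenance=pair.provenance,
                )
            )
    return [bins[k] for k in sorted(bins)]


def write_bins(bins: Sequence[SeedBin], outdir: str | Path) -> dict[str, tuple[Path, Path]]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    for b in bins:
        if not b.pairs:
            continue
        r1 = outdir / f"{b.seed_id}_R1.fastq"
        r2 = outdir / f"{b.seed_id}_R2.fastq"
        renamed = [
            PairedRead(
                id=p.id,
                mate1=type(p.mate1)(id=f"{p.id}/1", sequence=p.mate1.sequence,
                                    description=p.mate1.description, quality=p.mate1.quality),
                mate2=type(p.mate2)(id=f"{p.id}/2", sequence=p.mate2.sequence,
                                    description=p.mate2.description, quality=p.mate2.quality),
                sample_id=p.sample_id, provenance=p.provenance,
            )
            for p in b.pairs
        ]
        write_fastq_pair(renamed, r1, r2)
        files[b.seed_id] = (r1, r2)
    return files
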