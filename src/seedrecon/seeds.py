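"""Seed construction from amplicon data.

Seeds are high-abundance amplicon OTU centroids. Clustering is greedy
centroid (vsearch-style) at 99% global identity: unique sequences are scanned
in order of decreasing total count (ties broken lexicographically) and each
joins the first centroid it matches at or above the threshold, else founds a
new one. Sample selection and seed ranking follow the top-down walk over OTUs
ordered by their maximum per-sample relative abundance.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Sequence

import pandas as pd

from .alignment import best_local, global_identity
from .model import OTUTable, Seed, SeqRecord

logger = logging.getLogger(__name__)


def cluster_otus(
    amplicons: Iterable[tuple[str, SeqRecord]], identity: float = 0.99
) -> tuple[list[Seed], OTUTable]:
    """Greedy centroid clustering of (sample_id, record) amplicons.

    Returns one Seed per OTU (centroid sequence, per-sample counts and
    relative abundances) and the OTU x sample count table. OTU ids are
    assigned OTU_0001... in founding order.
    """
    if not (0.5 < identity <= 1.0):
        raise ValueError("identity must be in (0.5, 1.0]")
    counts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for sample_id, rec in amplicons:
        counts[rec.sequence][sample_id] += 1
    if not counts:
        raise ValueError("no amplicon sequences to cluster")
    uniques = sorted(counts, key=lambda s: (-sum(counts[s].values()), s))
    centroids: list[str] = []
    members: list[list[str]] = []
    threshold_pct = identity * 100.0
    for seq in uniques:
        for ci, cent in enumerate(centroids):
            ident, _ = global_identity(seq, cent)
            if ident >= threshold_pct - 1e-9:
                members[ci].append(seq)
                break
        else:
            centroids.append(seq)
            members.append([seq])
    sample_ids = sorted({s for per in counts.values() for s in per})
    rows = []
    for mem in members:
        row = {s: 0 for s in sample_ids}
        for seq in mem:
            for s, c in counts[seq].items():
                row[s] += c
        rows.append(row)
    otu_ids = [f"OTU_{i + 1:04d}" for i in range(len(centroids))]
    table = OTUTable(counts=pd.DataFrame(rows, index=otu_ids, columns=sample_ids))
    rel = table.rel_abundance()
    seeds = [
        Seed(
            id=oid,
            sequence=cent,
            counts=table.counts.loc[oid].to_dict(),
            rel_abundance=rel.loc[oid].to_dict(),
        )
        for oid, cent in zip(otu_ids, centroids)
    ]
    return seeds, table


def filter_length(
    seeds: Sequence[Seed], bounds: tuple[int, int] = (150, 600)
) -> list[Seed]:
    """Drop seeds outside the length bounds (guards against non-amplicon junk)."""
    kept = []
    for s in seeds:
        if bounds[0] <= len(s.sequence) <= bounds[1]:
            kept.append(s)
        else:
            logger.warning("seed %s length %d outside bounds %s; excluded", s.id, len(s.sequence), bounds)
    return kept


def filter_known(
    seeds: Sequence[Seed], reference: Sequence[SeqRecord], identity: float = 0.99
) -> tuple[list[Seed], list[tuple[Seed, str]]]:
    """Partition seeds into (novel, known-with-reference-id) against a 16S reference.

    A seed is known iff some local alignment to a reference record covers at
    least 95% of the seed at strictly more than the identity threshold.
    An empty reference leaves every seed novel.
    """
    novel: list[Seed] = []
    known: list[tuple[Seed, str]] = []
    threshold_pct = identity * 100.0
    for seed in seeds:
        match_id = None
        for ref in reference:
            aln = best_local(seed.sequence, ref.sequence)
            if aln is None:
                continue
            coverage = (aln.query_span[1] - aln.query_span[0]) / len(seed.sequence)
            if coverage >= 0.95 and aln.identity > threshold_pct:
                match_id = ref.id
                break
        if match_id is None:
            novel.append(seed)
        else:
            known.append((seed, match_id))
    return novel, known


def rank_otus(table: OTUTable, statistic: str = "max") -> list[str]:
    """OTU ids ranked by per-sample relative abundance (desc), ties by id."""
    rel = table.rel_abundance()
    if statistic == "max":
        stat = rel.max(axis=1)
    elif statistic == "mean":
        stat = rel.mean(axis=1)
    else:
        raise ValueError(f"unknown ranking statistic {statistic!r}")
    return sorted(table.otu_ids, key=lambda o: (-stat[o], o))


def select_samples(table: OTUTable, n: int, statistic: str = "max") -> list[str]:
    """Pick the n samples in which the top-ranked OTUs attain their peak abundance.

    Walk the abundance-ranked OTU list; each OTU contributes its argmax sample
    (ties by sample id) to an ordered set, until the set reaches size n. If the
    walk exhausts all OTUs first, remaining slots are filled with the unused
    samples in id order.
    """
    if not (1 <= n <= len(table.sample_ids)):
        raise ValueError(f"n must be in [1, {len(table.sample_ids)}], got {n}")
    rel = table.rel_abundance()
    chosen: list[str] = []
    for otu in rank_otus(table, statistic):
        row = rel.loc[otu]
        peak = row.max()
        sample = sorted(s for s in row.index if row[s] == peak)[0]
        if sample not in chosen:
            chosen.append(sample)
        if len(chosen) == n:
            return chosen
    for s in sorted(table.sample_ids):
        if s not in chosen:
            chosen.append(s)
        if len(chosen) == n:
            break
    return chosen


def select_seeds(
    seeds: Sequence[Seed],
    table: OTUTable,
    selected_samples: Sequence[str],
    top_k: int = 300,
    statistic: str = "max",
) -> list[Seed]:
    """Rank seeds within the selected samples and keep the top K.

    The ranking key is maximum per-sample relative abundance restricted to the
    selected samples (ties by total count desc, then id). Relative abundances
    use full per-sample totals, so restricting columns does not inflate them.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    rel = table.rel_abundance()[list(selected_samples)]
    by_id = {s.id: s for s in seeds}
    candidates = [oid for oid in table.otu_ids if oid in by_id]
    if statistic == "max":
        stat = rel.max(axis=1)
    elif statistic == "mean":
        stat = rel.mean(axis=1)
    else:
        raise ValueError(f"unknown ranking statistic {statistic!r}")
    total = table.counts.sum(axis=1)
    ranked = sorted(candidates, key=lambda o: (-stat[o], -total[o], o))
    return [by_id[o] for o in ranked[:top_k]]
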