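"""Pairwise alignment primitives.

One identity definition is used everywhere: matches / alignment columns, with
gap columns counting as mismatches. Global and semiglobal (infix) alignments
run on edlib; best local alignments (read-vs-seed recruitment, novelty
filtering) run on Bio.Align.PairwiseAligner with a single affine scheme
(match +2, mismatch -3, gap open -5, gap extend -2).
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache

import edlib
import numpy as np
from Bio import Align

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(matches, columns) from an edlib extended cigar."""
    matches = 0
    columns = 0
    for n, op in _CIGAR_RE.findall(cigar):
        n = int(n)
        columns += n
        if op == "=":
            matches += n
    return matches, columns


def global_identity(a: str, b: str) -> tuple[float, int]:
    """Percent identity of the optimal global (NW) alignment and its column count."""
    if not a or not b:
        return 0.0, 0
    res = edlib.align(a, b, mode="NW", task="path")
    m, cols = _cigar_stats(res["cigar"])
    return 100.0 * m / cols, cols


def infix_identity(query: str, target: str) -> tuple[float, tuple[int, int], int]:
    """Align the whole query into the best-matching infix of target (edlib HW).

    End gaps on the target are free; the query is consumed entirely. Returns
    (percent identity, target span 0-based half-open, alignment columns).
    """
    if not query or not target:
        return 0.0, (0, 0), 0
    res = edlib.align(query, target, mode="HW", task="path")
    m, cols = _cigar_stats(res["cigar"])
    start, end = res["locations"][0]
    return 100.0 * m / cols, (start, end + 1), cols


def semiglobal_identity(a: str, b: str) -> tuple[float, tuple[int, int], int]:
    """End-gap-free identity of a against b, the shorter consumed entirely.

    Used for contig-vs-truth comparison: neither dangling end is penalised,
    mirroring how vsearch-style global identities are reported for sequences
    of unequal length. Returns (identity, span on the longer sequence, columns).
    """
    if len(a) <= len(b):
        return infix_identity(a, b)
    ident, _, cols = infix_identity(b, a)
    return ident, (0, len(b)), cols


def alignment_profile(query: str, target: str) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative (matches, columns) of the query-vs-target alignment, indexed
    by query position.

    The alignment is semiglobal: the shorter sequence is placed as an infix of
    the longer, so a parent that covers only part of the query contributes
    columns only over its span, and dangling ends of either sequence are free.
    Entry i gives the statistics over all columns attributed to query positions
    < i. Used by the two-parent chimera scan.
    """
    n = len(query)
    cum_m = np.zeros(n + 1, dtype=int)
    cum_c = np.zeros(n + 1, dtype=int)
    if not query or not target:
        return cum_m, cum_c
    query_is_short = len(query) <= len(target)
    if query_is_short:
        res = edlib.align(query, target, mode="HW", task="path")
        qpos = 0
    else:
        res = edlib.align(target, query, mode="HW", task="path")
        qpos = res["locations"][0][0]  # span start on the (long) query
        cum_m[: qpos + 1] = 0
    m_run = 0
    c_run = 0
    for cnt, op in _CIGAR_RE.findall(res["cigar"]):
        cnt = int(cnt)
        # ops consume edlib's query; map that onto OUR query axis
        consumes_query = (op in ("=", "X", "M")) or (
            op == "I" if query_is_short else op == "D"
        )
        if consumes_query:
            for _ in range(cnt):
                if op == "=":
                    m_run += 1
                c_run += 1
                qpos += 1
                cum_m[qpos] = m_run
                cum_c[qpos] = c_run
        else:  # gap in our query; attribute columns to the current boundary
            c_run += cnt
            cum_c[qpos] = c_run
    cum_m[qpos:] = m_run
    cum_c[qpos:] = c_run
    return cum_m, cum_c


@dataclass
class LocalAlignment:
    score: float
    identity: float  # percent
    columns: int
    query_span: tuple[int, int]  # on the query as passed
    target_span: tuple[int, int]
    mismatches: int
    gap_opens: int


@lru_cache(maxsize=8)
def _aligner(match: float, mismatch: float, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = gap_open
    a.extend_gap_score = gap_extend
    return a


def best_local(
    query: str,
    target: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> LocalAlignment | None:
    """Best-scoring local alignment of query against target, or None if score <= 0."""
    aligner = _aligner(match, mismatch, gap_open, gap_extend)
    alns = aligner.align(target, query)
    try:
        aln = alns[0]
    except IndexError:
        return None
    if aln.score <= 0:
        return None
    counts = aln.counts()
    t_blocks, q_blocks = aln.aligned
    if len(q_blocks) == 0:
        return None
    columns = counts.identities + counts.mismatches + counts.internal_gaps
    gap_opens = counts.open_internal_insertions + counts.open_internal_deletions
    return LocalAlignment(
        score=float(aln.score),
        identity=100.0 * counts.identities / columns,
        columns=int(columns),
        query_span=(int(q_blocks[0][0]), int(q_blocks[-1][1])),
        target_span=(int(t_blocks[0][0]), int(t_blocks[-1][1])),
        mismatches=int(counts.mismatches),
        gap_opens=int(gap_opens),
    )
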