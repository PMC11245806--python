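"""Seeded assembly: grow one contig per seed from its read bin.

The built-in assembler is a greedy consensus extender. The seed is the
trusted backbone; every mate (either orientation) is anchored to the current
contig by exact k-mer votes and verified by a gapless overlap comparison, then
the contig is extended one base at a time on each side using the majority base
among overhanging reads. Extension stops when support drops below ``min_cov``
or the dominant/secondary base ratio falls below ``branch_ratio`` — halting on
ambiguity is deliberate: a truncated contig beats a mosaic of several taxa.

An external assembler (e.g. SPAdes with the seed as a trusted contig) can be
plugged in through :func:`external_assembler`.
"""
from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .alignment import infix_identity
from .io_formats import read_fasta, write_fastq_pair
from .model import ReconstructedSeq, Seed, SeedBin, SeqRecord, revcomp

logger = logging.getLogger(__name__)


@dataclass
class AssemblyParams:
    k: int = 31  # anchoring k-mer size
    min_cov: int = 3  # minimum overhanging reads supporting an extension base
    max_len: int = 1700  # contig cap (16S plus slack)
    min_report_len: int = 800  # minimum length of interest (> 50% of full 16S)
    branch_ratio: float = 3.0  # dominant/secondary support ratio to proceed
    max_mismatch_frac: float = 0.05  # placement verification tolerance

    def validate(self) -> list[str]:
        errs = []
        if self.k < 15:
            errs.append("k must be >= 15")
        if self.min_cov < 1:
            errs.append("min_cov must be >= 1")
        if self.branch_ratio < 1.0:
            errs.append("branch_ratio must be >= 1")
        return errs


def _place_read(
    seq: str, contig_index: dict[str, list[int]], contig: str, k: int, max_mm_frac: float
) -> int | None:
    """Offset of the read on the contig, or None. Gapless: substitution-only
    error model, so a read sits at a single offset voted by its exact k-mers."""
    votes: Counter[int] = Counter()
    step = max(1, (len(seq) - k) // 12) if len(seq) > k else 1
    positions = list(range(0, len(seq) - k + 1, step))
    if positions and positions[-1] != len(seq) - k:
        positions.append(len(seq) - k)
    for i in positions:
        for cpos in contig_index.get(seq[i : i + k], ()):
            votes[cpos - i] += 1
    if not votes:
        return None
    offset = min(votes, key=lambda o: (-votes[o], o))
    a, b = max(0, offset), min(len(contig), offset + len(seq))
    if b - a < k:
        return None
    mism = sum(1 for i in range(a, b) if contig[i] != seq[i - offset])
    if mism > max_mm_frac * (b - a):
        return None
    return offset


def _index_contig(contig: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = defaultdict(list)
    for i in range(len(contig) - k + 1):
        idx[contig[i : i + k]].append(i)
    return idx


def _extend_right(
    contig: str, placements: list[tuple[int, str]], params: AssemblyParams, room: int
) -> str:
    """Consensus bases beyond the contig's right end, stopping on weak or
    ambiguous support."""
    overhangs = [(off, seq) for off, seq in placements if off + len(seq) > len(contig)]
    ext: list[str] = []
    j = len(contig)
    while len(ext) < room:
        bases = [seq[j - off] for off, seq in overhangs if 0 <= j - off < len(seq)]
        if len(bases) < params.min_cov:
            break
        counts = Counter(bases).most_common()
        c1 = counts[0][1]
        c2 = counts[1][1] if len(counts) > 1 else 0
        if c1 < params.min_cov or (c2 > 0 and c1 / c2 < params.branch_ratio):
            break
        ext.append(counts[0][0])
        j += 1
    return "".join(ext)


def assemble_seed(
    bin_: SeedBin, seed: Seed, params: AssemblyParams | None = None
) -> ReconstructedSeq:
    """Greedy seeded consensus assembly of one bin.

    Alternates read placement (both mates, both orientations, against the
    current contig) with left/right consensus extension until the contig stops
    growing or reaches ``max_len``. Never raises on hard inputs; an empty or
    underpowered bin returns status ``failed`` with length 0.
    """
    params = params or AssemblyParams()
    if len(seed.sequence) < params.k:
        raise ValueError(f"seed {seed.id} shorter than k={params.k}")
    reads: list[tuple[str, str]] = []  # (pair_id, oriented candidate sequence)
    for p in bin_.pairs:
        for rec in (p.mate1, p.mate2):
            if len(rec.sequence) >= params.k:
                reads.append((p.id, rec.sequence))
                reads.append((p.id, revcomp(rec.sequence)))
    contig = seed.sequence
    left_total = 0
    placed_pairs: set[str] = set()
    while True:
        index = _index_contig(contig, params.k)
        placements: list[tuple[int, str]] = []
        placed_pairs = set()
        placed_variant: dict[tuple[str, str], int] = {}
        for pid, seq in reads:
            key = (pid, min(seq, revcomp(seq)))
            if key in placed_variant:
                continue  # the opposite orientation already placed
            off = _place_read(seq, index, contig, params.k, params.max_mismatch_frac)
            if off is not None:
                placements.append((off, seq))
                placed_variant[key] = off
                placed_pairs.add(pid)
        room = params.max_len - len(contig)
        right = _extend_right(contig, placements, params, room) if room > 0 else ""
        contig_r = contig + right
        room = params.max_len - len(contig_r)
        rc_placements = [
            (len(contig_r) - (off + len(seq)), revcomp(seq)) for off, seq in placements
        ]
        left = _extend_right(revcomp(contig_r), rc_placements, params, room) if room > 0 else ""
        grew = len(right) + len(left)
        contig = revcomp(revcomp(contig_r) + left)
        left_total += len(left)
        if grew == 0 or len(contig) >= params.max_len:
            break
    extended = len(contig) > len(seed.sequence)
    n_pairs_used = len(placed_pairs)
    if not extended and len(bin_.pairs) < params.min_cov:
        return ReconstructedSeq(
            seed_id=seed.id, sequence="", length=0, n_pairs_used=n_pairs_used,
            seed_span_in_contig=(0, 0), status="failed",
        )
    return ReconstructedSeq(
        seed_id=seed.id, sequence=contig, length=len(contig),
        n_pairs_used=n_pairs_used,
        seed_span_in_contig=(left_total, left_total + len(seed.sequence)),
        status="ok",
    )


def external_assembler(
    bin_: SeedBin, seed: Seed, command_template: str, params: AssemblyParams | None = None
) -> ReconstructedSeq:
    """Run a user-supplied assembler command per bin and wrap its best contig.

    The template receives ``{r1}``, ``{r2}``, ``{seed}`` and ``{outdir}``; the
    command must write ``contigs.fasta`` under ``{outdir}``. The contig with
    the best seed alignment is selected; alternatives are logged.
    """
    params = params or AssemblyParams()
    tool = command_template.split()[0]
    if shutil.which(tool) is None:
        raise FileNotFoundError(f"external assembler command not found: {tool!r}")
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        r1, r2 = tmp / "reads_R1.fastq", tmp / "reads_R2.fastq"
        write_fastq_pair(bin_.pairs, r1, r2)
        seed_fa = tmp / "seed.fasta"
        seed_fa.write_text(f">{seed.id}\n{seed.sequence}\n")
        outdir = tmp / "asm"
        outdir.mkdir()
        cmd = command_template.format(r1=r1, r2=r2, seed=seed_fa, outdir=outdir)
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        if proc.returncode != 0:
            logger.error("external assembler failed for %s: %s", seed.id, proc.stderr[-500:])
            return ReconstructedSeq(seed.id, "", 0, len(bin_.pairs), (0, 0), "failed")
        contigs_file = outdir / "contigs.fasta"
        if not contigs_file.exists():
            return ReconstructedSeq(seed.id, "", 0, len(bin_.pairs), (0, 0), "failed")
        best = None
        for rec in read_fasta(contigs_file):
            ident, span, _ = infix_identity(seed.sequence, rec.sequence)
            if best is None or ident > best[0]:
                best = (ident, span, rec)
        if best is None or best[0] < 99.0:
            return ReconstructedSeq(seed.id, "", 0, len(bin_.pairs), (0, 0), "failed")
        ident, span, rec = best
        return ReconstructedSeq(
            seed_id=seed.id, sequence=rec.sequence, length=len(rec.sequence),
            n_pairs_used=len(bin_.pairs), seed_span_in_contig=span, status="ok",
        )


def length_filter(
    results: Sequence[ReconstructedSeq], min_report_len: int = 800
) -> tuple[list[ReconstructedSeq], list[ReconstructedSeq]]:
    """Partition reconstructions at the minimum length of interest (inclusive).

    Short non-failed results are re-labelled ``below_min_len``.
    """
    reported, short = [], []
    for r in results:
        if r.length >= min_report_len:
            reported.append(r)
        else:
            if r.status == "ok":
                r.status = "below_min_len"
            short.append(r)
    return reported, short


def chimera_check(
    contig: SeqRecord | ReconstructedSeq,
    parent_pool: Sequence[SeqRecord],
    min_div: float = 3.0,
    min_improve: float = 2.0,
    step: int = 10,
) -> str:
    """Two-parent chimera verdict: ``clean`` or ``flagged``.

    For every ordered parent pair (P, Q) whose mutual identity is at most
    100 - min_div percent, a single crossover is scanned along the contig at
    ``step`` nt resolution; the contig is flagged iff the best chimeric
    identity (prefix vs P plus suffix vs Q) beats the best single-parent
    identity by at least ``min_improve`` points. A pool with fewer than two
    records (after excluding the contig itself) is clean by definition.
    """
    from .alignment import alignment_profile, global_identity

    seq = contig.sequence
    cid = getattr(contig, "seed_id", None) or getattr(contig, "id", None)
    pool = [p for p in parent_pool if p.id != cid and p.sequence != seq]
    if len(pool) < 2:
        logger.info("chimera check for %s: pool < 2 parents, clean by definition", cid)
        return "clean"
    profiles = {p.id: alignment_profile(seq, p.sequence) for p in pool}
    totals = {
        pid: (m[-1], c[-1]) for pid, (m, c) in profiles.items()
    }
    i1 = max(100.0 * m / c for m, c in totals.values() if c > 0)
    pair_ident: dict[tuple[str, str], float] = {}
    for i, p in enumerate(pool):
        for q in pool[i + 1 :]:
            ident, _ = global_identity(p.sequence, q.sequence)
            pair_ident[(p.id, q.id)] = pair_ident[(q.id, p.id)] = ident
    best_i2 = 0.0
    crossovers = list(range(step, len(seq), step))
    for p in pool:
        mp, cp = profiles[p.id]
        for q in pool:
            if p.id == q.id or pair_ident[(p.id, q.id)] > 100.0 - min_div:
                continue
            mq, cq = profiles[q.id]
            for x in crossovers:
                m2 = mp[x] + (mq[-1] - mq[x])
                c2 = cp[x] + (cq[-1] - cq[x])
                if c2 > 0:
                    best_i2 = max(best_i2, 100.0 * m2 / c2)
    return "flagged" if best_i2 - i1 >= min_improve else "clean"
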