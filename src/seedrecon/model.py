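"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open throughout; the BLAST-dialect hit table
writer converts to 1-based inclusive on output.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> str:
    """Uppercase and map U -> T. Raises on characters outside {A,C,G,T,N,U}."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid sequence characters: {sorted(bad)}")
    return s


@dataclass
class SeqRecord:
    """A named DNA sequence; the carrier for seeds, reads, contigs and truth genes."""

    id: str
    sequence: str
    description: str = ""
    quality: str | None = None  # phred+33 string, carried through but never scored

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"record id must be non-empty and whitespace-free: {self.id!r}")
        self.sequence = normalize_sequence(self.sequence)
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PairedRead:
    """Two mates sharing a pair id; provenance is the simulated genome of origin."""

    id: str
    mate1: SeqRecord
    mate2: SeqRecord
    sample_id: str = ""
    provenance: str | None = None


@dataclass
class OTUTable:
    """OTU x sample count matrix (non-negative integers)."""

    counts: pd.DataFrame  # index: otu ids, columns: sample ids

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise ValueError("OTU table row/column labels must be unique")
        if (df.values < 0).any():
            raise ValueError("OTU table counts must be non-negative")
        self.counts = df.astype(int)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def rel_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances; all-zero samples stay at zero."""
        totals = self.counts.sum(axis=0).replace(0, 1)
        return self.counts / totals


@dataclass
class Seed:
    """An amplicon OTU centroid with per-sample counts and relative abundances."""

    id: str
    sequence: str
    counts: dict[str, int] = field(default_factory=dict)
    rel_abundance: dict[str, float] = field(default_factory=dict)


@dataclass
class AlignmentHit:
    """Best local alignment of one read mate against one seed.

    read_span is on the read's forward (as-sequenced) orientation; seed_span is
    always ascending on the seed. strand '-' means the reverse complement of the
    mate aligned to the seed.
    """

    read_id: str
    mate: int  # 1 or 2
    seed_id: str
    identity: float  # percent, matches / alignment columns (gaps count)
    aln_len: int  # alignment columns
    read_span: tuple[int, int]
    seed_span: tuple[int, int]
    strand: str  # '+' or '-'
    score: float
    mismatches: int = 0
    gap_opens: int = 0


@dataclass
class PairAssignment:
    read_id: str
    sample_id: str
    assigned_seed_id: str | None
    reason: str | None = None  # no_hit | too_many_seeds | geometry_fail when discarded
    matched_seed_ids: frozenset[str] = frozenset()
    tie_break_used: bool = False

    @property
    def assigned(self) -> bool:
        return self.assigned_seed_id is not None


@dataclass
class SeedBin:
    """All read pairs assigned to one seed, pooled over samples."""

    seed_id: str
    pairs: list[PairedRead] = field(default_factory=list)


@dataclass
class ReconstructedSeq:
    seed_id: str
    sequence: str
    length: int
    n_pairs_used: int
    seed_span_in_contig: tuple[int, int]
    status: str  # ok | failed | below_min_len
    chimera: str = "clean"  # clean | flagged
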