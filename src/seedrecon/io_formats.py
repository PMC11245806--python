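"""Readers and writers for every external format the pipeline touches.

FASTA/FASTQ go through Bio.SeqIO (gzip transparently supported); the OTU count
table is a plain TSV handled by pandas; alignment hits use a 12-column
BLAST-outfmt-6-style table. Provenance tags written by the simulator
(" genome=<ID> locus=<copy>") are parsed here.
"""
from __future__ import annotations

import gzip
import io
import re
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import pandas as pd
from Bio import SeqIO

from .model import AlignmentHit, OTUTable, PairedRead, SeqRecord

_PROVENANCE_RE = re.compile(r"(?:^|\s)genome=(\S+)")
_MATE_SUFFIX_RE = re.compile(r"/[12]$")


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def parse_provenance(header: str) -> str | None:
    """Extract the simulator's genome-of-origin tag; None when absent."""
    m = _PROVENANCE_RE.search(header)
    return m.group(1) if m else None


def format_provenance(genome_id: str, locus: int | None = None) -> str:
    tag = f"genome={genome_id}"
    if locus is not None:
        tag += f" locus={locus}"
    return tag


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file; sequences uppercased, U mapped to T."""
    records: list[SeqRecord] = []
    with _open_text(path) as fh:
        first = fh.read(1)
        if first == "":
            return []
        if first != ">":
            raise ValueError(f"{path}: line 1: sequence data before first FASTA header")
        fh.seek(0)
        for rec in SeqIO.parse(fh, "fasta"):
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            records.append(SeqRecord(id=rec.id, sequence=str(rec.seq), description=desc))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[SeqRecord]:
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield SeqRecord(id=rec.id, sequence=str(rec.seq), description=desc, quality=qual)


def pair_id(read_id: str) -> str:
    """Normalize a mate id to its pair id (strip trailing /1 or /2)."""
    return _MATE_SUFFIX_RE.sub("", read_id)


def read_fastq_pair(
    path1: str | Path, path2: str | Path, sample_id: str = ""
) -> Iterator[PairedRead]:
    """Stream read pairs from two FASTQ files (optionally gzipped).

    Mates must pair up in file order after stripping /1, /2 suffixes; a count
    mismatch or an unpairable id raises ValueError.
    """
    it1, it2 = read_fastq(path1), read_fastq(path2)
    n1 = n2 = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            n1 += r1 is not None
            n2 += r2 is not None
            for it in (it1, it2):
                for _ in it:
                    if it is it1:
                        n1 += 1
                    else:
                        n2 += 1
            raise ValueError(
                f"paired FASTQ record count mismatch: {path1} has {n1}, {path2} has {n2}"
            )
        n1 += 1
        n2 += 1
        pid1, pid2 = pair_id(r1.id), pair_id(r2.id)
        if pid1 != pid2:
            raise ValueError(f"unpairable read ids at record {n1}: {r1.id!r} vs {r2.id!r}")
        prov = parse_provenance(r1.description) or parse_provenance(r2.description)
        yield PairedRead(id=pid1, mate1=r1, mate2=r2, sample_id=sample_id, provenance=prov)


def write_fastq_pair(
    pairs: Iterable[PairedRead], path1: str | Path, path2: str | Path
) -> None:
    with _open_text(path1, "wt") as f1, _open_text(path2, "wt") as f2:
        for p in pairs:
            for rec, fh, mate in ((p.mate1, f1, 1), (p.mate2, f2, 2)):
                rid = rec.id if _MATE_SUFFIX_RE.search(rec.id) else f"{p.id}/{mate}"
                header = rid if not rec.description else f"{rid} {rec.description}"
                qual = rec.quality or "I" * len(rec.sequence)
                fh.write(f"@{header}\n{rec.sequence}\n+\n{qual}\n")


def read_otu_table(path: str | Path) -> OTUTable:
    """Read a TSV count table: first column OTU id, remaining columns samples."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    counts = pd.DataFrame(index=df.index.astype(str), columns=df.columns.astype(str), dtype=float)
    for j, col in enumerate(df.columns):
        for i, val in enumerate(df[col]):
            try:
                x = float(val)
                if x < 0 or x != int(x):
                    raise ValueError
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: invalid count {val!r} at OTU {df.index[i]!r}, sample {col!r}"
                ) from None
            counts.iloc[i, j] = x
    return OTUTable(counts=counts.fillna(0).astype(int))


def write_otu_table(table: OTUTable, path: str | Path) -> None:
    table.counts.rename_axis("otu_id").to_csv(path, sep="\t")


_HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def write_hits_table(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits as 12-column BLAST-outfmt-6-style rows, sorted by (read, seed).

    Query coordinates are 1-based inclusive ascending on the read's forward
    orientation; subject coordinates descend for minus-strand hits. evalue is
    written as 0 and bitscore carries the raw alignment score.
    """
    rows = []
    for h in sorted(hits, key=lambda h: (h.read_id, h.mate, h.seed_id)):
        qstart, qend = h.read_span[0] + 1, h.read_span[1]
        if h.strand == "+":
            sstart, send = h.seed_span[0] + 1, h.seed_span[1]
        else:
            sstart, send = h.seed_span[1], h.seed_span[0] + 1
        rows.append(
            f"{h.read_id}/{h.mate}\t{h.seed_id}\t{h.identity:.2f}\t{h.aln_len}\t"
            f"{h.mismatches}\t{h.gap_opens}\t{qstart}\t{qend}\t{sstart}\t{send}\t"
            f"0\t{h.score:g}"
        )
    Path(path).write_text("".join(r + "\n" for r in rows))


def read_hits_table(path: str | Path) -> list[AlignmentHit]:
    hits: list[AlignmentHit] = []
    text = Path(path).read_text()
    for line in io.StringIO(text):
        f = line.rstrip("\n").split("\t")
        if len(f) != 12:
            raise ValueError(f"{path}: expected 12 columns, got {len(f)}")
        qid = f[0]
        mate = 1
        m = _MATE_SUFFIX_RE.search(qid)
        if m:
            mate = int(m.group(0)[1])
            qid = qid[: m.start()]
        sstart, send = int(f[8]), int(f[9])
        if sstart <= send:
            strand, seed_span = "+", (sstart - 1, send)
        else:
            strand, seed_span = "-", (send - 1, sstart)
        hits.append(
            AlignmentHit(
                read_id=qid, mate=mate, seed_id=f[1], identity=float(f[2]),
                aln_len=int(f[3]), read_span=(int(f[6]) - 1, int(f[7])),
                seed_span=seed_span, strand=strand, score=float(f[11]),
                mismatches=int(f[4]), gap_opens=int(f[5]),
            )
        )
    return hits
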