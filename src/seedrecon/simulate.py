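"""Synthetic amplicon + shotgun community simulator with full ground truth.

The simulator emulates a co-sequencing design: a fixed set of bacterial-like
genomes, each carrying 1-3 nearly identical 16S rRNA gene copies embedded in a
random backbone, is sampled under per-sample exponential abundances. Shotgun
samples are 150 bp read pairs drawn genome-proportionally; amplicon samples
are merged ~440 nt V3-V4-like windows excised from the 16S genes. Every read
header carries a ``genome=`` provenance tag so recruitment can be scored
exactly.

The 16S genes are built from one template with alternating conserved blocks
(shared by all genomes) and variable blocks (mutated per genome), so that
inter-genome 16S identities span roughly 85-99% while the amplicon window
still contains enough variable sequence to tell genomes apart.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import format_provenance, write_fasta, write_fastq_pair
from .model import PairedRead, SeqRecord, revcomp

#: Conserved/variable layout of the 1550 nt 16S template. The simulated
#: amplicon window (default 420-860) starts and ends inside conserved blocks,
#: the way real V3-V4 primers sit in conserved regions.
TEMPLATE_SEGMENTS: list[tuple[int, int, str]] = [
    (0, 100, "cons"), (100, 160, "var"), (160, 240, "cons"), (240, 300, "var"),
    (300, 470, "cons"), (470, 540, "var"), (540, 650, "cons"), (650, 740, "var"),
    (740, 880, "cons"), (880, 960, "var"), (960, 1100, "cons"), (1100, 1180, "var"),
    (1180, 1300, "cons"), (1300, 1380, "var"), (1380, 1550, "cons"),
]
TEMPLATE_LEN = TEMPLATE_SEGMENTS[-1][1]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


@dataclass
class SimParams:
    """Study conditions for one simulated dataset.

    Defaults are desk-scale: 20 genomes and 4+4 samples of 50k shotgun pairs
    stand in for a 100-genome, 20+20-sample, 10M-pair design; every knob is
    overridable.
    """

    n_genomes: int = 20
    n_samples_low: int = 4
    n_samples_high: int = 4
    shotgun_read_len: int = 150
    amplicon_read_len: int = 300  # per-mate length of the (virtually merged) amplicon pairs
    n_shotgun_pairs: int = 50_000
    n_amplicon_reads: int = 5_000
    substitution_error_rate: float = 0.005
    indel_error_rate: float = 0.0
    insert_mean: float = 350.0
    insert_sd: float = 40.0
    amplicon_region: tuple[int, int] = (420, 860)
    backbone_len: int = 32_000
    rrna_copies: tuple[int, int] = (1, 3)
    copy_divergence: float = 0.002
    genome_divergence: tuple[float, float] = (0.02, 0.35)
    low_diversity_exponent: float = 3.0
    rng_seed: int = 1

    def validate(self) -> list[str]:
        errs = []
        if self.n_genomes < 2:
            errs.append("n_genomes must be >= 2")
        if self.shotgun_read_len <= 0 or self.amplicon_read_len <= 0:
            errs.append("read lengths must be positive")
        if not (0.0 <= self.substitution_error_rate <= 0.1):
            errs.append("substitution_error_rate must be in [0, 0.1]")
        a, b = self.amplicon_region
        if not (350 <= b - a <= 500):
            errs.append("amplicon window length must be in [350, 500]")
        if b > TEMPLATE_LEN or a < 0:
            errs.append("amplicon window must lie inside the 16S template")
        if self.n_shotgun_pairs < 1:
            errs.append("n_shotgun_pairs must be >= 1")
        if self.backbone_len < 20 * TEMPLATE_LEN:
            errs.append("backbone must be >= 20x the 16S length")
        return errs


@dataclass
class SyntheticGenome:
    id: str
    sequence: str  # full genome, 16S copies embedded verbatim
    rrna_loci: list[tuple[int, str]]  # (position in sequence, gene sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CommunitySim:
    """Genomes + per-sample abundances: the evaluation ground truth."""

    genomes: list[SyntheticGenome]
    abundances: pd.DataFrame  # genome x sample, columns sum to 1
    diversity_mode: dict[str, str]  # sample id -> low | high
    params: SimParams = field(default_factory=SimParams)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundances.columns)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def mutate_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each position independently with the given probability."""
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    idx = np.nonzero(rng.random(arr.size) < rate)[0]
    if idx.size == 0:
        return seq
    cur = _BASE_INDEX[arr[idx]]
    shift = rng.integers(1, 4, size=idx.size)
    arr[idx] = _BASES[(cur + shift) % 4]
    return arr.tobytes().decode()


def _apply_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = []
    for ch in seq:
        r = rng.random()
        if r < rate / 2:
            continue  # deletion
        out.append(ch)
        if r > 1 - rate / 2:
            out.append(_BASES[rng.integers(0, 4)].tobytes().decode())
    return "".join(out)


def _mutate_variable_blocks(template: str, p: float, rng: np.random.Generator) -> str:
    gene = list(template)
    for start, end, kind in TEMPLATE_SEGMENTS:
        if kind != "var":
            continue
        block = mutate_substitutions(template[start:end], p, rng)
        gene[start:end] = block
    return "".join(gene)


def build_genomes(params: SimParams, rng: np.random.Generator) -> list[SyntheticGenome]:
    """Construct the genome set: shared 16S template, per-genome variable blocks.

    Each genome draws a variable-block mutation probability from
    ``genome_divergence``, yielding an inter-genome identity gradient; its 1-3
    16S copies are then derived from the genome gene at ``copy_divergence``
    (>= 99% mutual identity) and embedded at spread-out backbone positions.
    """
    if params.n_genomes < 2:
        raise ValueError("need at least 2 genomes")
    template = _random_seq(rng, TEMPLATE_LEN)
    genomes: list[SyntheticGenome] = []
    lo, hi = params.genome_divergence
    for g in range(params.n_genomes):
        gid = f"G{g + 1:03d}"
        p = rng.uniform(lo, hi)
        gene = _mutate_variable_blocks(template, p, rng)
        n_copies = int(rng.integers(params.rrna_copies[0], params.rrna_copies[1] + 1))
        copies = [mutate_substitutions(gene, params.copy_divergence, rng) for _ in range(n_copies)]
        backbone = _random_seq(rng, params.backbone_len)
        # one insertion point per equal backbone slice keeps loci non-overlapping
        slice_len = params.backbone_len // n_copies
        parts: list[str] = []
        loci: list[tuple[int, str]] = []
        offset = 0
        pos = 0
        for c, copy_seq in enumerate(copies):
            cut = int(rng.integers(c * slice_len + 200, (c + 1) * slice_len - 200))
            parts.append(backbone[offset:cut])
            pos += cut - offset
            loci.append((pos, copy_seq))
            parts.append(copy_seq)
            pos += len(copy_seq)
            offset = cut
        parts.append(backbone[offset:])
        genomes.append(SyntheticGenome(id=gid, sequence="".join(parts), rrna_loci=loci))
    return genomes


def sample_abundances(
    n_genomes: int, diversity_mode: str, rng: np.random.Generator, low_exponent: float = 3.0
) -> np.ndarray:
    """Exponential abundance draws, normalized to sum to 1.

    Low-diversity samples temper the draws by raising them to ``low_exponent``
    before normalizing, so the largest draw dominates; high-diversity samples
    use the raw exponential draws.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    x = rng.exponential(1.0, size=n_genomes)
    if diversity_mode == "low":
        x = x ** low_exponent
    elif diversity_mode != "high":
        raise ValueError(f"unknown diversity mode {diversity_mode!r}")
    return x / x.sum()


def build_community(params: SimParams) -> CommunitySim:
    """Genomes plus per-sample abundance vectors, deterministic in rng_seed."""
    rng = np.random.default_rng([0, params.rng_seed])
    genomes = build_genomes(params, rng)
    sample_ids: list[str] = []
    modes: dict[str, str] = {}
    cols = {}
    ab_rng = np.random.default_rng([1, params.rng_seed])
    for i in range(params.n_samples_low):
        sid = f"L{i + 1:02d}"
        sample_ids.append(sid)
        modes[sid] = "low"
        cols[sid] = sample_abundances(params.n_genomes, "low", ab_rng, params.low_diversity_exponent)
    for i in range(params.n_samples_high):
        sid = f"H{i + 1:02d}"
        sample_ids.append(sid)
        modes[sid] = "high"
        cols[sid] = sample_abundances(params.n_genomes, "high", ab_rng, params.low_diversity_exponent)
    ab = pd.DataFrame(cols, index=[g.id for g in genomes])
    return CommunitySim(genomes=genomes, abundances=ab, diversity_mode=modes, params=params)


def _overlapping_locus(genome: SyntheticGenome, start: int, end: int) -> int | None:
    for i, (pos, seq) in enumerate(genome.rrna_loci, start=1):
        if start < pos + len(seq) and end > pos:
            return i
    return None


def simulate_shotgun(
    community: CommunitySim, sample_id: str, params: SimParams, rng: np.random.Generator
) -> list[PairedRead]:
    """Paired shotgun reads for one sample, genome-of-origin in every header.

    Fragments are drawn genome-proportionally to abundance x genome length;
    insert sizes are normal, truncated at 2*read_len - 20; mate 2 is the
    reverse complement of the fragment's far end.
    """
    if params.n_shotgun_pairs < 1:
        raise ValueError("requested pairs must be >= 1")
    ab = community.abundances[sample_id].to_numpy()
    lens = np.array([len(g) for g in community.genomes], dtype=float)
    w = ab * lens
    w = w / w.sum()
    rl = params.shotgun_read_len
    n = params.n_shotgun_pairs
    gidx = rng.choice(len(w), size=n, p=w)
    inserts = np.maximum(
        np.rint(rng.normal(params.insert_mean, params.insert_sd, size=n)).astype(int),
        2 * rl - 20,
    )
    u = rng.random(n)
    pairs: list[PairedRead] = []
    for i in range(n):
        g = community.genomes[gidx[i]]
        ins = min(int(inserts[i]), len(g))
        start = int(u[i] * (len(g) - ins + 1))
        frag = g.sequence[start : start + ins]
        m1 = frag[:rl]
        m2 = revcomp(frag[-rl:])
        m1 = mutate_substitutions(m1, params.substitution_error_rate, rng)
        m2 = mutate_substitutions(m2, params.substitution_error_rate, rng)
        if params.indel_error_rate > 0:
            m1 = _apply_indels(m1, params.indel_error_rate, rng)
            m2 = _apply_indels(m2, params.indel_error_rate, rng)
        locus = _overlapping_locus(g, start, start + ins)
        desc = format_provenance(g.id, locus)
        pid = f"{sample_id}_{i:06d}"
        pairs.append(
            PairedRead(
                id=pid,
                mate1=SeqRecord(id=f"{pid}/1", sequence=m1, description=desc),
                mate2=SeqRecord(id=f"{pid}/2", sequence=m2, description=desc),
                sample_id=sample_id,
                provenance=g.id,
            )
        )
    return pairs


def simulate_amplicons(
    community: CommunitySim, sample_id: str, params: SimParams, rng: np.random.Generator
) -> list[SeqRecord]:
    """Merged amplicon reads (~440 nt V3-V4-like window) for one sample.

    Each read picks a genome proportional to abundance and one of its 16S
    copies uniformly, excises the amplicon window and applies substitution
    errors. Reads are emitted as already-merged single sequences.
    """
    a, b = params.amplicon_region
    for g in community.genomes:
        for _, seq in g.rrna_loci:
            if b > len(seq):
                raise ValueError(
                    f"amplicon window {params.amplicon_region} exceeds a 16S locus of {g.id}"
                )
    ab = community.abundances[sample_id].to_numpy()
    gidx = rng.choice(len(ab), size=params.n_amplicon_reads, p=ab / ab.sum())
    reads: list[SeqRecord] = []
    for i in range(params.n_amplicon_reads):
        g = community.genomes[gidx[i]]
        locus = int(rng.integers(0, len(g.rrna_loci)))
        window = g.rrna_loci[locus][1][a:b]
        window = mutate_substitutions(window, params.substitution_error_rate, rng)
        reads.append(
            SeqRecord(
                id=f"{sample_id}_a{i:06d}",
                sequence=window,
                description=format_provenance(g.id, locus + 1),
            )
        )
    return reads


def truth_tables(community: CommunitySim) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Truth 16S records (one per locus, genome-tagged) and the abundance table."""
    truth = [
        SeqRecord(
            id=f"{g.id}_L{i}",
            sequence=seq,
            description=format_provenance(g.id, i),
        )
        for g in community.genomes
        for i, (_, seq) in enumerate(g.rrna_loci, start=1)
    ]
    return truth, community.abundances.copy()


def simulate_dataset(params: SimParams, outdir: str | Path) -> dict[str, Path]:
    """Run the full simulation and write FASTQ/FASTA/TSV outputs.

    Per sample: ``<sid>_R1.fastq``/``<sid>_R2.fastq`` shotgun pairs and
    ``<sid>_amplicons.fastq``. Plus ``truth_16s.fasta``, ``abundances.tsv``
    and ``samples.tsv`` (sample id, diversity mode). Byte-deterministic for a
    fixed rng_seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    community = build_community(params)
    files: dict[str, Path] = {}
    for k, sid in enumerate(community.sample_ids):
        rng = np.random.default_rng([2, k, params.rng_seed])
        pairs = simulate_shotgun(community, sid, params, rng)
        r1, r2 = outdir / f"{sid}_R1.fastq", outdir / f"{sid}_R2.fastq"
        write_fastq_pair(pairs, r1, r2)
        files[f"shotgun_{sid}_R1"], files[f"shotgun_{sid}_R2"] = r1, r2
        arng = np.random.default_rng([3, k, params.rng_seed])
        amps = simulate_amplicons(community, sid, params, arng)
        af = outdir / f"{sid}_amplicons.fastq"
        with open(af, "w") as fh:
            for rec in amps:
                fh.write(f"@{rec.id} {rec.description}\n{rec.sequence}\n+\n{'I' * len(rec.sequence)}\n")
        files[f"amplicons_{sid}"] = af
    truth, ab = truth_tables(community)
    tf = outdir / "truth_16s.fasta"
    write_fasta(truth, tf)
    files["truth_16s"] = tf
    abf = outdir / "abundances.tsv"
    ab.rename_axis("genome_id").to_csv(abf, sep="\t")
    files["abundances"] = abf
    sf = outdir / "samples.tsv"
    pd.DataFrame(
        {"sample_id": community.sample_ids,
         "diversity": [community.diversity_mode[s] for s in community.sample_ids]}
    ).to_csv(sf, sep="\t", index=False)
    files["samples"] = sf
    return files
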