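# Methods

This note documents the models, algorithms and defaults implemented in
`seedrecon`, the assumptions behind them, and what the synthetic-data tests
do and do not demonstrate about real data.

## Identity definitions

One identity definition is used throughout: **matches / alignment columns**,
with gap columns counting as mismatches. Three alignment modes apply it:

- **Global** (edlib, Needleman–Wunsch): OTU clustering and parent-pair
  divergence in the chimera check.
- **Semiglobal / infix** (edlib HW): the shorter sequence is consumed
  entirely, dangling ends of the longer are free. Used for seed-to-truth
  mapping, contig-to-truth success scoring (the vsearch-style ≥ 99% rule) and
  the chimera profiles.
- **Best local** (Bio.Align.PairwiseAligner; match +2, mismatch −3, gap open
  −5, gap extend −2): read recruitment and reference novelty filtering. One
  affine scheme is used everywhere and is configurable only in code; the
  method's filters act on identity and geometry, not on scores.

## Seeds

Greedy centroid clustering at 99% identity: exact duplicates are
dereplicated, unique sequences sorted by total count (descending, ties
lexicographic), and each sequence joins the first centroid at ≥ 99% global
identity, else founds a new OTU. The procedure is deterministic and
permutation-invariant. 99% is a deliberate compromise: wide enough to absorb
the slightly divergent 16S copies within one genome, narrow enough to keep
distinct species apart.

OTUs are ranked by their **maximum** per-sample relative abundance (the
statistic can be switched to the mean via configuration). Sample selection
walks the ranked OTU list and collects each OTU's peak-abundance sample into
an ordered set until *n* samples are reached; this guarantees every selected
sample contains at least one highly abundant seed. Ties (equal abundance,
equal peak) break lexicographically by id so results are reproducible.
Seeds outside 150–600 nt are excluded as non-amplicon artefacts. Novelty
filtering against a reference FASTA can run before or after top-K selection
(`filter_order`); the default filters first.

## Recruitment

Parameters (defaults): minimum identity **98%**, multiplicity cap **m = 3**,
minimum alignment length **50 nt**, seed-terminus tolerance **δ = 5 nt**,
read-coverage tolerance **ε = 5 nt**, prefilter k-mer **13**.

The exact k-mer prefilter skips mate–seed combinations sharing no 13-mer on
either strand. At the default threshold a 150 nt mate at ≥ 98% identity has
at most 3 mismatches, so by pigeonhole it shares an exact ⌈150/4⌉ > 13-mer
with the seed; the shortest admissible hit (50 nt, ≤ 1 mismatch) still
guarantees a shared 17-mer. The prefilter is therefore lossless at defaults
(verified against exhaustive alignment in the tests) and can be disabled.

**Geometry rule.** A hit passes iff (a) the alignment covers the whole read
up to ε, or (b) it abuts a seed terminus (within δ) and every unaligned read
end longer than ε hangs off that terminus — i.e. would extend *beyond* the
seed, never into its interior. Internal partial alignments are how
conserved-region reads from foreign taxa look, and are rejected.

**Assignment.** Multiplicity is counted per *pair*: the union of both mates'
geometry-passing seeds. Pairs matching more than m seeds are discarded;
otherwise the pair goes to the matched seed with the highest amplicon
relative abundance in the pair's own sample (absent seeds count as 0; ties
break by seed id). All geometry-passing matches compete in this tie-break
regardless of small score differences — the rationale is probabilistic (the
read more likely originates from the more abundant taxon), not score-based.
Every input pair ends in exactly one state: assigned, or discarded with
reason `no_hit`, `geometry_fail` or `too_many_seeds`; per-stage counters make
this conservation visible in the logs.

Threshold sweeps reuse one alignment pass at the lowest threshold and filter,
which is exact because thresholds only filter the best-scoring alignments.

## Seeded assembly

The built-in assembler is a greedy consensus extender, chosen so the package
is self-contained and verifiable offline; any competent seeded assembler can
replace it through the `external_assembler` hook (a command template that
receives the bin and the seed as a trusted contig). Defaults: anchor k-mer
**31**, minimum extension support **min_cov = 3**, branch ratio **3.0**,
contig cap **1700 nt**, report length **≥ 800 nt** (inclusive; > 50% of the
full gene).

Each round, every mate (both orientations) is anchored to the current contig
by exact 31-mer offset votes and verified by a gapless overlap comparison
(≤ 5% mismatches) — gapless because the default error model is
substitution-only. Each flank then grows base by base from the majority base
among overhanging reads, requiring support ≥ min_cov and a
dominant/secondary ratio ≥ branch_ratio. Extension halts on ambiguity rather
than forking: a truncated contig is preferred to a mosaic, which is the
characteristic failure mode of 16S assembly. Because placement is re-run
against the grown contig every round, a pair whose second mate lies beyond
the current contig is picked up as soon as the contig reaches it (paired
rescue). Assembly is deterministic given the bin order and never raises on
hard inputs; an empty or underpowered bin returns `failed` with length 0.

A consequence of halting on ambiguity: genomes whose multiple 16S copies
disagree at a few positions can stop extension early when both variants are
well supported. This is intentional conservatism; the reported contig is
still pure.

## Chimera check

A simplified two-parent, single-crossover model (uchime-inspired; it does
**not** replicate VSEARCH verdicts). For a contig and a parent pool, per-
parent profiles record cumulative matches and columns by contig position,
computed by semiglobal placement — the shorter of contig/parent aligned as an
infix of the longer — so a parent covering only part of the contig
contributes only over its span and dangling ends are free. The best
single-parent identity I1 is compared with the best chimeric identity I2 over
all ordered parent pairs at most 97% mutually identical and all crossovers on
a 10 nt grid; the contig is flagged iff I2 − I1 ≥ 2 points. Pools with fewer
than two parents (after excluding the contig itself) are clean by definition.
In the pipeline the parent pool is the **seed set**: seeds share the amplicon
window, so their spans on a contig are comparable, whereas contig-vs-contig
pools compare disjoint genomic extents and are uninformative under a single
crossover.

## The simulator

The simulator emulates a paired amplicon + shotgun co-sequencing design on a
mock community, at desk scale (defaults: 20 genomes, 4 low- + 4 high-
diversity samples, 50k shotgun pairs and 5k amplicons per sample; the
original design this stands in for used 100 genomes, 20 + 20 samples and 10M
pairs — all knobs are overridable).

- **16S genes**: one 1550 nt template with alternating conserved blocks
  (shared by all genomes) and variable blocks, mutated per genome at a
  probability drawn from `genome_divergence` (default 0.02–0.35), giving
  inter-genome identities spanning roughly 85–99%. Each genome carries 1–3
  copies at 99%+ mutual identity (`copy_divergence` 0.002), embedded in a
  32 kb random backbone so most shotgun reads are non-16S. The amplicon
  window (420–860, 440 nt) starts and ends inside conserved blocks, the way
  real V3–V4 primers sit in conserved regions.
- **Abundances**: i.i.d. exponential draws per sample, normalized.
  Low-diversity samples raise the draws to the power 3 before normalizing
  (one genome dominates); high-diversity samples use the raw draws. The same
  vector drives both the amplicon and the shotgun sample.
- **Shotgun reads**: 150 nt pairs; fragments drawn proportional to
  abundance × genome length; insert ~ Normal(350, 40) truncated at 280;
  mate 2 reverse-complemented; i.i.d. substitution errors (default 0.5%,
  indels default off). Every header carries `genome=<id>` (and `locus=<copy>`
  when the fragment overlaps an rRNA locus), which is what makes exact
  correct/incorrect recruitment scoring possible.
- **Amplicons**: emitted as already-merged single 440 nt window sequences
  (paired-amplicon merging is not re-implemented; the pipeline consumes OTU
  centroids, not raw amplicon pairs).

**What passing tests show — and don't.** The simulator has no quality-score
model, no PCR chimeras, no indel-rich error profile, and its inter-genome
divergence is block-uniform rather than phylogenetically structured. Tests on
it demonstrate the *logic* of recruitment and seeded assembly — separability,
threshold behaviour, coverage-to-length scaling, conservation — not
performance on real environmental data, where diversity is far higher and
taxa absent from the seed set contribute confounding reads.

## Evaluation

A seed maps to its source genome by semiglobal alignment into the truth 16S
set at ≥ 99% identity; ambiguous seeds (best identity tied between genomes)
are excluded and counted. A recruited pair is **correct** iff its provenance
tag equals the assigned seed's genome — genome-level, so recruitment across
16S copies of one genome counts as correct. Reconstruction **success** is
end-gap-free identity ≥ 99% to some truth gene, deliberately distinct from
the local identity used during recruitment.

## Numerical and degenerate-input choices

- All ties (sort orders, argmax samples, tie-broken seeds, base calls) break
  lexicographically or by first occurrence; identical inputs give identical
  outputs, and the pipeline manifest (config hash + output checksums, no
  timestamps) makes this checkable end to end.
- Identity comparisons use a 1e-9 slack so 98.0 passes a 98% threshold.
- Empty reference ⇒ all seeds novel; empty bins ⇒ `failed` contigs; empty
  threshold lists ⇒ empty reports; absent abundance ⇒ 0 in the tie-break.
- Acceptance-scale runs use 10–20 genomes, 2–6 samples and 4–6k pairs per
  sample: large enough for the recruitment statistics to stabilize (the
  incorrect-pair fraction at m = 3 sits well below 1% at this size), small
  enough for minutes-scale runtimes.

## Known limitations

- The consensus extender is substitution-only; indel-rich reads (set
  `indel_error_rate` > 0) truncate extension early rather than misassemble.
- Recruitment aligns raw reads; no quality filtering is applied (quality
  strings are carried through but never used). This assumes upstream
  preprocessing where needed.
- The chimera model detects single-crossover PCR-style chimeras between
  sufficiently divergent parents; intermixed multi-segment mosaics are out of
  its reach, which is precisely why the pipeline prevents them upstream
  (geometry rule, multiplicity cap, branch halting) rather than detecting
  them downstream.
- `external_assembler` is provided but exercised only for its error paths in
  the test suite; validating a specific external tool is the user's task.
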