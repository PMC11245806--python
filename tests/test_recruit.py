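"""Read recruitment: alignment, geometry rule, pair assignment, sweeps, binning."""
from __future__ import annotations

from collections import defaultdict

import numpy as np
import pytest

from seedrecon.model import AlignmentHit, PairedRead, Seed, SeqRecord, revcomp
from seedrecon.recruit import (
    RecruitParams,
    align_to_seeds,
    assign_pairs,
    bin_pairs,
    filter_geometry,
    geometry_pass,
    recruit_sample,
    sweep_identity,
    sweep_multiplicity,
)


def _pair(pid, m1, m2, sample=""):
    return PairedRead(id=pid, mate1=SeqRecord(f"{pid}/1", m1),
                      mate2=SeqRecord(f"{pid}/2", m2), sample_id=sample)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture()
def two_seeds(rng):
    return [Seed(id="OTU_0001", sequence=_random_seq(rng, 440)),
            Seed(id="OTU_0002", sequence=_random_seq(rng, 440))]


class TestAlign:
    def test_exact_substring_hit(self, two_seeds, rng):
        seed = two_seeds[0]
        read = seed.sequence[100:250]
        pairs = [_pair("p1", read, revcomp(seed.sequence[250:400]))]
        hits = align_to_seeds(pairs, two_seeds)
        h1 = [h for h in hits if h.mate == 1][0]
        assert h1.identity == 100.0 and h1.aln_len == 150
        assert h1.seed_span == (100, 250) and h1.strand == "+"
        h2 = [h for h in hits if h.mate == 2][0]
        assert h2.strand == "-" and h2.seed_span == (250, 400)

    def test_three_substitutions_is_98(self, two_seeds, rng):
        seed = two_seeds[0]
        read = list(seed.sequence[100:250])
        for p in (10, 70, 130):
            read[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[p]]
        pairs = [_pair("p1", "".join(read), revcomp(seed.sequence[250:400]))]
        hits = align_to_seeds(pairs, two_seeds, RecruitParams(min_identity=98.0))
        h1 = [h for h in hits if h.mate == 1][0]
        assert h1.identity == pytest.approx(98.0, abs=0.01)

    def test_prefilter_equals_exhaustive(self, small_community, rng):
        """k-mer prefilter loses no geometry-relevant hits at default thresholds."""
        from seedrecon.simulate import simulate_shotgun

        com = small_community
        a, b = com.params.amplicon_region
        seeds = [Seed(id=f"S{i}", sequence=g.rrna_loci[0][1][a:b])
                 for i, g in enumerate(com.genomes)]
        pairs = simulate_shotgun(com, "H01", com.params, rng)[:200]
        on = align_to_seeds(pairs, seeds, RecruitParams(prefilter_k=13))
        off = align_to_seeds(pairs, seeds, RecruitParams(prefilter_k=0))
        key = lambda h: (h.read_id, h.mate, h.seed_id, h.read_span, h.seed_span, h.strand)
        assert sorted(map(key, on)) == sorted(map(key, off))


class TestGeometry:
    def _hit(self, read_span, seed_span, strand="+"):
        return AlignmentHit("p", 1, "s", 100.0, read_span[1] - read_span[0],
                            read_span, seed_span, strand, 300.0)

    def test_full_read_mid_seed(self):
        assert geometry_pass(self._hit((0, 150), (100, 250)), 150, 440)

    def test_overhang_at_seed_end(self):
        # 90 nt aligned reaching the seed's 3' end, 60 nt hanging beyond it
        assert geometry_pass(self._hit((0, 90), (350, 440)), 150, 440)

    def test_internal_partial_rejected(self):
        # alignment stops 40 nt short of the read end inside the seed interior
        assert not geometry_pass(self._hit((40, 110), (150, 220)), 150, 440)

    def test_overhang_on_wrong_side_rejected(self):
        # unaligned suffix would extend INTO the seed, not off its end
        assert not geometry_pass(self._hit((0, 90), (0, 90)), 150, 440)

    def test_minus_strand_orientation(self):
        # forward-orientation prefix unaligned; on '-' it hangs off the seed 3' end
        assert geometry_pass(self._hit((60, 150), (350, 440), strand="-"), 150, 440)
        assert not geometry_pass(self._hit((60, 150), (0, 90), strand="-"), 150, 440)


class TestAssign:
    def _mkhit(self, pid, seed_id, mate=1):
        return AlignmentHit(pid, mate, seed_id, 100.0, 150, (0, 150), (0, 150), "+", 300.0)

    def test_abundance_tie_break(self):
        hits = [self._mkhit("p1", "A", 1), self._mkhit("p1", "B", 2)]
        out = assign_pairs(hits, "s1", {"A": 0.04, "B": 0.01})
        assert out[0].assigned_seed_id == "A" and out[0].tie_break_used

    def test_too_many_seeds_discarded(self):
        hits = [self._mkhit("p1", s) for s in "ABCD"]
        out = assign_pairs(hits, "s1", {}, RecruitParams(max_matches=3))
        assert out[0].reason == "too_many_seeds" and not out[0].assigned

    def test_equal_abundance_lexicographic(self):
        hits = [self._mkhit("p1", "B"), self._mkhit("p1", "A")]
        out = assign_pairs(hits, "s1", {"A": 0.0, "B": 0.0})
        assert out[0].assigned_seed_id == "A"

    def test_matches_brute_force_oracle(self, rng):
        seeds = list("ABCDEF")
        abundance = {s: float(np.round(rng.random(), 3)) for s in seeds}
        hits, truth = [], {}
        for i in range(50):
            pid = f"p{i:02d}"
            k = int(rng.integers(1, 6))
            chosen = sorted(rng.choice(seeds, size=k, replace=False))
            for s in chosen:
                hits.append(self._mkhit(pid, s, mate=int(rng.integers(1, 3))))
            if k > 3:
                truth[pid] = None
            else:
                truth[pid] = max(chosen, key=lambda s: (abundance[s], [-ord(c) for c in s]))
        out = {a.read_id: a for a in assign_pairs(hits, "s1", abundance, RecruitParams(max_matches=3))}
        for pid, expected in truth.items():
            assert out[pid].assigned_seed_id == expected

    def test_conservation(self, small_community, rng):
        """Every pair is assigned or discarded with exactly one reason."""
        from seedrecon.simulate import simulate_shotgun

        com = small_community
        a, b = com.params.amplicon_region
        seeds = [Seed(id=f"S{i}", sequence=g.rrna_loci[0][1][a:b],
                      rel_abundance={"L01": float(x)})
                 for i, (g, x) in enumerate(zip(com.genomes, com.abundances["L01"]))]
        pairs = simulate_shotgun(com, "L01", com.params, rng)[:400]
        assignments, _ = recruit_sample(pairs, seeds, "L01")
        assert len(assignments) == len(pairs)
        for a_ in assignments:
            assert a_.assigned != (a_.reason is not None)


class TestSweeps:
    def test_exact_reads_same_at_99_and_100(self, two_seeds):
        """Error-free reads taken verbatim from seeds align at exactly 100%."""
        reads = [
            _pair(f"p{i}", two_seeds[i % 2].sequence[i : i + 150],
                  revcomp(two_seeds[i % 2].sequence[200 + i : 350 + i]))
            for i in range(10)
        ]
        df = sweep_identity(reads, two_seeds, [99.0, 100.0], "s1")
        assert df.n_hits.iloc[0] == df.n_hits.iloc[1]
        assert df.n_assigned.iloc[0] == df.n_assigned.iloc[1]

    def test_empty_thresholds(self, two_seeds):
        assert sweep_identity([], two_seeds, [], "s1").empty

    def test_hit_counts_non_increasing(self, small_community, rng):
        from seedrecon.simulate import SimParams, build_community, simulate_shotgun
        import dataclasses

        params = dataclasses.replace(small_community.params, substitution_error_rate=0.01)
        com = build_community(params)
        a, b = params.amplicon_region
        seeds = [Seed(id=f"S{i}", sequence=g.rrna_loci[0][1][a:b])
                 for i, g in enumerate(com.genomes)]
        pairs = simulate_shotgun(com, "H01", params, rng)[:500]
        df = sweep_identity(pairs, seeds, [95, 96, 97, 98, 99, 100], "H01")
        assert (np.diff(df.n_hits.to_numpy()) <= 0).all()

    def test_multiplicity_counts_match_recount(self, rng):
        mk = lambda pid, sid: AlignmentHit(pid, 1, sid, 100.0, 150, (0, 150), (0, 150), "+", 300.0)
        seeds = list("ABCDE")
        hits = []
        matched = defaultdict(set)
        for i in range(100):
            pid = f"p{i:03d}"
            for s in rng.choice(seeds, size=int(rng.integers(1, 6)), replace=False):
                hits.append(mk(pid, s))
                matched[pid].add(s)
        ab = {s: float(rng.random()) for s in seeds}
        df = sweep_multiplicity(hits, "s1", ab, m_values=range(1, 11))
        for _, row in df.iterrows():
            expected = sum(1 for ss in matched.values() if len(ss) <= row["m"])
            assert row["n_assigned"] == expected
        assert (np.diff(df.n_assigned.to_numpy()) >= 0).all()

    def test_m1_discards_multi_match(self):
        mk = lambda pid, sid: AlignmentHit(pid, 1, sid, 100.0, 150, (0, 150), (0, 150), "+", 300.0)
        hits = [mk("p1", "A"), mk("p1", "B"), mk("p2", "A")]
        df = sweep_multiplicity(hits, "s1", {"A": 0.1, "B": 0.2}, m_values=[1, 2])
        assert df.n_assigned.tolist() == [1, 2]


class TestBins:
    def test_same_pair_id_in_two_samples(self):
        p = _pair("p1", "ACGT" * 40, "TTTT" * 40)
        assigns = {
            "s1": [type("A", (), {"assigned": True, "assigned_seed_id": "X", "read_id": "p1"})()],
            "s2": [type("A", (), {"assigned": True, "assigned_seed_id": "X", "read_id": "p1"})()],
        }
        bins = bin_pairs(assigns, {"s1": {"p1": p}, "s2": {"p1": p}})
        assert len(bins) == 1 and len(bins[0].pairs) == 2
        assert {q.id for q in bins[0].pairs} == {"s1:p1", "s2:p1"}

    def test_binned_equals_assigned(self, small_community, rng):
        from seedrecon.simulate import simulate_shotgun

        com = small_community
        a, b = com.params.amplicon_region
        seeds = [Seed(id=f"S{i}", sequence=g.rrna_loci[0][1][a:b])
                 for i, g in enumerate(com.genomes)]
        assigns_by, pairs_by = {}, {}
        for sid in com.sample_ids:
            pairs = simulate_shotgun(com, sid, com.params, rng)[:300]
            assigns, _ = recruit_sample(pairs, seeds, sid)
            assigns_by[sid] = assigns
            pairs_by[sid] = {p.id: p for p in pairs}
        bins = bin_pairs(assigns_by, pairs_by)
        total_assigned = sum(a.assigned for alist in assigns_by.values() for a in alist)
        assert sum(len(b.pairs) for b in bins) == total_assigned
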