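"""OTU clustering, novelty filtering and the sample/seed selection walk."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from seedrecon.alignment import global_identity
from seedrecon.model import OTUTable, Seed, SeqRecord
from seedrecon.seeds import (
    cluster_otus,
    filter_known,
    filter_length,
    rank_otus,
    select_samples,
    select_seeds,
)


def _mutate(seq, positions, rng):
    bases = "ACGT"
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in bases if b != out[p]])
    return "".join(out)


class TestClusterOtus:
    def test_identical_sequences_one_otu(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        seeds, table = cluster_otus([("s1", SeqRecord("a", seq)),
                                     ("s1", SeqRecord("b", seq)),
                                     ("s2", SeqRecord("c", seq))])
        assert len(seeds) == 1
        assert table.counts.values.sum() == 3
        assert seeds[0].counts == {"s1": 2, "s2": 1}

    def test_divergent_sequences_two_otus(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        other = _mutate(seq, rng.choice(300, size=15, replace=False), rng)  # ~95%
        seeds, _ = cluster_otus([("s1", SeqRecord("a", seq)), ("s1", SeqRecord("b", other))])
        assert len(seeds) == 2

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            cluster_otus([])

    def _random_fixture(self, rng, n=30):
        """Members mutated <=0.5% from 4 prototypes that are ~5% divergent."""
        L = 400
        base = "".join(rng.choice(list("ACGT"), size=L))
        protos = [base] + [
            _mutate(base, rng.choice(L, size=20 + 5 * i, replace=False), rng)
            for i in range(1, 4)
        ]
        amplicons = []
        for i in range(n):
            proto = protos[int(rng.integers(0, 4))]
            seq = _mutate(proto, rng.choice(L, size=int(rng.integers(0, 3)), replace=False), rng)
            amplicons.append((f"s{int(rng.integers(1, 4))}", SeqRecord(f"r{i}", seq)))
        return amplicons

    def _oracle_partition(self, amplicons, threshold=99.0):
        """Brute-force greedy scan with Hamming identity (equal-length,
        substitution-only fixture makes Hamming the exact global identity)."""
        counts = {}
        for sample, rec in amplicons:
            counts.setdefault(rec.sequence, {}).setdefault(sample, 0)
            counts[rec.sequence][sample] += 1
        order = sorted(counts, key=lambda s: (-sum(counts[s].values()), s))
        centroids, assign = [], {}
        for seq in order:
            for c in centroids:
                ident = 100.0 * sum(a == b for a, b in zip(seq, c)) / len(seq)
                if ident >= threshold:
                    assign[seq] = c
                    break
            else:
                centroids.append(seq)
                assign[seq] = seq
        return centroids, assign

    def test_matches_brute_force_oracle(self, rng):
        amplicons = self._random_fixture(rng)
        seeds, table = cluster_otus(amplicons, 0.99)
        centroids, assign = self._oracle_partition(amplicons)
        assert [s.sequence for s in seeds] == centroids
        # aggregate oracle counts per centroid and compare
        agg = {c: 0 for c in centroids}
        for (sample, rec) in amplicons:
            agg[assign[rec.sequence]] += 1
        for s in seeds:
            assert sum(s.counts.values()) == agg[s.sequence]

    def test_members_within_radius_of_centroid(self, rng):
        amplicons = self._random_fixture(rng)
        seeds, _ = cluster_otus(amplicons, 0.99)
        _, assign = self._oracle_partition(amplicons)
        for seq, cent in assign.items():
            ident, _ = global_identity(seq, cent)
            assert ident >= 99.0

    def test_permutation_invariance(self, rng):
        amplicons = self._random_fixture(rng)
        seeds1, t1 = cluster_otus(amplicons, 0.99)
        shuffled = list(amplicons)
        rng.shuffle(shuffled)
        seeds2, t2 = cluster_otus(shuffled, 0.99)
        assert [s.sequence for s in seeds1] == [s.sequence for s in seeds2]
        assert t1.counts.equals(t2.counts)

    def test_simulated_amplicons_recover_genomes(self, small_community, rng):
        """Zero-error amplicons cluster into one OTU per sampled genome."""
        from seedrecon.io_formats import parse_provenance
        from seedrecon.simulate import simulate_amplicons

        com = small_community
        amp, genomes_seen = [], set()
        for sid in com.sample_ids:
            for rec in simulate_amplicons(com, sid, com.params, rng):
                amp.append((sid, rec))
                genomes_seen.add(parse_provenance(rec.description))
        seeds, _ = cluster_otus(amp, 0.99)
        assert len(seeds) == len(genomes_seen)


class TestFilterKnown:
    def test_reference_substring_is_known(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=1500))
        seed = Seed(id="s", sequence=ref[420:860])
        novel, known = filter_known([seed], [SeqRecord("ref1", ref)])
        assert novel == [] and known[0][1] == "ref1"

    def test_empty_reference_all_novel(self):
        seed = Seed(id="s", sequence="ACGT" * 100)
        novel, known = filter_known([seed], [])
        assert [s.id for s in novel] == ["s"] and known == []

    def test_below_threshold_is_novel(self, rng):
        """A seed ~1.5% diverged from its best reference stays novel at 99%."""
        ref = "".join(rng.choice(list("ACGT"), size=1500))
        window = ref[420:860]
        mutated = _mutate(window, rng.choice(len(window), size=7, replace=False), rng)
        novel, known = filter_known([Seed(id="s", sequence=mutated)], [SeqRecord("ref1", ref)])
        assert [s.id for s in novel] == ["s"]


class TestSelection:
    def _table(self, counts, otus=None, samples=None):
        otus = otus or [f"OTU_{i + 1:04d}" for i in range(len(counts))]
        samples = samples or [f"s{j + 1}" for j in range(len(counts[0]))]
        return OTUTable(counts=pd.DataFrame(counts, index=otus, columns=samples))

    def test_top_otus_peaking_in_same_sample(self):
        # columns sum to 100, so counts read as relative abundances: the two
        # top-ranked OTUs (C .50, A .45) both peak in s1; the n=2 walk must
        # continue to B's peak sample s3
        t = self._table(
            [[45, 40, 35], [5, 35, 45], [50, 25, 20]],
            otus=["A", "B", "C"], samples=["s1", "s2", "s3"],
        )
        assert select_samples(t, 2) == ["s1", "s3"]

    def test_n_equals_sample_count(self):
        t = self._table([[5, 1], [1, 5]])
        assert sorted(select_samples(t, 2)) == ["s1", "s2"]

    def test_n_too_large_errors(self):
        t = self._table([[5, 1]])
        with pytest.raises(ValueError):
            select_samples(t, 3)

    def test_walk_matches_brute_force(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 50, size=(5, 4))
            counts[0, :] = np.maximum(counts[0, :], 1)  # keep column sums > 0
            t = self._table(counts.tolist())
            n = int(rng.integers(1, 5))
            # oracle: explicit walk over the ranked OTU list
            rel = t.rel_abundance()
            ranked = sorted(t.otu_ids, key=lambda o: (-rel.loc[o].max(), o))
            expected: list[str] = []
            for o in ranked:
                row = rel.loc[o]
                argmax = min(s for s in t.sample_ids if row[s] == row.max())
                if argmax not in expected:
                    expected.append(argmax)
                if len(expected) == n:
                    break
            for s in sorted(t.sample_ids):
                if len(expected) == n:
                    break
                if s not in expected:
                    expected.append(s)
            assert select_samples(t, n) == expected

    def test_select_seeds_sort_oracle(self, rng):
        counts = rng.integers(0, 100, size=(20, 4))
        counts[:, 0] += 1
        t = self._table(counts.tolist())
        seeds = [Seed(id=o, sequence="A" * 400) for o in t.otu_ids]
        chosen = select_seeds(seeds, t, t.sample_ids, top_k=10)
        rel = t.rel_abundance()
        total = t.counts.sum(axis=1)
        expected = sorted(t.otu_ids, key=lambda o: (-rel.loc[o].max(), -total[o], o))[:10]
        assert [s.id for s in chosen] == expected

    def test_top_k_larger_than_pool(self):
        t = self._table([[5, 1], [1, 5]])
        seeds = [Seed(id=o, sequence="A" * 400) for o in t.otu_ids]
        assert len(select_seeds(seeds, t, t.sample_ids, top_k=100)) == 2

    def test_abundance_orders_seeds(self):
        t = self._table([[10, 0], [5, 0], [100, 100]],
                        otus=["A", "B", "C"], samples=["s1", "s2"])
        seeds = [Seed(id=o, sequence="A" * 400) for o in t.otu_ids]
        chosen = select_seeds(seeds, t, ["s1", "s2"], top_k=3)
        assert [s.id for s in chosen] == ["C", "A", "B"]

    def test_length_bounds(self):
        seeds = [Seed(id="ok", sequence="A" * 400), Seed(id="short", sequence="A" * 50)]
        assert [s.id for s in filter_length(seeds)] == ["ok"]
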