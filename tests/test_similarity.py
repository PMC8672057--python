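"""Greedy clustering and the similarity network."""

import numpy as np
import pytest

import networkx  # noqa: F401  (transitive-closure oracle uses plain sets)

from mitocomp.annotation_io import SequenceRecord, reverse_complement
from mitocomp.similarity import (
    SimilarityEdge,
    build_network,
    components,
    greedy_cluster,
)
from mitocomp.synthetic_data import GeneratorConfig, plant_families

from conftest import random_dna


def _records(rng, n, length=800):
    return [SequenceRecord(f"g{i}", random_dna(rng, length)) for i in range(n)]


class TestGreedyCluster:
    def test_distinct_genomes_all_singletons(self, rng):
        recs = _records(rng, 6)
        clusters = greedy_cluster(recs, 0.90)
        assert len(clusters) == 6
        assert all(not c.members for c in clusters)

    def test_exact_duplicate_absorbed_at_threshold_one(self, rng):
        recs = _records(rng, 4)
        dup = SequenceRecord("g0dup", recs[0].seq)
        clusters = greedy_cluster(recs + [dup], threshold=1.0)
        assert len(clusters) == 4
        sizes = sorted(c.size for c in clusters)
        assert sizes == [1, 1, 1, 2]

    def test_partition_property(self, rng):
        recs = _records(rng, 8, length=600)
        clusters = greedy_cluster(recs, 0.90)
        seen = [gid for c in clusters for gid in c.ids]
        assert sorted(seen) == sorted(r.id for r in recs)

    def test_representative_is_longest_member(self, rng):
        base = random_dna(rng, 1000)
        recs = [
            SequenceRecord("short", base[:900]),
            SequenceRecord("long", base),
        ]
        (cluster,) = greedy_cluster(recs, 0.90)
        assert cluster.representative == "long"

    def test_planted_families_recovered(self):
        cfg = GeneratorConfig(
            seed=5,
            family_structure=[(3, 0.95)] * 5,
            length_median=5000,
            length_sigma=0.3,
            length_max=8000,
        )
        records, truth = plant_families(cfg)
        clusters = greedy_cluster(records, 0.90)
        got = {frozenset(c.ids) for c in clusters}
        want = {}
        for gid, fam in truth.family_of.items():
            want.setdefault(fam, set()).add(gid)
        assert got == {frozenset(v) for v in want.values()}

    def test_low_identity_families_stay_singletons(self):
        cfg = GeneratorConfig(
            seed=6,
            family_structure=[(3, 0.5)] * 3,
            length_median=5000,
            length_sigma=0.3,
            length_max=8000,
        )
        records, _ = plant_families(cfg)
        clusters = greedy_cluster(records, 0.90)
        assert len(clusters) == len(records)

    def test_threshold_sweep_monotone(self):
        cfg = GeneratorConfig(
            seed=9,
            family_structure=[(3, 0.95)] * 4,
            length_median=4500,
            length_sigma=0.25,
            length_max=7000,
        )
        records, _ = plant_families(cfg)
        counts = [len(greedy_cluster(records, t)) for t in (0.70, 0.90, 0.99)]
        assert counts[0] <= counts[1] <= counts[2]


class TestNetwork:
    def test_longest_alignment_rule_on_constructed_pair(self, rng):
        seg_long, seg_short = random_dna(rng, 300), random_dna(rng, 120)
        deg = list(seg_long)
        for pos in rng.choice(300, size=36, replace=False):
            deg[pos] = "ACGT"[("ACGT".index(deg[pos]) + 1) % 4]
        a = random_dna(rng, 700) + seg_long + random_dna(rng, 900) + seg_short + random_dna(rng, 600)
        b = random_dna(rng, 500) + "".join(deg) + random_dna(rng, 800) + seg_short + random_dna(rng, 400)
        (edge,) = build_network(
            [SequenceRecord("A", a), SequenceRecord("B", b)], min_hsp_len=100
        )
        # the edge carries the long degraded segment, not the short
        # perfect one with its higher identity
        assert edge.hsp_len > 200
        assert edge.identity < 0.95

    def test_no_shared_seeds_no_edge(self, rng):
        a = "AC" * 2000
        b = "TG" * 2000  # revcomp of b is CA-repeats: shares seeds with a
        c = random_dna(rng, 3000)
        edges = build_network(
            [SequenceRecord("A", a), SequenceRecord("C", c)], min_hsp_len=50
        )
        assert edges == []

    def test_edge_identity_invariant_under_reverse_complement(self, rng):
        base = random_dna(rng, 1500)
        mut = list(base)
        for pos in rng.choice(1500, size=75, replace=False):
            mut[pos] = "ACGT"[("ACGT".index(mut[pos]) + 1) % 4]
        recs = [SequenceRecord("A", base), SequenceRecord("B", "".join(mut))]
        (e1,) = build_network(recs, min_hsp_len=100)
        recs_rc = [recs[0], SequenceRecord("B", reverse_complement(recs[1].seq))]
        (e2,) = build_network(recs_rc, min_hsp_len=100)
        assert e1.identity == pytest.approx(e2.identity, abs=0.01)
        assert e1.hsp_len == pytest.approx(e2.hsp_len, rel=0.02)

    def test_planted_two_family_components(self):
        cfg = GeneratorConfig(
            seed=3,
            family_structure=[(3, 0.95), (3, 0.95)],
            length_median=4000,
            length_sigma=0.2,
            length_max=6000,
        )
        records, truth = plant_families(cfg)
        edges = build_network(records, min_identity=0.7, min_hsp_len=500)
        comps = components(edges, [r.id for r in records])
        want = {}
        for gid, fam in truth.family_of.items():
            want.setdefault(fam, set()).add(gid)
        assert {frozenset(c) for c in comps} == {frozenset(v) for v in want.values()}


class TestComponents:
    def test_simple_chain_and_isolate(self):
        edges = [SimilarityEdge("a", "b", 10, 0.9), SimilarityEdge("b", "c", 10, 0.9)]
        comps = components(edges, ["a", "b", "c", "d"])
        assert {frozenset(c) for c in comps} == {
            frozenset({"a", "b", "c"}),
            frozenset({"d"}),
        }

    def test_empty_edge_list_gives_singletons(self):
        comps = components([], [f"n{i}" for i in range(5)])
        assert len(comps) == 5

    def test_matches_transitive_closure_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 50))
            ids = [f"n{i}" for i in range(n)]
            pairs = set()
            for _ in range(int(rng.integers(0, 2 * n))):
                i, j = rng.integers(0, n, size=2)
                if i != j:
                    pairs.add(tuple(sorted((f"n{i}", f"n{j}"))))
            edges = [SimilarityEdge(u, v, 10, 0.5) for u, v in pairs]
            got = {frozenset(c) for c in components(edges, ids)}
            # brute-force transitive closure
            parts = {i: {i} for i in ids}
            for u, v in pairs:
                merged = parts[u] | parts[v]
                for node in merged:
                    parts[node] = merged
            want = {frozenset(p) for p in parts.values()}
            assert got == want

    def test_edge_normalizes_direction_and_rejects_self(self):
        e = SimilarityEdge("z", "a", 10, 0.5)
        assert (e.u, e.v) == ("a", "z")
        with pytest.raises(ValueError):
            SimilarityEdge("a", "a", 10, 0.5)
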