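"""Generator ground truth, determinism, and mutated-copy calibration."""

import numpy as np
import pytest

from mitocomp.align import clustering_identity
from mitocomp.annotation_io import SequenceRecord
from mitocomp.classify import DomainHit, category_census, classify_genome, presence_matrix
from mitocomp.intervals import overlap_report, pool_reports
from mitocomp.synthetic_data import (
    GeneratorConfig,
    generate_dataset,
    mutate_copy,
    plant_families,
    write_dataset,
)

from conftest import random_dna


def reclassify_from_hits(genome, truth):
    """Re-run the triage from the emitted hit tables (not planted labels)."""
    d_hits = {
        orf: [DomainHit(orf, d, sf, ev) for d, sf, ev in hits]
        for orf, hits in truth.domain_hits[genome.id].items()
    }
    i_hits = {
        orf: [(c, i) for c, i in hits]
        for orf, hits in truth.id_hits[genome.id].items()
    }
    for f in genome.features:
        f.category = f.subtype = None
    classify_genome(genome, d_hits, i_hits)
    return genome


class TestGenerateDataset:
    def test_census_equals_truth_for_every_genome(self):
        cfg = GeneratorConfig(n_genomes=15, seed=42)
        genomes, truth = generate_dataset(cfg)
        for g in genomes:
            reclassify_from_hits(g, truth)
            census = category_census(g)
            for cat, n in truth.counts(g.id).items():
                assert census[f"n_{cat}"] == n, (g.id, cat)

    def test_presence_matrix_equals_truth(self):
        for dropout in (0.0, 0.3, 1.0):
            cfg = GeneratorConfig(n_genomes=10, seed=7, core_dropout=dropout)
            genomes, truth = generate_dataset(cfg)
            got = presence_matrix(genomes)
            want = truth.presence_frame().loc[got.index]
            assert got.equals(want)

    def test_no_dropout_no_introns_forced_case(self):
        cfg = GeneratorConfig(n_genomes=6, seed=1, core_dropout=0, intron_mean=0,
                              heg_embedding=0.0)
        genomes, truth = generate_dataset(cfg)
        pm = presence_matrix(genomes)
        assert pm.values.all()
        assert all(truth.counts(g.id)["intron"] == 0 for g in genomes)

    def test_full_embedding_forces_within_fraction_one(self):
        cfg = GeneratorConfig(n_genomes=8, seed=2, heg_embedding=1.0)
        genomes, truth = generate_dataset(cfg)
        reports = [
            overlap_report(
                g.features_in_category("HEG"),
                g.features_in_category("intron"),
                len(g.record),
                g.record.topology,
            )
            for g in genomes
        ]
        pooled = pool_reports(reports)
        assert pooled.n_a > 0
        assert pooled.frac_within == 1.0

    def test_zero_embedding_forces_no_overlap(self):
        cfg = GeneratorConfig(n_genomes=8, seed=2, heg_embedding=0.0)
        genomes, _ = generate_dataset(cfg)
        reports = [
            overlap_report(
                g.features_in_category("HEG"),
                g.features_in_category("intron"),
                len(g.record),
                g.record.topology,
            )
            for g in genomes
        ]
        pooled = pool_reports(reports)
        assert pooled.frac_overlapping == 0.0

    def test_gc_target_met(self):
        from mitocomp.annotation_io import gc_content

        cfg = GeneratorConfig(n_genomes=5, seed=3, gc_mean=0.40, gc_sd=0.0,
                              rotate_circular=False)
        genomes, _ = generate_dataset(cfg)
        for g in genomes:
            assert abs(gc_content(g.record.seq) - 0.40) < 0.02

    def test_seed_reproducibility_byte_identical_files(self, tmp_path):
        cfg = GeneratorConfig(n_genomes=5, seed=99)
        for sub in ("a", "b"):
            genomes, truth = generate_dataset(cfg)
            write_dataset(genomes, truth, tmp_path / sub)
        for rel in ["genomes.fasta", "metadata.tsv", "truth.json",
                    "domain_hits.tsv", "id_hits.tsv"]:
            assert (tmp_path / "a" / rel).read_bytes() == (
                tmp_path / "b" / rel
            ).read_bytes()
        a_feats = sorted((tmp_path / "a" / "features").iterdir())
        b_feats = sorted((tmp_path / "b" / "features").iterdir())
        assert [p.name for p in a_feats] == [p.name for p in b_feats]
        for pa, pb in zip(a_feats, b_feats):
            assert pa.read_bytes() == pb.read_bytes()

    def test_different_seeds_differ(self):
        g1, _ = generate_dataset(GeneratorConfig(n_genomes=2, seed=1))
        g2, _ = generate_dataset(GeneratorConfig(n_genomes=2, seed=2))
        assert g1[0].record.seq != g2[0].record.seq

    def test_truth_features_match_emitted_annotations(self):
        cfg = GeneratorConfig(n_genomes=5, seed=13)
        genomes, truth = generate_dataset(cfg)
        for g in genomes:
            got = [(f.name, f.start, f.end, f.wraps_origin) for f in g.features]
            want = [
                (t["name"], t["start"], t["end"], t["wraps_origin"])
                for t in truth.genomes[g.id]["features"]
            ]
            assert got == want

    def test_coupling_strengthens_length_correlation(self):
        from mitocomp.stats import pearson, summarize

        rs = []
        for coupling in (0.2, 0.5, 0.9):
            cfg = GeneratorConfig(n_genomes=200, seed=42, heg_length_coupling=coupling)
            genomes, _ = generate_dataset(cfg)
            s = summarize(genomes)
            rs.append(pearson(s["length"], s["len_HEG"]).r)
        assert rs[0] > 0
        assert rs[0] < rs[1] < rs[2]


class TestMutateCopy:
    def test_target_one_is_identical(self, rng):
        rec = SequenceRecord("x", random_dna(rng, 500))
        assert mutate_copy(rec, 1.0, seed=5).seq == rec.seq

    def test_realized_identity_tracks_target(self, rng):
        rec = SequenceRecord("x", random_dna(rng, 5000))
        idents = [
            clustering_identity(rec.seq, mutate_copy(rec, 0.95, seed=s).seq)
            for s in range(20)
        ]
        assert all(0.92 <= i <= 0.98 for i in idents)

    def test_half_identity_copy_leaves_cluster(self, rng):
        from mitocomp.similarity import greedy_cluster

        rec = SequenceRecord("x", random_dna(rng, 4000))
        copy = mutate_copy(rec, 0.5, seed=3)
        clusters = greedy_cluster([rec, copy], 0.90)
        assert len(clusters) == 2

    def test_invalid_target_rejected(self, rng):
        rec = SequenceRecord("x", random_dna(rng, 100))
        with pytest.raises(ValueError):
            mutate_copy(rec, 0.0, seed=1)


class TestPlantFamilies:
    def test_family_of_one_is_passthrough(self):
        cfg = GeneratorConfig(seed=4, family_structure=[(1, 0.95)])
        records, truth = plant_families(cfg)
        assert len(records) == 1
        assert truth.target_identity[records[0].id] == 1.0

    def test_member_counts_and_labels(self):
        cfg = GeneratorConfig(
            seed=4, family_structure=[(4, 0.95), (2, 0.9)],
            length_median=4000, length_sigma=0.2, length_max=6000,
        )
        records, truth = plant_families(cfg)
        assert len(records) == 6
        fams = {}
        for gid, fam in truth.family_of.items():
            fams.setdefault(fam, []).append(gid)
        assert sorted(len(v) for v in fams.values()) == [2, 4]

    def test_ancestor_is_longest_member(self):
        cfg = GeneratorConfig(
            seed=8, family_structure=[(3, 0.95)] * 3,
            length_median=4000, length_sigma=0.2, length_max=6000,
        )
        records, truth = plant_families(cfg)
        by_fam = {}
        for r in records:
            by_fam.setdefault(truth.family_of[r.id], []).append(r)
        for members in by_fam.values():
            longest = max(members, key=lambda r: len(r.seq))
            assert longest.id.endswith("_0")
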