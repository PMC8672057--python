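"""Feature triage, core-gene presence, and the category census."""

import numpy as np
import pytest

from mitocomp.annotation_io import AnnotatedGenome, Feature, SequenceRecord
from mitocomp.classify import (
    CORE_ORDER,
    DomainHit,
    category_census,
    classify_feature,
    classify_genome,
    core_presence,
    phylum_core_frequency,
    presence_matrix,
    share_missing_core,
)

from conftest import random_dna


def F(name, start=1, end=90):
    return Feature(name, start, end)


class TestClassifyFeature:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("cox1", ("core_gene", "cox1")),
            ("COXI", ("core_gene", "cox1")),
            ("nadL4", ("core_gene", "nad4L")),
            ("rnl", ("rRNA", None)),
            ("rps3", ("rps3", None)),
            ("trnK", ("tRNA", None)),
            ("intron_IC1", ("intron", "IC1")),
            ("intron_II", ("intron", "II")),
        ],
    )
    def test_name_precedence(self, name, expected):
        assert classify_feature(F(name)) == expected

    def test_heg_from_domain_hit(self):
        hit = DomainHit("orf9", "LAGLIDADG_2", "LAGLIDADG", 1e-12)
        assert classify_feature(F("orf9"), hits=[hit]) == ("HEG", "LAGLIDADG")

    def test_giy_yig_family_parsed(self):
        hit = DomainHit("orf9", "GIY-YIG_sf", "GIY-YIG", 1e-8)
        assert classify_feature(F("orf9"), hits=[hit]) == ("HEG", "GIY-YIG")

    def test_dpo_by_identity_hit(self):
        assert classify_feature(F("orf3"), id_hits=[("dpo", 0.92)]) == ("dpo", None)

    def test_identity_at_threshold_not_above_is_ignored(self):
        # "above 80%" is a strict inequality
        assert classify_feature(F("orf3"), id_hits=[("dpo", 0.80)]) == ("uORF", None)

    def test_no_hits_is_uorf(self):
        assert classify_feature(F("orf7")) == ("uORF", None)

    def test_other_domain_is_domain_orf(self):
        hit = DomainHit("orf5", "HAD_like", "HAD", 1e-6)
        assert classify_feature(F("orf5"), hits=[hit]) == ("domain_orf", None)

    def test_weak_evalue_hit_ignored(self):
        hit = DomainHit("orf5", "HAD_like", "HAD", 0.5)
        assert classify_feature(F("orf5"), hits=[hit]) == ("uORF", None)

    def test_id_hit_outranks_domain_hit(self):
        hit = DomainHit("orf1", "LAGLIDADG_1", "LAGLIDADG", 1e-10)
        got = classify_feature(F("orf1"), hits=[hit], id_hits=[("rpo", 0.95)])
        assert got == ("rpo", None)

    def test_conflicting_tied_id_hits_fall_to_other(self):
        with pytest.warns(UserWarning, match="tied"):
            got = classify_feature(
                F("orf1"), id_hits=[("dpo", 0.9), ("rpo", 0.9)]
            )
        assert got == ("other", None)

    def test_higher_identity_wins_conflicts(self):
        got = classify_feature(F("orf1"), id_hits=[("dpo", 0.85), ("rpo", 0.95)])
        assert got == ("rpo", None)

    def test_order_independent(self):
        hits = [
            DomainHit("o", "GIY-YIG_1", "GIY-YIG", 1e-9),
            DomainHit("o", "HAD_like", "HAD", 1e-9),
        ]
        assert classify_feature(F("o"), hits=hits) == classify_feature(
            F("o"), hits=hits[::-1]
        )


class TestCorePresence:
    def _genome(self, names, seq="A" * 4000):
        feats = [Feature(n, 10 * i + 1, 10 * i + 5) for i, n in enumerate(names)]
        return AnnotatedGenome(SequenceRecord("g1", seq), feats)

    def test_all_named_present(self):
        g = self._genome(list(CORE_ORDER))
        assert core_presence(g).all()

    def test_missing_genes_absent_without_references(self):
        g = self._genome([n for n in CORE_ORDER if not n.startswith("nad")])
        pres = core_presence(g)
        for gene in CORE_ORDER:
            assert pres[gene] == (not gene.startswith("nad"))

    def test_similarity_rescue_of_unannotated_exact_copy(self, rng):
        ref = random_dna(rng, 300)
        seq = random_dna(rng, 1500) + ref + random_dna(rng, 1500)
        g = AnnotatedGenome(SequenceRecord("g1", seq), [])
        refs = {gene: [random_dna(rng, 300)] for gene in CORE_ORDER}
        refs["cox1"] = [ref]
        pres = core_presence(g, references=refs)
        assert pres["cox1"]
        assert pres.sum() == 1

    def test_threshold_above_one_degenerates_to_name_only(self, rng):
        ref = random_dna(rng, 300)
        seq = random_dna(rng, 500) + ref + random_dna(rng, 500)
        g = AnnotatedGenome(SequenceRecord("g1", seq), [])
        refs = {gene: [ref] for gene in CORE_ORDER}
        pres = core_presence(g, references=refs, identity_threshold=1.01)
        assert not pres.any()

    def test_missing_reference_errors(self):
        g = self._genome(["cox1"])
        with pytest.raises(ValueError, match="atp6"):
            core_presence(g, references={"cox1": ["ACGT"]})


class TestPresenceMatrix:
    def test_full_complements(self):
        gs = [
            AnnotatedGenome(
                SequenceRecord(f"g{i}", "A" * 1000),
                [Feature(n, j + 1, j + 2) for j, n in enumerate(CORE_ORDER)],
            )
            for i in range(3)
        ]
        m = presence_matrix(gs)
        assert m.shape == (3, 16)
        assert m.values.all()
        assert share_missing_core(m) == 0.0

    def test_single_genome_missing_one_gene(self):
        g = AnnotatedGenome(
            SequenceRecord("g", "A" * 1000),
            [Feature(n, j + 1, j + 2) for j, n in enumerate(CORE_ORDER) if n != "nad6"],
        )
        m = presence_matrix([g])
        assert not m.loc["g", "nad6"]
        assert share_missing_core(m) == 1.0

    def test_phylum_frequencies_are_group_means(self):
        gs = []
        for i, names in enumerate([CORE_ORDER, CORE_ORDER, CORE_ORDER[:-1]]):
            gs.append(
                AnnotatedGenome(
                    SequenceRecord(f"g{i}", "A" * 1000),
                    [Feature(n, j + 1, j + 2) for j, n in enumerate(names)],
                )
            )
        m = presence_matrix(gs)
        freq = phylum_core_frequency(
            m, {"g0": "Asco", "g1": "Basidio", "g2": "Basidio"}
        )
        assert freq.loc["Asco", "rnl"] == 1.0
        assert freq.loc["Basidio", "rnl"] == 0.5


class TestCensus:
    def test_counts_and_nested_heg_counts_both(self):
        g = AnnotatedGenome(
            SequenceRecord("g", "A" * 2000),
            [
                Feature("cox1", 1, 600, category="core_gene", subtype="cox1"),
                Feature("intron_IB", 100, 400, category="intron", subtype="IB"),
                Feature("intron_IA", 450, 550, category="intron", subtype="IA"),
                Feature("intron_II", 700, 900, category="intron", subtype="II"),
                Feature("orf1", 150, 350, category="HEG", subtype="LAGLIDADG"),
                Feature("orf2", 1000, 1200, category="HEG", subtype="GIY-YIG"),
            ],
        )
        c = category_census(g)
        assert c["n_intron"] == 3
        assert c["n_HEG"] == 2
        assert c["n_HEG_LAGLIDADG"] == 1
        assert c["n_HEG_GIYYIG"] == 1
        # nested HEG contributes to both categories' lengths
        assert c["len_HEG"] == 201 + 201
        assert c["len_intron"] == 301 + 101 + 201

    def test_classify_genome_fills_categories(self):
        g = AnnotatedGenome(
            SequenceRecord("g", "A" * 1000),
            [Feature("cox1", 1, 90), Feature("orf1", 100, 190)],
        )
        classify_genome(g)
        assert g.features[0].category == "core_gene"
        assert g.features[1].category == "uORF"
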