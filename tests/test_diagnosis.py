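"""Representation checks, the k-mer neighbor-vote screen, and cause calls."""

import pytest

from taxconcord.concordance import misidentification_calls
from taxconcord.diagnosis import (
    cause_breakdown,
    check_representation,
    classify_cause,
    diagnose,
    kmer_similarity,
    neighbor_vote_screen,
    DiagnosisRow,
)
from taxconcord.io import Assignment, ReferenceRecord
from taxconcord.simulate import SimulationConfig, generate
from taxconcord.taxonomy import parse_plain_lineage


def _lin(text):
    return parse_plain_lineage(text)


XYLODON_GOLD = Assignment(
    "OTU_116",
    _lin("Fungi;Basidiomycota;Agaricomycetes;Hymenochaetales;Schizoporaceae;Xylodon;Xylodon subflaviporus"),
    0.89,
    "binning",
)


class TestRepresentation:
    def _reference(self, *lineage_texts):
        return [ReferenceRecord(f"A{i}", _lin(t)) for i, t in enumerate(lineage_texts)]

    def test_absent_genus(self):
        ref = self._reference(
            "Fungi;Basidiomycota;Agaricomycetes;Hymenochaetales;Hymenochaetaceae;Phellinus;Phellinus igniarius",
            "Fungi;Basidiomycota;Agaricomycetes;Agaricales;Psathyrellaceae;Coprinopsis;Coprinopsis strossmayeri",
        )
        check = check_representation(XYLODON_GOLD, ref)
        assert check.target_genus == "Xylodon"
        assert not check.genus_present and not check.species_present

    def test_genus_present_wrong_congener_only(self):
        ref = self._reference(
            "Fungi;Basidiomycota;Agaricomycetes;Agaricales;Psathyrellaceae;Coprinopsis;Coprinopsis strossmayeri",
        )
        gold = Assignment(
            "OTU_186",
            _lin("Fungi;Basidiomycota;Agaricomycetes;Agaricales;Psathyrellaceae;Coprinopsis;Coprinopsis cinerea"),
            0.99,
            "binning",
        )
        check = check_representation(gold, ref)
        assert check.genus_present and not check.species_present

    def test_species_present_implies_genus_present(self):
        ref = self._reference(
            "Fungi;Basidiomycota;Agaricomycetes;Hymenochaetales;Schizoporaceae;Xylodon;Xylodon subflaviporus",
        )
        check = check_representation(XYLODON_GOLD, ref)
        assert check.species_present and check.genus_present

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError):
            check_representation(XYLODON_GOLD, [])

    def test_removing_a_genus_flips_exactly_its_lineages(self):
        ref_full = self._reference(
            "Fungi;Basidiomycota;Agaricomycetes;Hymenochaetales;Schizoporaceae;Xylodon;Xylodon subflaviporus",
            "Fungi;Basidiomycota;Agaricomycetes;Hymenochaetales;Hymenochaetaceae;Phellinus;Phellinus igniarius",
        )
        ref_removed = [r for r in ref_full if r.lineage.genus != "Xylodon"]
        phellinus_gold = Assignment("OTU_x", ref_full[1].lineage, None, "binning")
        assert check_representation(XYLODON_GOLD, ref_full).genus_present
        assert not check_representation(XYLODON_GOLD, ref_removed).genus_present
        assert check_representation(phellinus_gold, ref_removed).genus_present


class TestKmerSimilarity:
    def test_identical_sequences(self):
        s = "ACGTACGGTTACGATCGATCGATT"
        assert kmer_similarity(s, s, k=5) == 1.0

    def test_reverse_complement_is_identical(self):
        s = "ACGTTGCAAGGCTATCGAGGTCAG"
        rc = s[::-1].translate(str.maketrans("ACGT", "TGCA"))
        assert kmer_similarity(s, rc, k=5) == 1.0

    def test_matches_naive_enumeration(self, rng):
        """Against a nested-loop oracle over all k-mer windows."""

        def naive(a, b, k):
            def canon(km):
                rc = km[::-1].translate(str.maketrans("ACGT", "TGCA"))
                return min(km, rc)

            ka = {canon(a[i : i + k]) for i in range(len(a) - k + 1) if "N" not in a[i : i + k]}
            kb = {canon(b[i : i + k]) for i in range(len(b) - k + 1) if "N" not in b[i : i + k]}
            inter = sum(1 for x in ka if x in kb)
            return inter / min(len(ka), len(kb))

        bases = "ACGT"
        for _ in range(10):
            a = "".join(bases[i] for i in rng.integers(0, 4, size=300))
            b = "".join(bases[i] for i in rng.integers(0, 4, size=300))
            assert kmer_similarity(a, b, k=8) == pytest.approx(naive(a, b, 8))

    def test_ambiguous_bases_excluded(self):
        from taxconcord.diagnosis import kmer_set

        # only the two N-free windows survive, both the same canonical 4-mer
        assert kmer_set("ACGTNACGT", 4) == kmer_set("ACGT", 4)

    def test_short_sequence_raises_with_name(self):
        with pytest.raises(ValueError, match="ACC9"):
            kmer_similarity("ACG", "ACGTACGT", k=5, name="ACC9")


class TestNeighborVoteScreen:
    def test_planted_swaps_flagged_and_only_those(self):
        cfg = SimulationConfig(
            n_genera=35, species_per_genus=3, n_otus=5,
            genus_dropout_fraction=0.0, mislabel_fraction=0.04, seed=7,
        )
        res = generate(cfg)
        verdicts = neighbor_vote_screen(res.reference)
        flagged = {v.accession for v in verdicts if v.flagged}
        assert flagged == res.manifest.swapped_accessions
        assert len(flagged) == 4  # two cross-genus pairs

    def test_duplicated_sequence_twin_is_not_flagged(self):
        seq1 = "ACGT" * 50
        seq2 = "TTAG" * 50
        ref = [
            ReferenceRecord("A1", _lin("Fungi;Basidiomycota;Agaricomycetes;Agaricales;Psathyrellaceae;Coprinopsis;Coprinopsis cinerea"), seq1),
            ReferenceRecord("A2", _lin("Fungi;Basidiomycota;Agaricomycetes;Agaricales;Psathyrellaceae;Coprinopsis;Coprinopsis cinerea"), seq1),
            ReferenceRecord("A3", _lin("Fungi;Basidiomycota;Agaricomycetes;Hymenochaetales;Schizoporaceae;Xylodon;Xylodon subflaviporus"), seq2),
        ]
        verdicts = {v.accession: v for v in neighbor_vote_screen(ref)}
        assert not verdicts["A1"].flagged and not verdicts["A2"].flagged

    def test_hit_count_invariant(self):
        cfg = SimulationConfig(n_genera=10, species_per_genus=3, n_otus=5,
                               mislabel_fraction=0.0, genus_dropout_fraction=0.0, seed=3)
        res = generate(cfg)
        for v in neighbor_vote_screen(res.reference):
            assert 0 <= v.conspecific_hits <= v.congeneric_hits <= len(v.neighbor_ids)

    def test_adding_conspecific_evidence_only_unflags(self):
        """A correctly labeled twin can rescue a flagged record, never condemn a clean one."""
        seq_x = "ACGTGGTCAA" * 30
        seq_y = "TTAGCCGATG" * 30
        lin_x = _lin("Fungi;Basidiomycota;Agaricomycetes;Hymenochaetales;Schizoporaceae;Xylodon;Xylodon subflaviporus")
        lin_y = _lin("Fungi;Basidiomycota;Agaricomycetes;Agaricales;Psathyrellaceae;Coprinopsis;Coprinopsis cinerea")
        ref = [
            ReferenceRecord("A1", lin_y, seq_x),  # mislabeled: sequence is genus Xylodon
            ReferenceRecord("A2", lin_x, seq_x),
            ReferenceRecord("A3", lin_x, seq_x),
            ReferenceRecord("A4", lin_y, seq_y),
            ReferenceRecord("A5", lin_y, seq_y),
        ]
        before = {v.accession: v.flagged for v in neighbor_vote_screen(ref)}
        assert before == {"A1": True, "A2": False, "A3": False, "A4": False, "A5": False}
        rescued = ref + [ReferenceRecord("A6", lin_y, seq_x)]
        after = {v.accession: v.flagged for v in neighbor_vote_screen(rescued)}
        assert after["A1"] is False  # congeneric support appeared
        assert not any(after[a] for a in ("A2", "A3", "A4", "A5"))

    def test_deterministic_and_seed_free(self):
        cfg = SimulationConfig(n_genera=8, species_per_genus=3, n_otus=5,
                               mislabel_fraction=0.1, genus_dropout_fraction=0.0, seed=5)
        res = generate(cfg)
        assert neighbor_vote_screen(res.reference) == neighbor_vote_screen(res.reference)

    def test_too_few_sequenced_records_raise(self):
        ref = [ReferenceRecord("A1", _lin("Fungi;Mucor"), "ACGT" * 10),
               ReferenceRecord("A2", _lin("Fungi;Mucor"), None)]
        with pytest.raises(ValueError):
            neighbor_vote_screen(ref)


class TestCauseClassification:
    def test_underrepresentation_pattern(self):
        """Gold genus absent, matched reference clean: underrepresentation."""
        cfg = SimulationConfig(n_genera=20, species_per_genus=3, n_otus=60,
                               genus_dropout_fraction=0.2, mislabel_fraction=0.0,
                               classifier_noise=0.0, seed=13)
        res = generate(cfg)
        rows, _ = misidentification_calls(res.qiime, res.gold)
        diag, _ = diagnose(res.qiime, res.gold, res.reference, rows)
        dropped = set(res.manifest.dropped_genera)
        mis = [d for d in diag if d.cause != "not_misidentified"]
        assert mis, "expected some misidentifications from dropped genera"
        assert all(d.cause == "underrepresentation" for d in mis)
        assert all(d.gold_genus in dropped for d in mis)

    def test_mislabel_pattern(self):
        """Gold genus present, nearest reference relabeled: mislabeled_reference."""
        cfg = SimulationConfig(n_genera=20, species_per_genus=3, n_otus=120,
                               genus_dropout_fraction=0.0, mislabel_fraction=0.1,
                               classifier_noise=0.0, seed=17)
        res = generate(cfg)
        rows, _ = misidentification_calls(res.qiime, res.gold)
        diag, _ = diagnose(res.qiime, res.gold, res.reference, rows)
        mis = [d for d in diag if d.cause != "not_misidentified"]
        assert mis, "expected mislabel-driven misidentifications"
        assert all(d.cause == "mislabeled_reference" for d in mis)
        assert all(d.flagged_accessions for d in mis)

    def test_consistent_assignment_passes_through(self):
        cfg = SimulationConfig(n_genera=10, species_per_genus=3, n_otus=30,
                               genus_dropout_fraction=0.0, mislabel_fraction=0.0,
                               classifier_noise=0.0, seed=19)
        res = generate(cfg)
        rows, _ = misidentification_calls(res.qiime, res.gold)
        diag, _ = diagnose(res.qiime, res.gold, res.reference, rows)
        assert all(d.cause == "not_misidentified" for d in diag)


class TestCauseBreakdown:
    def test_zero_misidentifications(self):
        rows = [DiagnosisRow("OTU_1", "not_misidentified")]
        out = cause_breakdown(rows)
        assert out["n_misidentified"] == 0
        assert all(v == 0.0 for v in out["fractions"].values())

    def test_counting_and_merged_involvement(self):
        rows = [
            DiagnosisRow("O1", "underrepresentation"),
            DiagnosisRow("O2", "underrepresentation"),
            DiagnosisRow("O3", "mislabeled_reference"),
            DiagnosisRow("O4", "both"),
            DiagnosisRow("O5", "not_misidentified"),
        ]
        out = cause_breakdown(rows)
        assert out["n_misidentified"] == 4
        assert out["fractions"]["underrepresentation"] == 0.5
        assert out["fractions"]["mislabeled_reference"] == 0.25
        assert out["fractions"]["both"] == 0.25
        assert out["underrepresentation_involved"] == 0.75
        assert sum(out["fractions"].values()) == pytest.approx(1.0)

    def test_recovers_planted_mix(self):
        """Pipeline fractions equal the generator manifest's intended mix."""
        cfg = SimulationConfig(n_genera=35, species_per_genus=3, n_otus=200,
                               genus_dropout_fraction=0.2, mislabel_fraction=0.05,
                               classifier_noise=0.0, seed=11)
        res = generate(cfg)
        rows, _ = misidentification_calls(res.qiime, res.gold)
        diag, _ = diagnose(res.qiime, res.gold, res.reference, rows)
        out = cause_breakdown(diag)
        expected = res.manifest.expected["qiime_silva"]["cause_counts"]
        assert out["counts"] == {
            "mislabeled_reference": expected.get("mislabeled_reference", 0),
            "underrepresentation": expected.get("underrepresentation", 0),
            "both": expected.get("both", 0),
            "unexplained": expected.get("unexplained", 0),
        }
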