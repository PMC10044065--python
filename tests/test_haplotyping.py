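"""Haplotype calling, novel registration, and catalog semantics."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from hv1pop.haplotyping import (
    AmbiguousHaplogroupError,
    CatalogError,
    HaplotypeCatalog,
    UncallableError,
    VariantProfile,
    assign_subhaplogroup,
    call_haplotype,
    hamming_distance,
    register_novel,
)
from hv1pop.sequence_io import WindowSequence

from conftest import make_record, mutate

SEQS = st.text(alphabet="ACGT", min_size=8, max_size=8)


class TestHammingDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("ACGT", "ACGT", 0),
            ("ACGT", "ACTT", 1),
            ("ANGT", "ACTT", 1),  # N position skipped, one real difference
            ("A-GT", "ACGT", 0),  # gaps are missing, not differences
            ("NNNN", "ACGT", 0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert hamming_distance(a, b) == expected
        # brute-force position scan as independent oracle
        det = set("ACGT")
        oracle = sum(1 for x, y in zip(a, b) if x in det and y in det and x != y)
        assert oracle == expected

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError):
            hamming_distance("ACG", "ACGT")

    @given(SEQS, SEQS, SEQS)
    def test_pseudometric_on_determinate_sequences(self, a, b, c):
        assert hamming_distance(a, a) == 0
        assert hamming_distance(a, b) == hamming_distance(b, a)
        assert hamming_distance(a, c) <= hamming_distance(a, b) + hamming_distance(b, c)


class TestCalling:
    def test_catalog_records_call_back_to_themselves(self, toy_catalog):
        for rec in list(toy_catalog.records):
            win = WindowSequence(f"s_{rec.name}", rec.window_seq)
            call = call_haplotype(win, toy_catalog)
            assert call.haplotype_name == rec.name
            assert not call.is_novel
            assert call.distance_to_nearest_published == 0
            assert call.novel_sites == frozenset()

    def test_wildcard_match_with_leading_ns(self, toy_catalog):
        rec = toy_catalog.get("B2")
        masked = "N" * 5 + rec.window_seq[5:]
        win = WindowSequence("s", masked)
        call = call_haplotype(win, toy_catalog)
        # oracle: exhaustive comparison over the whole catalog
        matches = sorted(
            r.name
            for r in toy_catalog.records
            if hamming_distance(masked, r.window_seq) == 0
        )
        assert call.haplotype_name == matches[0] == "B2"

    def test_ambiguous_wildcard_match_flagged(self, toy_ref, toy_catalog):
        # A1 and A2 differ only at offset 5; masking it matches both
        masked = mutate(toy_catalog.get("A1").window_seq, 5, "T")  # becomes A2
        masked = masked[:5] + "N" + masked[6:]
        call = call_haplotype(WindowSequence("s", masked), toy_catalog)
        assert call.ambiguous
        assert call.haplotype_name == "A1"  # lexicographically smallest

    def test_one_substitution_forces_novel(self, toy_catalog):
        seq = mutate(toy_catalog.get("A1").window_seq, 14, "A")
        call = call_haplotype(WindowSequence("s", seq), toy_catalog)
        assert call.is_novel
        assert call.haplotype_name == "An1"
        assert call.distance_to_nearest_published == 1


class TestRegisterNovel:
    def test_novel_site_detection(self, toy_ref, toy_catalog):
        # offset 14 is not polymorphic in any catalog record
        assert toy_ref.position(14) not in toy_catalog.polymorphic_positions()
        seq = mutate(toy_catalog.get("A1").window_seq, 14, "A")
        rec = register_novel(WindowSequence("s", seq), toy_catalog)
        assert rec.name == "An1"
        assert rec.haplogroup == "A"
        assert rec.provenance == "novel"
        call = call_haplotype(WindowSequence("s2", seq), toy_catalog)
        assert call.novel_sites == frozenset({toy_ref.position(14)})

    def test_registration_idempotent(self, toy_catalog):
        seq = mutate(toy_catalog.get("A1").window_seq, 14, "A")
        first = register_novel(WindowSequence("s1", seq), toy_catalog)
        size = len(toy_catalog)
        second = register_novel(WindowSequence("s2", seq), toy_catalog)
        assert second.name == first.name
        assert len(toy_catalog) == size

    def test_per_haplogroup_indices_consecutive(self, toy_catalog):
        a_base = toy_catalog.get("A1").window_seq
        b_base = toy_catalog.get("B1").window_seq
        names = []
        for off, base_seq in [(14, a_base), (16, a_base), (14, b_base)]:
            seq = mutate(base_seq, off, "A" if base_seq[off] != "A" else "G")
            names.append(register_novel(WindowSequence(f"s{off}", seq), toy_catalog).name)
        assert names == ["An1", "An2", "Bn1"]
        all_names = [r.name for r in toy_catalog.records]
        assert len(all_names) == len(set(all_names))

    def test_too_much_missing_is_uncallable(self, toy_catalog):
        seq = mutate(toy_catalog.get("A1").window_seq, 14, "A")
        seq = "N" * 10 + seq[10:]  # 33% missing on the 30-bp toy window
        with pytest.raises(UncallableError):
            register_novel(WindowSequence("s", seq), toy_catalog)

    def test_cross_haplogroup_tie_is_hard_error(self, toy_ref):
        # two haplogroups whose founders sit 2 apart; midpoint is equidistant
        ref = toy_ref.ref_seq
        a1 = mutate(ref, 0, "T")
        b1 = mutate(ref, 1, "A")
        catalog = HaplotypeCatalog(
            toy_ref, [make_record("A1", a1, toy_ref), make_record("B1", b1, toy_ref)]
        )
        midpoint = mutate(mutate(ref, 5, "T"), 7, "C")  # distance 3 from both
        with pytest.raises(AmbiguousHaplogroupError):
            register_novel(WindowSequence("s", midpoint), catalog)

    def test_monotone_safety(self, toy_catalog):
        """Adding records never changes the call of a previously exact match."""
        target = toy_catalog.get("A2").window_seq
        before = call_haplotype(WindowSequence("s", target), toy_catalog)
        novel_seq = mutate(toy_catalog.get("B1").window_seq, 16, "G")
        register_novel(WindowSequence("x", novel_seq), toy_catalog)
        after = call_haplotype(WindowSequence("s", target), toy_catalog)
        assert after.haplotype_name == before.haplotype_name == "A2"


class TestSubhaplogroup:
    def test_identical_to_annotated(self, toy_catalog):
        rec = toy_catalog.get("A2")
        assert assign_subhaplogroup(rec, toy_catalog).label == "a2"

    def test_tie_resolves_lexicographically_and_flags(self, toy_ref, toy_catalog):
        # equidistant (d=1) from A1 (a1) and A2 (a2): mask the discriminating site
        seq = mutate(toy_catalog.get("A1").window_seq, 20, "A")
        rec = register_novel(WindowSequence("s", seq), toy_catalog)
        # distance to A1 is 1 (offset 20); to A2 it is 2 -> no tie yet; craft one:
        call = assign_subhaplogroup(rec, toy_catalog)
        assert call.label == "a1"
        tie_seq = mutate(toy_catalog.get("A1").window_seq, 5, "G")  # d=1 to A1, d=1 to A2
        tie_rec = register_novel(WindowSequence("t", tie_seq), toy_catalog)
        tie_call = assign_subhaplogroup(tie_rec, toy_catalog)
        assert tie_call.label == "a1"
        assert tie_call.ambiguous

    def test_beyond_threshold_absent(self, toy_ref, toy_catalog):
        seq = toy_catalog.get("A1").window_seq
        for off in (3, 6, 10, 13, 16, 19, 22):
            seq = mutate(seq, off, "A" if seq[off] != "A" else "C")
        rec = make_record("A99", seq, toy_ref)
        assert assign_subhaplogroup(rec, toy_catalog).label is None


class TestCatalogIO:
    def test_tsv_round_trip(self, tmp_path, toy_ref, toy_catalog):
        path = tmp_path / "catalog.tsv"
        toy_catalog.to_tsv(path)
        loaded = HaplotypeCatalog.from_tsv(path, toy_ref)
        assert [r.name for r in loaded.records] == [r.name for r in toy_catalog.records]
        for rec in toy_catalog.records:
            assert loaded.get(rec.name).window_seq == rec.window_seq
            assert loaded.get(rec.name).subhaplogroup == rec.subhaplogroup

    def test_fasta_loading(self, tmp_path, toy_ref, toy_catalog):
        path = tmp_path / "catalog.fasta"
        with open(path, "w") as fh:
            for rec in toy_catalog.records:
                fh.write(f">{rec.name}|{rec.haplogroup}|{rec.subhaplogroup}\n{rec.window_seq}\n")
        loaded = HaplotypeCatalog.from_fasta(path, toy_ref)
        assert {r.name for r in loaded.records} == {r.name for r in toy_catalog.records}

    def test_duplicate_sequence_rejected(self, toy_ref, toy_catalog):
        with pytest.raises(CatalogError, match="duplicates"):
            toy_catalog.add(make_record("A3", toy_catalog.get("A1").window_seq, toy_ref))

    def test_profile_parse_round_trip(self):
        profile = VariantProfile.parse("105:A>G;110:C>T;120:del:G")
        assert profile.token() == "105:A>G;110:C>T;120:del:G"
        assert VariantProfile.parse(".").token() == ""
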