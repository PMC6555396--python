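import gzip

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camphylo import (
    AMINO_ACIDS,
    CODONS,
    AversionMotif,
    GeneRecord,
    build_species_profile,
    extract_aa_motif,
    extract_codon_motif,
    filter_records,
    normalize_sequence,
    profile_from_fasta,
    read_fasta,
    select_longest_isoforms,
    translate,
)
from camphylo.errors import (
    ConfigurationError,
    EmptySequenceError,
    EmptySpeciesError,
    SequenceTooShortError,
)
from camphylo.motifs import parse_fasta_header

from conftest import EXAMPLE_UNIQUE_MOTIFS

ALL_CODON_SEQ = "".join(CODONS)

dna = st.text(alphabet="ACGT", min_size=3, max_size=600)


class TestNormalize:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("augaaa", "ATGAAA"),
            ("ATG", "ATG"),
            ("ATGN\nAAA", "ATGNAAA"),
            (" at g\tu ", "ATGT"),
        ],
    )
    def test_rules(self, raw, expected):
        assert normalize_sequence(raw) == expected

    def test_empty_names_record(self):
        with pytest.raises(EmptySequenceError, match="rec7"):
            normalize_sequence("  \n ", record_id="rec7")


class TestCodonMotif:
    def test_all_codons_used_gives_empty_motif(self):
        assert extract_codon_motif(ALL_CODON_SEQ).elements == ()

    def test_single_codon(self):
        motif = extract_codon_motif("AAA")
        assert len(motif) == 63 and "AAA" not in motif

    def test_three_codons(self):
        motif = extract_codon_motif("ATGAAATAA")
        assert len(motif) == 61
        assert set(CODONS) - set(motif) == {"ATG", "AAA", "TAA"}

    def test_too_short(self):
        with pytest.raises(SequenceTooShortError):
            extract_codon_motif("AT")

    def test_trailing_incomplete_codon_dropped(self):
        assert extract_codon_motif("AAAT") == extract_codon_motif("AAA")

    def test_ambiguity_codon_marks_nothing(self):
        # NNN and ANA mark no table entry as used
        assert extract_codon_motif("AAANNNANA") == extract_codon_motif("AAA")

    @given(dna)
    @settings(max_examples=200, deadline=None)
    def test_complementarity_against_brute_force(self, seq):
        """Observed codons and the motif partition the 64-codon table."""
        motif = set(extract_codon_motif(seq))
        observed = {seq[i:i + 3] for i in range(0, len(seq) - 2, 3)
                    if len(seq[i:i + 3]) == 3}
        assert motif | observed == set(CODONS)
        assert not (motif & observed)
        assert len(motif) == 64 - len(observed)


class TestTranslate:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ATGAAA", "MK"),
            ("TAA", "*"),
            ("ATGNNNAAA", "MXK"),
            ("TAAATG", "*M"),  # no halt at internal stop
        ],
    )
    def test_examples(self, seq, expected):
        assert translate(seq) == expected

    def test_unknown_table(self):
        with pytest.raises(ConfigurationError):
            translate("ATG", table_id=999)

    def test_alternate_table(self):
        # table 2 (vertebrate mitochondrial): TGA = Trp, AGA = stop
        assert translate("TGAAGA", table_id=2) == "W*"


class TestAminoAcidMotif:
    def test_full_alphabet_gives_empty(self):
        assert extract_aa_motif("".join(AMINO_ACIDS)).elements == ()

    def test_single_aa(self):
        motif = extract_aa_motif("M")
        assert len(motif) == 19 and "M" not in motif

    def test_stop_and_x_ignored(self):
        motif = extract_aa_motif("MK*X")
        assert len(motif) == 18 and not {"M", "K"} & set(motif)

    @given(dna)
    @settings(max_examples=100, deadline=None)
    def test_consistent_with_codon_complement(self, seq):
        """The aa motif is determined by the translated observed codons."""
        observed = set(CODONS) - set(extract_codon_motif(seq))
        observed_aas = {translate(c) for c in observed}
        expected = set(AMINO_ACIDS) - observed_aas
        assert set(extract_aa_motif(translate(seq))) == expected


class TestMotifType:
    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            AversionMotif(("ATA", "AAA"))

    def test_invalid_element_rejected(self):
        with pytest.raises(ValueError):
            AversionMotif(("AAU",))

    @given(st.sets(st.sampled_from(CODONS), max_size=64))
    @settings(max_examples=100, deadline=None)
    def test_text_round_trip(self, elements):
        m = AversionMotif(tuple(sorted(elements)))
        assert AversionMotif.from_text(m.to_text()) == m


class TestIsoformsAndFilters:
    @staticmethod
    def rec(gene, length, **kw):
        return GeneRecord(gene_id=gene, species="s", sequence="A" * length, **kw)

    def test_longest_kept(self):
        r = [self.rec("g1", 300), self.rec("g1", 450)]
        assert select_longest_isoforms(r) == [r[1]]

    def test_single_record_identity(self):
        r = [self.rec("g1", 90)]
        assert select_longest_isoforms(r) == r

    def test_tie_breaks_to_first(self):
        r = [self.rec("g1", 90), self.rec("g1", 90), self.rec("g1", 60)]
        assert select_longest_isoforms(r) == [r[0]]

    def test_untagged_always_kept(self):
        r = [self.rec(None, 30), self.rec(None, 20), self.rec("g1", 10)]
        assert select_longest_isoforms(r) == r

    def test_filter_defaults_drop_exceptions_only(self):
        r = [self.rec("g", 30) for _ in range(8)]
        r += [self.rec("x", 30, has_exception=True), self.rec("p", 30, is_partial=True)]
        kept = filter_records(r)
        assert len(kept) == 9 and all(not x.has_exception for x in kept)

    def test_filter_partials(self):
        r = [self.rec("g", 30) for _ in range(7)]
        r += [self.rec("p", 30, is_partial=True) for _ in range(3)]
        assert len(filter_records(r, drop_partials=True)) == 7

    def test_no_flags_identity(self):
        r = [self.rec("g", 30) for _ in range(5)]
        assert filter_records(r, drop_partials=True) == r

    def test_all_removed_is_error(self):
        r = [self.rec("x", 30, has_exception=True)]
        with pytest.raises(EmptySpeciesError, match="myfile"):
            filter_records(r, source="myfile")


class TestHeaderParsing:
    def test_refseq_style(self):
        gene, partial, exc = parse_fasta_header(
            "lcl|NC_1.1_cds_1 [gene=thrL] [protein=x] [partial=5']"
        )
        assert gene == "thrL" and partial and not exc

    def test_exception_markers(self):
        for marker in ("exception=ribosomal slippage", "transl_except=(pos:1..3)"):
            _, _, exc = parse_fasta_header(f"id [gene=a] [{marker}]")
            assert exc

    def test_plain_header(self):
        assert parse_fasta_header("gi|12345 some description") == (None, False, False)


class TestProfiles:
    def test_worked_example(self, example_records):
        prof = build_species_profile(example_records)
        assert {m.elements for m in prof.motifs} == EXAMPLE_UNIQUE_MOTIFS
        assert prof.n_genes == 4
        assert prof.motif_counts[AversionMotif(("AAA", "ATA"))] == 2

    def test_single_gene(self):
        recs = [GeneRecord(None, "s", ALL_CODON_SEQ)]
        prof = build_species_profile(recs)
        assert len(prof.motifs) == 1 and prof.n_genes == 1

    def test_identical_genes_collapse(self):
        recs = [GeneRecord(None, "s", "AAATTT"), GeneRecord(None, "s", "AAATTT")]
        prof = build_species_profile(recs)
        assert len(prof.motifs) == 1 and prof.n_genes == 2

    def test_unusable_genes_skipped_not_fatal(self):
        recs = [GeneRecord(None, "s", "AT"), GeneRecord(None, "s", "AAATTT")]
        assert build_species_profile(recs).n_genes == 1

    def test_all_unusable_is_error(self):
        with pytest.raises(EmptySpeciesError):
            build_species_profile([GeneRecord(None, "s", "AT")])

    def test_amino_acid_mode(self, example_records):
        prof = build_species_profile(example_records, mode="amino_acid")
        assert prof.mode == "amino_acid"
        assert all(set(m) <= set(AMINO_ACIDS) for m in prof.motifs)


class TestFastaIO:
    def test_read_fasta_labels_and_flags(self, example_fasta):
        recs = read_fasta(example_fasta)
        assert len(recs) == 4
        assert all(r.species == "example" for r in recs)
        assert [r.gene_id for r in recs] == ["g000", "g001", "g002", "g003"]

    def test_profile_from_fasta_matches_example(self, example_fasta):
        prof = profile_from_fasta(example_fasta)
        assert {m.elements for m in prof.motifs} == EXAMPLE_UNIQUE_MOTIFS

    def test_gzip_transparent(self, tmp_path, example_fasta):
        gz = tmp_path / "example2.fasta.gz"
        with gzip.open(gz, "wt") as fh:
            fh.write(example_fasta.read_text())
        plain = profile_from_fasta(example_fasta)
        zipped = profile_from_fasta(gz)
        assert zipped.motif_counts == plain.motif_counts
        assert zipped.species == "example2"

    def test_determinism(self, example_fasta):
        a = profile_from_fasta(example_fasta)
        b = profile_from_fasta(example_fasta)
        assert a.motif_counts == b.motif_counts
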