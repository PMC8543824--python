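"""Sequence construction: FASTA/TSV IO and variant embedding."""

import numpy as np
import pytest

from codoncnn.variants import (
    Effect,
    Origin,
    ReferenceTranscript,
    apply_variants,
    build_sample_sequences,
    filter_by_effect,
    invert_variant,
    read_transcript_fasta,
    read_variant_table,
    write_transcript_fasta,
    write_variant_table,
)

from conftest import make_variant, naive_splice, random_disjoint_variants


class TestFastaIO:
    def test_round_trip_preserves_records(self, tmp_path, small_reference):
        path = tmp_path / "ref.fasta"
        write_transcript_fasta(small_reference, path)
        back = read_transcript_fasta(path)
        assert [(t.transcript_id, t.gene_symbol, t.sequence) for t in back] == [
            (t.transcript_id, t.gene_symbol, t.sequence) for t in small_reference
        ]

    def test_two_records_with_lengths(self, tmp_path):
        path = tmp_path / "ref.fasta"
        path.write_text(">tx1|GENE1\nATGGCCAAA\n>tx2\nATGGCCAAATTT\n")
        records = read_transcript_fasta(path)
        assert [t.length_bases for t in records] == [9, 12]
        assert records[0].gene_symbol == "GENE1"
        assert records[1].gene_symbol == "tx2"

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        assert read_transcript_fasta(path) == []

    def test_invalid_character_is_located(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">tx1\nATGXCC\n")
        with pytest.raises(ValueError, match=r"tx1.*offset 3"):
            read_transcript_fasta(path)

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">tx1\nATG\n>tx1\nCCC\n")
        with pytest.raises(ValueError, match="tx1"):
            read_transcript_fasta(path)


class TestVariantTableIO:
    HEADER = "sample_id\ttranscript_id\tposition\tref_allele\talt_allele\torigin\teffect\n"

    def test_well_formed_rows_parse(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text(
            self.HEADER
            + "S1\ttx1\t4\tG\tT\tGERMLINE\tMODERATE\n"
            + "S1\ttx1\t7\tA\tATT\tSOMATIC\tHIGH\n"
            + "S2\ttx2\t1\tA\tC\tSOMATIC\tMODERATE\n"
        )
        records = read_variant_table(path)
        assert len(records) == 3
        assert records[0].origin is Origin.GERMLINE
        assert records[1].alt_allele == "ATT"

    def test_unknown_effect_maps_to_other_with_warning(self, tmp_path, caplog):
        path = tmp_path / "v.tsv"
        path.write_text(self.HEADER + "S1\ttx1\t4\tG\tT\tSOMATIC\tLOW\n")
        with caplog.at_level("WARNING"):
            records = read_variant_table(path)
        assert records[0].effect is Effect.OTHER
        assert "LOW" in caplog.text

    def test_bad_position_names_line(self, tmp_path):
        path = tmp_path / "v.tsv"
        rows = ["S1\ttx1\t4\tG\tT\tSOMATIC\tMODERATE\n"] * 3
        rows.append("S1\ttx1\tabc\tG\tT\tSOMATIC\tMODERATE\n")
        path.write_text(self.HEADER + "".join(rows))
        with pytest.raises(ValueError, match="line 5"):
            read_variant_table(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text("sample_id\ttranscript_id\tposition\n")
        with pytest.raises(ValueError, match="effect"):
            read_variant_table(path)

    def test_writer_reader_round_trip(self, tmp_path):
        variants = [
            make_variant("tx1", 3, "G", "GTT"),
            make_variant("tx1", 8, "AAC", "A", effect=Effect.HIGH),
        ]
        path = tmp_path / "v.tsv"
        write_variant_table(variants, path)
        assert read_variant_table(path) == variants


class TestVcfReader:
    def test_reads_anchored_records_with_info_keys(self, tmp_path):
        from codoncnn.variants import read_variant_vcf

        path = tmp_path / "v.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=tx1>\n"
            '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample">\n'
            '##INFO=<ID=ORIGIN,Number=1,Type=String,Description="Origin">\n'
            '##INFO=<ID=EFFECT,Number=1,Type=String,Description="Effect">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "tx1\t4\t.\tG\tT\t.\t.\tSAMPLE=S1;ORIGIN=SOMATIC;EFFECT=MODERATE\n"
            "tx1\t7\t.\tA\tATT\t.\t.\tSAMPLE=S1;ORIGIN=GERMLINE;EFFECT=HIGH\n"
        )
        records = read_variant_vcf(path)
        assert len(records) == 2
        assert records[0] == make_variant("tx1", 4, "G", "T", sample_id="S1")
        assert records[1].origin is Origin.GERMLINE
        assert records[1].alt_allele == "ATT"


class TestFilterByEffect:
    def test_moderate_and_high_kept(self):
        variants = [
            make_variant("t", 1, "A", "C", effect=e)
            for e in (Effect.MODERATE, Effect.MODERATE, Effect.HIGH, Effect.OTHER, Effect.OTHER)
        ]
        kept = filter_by_effect(variants, {Effect.MODERATE, Effect.HIGH})
        assert len(kept) == 3
        assert kept == variants[:3]

    def test_empty_input(self):
        assert filter_by_effect([], {Effect.HIGH}) == []

    def test_all_classes_is_identity(self):
        variants = [make_variant("t", 1, "A", "C", effect=e) for e in Effect]
        assert filter_by_effect(variants, set(Effect)) == variants


class TestApplyVariants:
    REF = ReferenceTranscript("tx1", "G1", "ATGGCC")

    def test_no_variants_is_identity(self):
        ref = ReferenceTranscript("tx1", "G1", "ATGGCCAAA")
        assert apply_variants(ref, []) == "ATGGCCAAA"

    def test_snv_splice(self):
        v = make_variant("tx1", 4, "G", "T")
        assert apply_variants(self.REF, [v]) == "ATGTCC"

    def test_insertion_then_inverse_round_trip(self):
        ins = make_variant("tx1", 3, "G", "GTT")
        mutated = apply_variants(self.REF, [ins])
        assert mutated == "ATGTTGCC"
        back = apply_variants(
            ReferenceTranscript("tx1", "G1", mutated), [invert_variant(ins)]
        )
        assert back == "ATGGCC"

    def test_ref_mismatch_reports_context(self):
        v = make_variant("tx1", 4, "C", "T", sample_id="S9")
        with pytest.raises(ValueError, match=r"S9.*position 4"):
            apply_variants(self.REF, [v])

    def test_overlapping_spans_rejected(self):
        a = make_variant("tx1", 3, "GGC", "G")
        b = make_variant("tx1", 4, "G", "T")
        with pytest.raises(ValueError, match="overlapping"):
            apply_variants(self.REF, [a, b])

    def test_length_conservation(self, small_reference):
        rng = np.random.default_rng(5)
        for ref in small_reference:
            variants = random_disjoint_variants(ref, rng)
            out = apply_variants(ref, variants)
            delta = sum(v.length_change for v in variants)
            assert len(out) == ref.length_bases + delta

    def test_matches_naive_splice_oracle_on_random_cases(self):
        """Descending-position application == left-to-right oracle, 1000 cases."""
        rng = np.random.default_rng(42)
        bases = "ACGT"
        for case in range(1000):
            L = int(rng.integers(10, 60))
            seq = "".join(bases[b] for b in rng.integers(0, 4, L))
            ref = ReferenceTranscript(f"t{case}", "G", seq)
            variants = random_disjoint_variants(ref, rng)
            assert apply_variants(ref, variants) == naive_splice(seq, variants)


class TestBuildSampleSequences:
    def test_zero_variants_reproduces_reference(self, small_reference):
        for mode in ("GERMLINE", "CANCER"):
            sset = build_sample_sequences(small_reference, [], [], mode, "S1")
            assert sset.sequences == {
                t.transcript_id: t.sequence for t in small_reference
            }

    def test_cancer_mode_embeds_both_origins(self):
        ref = [ReferenceTranscript("tx1", "G1", "ATGGCCAAA")]
        germ = [make_variant("tx1", 1, "A", "C", origin=Origin.GERMLINE)]
        som = [make_variant("tx1", 9, "A", "G", origin=Origin.SOMATIC)]
        cancer = build_sample_sequences(ref, germ, som, "CANCER", "S1")
        assert cancer.sequences["tx1"] == "CTGGCCAAG"
        assert cancer.provenance["GERMLINE_MODERATE"] == 1
        assert cancer.provenance["SOMATIC_MODERATE"] == 1

    def test_germline_mode_skips_somatic(self):
        ref = [ReferenceTranscript("tx1", "G1", "ATGGCCAAA")]
        germ = [make_variant("tx1", 1, "A", "C", origin=Origin.GERMLINE)]
        som = [make_variant("tx1", 9, "A", "G", origin=Origin.SOMATIC)]
        germline = build_sample_sequences(ref, germ, som, "GERMLINE", "S1")
        assert germline.sequences["tx1"] == "CTGGCCAAA"

    def test_unknown_transcript_is_error(self):
        ref = [ReferenceTranscript("tx1", "G1", "ATGGCC")]
        v = [make_variant("tx9", 1, "A", "C")]
        with pytest.raises(ValueError, match="tx9"):
            build_sample_sequences(ref, v, [], "GERMLINE", "S1")
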