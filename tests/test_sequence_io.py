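"""Reading, validation, codon counting and segment concatenation."""

import numpy as np
import pytest

from cubkit.genetics import ALL_CODONS, SENSE_CODONS
from cubkit.sequence_io import (
    CodingSequence,
    CodonCountTable,
    concatenate_segments,
    count_codons,
    read_fasta_cds,
    read_reference_usage,
    validate_cds,
    write_fasta,
)
from conftest import random_count_table


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadFasta:
    def test_normalizes_case_and_rna_alphabet(self, tmp_path):
        p = _write(tmp_path, "a.fasta", ">s1\natgaaauuu\n>s2\nAUGCCC\n")
        seqs = read_fasta_cds(p)
        assert [s.nt for s in seqs] == ["ATGAAATTT", "ATGCCC"]
        assert [s.length_nt for s in seqs] == [9, 6]

    def test_preserves_order_and_joins_metadata(self, tmp_path):
        p = _write(tmp_path, "a.fasta", ">s1\nATGAAA\n>s2\nATGCCC\n")
        meta = _write(
            tmp_path, "m.tsv",
            "strain_id\tsegment\tclade\thost\tcountry\ns1\tL\tSK\thuman\tKR\n",
        )
        seqs = read_fasta_cds(p, meta)
        assert seqs[0].clade == "SK" and seqs[0].segment == "L"
        assert seqs[1].clade is None  # absent from metadata: unset, warning logged

    def test_duplicate_id_raises(self, tmp_path):
        p = _write(tmp_path, "a.fasta", ">s1\nATG\n>s1\nCCC\n")
        with pytest.raises(ValueError, match="s1"):
            read_fasta_cds(p)

    def test_empty_file_returns_empty_list(self, tmp_path):
        assert read_fasta_cds(_write(tmp_path, "e.fasta", "")) == []

    def test_roundtrip(self, tmp_path):
        seqs = [CodingSequence("a", "ATGAAATTT"), CodingSequence("b", "ATGCCC")]
        out = tmp_path / "rt.fasta"
        write_fasta(seqs, out)
        back = read_fasta_cds(out)
        assert [(s.id, s.nt) for s in back] == [(s.id, s.nt) for s in seqs]


class TestValidate:
    @pytest.mark.parametrize(
        "nt, exp_nt, trimmed, dropped",
        [
            ("ATGAAATAA", "ATGAAATAA", 0, 0),  # stop retained in nt
            ("ATGAANTTT", "ATGTTT", 0, 1),     # ambiguous codon dropped, tallied
            ("ATGAA", "ATG", 2, 0),            # trailing incomplete codon trimmed
        ],
    )
    def test_cleaning(self, nt, exp_nt, trimmed, dropped):
        seq, report = validate_cds(CodingSequence("x", nt))
        assert seq.nt == exp_nt
        assert report.trimmed_nt == trimmed
        assert report.dropped_codons == dropped

    def test_empty_after_cleaning_raises(self):
        with pytest.raises(ValueError):
            validate_cds(CodingSequence("x", "NNN"))

    def test_idempotent(self):
        seq, _ = validate_cds(CodingSequence("x", "ATGAANTTTC"))
        again, report = validate_cds(seq)
        assert again.nt == seq.nt and report.clean


class TestCountCodons:
    def test_single_codon_sequence(self):
        t = count_codons(CodingSequence("x", "ATGATGATG"))
        assert t.counts["ATG"] == 3 and t.total_codons == 3

    def test_pool_vs_per_sequence(self):
        seqs = [CodingSequence("a", "AAA"), CodingSequence("b", "AAAAAA")]
        pooled = count_codons(seqs, pool=True)
        assert pooled.counts["AAA"] == 3
        per = count_codons(seqs, pool=False)
        assert [t.counts["AAA"] for t in per] == [1, 2]

    def test_pooled_equals_elementwise_sum(self):
        rng = np.random.default_rng(7)
        tables = [random_count_table(rng) for _ in range(4)]
        seqs = [
            CodingSequence(f"s{i}", "".join(c * n for c, n in t.counts.items()))
            for i, t in enumerate(tables)
        ]
        pooled = count_codons(seqs, pool=True)
        for codon in ALL_CODONS:
            assert pooled.counts[codon] == sum(t.counts[codon] for t in tables)

    def test_invalid_codon_key_rejected(self):
        with pytest.raises(ValueError):
            CodonCountTable({"AXA": 1})


class TestConcatenateSegments:
    def test_disjoint_union(self):
        wg = concatenate_segments(
            CodingSequence("s", "AAA", segment="L"),
            CodingSequence("s", "CCC", segment="M"),
            CodingSequence("s", "GGG", segment="S"),
        )
        assert wg.segment == "WG"
        t = count_codons(wg)
        assert (t.counts["AAA"], t.counts["CCC"], t.counts["GGG"]) == (1, 1, 1)

    def test_counts_equal_sum_of_segments_minus_stops(self):
        rng = np.random.default_rng(3)
        segs = []
        for name in "LMS":
            t = random_count_table(rng, max_count=4)
            segs.append(CodingSequence(
                "s", "".join(c * n for c, n in t.counts.items()), segment=name))
        wg = concatenate_segments(*segs)
        wg_counts = count_codons(wg)
        seg_counts = [count_codons(s) for s in segs]
        for codon in SENSE_CODONS:
            assert wg_counts.counts[codon] == sum(t.counts[codon] for t in seg_counts)

    def test_mismatched_ids_error(self):
        with pytest.raises(ValueError):
            concatenate_segments(
                CodingSequence("a", "AAA"), CodingSequence("b", "CCC"),
                CodingSequence("a", "GGG"))

    def test_empty_segment_error(self):
        with pytest.raises(ValueError):
            concatenate_segments(
                CodingSequence("a", "AAA"), CodingSequence("a", ""),
                CodingSequence("a", "GGG"))


class TestReferenceUsage:
    def test_uniform_table(self, tmp_path):
        rows = "\n".join(f"{c}\t1" for c in SENSE_CODONS)
        ref = read_reference_usage(_write(tmp_path, "r.tsv", f"codon\tcount\n{rows}\n"))
        assert all(abs(f - 1 / 61) < 1e-12 for f in ref.frequencies.values())

    def test_rna_spelling_normalized(self, tmp_path):
        rows = "codon\tcount\nUUU\t10\n" + "\n".join(
            f"{c}\t1" for c in SENSE_CODONS if c != "TTT")
        ref = read_reference_usage(_write(tmp_path, "r.tsv", rows + "\n"))
        assert ref.counts["TTT"] == 10

    def test_missing_codon_treated_as_zero(self, tmp_path):
        rows = "codon\tcount\n" + "\n".join(
            f"{c}\t1" for c in SENSE_CODONS if c != "CGT")
        ref = read_reference_usage(_write(tmp_path, "r.tsv", rows + "\n"))
        assert ref.counts["CGT"] == 0

    def test_stop_rows_ignored(self, tmp_path):
        rows = "codon\tcount\nTAA\t99\n" + "\n".join(f"{c}\t1" for c in SENSE_CODONS)
        ref = read_reference_usage(_write(tmp_path, "r.tsv", rows + "\n"))
        assert ref.counts["TAA"] == 0

    def test_non_numeric_count_errors(self, tmp_path):
        with pytest.raises(ValueError):
            read_reference_usage(_write(tmp_path, "r.tsv", "codon\tcount\nTTT\tmany\n"))
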