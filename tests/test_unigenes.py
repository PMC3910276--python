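"""Read cleaning, unigene selection, TPM, ORF calling, assembly stats."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from hypothesis import given, settings
from hypothesis import strategies as st

from interolog.unigenes import (
    READ1_ADAPTER,
    assembly_stats,
    clean_reads,
    compute_tpm,
    filter_by_length,
    find_longest_orf,
    parse_fastq,
    select_unigenes,
)


def _read(seq, read_id="r1"):
    rec = SeqRecord(Seq(seq), id=read_id, description="")
    rec.letter_annotations["phred_quality"] = [40] * len(seq)
    return rec


class TestCleanReads:
    def test_five_percent_boundary_is_kept(self):
        # exactly 5% N is not "larger than 5%"
        seq = "N" * 5 + "A" * 95
        kept, rep = clean_reads([_read(seq)])
        assert rep.kept == 1 and rep.dropped_n == 0

    def test_above_five_percent_is_dropped(self):
        seq = "N" * 6 + "A" * 94
        kept, rep = clean_reads([_read(seq)])
        assert kept == [] and rep.dropped_n == 1

    def test_adapter_suffix_trimmed(self):
        body = "ACGT" * 22  # 88 nt
        seq = body + READ1_ADAPTER[:12]
        kept, rep = clean_reads([_read(seq)])
        assert rep.trimmed == 1
        assert str(kept[0].seq) == body

    def test_short_adapter_overlap_not_trimmed(self):
        body = "ACGT" * 22
        seq = body + READ1_ADAPTER[:7]  # below the 8 nt minimum overlap
        kept, rep = clean_reads([_read(seq)])
        assert rep.trimmed == 0
        assert str(kept[0].seq) == seq

    def test_trimming_precedes_n_fraction_test(self):
        # 6 N in 94 nt body: >5% only after the adapter goes
        body = "N" * 6 + "A" * 88
        kept, rep = clean_reads([_read(body + READ1_ADAPTER[:10])])
        assert kept == [] and rep.trimmed == 1 and rep.dropped_n == 1

    def test_optional_quality_filter_defaults_off(self):
        rec = _read("A" * 50)
        rec.letter_annotations["phred_quality"] = [2] * 50
        kept, _ = clean_reads([rec])
        assert len(kept) == 1
        kept, rep = clean_reads([rec], min_mean_quality=20)
        assert kept == [] and rep.dropped_quality == 1

    def test_malformed_fastq_names_record_index(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@r1\nACGT\n+\nIIII\n@r2\nACGT\n+\nII\n")
        with pytest.raises(ValueError, match="record index 1"):
            with open(p) as fh:
                list(parse_fastq(fh))


class TestSelectUnigenes:
    def test_product_beats_length(self):
        df = pd.DataFrame(
            {
                "transcript_id": ["t_long", "t_short"],
                "gene_id": ["g1", "g1"],
                "length": [1000, 500],
                "isoform_percent": [30.0, 70.0],
            }
        )
        assert select_unigenes(df) == {"g1": "t_short"}  # 35000 > 30000

    def test_single_isoform_gene(self):
        df = pd.DataFrame(
            {"transcript_id": ["t1"], "gene_id": ["g1"], "length": [400],
             "isoform_percent": [100.0]}
        )
        assert select_unigenes(df) == {"g1": "t1"}

    def test_score_tie_broken_by_length(self):
        df = pd.DataFrame(
            {
                "transcript_id": ["a", "b"],
                "gene_id": ["g1", "g1"],
                "length": [800, 400],
                "isoform_percent": [50.0, 100.0],  # both score 40000
            }
        )
        assert select_unigenes(df) == {"g1": "a"}

    def test_one_choice_per_gene(self):
        rng = np.random.default_rng(5)
        n = 40
        df = pd.DataFrame(
            {
                "transcript_id": [f"t{i}" for i in range(n)],
                "gene_id": [f"g{i % 12}" for i in range(n)],
                "length": rng.integers(200, 3000, n),
                "isoform_percent": rng.uniform(1, 100, n),
            }
        )
        assert len(select_unigenes(df)) == df["gene_id"].nunique()


class TestTpm:
    def test_symmetric_transcripts_split_evenly(self):
        df = pd.DataFrame(
            {"transcript_id": ["a", "b"], "length": [300, 300],
             "expected_count": [7.0, 7.0]}
        )
        assert compute_tpm(df).tolist() == pytest.approx([5e5, 5e5])

    def test_zero_count_transcript_gets_zero(self):
        df = pd.DataFrame(
            {"transcript_id": ["a", "b"], "length": [100, 900],
             "expected_count": [10.0, 0.0]}
        )
        assert compute_tpm(df).tolist() == pytest.approx([1e6, 0.0])

    def test_length_normalization(self):
        # rates 1/100 and 2/400 -> 0.01 vs 0.005 -> 2/3 and 1/3 of a million
        df = pd.DataFrame(
            {"transcript_id": ["a", "b"], "length": [100, 400],
             "expected_count": [1.0, 2.0]}
        )
        tpm = compute_tpm(df)
        assert tpm.tolist() == pytest.approx([2e6 / 3, 1e6 / 3])

    def test_all_zero_counts_no_division_error(self):
        df = pd.DataFrame(
            {"transcript_id": ["a", "b"], "length": [100, 200],
             "expected_count": [0.0, 0.0]}
        )
        assert compute_tpm(df).tolist() == [0.0, 0.0]

    @given(st.lists(st.tuples(st.integers(1, 5000), st.floats(0.01, 1e5)),
                    min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_sums_to_one_million(self, rows):
        df = pd.DataFrame(
            {"transcript_id": [f"t{i}" for i in range(len(rows))],
             "length": [r[0] for r in rows],
             "expected_count": [r[1] for r in rows]}
        )
        assert compute_tpm(df).sum() == pytest.approx(1e6, rel=1e-9)


def _revcomp(s):
    return str(Seq(s).reverse_complement())


class TestFindLongestOrf:
    def test_simple_forward_orf(self):
        call = find_longest_orf("ATGAAATAG")
        assert (call.strand, call.start, call.end, call.protein) == ("+", 1, 9, "MK")
        assert call.has_stop

    def test_minus_strand_orf(self):
        call = find_longest_orf("CTATTTCAT")  # revcomp is ATGAAATAG
        assert (call.strand, call.start, call.end, call.protein) == ("-", 1, 9, "MK")

    def test_longest_orf_wins(self):
        # 9 nt ORF then a 15 nt ORF downstream, separated by padding
        seq = "ATGAAATAG" + "CC" + "ATGAAAGAAGCATGA"
        call = find_longest_orf(seq)
        assert call.nt_length == 15
        assert call.protein == "MKEA"

    def test_stop_included_in_coordinates(self):
        call = find_longest_orf("CCATGAAATAGCC")
        assert (call.start, call.end) == (3, 11)
        assert (call.end - call.start + 1) % 3 == 0

    def test_open_stretch_when_no_stop(self):
        call = find_longest_orf("ATGAAAGGG")
        assert call.found and not call.has_stop
        assert call.protein == "MKG"

    def test_no_orf_and_empty_sequence(self):
        assert not find_longest_orf("CCCCCC").found
        assert not find_longest_orf("").found

    @staticmethod
    def _enumerate_orf_lengths(seq):
        """Independent brute enumeration of all complete ORF lengths (6 frames)."""
        lengths = []
        for s in (seq, _revcomp(seq)):
            for frame in range(3):
                codons = [s[i : i + 3] for i in range(frame, len(s) - 2, 3)]
                start = None
                for ci, codon in enumerate(codons):
                    if start is None and codon == "ATG":
                        start = ci
                    elif start is not None and codon in {"TAA", "TAG", "TGA"}:
                        lengths.append(3 * (ci - start + 1))
                        start = None
        return lengths

    def test_strand_symmetry_on_random_sequences(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=120))
            fwd = find_longest_orf(seq)
            rev = find_longest_orf(_revcomp(seq))
            assert fwd.found == rev.found
            if not fwd.found:
                continue
            assert fwd.nt_length == rev.nt_length
            lengths = self._enumerate_orf_lengths(seq)
            if lengths and lengths.count(max(lengths)) == 1:
                # unique longest ORF: the call is fully strand-symmetric
                assert fwd.protein == rev.protein
                assert fwd.strand != rev.strand
                assert rev.start == len(seq) - fwd.end + 1
                assert rev.end == len(seq) - fwd.start + 1


class TestAssemblyStats:
    def test_hand_scanned_n50(self):
        s = assembly_stats([2, 3, 4, 5, 6])
        assert (s.n50, s.mean_length, s.total_nt) == (5, 4.0, 20)

    def test_single_sequence(self):
        s = assembly_stats([10])
        assert (s.n50, s.mean_length) == (10, 10.0)

    def test_equal_lengths(self):
        assert assembly_stats([77] * 9).n50 == 77

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            assembly_stats([])

    def test_n50_matches_prefix_scan_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            lengths = rng.integers(1, 5000, size=int(rng.integers(1, 60))).tolist()
            total = sum(lengths)
            cum, expected = 0, None
            for length in sorted(lengths, reverse=True):
                cum += length
                if cum >= total / 2:
                    expected = length
                    break
            stats = assembly_stats(lengths)
            assert stats.n50 == expected
            assert stats.n50 >= min(lengths)
            assert stats.total_nt == total


class TestLengthFilter:
    def test_strictly_longer_than_300(self):
        recs = [
            SeqRecord(Seq("A" * 299), id="a"),
            SeqRecord(Seq("A" * 300), id="b"),
            SeqRecord(Seq("A" * 301), id="c"),
        ]
        assert [r.id for r in filter_by_length(recs)] == ["c"]
        assert [r.id for r in filter_by_length(recs, strict=False)] == ["b", "c"]
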