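import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from preyweb.read_processing import (
    FastqFormatError,
    Read,
    SampleSheetEntry,
    SampleSheetError,
    demultiplex,
    parse_fastq,
    parse_sample_sheet,
    process_reads,
    quality_filter,
    trim_3prime,
    trim_primer,
    write_fastq,
)
from oracles import filter_label_oracle, trim_oracle


class TestDemultiplex:
    def test_exact_match_assigned(self, make_read, simple_sheet):
        read = make_read(fwd_index="AAAAAAAA", rev_index="CCCCCCCC")
        assigned, stats = demultiplex([read], simple_sheet)
        assert [r.read_id for r in assigned["s1"]] == ["r1"]
        assert stats.n_assigned == 1

    def test_single_index_mismatch_discarded(self, make_read, simple_sheet):
        read = make_read(fwd_index="AAAAAAAT", rev_index="CCCCCCCC")
        assigned, stats = demultiplex([read], simple_sheet)
        assert stats.n_index_mismatch == 1
        assert all(not reads for reads in assigned.values())

    def test_low_quality_index_discarded_even_if_matching(
        self, make_read, simple_sheet
    ):
        read = make_read(fwd_index="AAAAAAAA", rev_index="CCCCCCCC")
        read = Read(
            read_id=read.read_id,
            bases=read.bases,
            quals=read.quals,
            fwd_index=read.fwd_index,
            rev_index=read.rev_index,
            fwd_index_quals=(35, 35, 35, 29, 35, 35, 35, 35),
            rev_index_quals=read.rev_index_quals,
        )
        _, stats = demultiplex([read], simple_sheet)
        assert stats.n_index_lowq == 1
        assert stats.n_assigned == 0

    def test_q30_index_boundary_is_kept(self, make_read, simple_sheet):
        read = make_read(index_q=30)
        _, stats = demultiplex([read], simple_sheet)
        assert stats.n_index_lowq == 0
        assert stats.n_assigned == 1

    def test_lowq_checked_before_mismatch(self, make_read, simple_sheet):
        read = make_read(fwd_index="NNNNNNNN", index_q=2)
        _, stats = demultiplex([read], simple_sheet)
        assert stats.n_index_lowq == 1
        assert stats.n_index_mismatch == 0

    def test_one_mismatch_allowed_mode(self, make_read, simple_sheet):
        read = make_read(fwd_index="AAAAAAAT", rev_index="CCCCCCCC")
        assigned, stats = demultiplex([read], simple_sheet, allowed_mismatches=1)
        assert len(assigned["s1"]) == 1

    def test_duplicate_index_pairs_rejected(self, make_read):
        sheet = [
            SampleSheetEntry("a", "x", "s", "AAAAAAAA", "CCCCCCCC"),
            SampleSheetEntry("b", "x", "s", "AAAAAAAA", "CCCCCCCC"),
        ]
        with pytest.raises(SampleSheetError):
            demultiplex([make_read()], sheet)

    def test_empty_sheet_rejected(self, make_read):
        with pytest.raises(SampleSheetError):
            demultiplex([make_read()], [])


class TestTrim3Prime:
    def test_clean_read_unchanged(self, make_read):
        read = make_read(quals=[35] * 200)
        assert trim_3prime(read) is read

    def test_five_bad_terminal_bases_trimmed(self, make_read):
        read = make_read(bases="A" * 205, quals=[35] * 200 + [20] * 5)
        assert len(trim_3prime(read)) == 200

    def test_cascading_trim(self, make_read):
        quals = [35] * 10 + [20] + [35] * 4
        read = make_read(bases="A" * 15, quals=quals)
        # trimming peels until the Q20 base leaves the 5-base window
        assert len(trim_3prime(read)) == 10

    def test_short_read_left_alone(self, make_read):
        read = make_read(bases="ACG", quals=[5, 5, 5])
        assert trim_3prime(read) is read

    def test_bases_and_quals_trimmed_together(self, make_read):
        read = make_read(bases="ACGTACGT", quals=[35] * 7 + [10])
        out = trim_3prime(read)
        assert len(out.bases) == len(out.quals)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=41), min_size=0, max_size=60))
    def test_matches_oracle_and_idempotent(self, quals):
        read = Read(read_id="r", bases="A" * len(quals), quals=tuple(quals))
        out = trim_3prime(read)
        assert len(out) == trim_oracle(list(quals))
        assert len(out) <= len(read)
        assert len(trim_3prime(out)) == len(out)  # idempotent


class TestQualityFilter:
    def test_169_bases_rejected(self, make_read):
        read = make_read(bases="A" * 169, quals=[40] * 169)
        assert quality_filter(read) == (False, "length")

    def test_170_bases_kept(self, make_read):
        read = make_read(bases="A" * 170, quals=[40] * 170)
        assert quality_filter(read) == (True, "")

    def test_ten_percent_lowq_rejected(self, make_read):
        quals = [29] * 20 + [40] * 180
        read = make_read(bases="A" * 200, quals=quals)
        assert quality_filter(read) == (False, "quality_fraction")

    def test_just_under_ten_percent_kept(self, make_read):
        quals = [29] * 19 + [40] * 181
        read = make_read(bases="A" * 200, quals=quals)
        assert quality_filter(read) == (True, "")


class TestTrimPrimer:
    def test_exact_primer_with_pad_stripped(self, make_read):
        primer = "TGTGAACTGCAGGACACATGA"
        bases = "NNNN" + primer + "ACGT" * 50
        read = make_read(bases=bases, quals=[35] * len(bases))
        out = trim_primer(read, primer)
        assert out.bases == "ACGT" * 50

    def test_one_mismatch_tolerated(self, make_read):
        primer = "TGTGAACTGCAGGACACATGA"
        seen = "A" + primer[1:]
        bases = seen + "ACGT" * 50
        read = make_read(bases=bases, quals=[35] * len(bases))
        assert trim_primer(read, primer).bases == "ACGT" * 50

    def test_absent_primer_returns_none(self, make_read):
        read = make_read(bases="G" * 100, quals=[35] * 100)
        assert trim_primer(read, "TGTGAACTGCAGGACACATGA") is None


class TestFastqRoundtrip:
    def test_roundtrip(self, make_read):
        reads = [make_read(read_id=f"r{i}") for i in range(3)]
        buf = io.StringIO()
        write_fastq(reads, buf)
        buf.seek(0)
        back = list(parse_fastq(buf))
        assert back == reads

    def test_bad_header_raises(self):
        with pytest.raises(FastqFormatError):
            list(parse_fastq(io.StringIO("notfastq\nACGT\n+\nIIII\n")))

    def test_non_phred33_rejected(self):
        # qualities above the Phred+33 ceiling
        with pytest.raises(FastqFormatError):
            list(parse_fastq(io.StringIO("@r\nACGT\n+\n~~~~\n")))


class TestSampleSheet:
    def test_parse_with_subject_column(self):
        text = (
            "sample_id\tspecies\tsetting\tfwd_index\trev_index"
            "\tis_negative_control\tsubject_id\n"
            "s1.blockA\tSpiderA\tblockA\tAAAAAAAA\tCCCCCCCC\t0\tind1\n"
            "s1.noblock\tSpiderA\tnoblock\tAAAAAAAA\tGGGGGGGG\t0\tind1\n"
        )
        entries = parse_sample_sheet(io.StringIO(text))
        assert entries[0].subject_id == "ind1"
        assert entries[0].sample_id == "s1.blockA"

    def test_subject_defaults_to_sample_id(self):
        text = (
            "sample_id\tspecies\tsetting\tfwd_index\trev_index"
            "\tis_negative_control\n"
            "s1\tSpiderA\tblockA\tAAAAAAAA\tCCCCCCCC\t0\n"
        )
        assert parse_sample_sheet(io.StringIO(text))[0].subject_id == "s1"

    def test_duplicate_pairs_rejected(self):
        text = (
            "sample_id\tspecies\tsetting\tfwd_index\trev_index"
            "\tis_negative_control\n"
            "s1\tA\tx\tAAAAAAAA\tCCCCCCCC\t0\n"
            "s2\tB\tx\tAAAAAAAA\tCCCCCCCC\t0\n"
        )
        with pytest.raises(SampleSheetError):
            parse_sample_sheet(io.StringIO(text))


class TestPartitionInvariant:
    def _random_reads(self, rng, n=300):
        reads = []
        for i in range(n):
            length = int(rng.integers(100, 260))
            bases = "".join(rng.choice(list("ACGT"), size=length))
            quals = rng.integers(20, 41, size=length).tolist()
            known = rng.random() < 0.8
            fwd = "AAAAAAAA" if known else "TTTTTTTT"
            iq = 35 if rng.random() < 0.9 else 25
            reads.append(
                Read(
                    read_id=f"r{i}",
                    bases=bases,
                    quals=tuple(quals),
                    fwd_index=fwd,
                    rev_index="CCCCCCCC",
                    fwd_index_quals=tuple([iq] * 8),
                    rev_index_quals=tuple([35] * 8),
                )
            )
        return reads

    def test_every_read_in_exactly_one_class(self, rng):
        sheet = [SampleSheetEntry("s1", "A", "x", "AAAAAAAA", "CCCCCCCC")]
        reads = self._random_reads(rng)
        kept, stats = process_reads(reads, sheet)
        assert stats.n_input == len(reads)
        assert (
            stats.n_index_lowq
            + stats.n_index_mismatch
            + stats.n_trimmed_short
            + stats.n_lowq_frac
            + stats.n_kept
        ) == stats.n_input
        assert sum(len(v) for v in kept.values()) == stats.n_kept

    def test_order_stability(self, rng):
        sheet = [SampleSheetEntry("s1", "A", "x", "AAAAAAAA", "CCCCCCCC")]
        reads = self._random_reads(rng, n=120)
        kept_fwd, _ = process_reads(reads, sheet)
        kept_rev, _ = process_reads(list(reversed(reads)), sheet)
        ids_fwd = {sid: sorted(r.read_id for r in v) for sid, v in kept_fwd.items()}
        ids_rev = {sid: sorted(r.read_id for r in v) for sid, v in kept_rev.items()}
        assert ids_fwd == ids_rev
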