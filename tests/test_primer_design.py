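import pytest

from preyweb import iupac
from preyweb.primer_design import (
    AlignmentShapeError,
    CoordinateError,
    WindowingError,
    build_profile,
    design_blocking_primers,
    find_discriminative_windows,
    match_primer,
)

# published primer sequences (amplification + blocking)
ITS3_HEXA_F = "TGTGAACTGCAGGACACATGA"
ITS4_HEXA_R = "TCCTCCGCTTATTAATATGC"
ITS3_ARANEAE_F = "TGTGAATTGCAGGACACATYG"
ITS4_ARANEAE_R = "TCCTCCGCTTATTTATATGC"
BLOCK_A = "ATTGCAGGACACATTGAGC"
BLOCK_B = "GACACATTGAGCACTGATT"


class TestBuildProfile:
    def test_single_sequence_identity(self):
        prof = build_profile(["ACGT"], "x")
        assert prof.consensus() == "ACGT"
        assert prof.n_sequences == 1
        for col, base in zip(prof.columns, "ACGT"):
            assert col.base_freq(base) == 1.0
            assert col.gap_fraction == 0.0

    def test_two_sequence_ambiguity_M(self):
        prof = build_profile(["AAAA", "CAAA"], "x")
        assert prof.columns[0].consensus_code == "M"  # {A, C}
        assert prof.columns[1].consensus_code == "A"

    def test_gap_majority_column(self):
        # 10 sequences, 6 have '-' at column 7
        seqs = []
        for i in range(10):
            s = list("ACGTACGTAC")
            if i < 6:
                s[7] = "-"
            seqs.append("".join(s))
        prof = build_profile(seqs, "x")
        assert prof.columns[7].gap_fraction == pytest.approx(0.6)
        assert prof.columns[7].consensus_code == "-"

    def test_column_frequencies_sum_to_one(self):
        prof = build_profile(["ACGT", "AC-T", "GCGA"], "x")
        for col in prof.columns:
            if col.gap_fraction < 1.0:
                total = col.freq_A + col.freq_C + col.freq_G + col.freq_T
                assert total == pytest.approx(1.0, abs=1e-9)

    def test_iupac_weight_split(self):
        prof = build_profile(["R"], "x")  # R = {A, G}
        assert prof.columns[0].freq_A == pytest.approx(0.5)
        assert prof.columns[0].freq_G == pytest.approx(0.5)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(AlignmentShapeError):
            build_profile(["ACGT", "ACG"], "x")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_profile([], "x")


class TestMatchPrimer:
    def test_published_reverse_primers_differ_at_position_14(self):
        report = match_primer(ITS4_HEXA_R, ITS4_ARANEAE_R)
        assert report.total_mismatches == 1
        assert report.three_prime_mismatches == 0
        assert report.per_position[13] == "mismatch"  # position 14, 1-based

    def test_self_match_is_clean(self):
        for primer in (ITS3_HEXA_F, ITS4_HEXA_R, ITS3_ARANEAE_F, BLOCK_A):
            assert match_primer(primer, primer).total_mismatches == 0

    def test_degenerate_Y_matches_C(self):
        assert ITS3_ARANEAE_F[19] == "Y"
        site = ITS3_ARANEAE_F[:19] + "C" + ITS3_ARANEAE_F[20:]
        report = match_primer(ITS3_ARANEAE_F, site)
        assert report.per_position[19] == "match"

    def test_gap_in_site_counts_as_mismatch_and_indel(self):
        report = match_primer("ACGT", "AC-T")
        assert report.total_mismatches == 1
        assert report.indel_overlap
        assert report.per_position[2] == "gap"

    def test_strict_n_site_never_matches(self):
        assert match_primer("ACGT", "ACNT").total_mismatches == 1

    def test_length_mismatch_raises(self):
        with pytest.raises(WindowingError):
            match_primer("ACGT", "ACG")

    def test_blocking_primer_prefix_matches_araneae_forward(self):
        # 14-nt prefix of blocking primer A = positions 6-19 (1-based)
        # of the excluded-clade forward primer
        assert BLOCK_A[:14] == ITS3_ARANEAE_F[5:19]


def _indel_fixture():
    """60-column alignments identical except a deletion in the excluded
    clade at column 40 (0-based)."""
    base = (
        "TGTGAACTGCAGGACACATGAAACGTTCGATCGGATCCAATGGCATCGTAGCTAGCTAGA"
    )
    assert len(base) == 60
    target = [base, base, base]
    excl_seq = base[:40] + "-" + base[41:]
    excluded = [excl_seq, excl_seq, excl_seq]
    return build_profile(target, "target"), build_profile(excluded, "excluded")


class TestDiscriminativeWindows:
    def test_identical_profiles_give_no_candidates(self):
        prof = build_profile(["ACGTACGTACGTACGTACGTACGT" * 2], "x")
        assert find_discriminative_windows(prof, prof, (17, 20)) == []

    def test_indel_fixture_top_forward_ends_at_deletion(self):
        target, excluded = _indel_fixture()
        out = find_discriminative_windows(target, excluded, (15, 20))
        assert out
        top_forward = next(c for c in out if c.direction == "forward")
        # 0-based half-open: stop=41 means the 3'-terminal position is
        # column 40, the deletion site
        assert top_forward.window[1] == 41
        assert top_forward.excluded_report.indel_overlap
        assert top_forward.excluded_report.three_prime_mismatches >= 1

    def test_two_terminal_mismatches_outrank_one(self):
        base = "TGTGAACTGCAGGACACATGAAACGTTCGATCGGATCCAATGGCATCGTAGCTAGCTAGA"
        # site X: two substitutions at columns 18,19; site Y: one at column 49
        exc = list(base)
        exc[18] = "G" if base[18] != "G" else "A"
        exc[19] = "C" if base[19] != "C" else "T"
        exc[49] = "T" if base[49] != "T" else "G"
        target = build_profile([base], "t")
        excluded = build_profile(["".join(exc)], "e")
        out = find_discriminative_windows(target, excluded, (15, 20))
        assert out[0].excluded_report.three_prime_mismatches == 2

    def test_coordinate_mismatch_raises(self):
        a = build_profile(["ACGTACGTACGTACGTACGTACGT"], "a")
        b = build_profile(["ACGTACGTACGTACGTACGTACG"], "b")
        with pytest.raises(CoordinateError):
            find_discriminative_windows(a, b, (17, 20))

    def test_enumeration_order_does_not_change_ranking(self):
        target, excluded = _indel_fixture()
        fwd_first = find_discriminative_windows(
            target, excluded, (15, 20), directions=("forward", "reverse")
        )
        rev_first = find_discriminative_windows(
            target, excluded, (15, 20), directions=("reverse", "forward")
        )
        assert fwd_first == rev_first

    def test_candidates_conserved_in_target(self):
        target, excluded = _indel_fixture()
        for cand in find_discriminative_windows(target, excluded, (15, 20)):
            assert cand.target_conservation >= 0.9
            # primer is read off the target consensus: re-scoring against
            # it must be clean
            start, stop = cand.window
            site = target.consensus(start, stop)
            if cand.direction == "reverse":
                site = iupac.reverse_complement(site)
            assert match_primer(cand.sequence, site).total_mismatches == 0


class TestBlockingPrimers:
    def test_indel_fixture_yields_blocking_candidates(self):
        target, excluded = _indel_fixture()
        out = design_blocking_primers(excluded, target, (38, 42), (15, 20))
        assert out
        for cand in out:
            assert cand.is_blocking
            assert cand.three_prime_modification == "C3_spacer"
            assert cand.excluded_report.three_prime_mismatches >= 1
            # spans the anchor
            assert cand.window[0] < 42 and cand.window[1] > 38

    def test_blocking_primer_matches_excluded_consensus(self):
        target, excluded = _indel_fixture()
        for cand in design_blocking_primers(excluded, target, (38, 42), (15, 20)):
            start, stop = cand.window
            ungapped = excluded.consensus(start, stop).replace("-", "")
            assert cand.sequence == ungapped

    def test_identical_profiles_give_empty_list(self):
        prof = build_profile(["ACGTACGTACGTACGTACGTACGTACGTACGT"], "x")
        assert design_blocking_primers(prof, prof, (10, 14), (15, 20)) == []

    def test_anchor_outside_alignment_raises(self):
        target, excluded = _indel_fixture()
        with pytest.raises(CoordinateError):
            design_blocking_primers(excluded, target, (55, 70), (15, 20))


class TestExhaustiveOracle:
    def test_window_scan_matches_brute_force(self):
        """Independent exhaustive enumeration reproduces the candidate set
        on alignments of <= 80 columns."""
        target, excluded = _indel_fixture()
        length_range = (15, 20)
        k3 = 3
        got = find_discriminative_windows(target, excluded, length_range)

        expected = []
        ncol = len(target.columns)
        for length in range(length_range[0], length_range[1] + 1):
            for start in range(ncol - length + 1):
                stop = start + length
                tgt_cols = target.columns[start:stop]
                if any(c.consensus_code == "-" for c in tgt_cols):
                    continue
                seq = "".join(c.consensus_code for c in tgt_cols)
                site = excluded.consensus(start, stop)
                for direction in ("forward", "reverse"):
                    p, s = seq, site
                    if direction == "reverse":
                        p = iupac.reverse_complement(p)
                        s = iupac.reverse_complement(s)
                    if sum(c not in "ACGT" for c in p) > 2:
                        continue
                    cons = sum(
                        c.consensus_frequency() for c in tgt_cols
                    ) / len(tgt_cols)
                    if cons < 0.9:
                        continue
                    report = match_primer(p, s, k_3prime=k3)
                    if report.total_mismatches == 0:
                        continue
                    expected.append((p, direction, (start, stop), report))

        def key(item):
            p, direction, window, report = item
            return (
                -report.three_prime_mismatches,
                -int("gap" in report.per_position[-k3:]),
                -report.total_mismatches,
                0.0,  # conservation ties (all 1.0 in this fixture)
                window,
                direction,
            )

        expected.sort(key=key)
        assert [(c.sequence, c.direction, c.window) for c in got] == [
            (p, d, w) for p, d, w, _ in expected
        ]
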