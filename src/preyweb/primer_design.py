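"""Clade-discriminative amplification-primer and blocking-primer design.

Works on two pre-computed multiple alignments sharing one coordinate
system: a target clade (amplified) and an excluded clade (suppressed).
Candidate windows are enumerated exhaustively; discriminative windows are
ranked by mismatch load against the excluded clade concentrated at the
primer 3' terminus, and blocking primers are anchored on insertion/deletion
columns and flagged for a C3 spacer so they cannot be extended.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from . import iupac

DEFAULT_LENGTH_RANGE = (17, 25)
DEFAULT_K3 = 3
DEFAULT_INCLUSION = 0.2
DEFAULT_GAP_MAJORITY = 0.5
DEFAULT_MAX_DEGENERATE = 2


class AlignmentShapeError(ValueError):
    """Records of a gapped alignment differ in length."""


class CoordinateError(ValueError):
    """Profiles or windows on incompatible alignment coordinates."""


class WindowingError(ValueError):
    """Primer and extracted site have different lengths."""


@dataclass(frozen=True)
class ProfileColumn:
    freq_A: float
    freq_C: float
    freq_G: float
    freq_T: float
    gap_fraction: float
    consensus_code: str

    def base_freq(self, base: str) -> float:
        return getattr(self, f"freq_{base}")

    def consensus_frequency(self) -> float:
        """Summed frequency of the bases covered by the consensus code."""
        if self.consensus_code == iupac.GAP:
            return 0.0
        return sum(self.base_freq(b) for b in iupac.base_set(self.consensus_code))


@dataclass(frozen=True)
class AlignmentProfile:
    clade_label: str
    n_sequences: int
    columns: tuple[ProfileColumn, ...]

    def __len__(self) -> int:
        return len(self.columns)

    def consensus(self, start: int = 0, stop: int | None = None) -> str:
        stop = len(self.columns) if stop is None else stop
        return "".join(c.consensus_code for c in self.columns[start:stop])


@dataclass(frozen=True)
class MismatchReport:
    aligned_length: int
    total_mismatches: int
    three_prime_mismatches: int
    indel_overlap: bool
    per_position: tuple[str, ...]  # 'match' | 'mismatch' | 'gap', 5'->3'

    def __post_init__(self) -> None:
        if not (
            self.three_prime_mismatches
            <= self.total_mismatches
            <= self.aligned_length
        ):
            raise ValueError("inconsistent mismatch counts")

    def three_prime_gap(self, k: int = DEFAULT_K3) -> bool:
        return "gap" in self.per_position[-k:]


@dataclass(frozen=True)
class PrimerCandidate:
    sequence: str
    direction: str  # 'forward' | 'reverse'
    window: tuple[int, int]  # 0-based half-open alignment columns
    target_conservation: float
    excluded_report: MismatchReport
    is_blocking: bool = False
    three_prime_modification: str = "none"  # 'none' | 'C3_spacer'

    def __post_init__(self) -> None:
        if self.is_blocking and self.three_prime_modification != "C3_spacer":
            raise ValueError("blocking primers require a C3 spacer")


def build_profile(
    alignment: Iterable[tuple[str, str]] | Iterable[str],
    clade_label: str,
    inclusion_threshold: float = DEFAULT_INCLUSION,
    gap_majority: float = DEFAULT_GAP_MAJORITY,
) -> AlignmentProfile:
    """Column-wise base/gap frequencies and IUPAC consensus of an alignment.

    `alignment` yields aligned sequences, or (id, sequence) pairs.  IUPAC
    residues distribute fractional weight over their base sets; 'N' weighs
    each base 0.25.  The consensus code is the minimal IUPAC code covering
    every base whose (non-gap) frequency reaches `inclusion_threshold`;
    a column whose gap fraction reaches `gap_majority` is called '-'.
    """
    seqs: list[str] = []
    for rec in alignment:
        seq = rec[1] if isinstance(rec, tuple) else rec
        seqs.append(seq.upper())
    if not seqs:
        raise ValueError("empty alignment")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise AlignmentShapeError("aligned records differ in length")

    n = len(seqs)
    columns: list[ProfileColumn] = []
    for col in range(length):
        weight = {"A": 0.0, "C": 0.0, "G": 0.0, "T": 0.0}
        gaps = 0
        for s in seqs:
            ch = s[col]
            if ch in (iupac.GAP, "."):
                gaps += 1
                continue
            bases = iupac.base_set(ch)
            w = 1.0 / len(bases)
            for b in bases:
                weight[b] += w
        non_gap = n - gaps
        gap_fraction = gaps / n
        if non_gap > 0:
            freqs = {b: weight[b] / non_gap for b in "ACGT"}
        else:
            freqs = {b: 0.0 for b in "ACGT"}
        if gap_fraction >= gap_majority or non_gap == 0:
            code = iupac.GAP
        else:
            included = {b for b in "ACGT" if freqs[b] >= inclusion_threshold}
            if not included:
                included = {max("ACGT", key=lambda b: freqs[b])}
            code = iupac.code_for(included)
        columns.append(
            ProfileColumn(
                freq_A=freqs["A"],
                freq_C=freqs["C"],
                freq_G=freqs["G"],
                freq_T=freqs["T"],
                gap_fraction=gap_fraction,
                consensus_code=code,
            )
        )
    return AlignmentProfile(
        clade_label=clade_label, n_sequences=n, columns=tuple(columns)
    )


def match_primer(
    primer: str,
    site: str,
    k_3prime: int = DEFAULT_K3,
    strict_n: bool = True,
) -> MismatchReport:
    """Score a primer (5'->3') against a site given in primer orientation.

    Position i matches iff the site base is in the primer code's IUPAC
    base set.  A gap character in the site counts as a mismatch and sets
    `indel_overlap`.
    """
    if not primer or not site:
        raise ValueError("primer and site must be non-empty")
    if len(primer) != len(site):
        raise WindowingError(
            f"primer length {len(primer)} != site length {len(site)}"
        )
    flags: list[str] = []
    indel = False
    for p, s in zip(primer.upper(), site.upper()):
        if s == iupac.GAP:
            flags.append("gap")
            indel = True
        elif iupac.matches(p, s, strict_n=strict_n):
            flags.append("match")
        else:
            flags.append("mismatch")
    total = sum(f != "match" for f in flags)
    k = min(k_3prime, len(flags))
    three_prime = sum(f != "match" for f in flags[-k:])
    return MismatchReport(
        aligned_length=len(flags),
        total_mismatches=total,
        three_prime_mismatches=three_prime,
        indel_overlap=indel,
        per_position=tuple(flags),
    )


def _window_candidate(
    target: AlignmentProfile,
    excluded: AlignmentProfile,
    start: int,
    stop: int,
    direction: str,
    k_3prime: int,
    min_target_conservation: float,
    max_degenerate: int,
) -> PrimerCandidate | None:
    tgt_cols = target.columns[start:stop]
    if any(c.consensus_code == iupac.GAP for c in tgt_cols):
        return None
    seq = "".join(c.consensus_code for c in tgt_cols)
    site = excluded.consensus(start, stop)
    if direction == "reverse":
        seq = iupac.reverse_complement(seq)
        site = iupac.reverse_complement(site)
    if sum(iupac.is_degenerate(c) for c in seq) > max_degenerate:
        return None
    conservation = sum(c.consensus_frequency() for c in tgt_cols) / len(tgt_cols)
    if conservation < min_target_conservation:
        return None
    report = match_primer(seq, site, k_3prime=k_3prime)
    return PrimerCandidate(
        sequence=seq,
        direction=direction,
        window=(start, stop),
        target_conservation=conservation,
        excluded_report=report,
    )


def _rank_key(c: PrimerCandidate, k_3prime: int):
    r = c.excluded_report
    return (
        -r.three_prime_mismatches,
        -int(r.three_prime_gap(k_3prime)),
        -r.total_mismatches,
        -c.target_conservation,
        c.window,
        c.direction,
    )


def find_discriminative_windows(
    target: AlignmentProfile,
    excluded: AlignmentProfile,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    min_target_conservation: float = 0.9,
    k_3prime: int = DEFAULT_K3,
    max_degenerate: int = DEFAULT_MAX_DEGENERATE,
    directions: Sequence[str] = ("forward", "reverse"),
) -> list[PrimerCandidate]:
    """Exhaustively enumerate and rank clade-discriminative primer windows.

    Every window start and length in range is scored in both orientations;
    candidates conserved in the target below threshold, exceeding the
    degeneracy budget, or with zero mismatches to the excluded consensus
    are dropped.  Ranking (descending): excluded 3'-terminal mismatches,
    indel overlap at the 3' terminus, excluded total mismatches, target
    conservation; window coordinates break remaining ties, making the
    order total and independent of enumeration order.
    """
    if len(target) != len(excluded):
        raise CoordinateError(
            f"profiles differ in column count: {len(target)} != {len(excluded)}"
        )
    lo, hi = length_range
    ncol = len(target)
    out: list[PrimerCandidate] = []
    for length in range(lo, hi + 1):
        for start in range(0, ncol - length + 1):
            for direction in directions:
                cand = _window_candidate(
                    target,
                    excluded,
                    start,
                    start + length,
                    direction,
                    k_3prime,
                    min_target_conservation,
                    max_degenerate,
                )
                if cand is None:
                    continue
                if cand.excluded_report.total_mismatches == 0:
                    continue  # not discriminative
                out.append(cand)
    out.sort(key=lambda c: _rank_key(c, k_3prime))
    return out


def design_blocking_primers(
    excluded: AlignmentProfile,
    target: AlignmentProfile,
    anchor_window: tuple[int, int],
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    k_3prime: int = DEFAULT_K3,
    max_degenerate: int = DEFAULT_MAX_DEGENERATE,
) -> list[PrimerCandidate]:
    """Design excluded-clade blocking primers spanning an indel anchor.

    Each candidate is read off the excluded-clade consensus (gap columns
    dropped, so the primer spans the insertion/deletion junction), must
    overlap `anchor_window`, and must carry at least one mismatch to the
    target consensus within its `k_3prime` terminal positions — a column
    deleted in the excluded clade but present in the target counts as a
    mismatch there.  All candidates are flagged with a 3' C3 spacer.
    """
    if len(target) != len(excluded):
        raise CoordinateError("profiles differ in column count")
    a_start, a_stop = anchor_window
    ncol = len(excluded)
    if not (0 <= a_start < a_stop <= ncol):
        raise CoordinateError(f"anchor {anchor_window} outside alignment")
    lo, hi = length_range
    out: list[PrimerCandidate] = []
    # enumerate column windows; primer length = non-gap excluded columns
    max_span = hi * 2  # a window may contain gap columns
    for start in range(0, ncol):
        for stop in range(start + lo, min(ncol, start + max_span) + 1):
            if stop <= a_start or start >= a_stop:
                continue  # no overlap with the anchor
            cols = range(start, stop)
            primer_chars: list[str] = []
            flags: list[str] = []
            indel = False
            ok = True
            for c in cols:
                exc = excluded.columns[c].consensus_code
                tgt = target.columns[c].consensus_code
                if exc == iupac.GAP:
                    # deletion in the excluded clade; a target base here is
                    # skipped by the primer -> mismatch attributed to the
                    # junction (the next primer position)
                    if tgt != iupac.GAP:
                        flags.append("gap")
                        indel = True
                    continue
                primer_chars.append(exc)
                if tgt == iupac.GAP:
                    flags.append("gap")
                    indel = True
                elif iupac.matches(exc, tgt):
                    flags.append("match")
                else:
                    flags.append("mismatch")
            plen = len(primer_chars)
            if not (lo <= plen <= hi):
                continue
            seq = "".join(primer_chars)
            if sum(iupac.is_degenerate(ch) for ch in seq) > max_degenerate:
                ok = False
            k = min(k_3prime, len(flags))
            three_prime = sum(f != "match" for f in flags[-k:])
            if three_prime < 1 or not ok:
                continue
            total = sum(f != "match" for f in flags)
            report = MismatchReport(
                aligned_length=len(flags),
                total_mismatches=total,
                three_prime_mismatches=three_prime,
                indel_overlap=indel,
                per_position=tuple(flags),
            )
            tgt_cols = [
                excluded.columns[c]
                for c in cols
                if excluded.columns[c].consensus_code != iupac.GAP
            ]
            conservation = sum(c.consensus_frequency() for c in tgt_cols) / plen
            out.append(
                PrimerCandidate(
                    sequence=seq,
                    direction="forward",
                    window=(start, stop),
                    target_conservation=conservation,
                    excluded_report=report,
                    is_blocking=True,
                    three_prime_modification="C3_spacer",
                )
            )
    out.sort(key=lambda c: _rank_key(c, k_3prime))
    return out


def candidates_to_tsv(candidates: Sequence[PrimerCandidate]) -> str:
    """Serialize candidates as a TSV table (1-based inclusive coordinates)."""
    lines = [
        "sequence\tdirection\twindow_start\twindow_end\tlength"
        "\ttarget_conservation\texcluded_total_mismatches"
        "\texcluded_3prime_mismatches\tindel_overlap\tmodification"
    ]
    for c in candidates:
        r = c.excluded_report
        lines.append(
            "\t".join(
                [
                    c.sequence,
                    c.direction,
                    str(c.window[0] + 1),
                    str(c.window[1]),
                    str(len(c.sequence)),
                    f"{c.target_conservation:.4f}",
                    str(r.total_mismatches),
                    str(r.three_prime_mismatches),
                    str(int(r.indel_overlap)),
                    c.three_prime_modification,
                ]
            )
        )
    return "\n".join(lines) + "\n"
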