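"""Demultiplexing and quality control of indexed forward amplicon reads.

The filter cascade mirrors a stringent index-and-quality dialect: reads
with any index base below Q30 are dropped, index matching is exact by
default, 3' ends are peeled back until the terminal five bases are all
Q30+, and reads shorter than 170 bp or carrying >= 10% sub-Q30 bases are
eliminated.  Each read lands in exactly one accounting class.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from . import iupac

PHRED_OFFSET = 33

DEFAULT_MIN_INDEX_Q = 30
DEFAULT_TRIM_WINDOW = 5
DEFAULT_TRIM_MIN_Q = 30
DEFAULT_MIN_LEN = 170
DEFAULT_MAX_LOWQ_FRACTION = 0.10
DEFAULT_Q_THRESH = 30


class SampleSheetError(ValueError):
    pass


class FastqFormatError(ValueError):
    pass


@dataclass(frozen=True)
class Read:
    read_id: str
    bases: str
    quals: tuple[int, ...]
    fwd_index: str = ""
    rev_index: str = ""
    fwd_index_quals: tuple[int, ...] = ()
    rev_index_quals: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.bases):
            raise ValueError("bases and quals differ in length")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class SampleSheetEntry:
    sample_id: str
    species_label: str
    setting_label: str
    fwd_index: str
    rev_index: str
    is_negative_control: bool = False
    subject_id: str = ""  # physical specimen; defaults to sample_id

    def __post_init__(self) -> None:
        if not self.subject_id:
            object.__setattr__(self, "subject_id", self.sample_id)

    @property
    def index_pair(self) -> tuple[str, str]:
        return (self.fwd_index, self.rev_index)


@dataclass
class FilterStats:
    n_input: int = 0
    n_index_lowq: int = 0
    n_index_mismatch: int = 0
    n_assigned: int = 0
    n_trimmed_short: int = 0
    n_lowq_frac: int = 0
    n_kept: int = 0

    def validate(self) -> None:
        assert self.n_assigned == self.n_input - self.n_index_lowq - self.n_index_mismatch
        assert self.n_kept == self.n_assigned - self.n_trimmed_short - self.n_lowq_frac


def _decode_quals(qstring: str) -> tuple[int, ...]:
    quals = tuple(ord(c) - PHRED_OFFSET for c in qstring)
    if any(q < 0 or q > 60 for q in quals):
        raise FastqFormatError(
            "quality values outside Phred+33 range 0-60; "
            "only Phred+33 encoding is supported"
        )
    return quals


def encode_quals(quals: Sequence[int]) -> str:
    return "".join(chr(q + PHRED_OFFSET) for q in quals)


def _parse_header_indexes(header: str):
    """Extract index bases/qualities from the header convention
    `idx:FFFF+RRRR iqual:<phred33>+<phred33>` emitted by the simulator
    (and usable for re-encoding demultiplexer-ready data as plain FASTQ)."""
    fwd = rev = ""
    fq: tuple[int, ...] = ()
    rq: tuple[int, ...] = ()
    for token in header.split()[1:]:
        if token.startswith("idx:") and "+" in token:
            fwd, rev = token[4:].split("+", 1)
        elif token.startswith("iqual:") and "+" in token:
            f, r = token[6:].split("+", 1)
            fq, rq = _decode_quals(f), _decode_quals(r)
    return fwd, rev, fq, rq


def parse_fastq(source: str | Path | io.TextIOBase) -> Iterator[Read]:
    """Stream Phred+33 FASTQ records; transparently opens .gz paths."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        opener = gzip.open if path.suffix == ".gz" else open
        handle = opener(path, "rt")
        close = True
    else:
        handle, close = source, False
    try:
        while True:
            header = handle.readline()
            if not header:
                return
            header = header.rstrip("\n")
            if not header:
                continue
            if not header.startswith("@"):
                raise FastqFormatError(f"bad FASTQ header: {header!r}")
            bases = handle.readline().rstrip("\n").upper()
            plus = handle.readline()
            if not plus.startswith("+"):
                raise FastqFormatError("missing '+' separator line")
            qstring = handle.readline().rstrip("\n")
            fwd, rev, fq, rq = _parse_header_indexes(header)
            yield Read(
                read_id=header[1:].split()[0],
                bases=bases,
                quals=_decode_quals(qstring),
                fwd_index=fwd,
                rev_index=rev,
                fwd_index_quals=fq,
                rev_index_quals=rq,
            )
    finally:
        if close:
            handle.close()


def write_fastq(reads: Iterable[Read], handle: io.TextIOBase) -> None:
    for r in reads:
        header = f"@{r.read_id}"
        if r.fwd_index:
            header += (
                f" idx:{r.fwd_index}+{r.rev_index}"
                f" iqual:{encode_quals(r.fwd_index_quals)}"
                f"+{encode_quals(r.rev_index_quals)}"
            )
        handle.write(f"{header}\n{r.bases}\n+\n{encode_quals(r.quals)}\n")


def parse_sample_sheet(source: str | Path | io.TextIOBase) -> list[SampleSheetEntry]:
    """Read the TSV sample sheet.

    Required columns: sample_id, species, setting, fwd_index, rev_index,
    is_negative_control.  Optional: subject_id (physical specimen shared
    across PCR settings; defaults to sample_id).
    """
    if isinstance(source, (str, Path)):
        handle = open(source)
        close = True
    else:
        handle, close = source, False
    try:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    finally:
        if close:
            handle.close()
    if not lines:
        raise SampleSheetError("empty sample sheet")
    header = lines[0].split("\t")
    required = ["sample_id", "species", "setting", "fwd_index", "rev_index",
                "is_negative_control"]
    missing = [c for c in required if c not in header]
    if missing:
        raise SampleSheetError(f"sample sheet missing columns: {missing}")
    idx = {c: header.index(c) for c in header}
    entries: list[SampleSheetEntry] = []
    for ln in lines[1:]:
        f = ln.split("\t")
        entries.append(
            SampleSheetEntry(
                sample_id=f[idx["sample_id"]],
                species_label=f[idx["species"]],
                setting_label=f[idx["setting"]],
                fwd_index=f[idx["fwd_index"]].upper(),
                rev_index=f[idx["rev_index"]].upper(),
                is_negative_control=f[idx["is_negative_control"]].lower()
                in ("1", "true", "yes"),
                subject_id=f[idx["subject_id"]] if "subject_id" in idx else "",
            )
        )
    pairs = [e.index_pair for e in entries]
    if len(set(pairs)) != len(pairs):
        raise SampleSheetError("duplicate index pairs in sample sheet")
    return entries


def _hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads: Iterable[Read],
    sheet: Sequence[SampleSheetEntry],
    min_index_q: int = DEFAULT_MIN_INDEX_Q,
    allowed_mismatches: int = 0,
    index_quality_mode: str = "any",  # 'any' base < Q or 'mean' < Q
) -> tuple[dict[str, list[Read]], FilterStats]:
    """Assign reads to samples by their 8-mer index pair.

    A read is discarded first if its index qualities fail (`any` mode:
    any index base below `min_index_q`); then if no sheet entry matches
    both indexes within `allowed_mismatches` (default exact).
    """
    if not sheet:
        raise SampleSheetError("sample sheet is empty")
    pairs = [e.index_pair for e in sheet]
    if len(set(pairs)) != len(pairs):
        raise SampleSheetError("duplicate index pairs in sample sheet")
    exact = {e.index_pair: e.sample_id for e in sheet}

    stats = FilterStats()
    out: dict[str, list[Read]] = {e.sample_id: [] for e in sheet}
    for read in reads:
        stats.n_input += 1
        iq = read.fwd_index_quals + read.rev_index_quals
        if index_quality_mode == "mean":
            bad = bool(iq) and sum(iq) / len(iq) < min_index_q
        else:
            bad = any(q < min_index_q for q in iq)
        if bad:
            stats.n_index_lowq += 1
            continue
        sample_id = None
        if allowed_mismatches == 0:
            sample_id = exact.get((read.fwd_index, read.rev_index))
        else:
            best, best_d = None, allowed_mismatches + 1
            for e in sheet:
                d = _hamming(read.fwd_index, e.fwd_index) + _hamming(
                    read.rev_index, e.rev_index
                )
                if d < best_d:
                    best, best_d = e.sample_id, d
            if best_d <= allowed_mismatches:
                sample_id = best
        if sample_id is None:
            stats.n_index_mismatch += 1
            continue
        stats.n_assigned += 1
        out[sample_id].append(read)
    return out, stats


def trim_3prime(
    read: Read,
    window: int = DEFAULT_TRIM_WINDOW,
    min_q: int = DEFAULT_TRIM_MIN_Q,
) -> Read:
    """Peel low-quality bases off the 3' end.

    The terminal base is removed while the read still has at least
    `window` bases and any of the last `window` qualities is below
    `min_q`; a read shorter than the window is returned unchanged (the
    length filter downstream disposes of it).
    """
    quals = list(read.quals)
    end = len(quals)
    while end >= window and any(q < min_q for q in quals[end - window : end]):
        end -= 1
    if end == len(quals):
        return read
    return replace(read, bases=read.bases[:end], quals=tuple(quals[:end]))


def quality_filter(
    read: Read,
    min_len: int = DEFAULT_MIN_LEN,
    max_lowq_fraction: float = DEFAULT_MAX_LOWQ_FRACTION,
    q_thresh: int = DEFAULT_Q_THRESH,
) -> tuple[bool, str]:
    """(keep, reason) after the length and low-quality-fraction filters.

    Rejects reads shorter than `min_len`, then reads whose fraction of
    sub-`q_thresh` bases reaches `max_lowq_fraction`.
    """
    if len(read) < min_len:
        return False, "length"
    lowq = sum(q < q_thresh for q in read.quals)
    if lowq / len(read) >= max_lowq_fraction:
        return False, "quality_fraction"
    return True, ""


def trim_primer(
    read: Read,
    primer: str,
    max_pad: int = 6,
    max_mismatches: int = 1,
) -> Read | None:
    """Strip a variable-length N-pad plus the forward primer off the 5' end.

    The primer (IUPAC-aware) is sought at offsets 0..max_pad; the best
    offset within `max_mismatches` wins.  Returns None when the primer is
    not found (read left untouched by callers that treat this as optional).
    """
    plen = len(primer)
    best_off, best_mm = None, max_mismatches + 1
    for off in range(0, max_pad + 1):
        site = read.bases[off : off + plen]
        if len(site) < plen:
            break
        mm = sum(
            not iupac.matches(p, b, strict_n=False)
            for p, b in zip(primer, site)
        )
        if mm < best_mm:
            best_off, best_mm = off, mm
    if best_off is None:
        return None
    cut = best_off + plen
    return replace(read, bases=read.bases[cut:], quals=read.quals[cut:])


def _process_stream(
    reads: Iterable[Read],
    sheet: Sequence[SampleSheetEntry],
    collect,
    min_index_q: int = DEFAULT_MIN_INDEX_Q,
    allowed_mismatches: int = 0,
    trim_window: int = DEFAULT_TRIM_WINDOW,
    trim_min_q: int = DEFAULT_TRIM_MIN_Q,
    min_len: int = DEFAULT_MIN_LEN,
    max_lowq_fraction: float = DEFAULT_MAX_LOWQ_FRACTION,
    q_thresh: int = DEFAULT_Q_THRESH,
    primer: str | None = None,
) -> FilterStats:
    """Single-pass cascade; `collect(sample_id, read)` receives kept reads.

    Rejection classes are assessed in the fixed order index quality ->
    index mismatch -> length -> low-quality fraction, so each read lands
    in exactly one accounting class.
    """
    if not sheet:
        raise SampleSheetError("sample sheet is empty")
    pairs = [e.index_pair for e in sheet]
    if len(set(pairs)) != len(pairs):
        raise SampleSheetError("duplicate index pairs in sample sheet")
    exact = {e.index_pair: e.sample_id for e in sheet}

    stats = FilterStats()
    for read in reads:
        stats.n_input += 1
        iq = read.fwd_index_quals + read.rev_index_quals
        if any(q < min_index_q for q in iq):
            stats.n_index_lowq += 1
            continue
        sample_id = None
        if allowed_mismatches == 0:
            sample_id = exact.get((read.fwd_index, read.rev_index))
        else:
            best, best_d = None, allowed_mismatches + 1
            for e in sheet:
                d = _hamming(read.fwd_index, e.fwd_index) + _hamming(
                    read.rev_index, e.rev_index
                )
                if d < best_d:
                    best, best_d = e.sample_id, d
            if best_d <= allowed_mismatches:
                sample_id = best
        if sample_id is None:
            stats.n_index_mismatch += 1
            continue
        stats.n_assigned += 1
        if primer:
            stripped = trim_primer(read, primer)
            if stripped is not None:
                read = stripped
        read = trim_3prime(read, window=trim_window, min_q=trim_min_q)
        ok, reason = quality_filter(
            read,
            min_len=min_len,
            max_lowq_fraction=max_lowq_fraction,
            q_thresh=q_thresh,
        )
        if not ok:
            if reason == "length":
                stats.n_trimmed_short += 1
            else:
                stats.n_lowq_frac += 1
            continue
        stats.n_kept += 1
        collect(sample_id, read)
    stats.validate()
    return stats


def process_reads(
    reads: Iterable[Read],
    sheet: Sequence[SampleSheetEntry],
    **kwargs,
) -> tuple[dict[str, list[Read]], FilterStats]:
    """Full cascade: demultiplex, optional primer strip, 3' trim, filters."""
    kept: dict[str, list[Read]] = {e.sample_id: [] for e in sheet}
    stats = _process_stream(
        reads, sheet, lambda sid, r: kept[sid].append(r), **kwargs
    )
    return kept, stats


def process_to_sequences(
    reads: Iterable[Read],
    sheet: Sequence[SampleSheetEntry],
    **kwargs,
) -> tuple[dict[str, list[str]], FilterStats]:
    """Like `process_reads` but keeps only base strings per sample —
    the memory-flat entry point for clustering large runs."""
    kept: dict[str, list[str]] = {e.sample_id: [] for e in sheet}
    stats = _process_stream(
        reads, sheet, lambda sid, r: kept[sid].append(r.bases), **kwargs
    )
    return kept, stats
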