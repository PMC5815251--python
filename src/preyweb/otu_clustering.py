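"""Dereplication and abundance-ordered greedy centroid clustering at 97%.

Unique sequences are processed from most to least abundant; each joins
the best-scoring existing centroid at or above the identity cutoff
(earliest-created centroid on ties) or founds a new OTU.  Identity is the
shared end-gap-free global-alignment measure from `preyweb.align`.

Joining additionally requires the alignment to cover at least
`min_coverage` (default 0.8) of the shorter sequence, so a qualifying
join implies >= cutoff * min_coverage * min_len matching columns.  That
lower bound drives a conservative shared-k-mer screen over centroids: a
qualifying alignment has at most floor((1-t)*(la+lb)) non-matching
columns, each destroying at most k of the shorter sequence's k-mer
windows, leaving at least
ceil(t * min_coverage * min_len) - k + 1 - k*floor((1-t)*(la+lb))
intact shared k-mers.  Candidates sharing fewer distinct k-mers cannot
qualify and are skipped without aligning, so (absent pathological k-mer
repeat structure, which biological markers at these lengths do not
show) screened results equal the unscreened brute-force greedy rule.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import alignment_stats, band_for_cutoff

DEFAULT_IDENTITY_CUTOFF = 0.97
DEFAULT_MIN_COVERAGE = 0.8
DEFAULT_MIN_OTU_READS = 11
_KMER = 8


class ConsistencyError(ValueError):
    pass


@dataclass
class UniqueSeq:
    sequence: str
    abundance: int
    per_sample_counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.abundance != sum(self.per_sample_counts.values()):
            raise ValueError("abundance != sum of per-sample counts")
        if self.abundance < 1:
            raise ValueError("abundance must be >= 1")


@dataclass
class OTU:
    otu_id: str
    centroid: str
    members: list[UniqueSeq]

    @property
    def total_reads(self) -> int:
        return sum(m.abundance for m in self.members)

    @property
    def per_sample_counts(self) -> dict[str, int]:
        counts: dict[str, int] = defaultdict(int)
        for m in self.members:
            for sid, c in m.per_sample_counts.items():
                counts[sid] += c
        return dict(counts)


@dataclass
class OTUTable:
    samples: list[str]
    otus: list[OTU]
    counts: np.ndarray  # shape (n_samples, n_otus), int64

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.samples), len(self.otus)):
            raise ConsistencyError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ConsistencyError("negative counts")

    def otu_ids(self) -> list[str]:
        return [o.otu_id for o in self.otus]

    def subset_samples(self, sample_ids: Sequence[str]) -> "OTUTable":
        index = {s: i for i, s in enumerate(self.samples)}
        rows = [index[s] for s in sample_ids]
        return OTUTable(
            samples=list(sample_ids),
            otus=self.otus,
            counts=self.counts[rows, :].copy(),
        )

    def to_tsv(self) -> str:
        lines = ["sample\t" + "\t".join(self.otu_ids())]
        for i, s in enumerate(self.samples):
            lines.append(s + "\t" + "\t".join(map(str, self.counts[i])))
        return "\n".join(lines) + "\n"


def dereplicate(reads_per_sample: Mapping[str, Iterable[str]]) -> list[UniqueSeq]:
    """Collapse identical sequences across samples.

    Returns uniques sorted by (abundance descending, sequence ascending),
    the order the greedy clusterer consumes.
    """
    table: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for sample_id, seqs in reads_per_sample.items():
        for seq in seqs:
            table[seq][sample_id] += 1
    uniques = [
        UniqueSeq(
            sequence=seq,
            abundance=sum(counts.values()),
            per_sample_counts=dict(counts),
        )
        for seq, counts in table.items()
    ]
    uniques.sort(key=lambda u: (-u.abundance, u.sequence))
    return uniques


def _kmer_codes(seq: str, k: int = _KMER) -> np.ndarray:
    """k-mers of `seq` encoded as base-4 integers (positional, with repeats).

    Repeats only ever inflate the shared-k-mer estimate, which keeps the
    screen conservative, so no dedup is needed."""
    if len(seq) < k:
        return np.empty(0, dtype=np.int64)
    enc = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    code = np.zeros(enc.shape, dtype=np.int64)
    code[enc == ord("C")] = 1
    code[enc == ord("G")] = 2
    code[enc == ord("T")] = 3
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(code, k)
    return windows @ powers


class _CentroidIndex:
    """k-mer -> centroid bitset index backing the conservative screen."""

    def __init__(self, cutoff: float, min_coverage: float, k: int = _KMER):
        self.cutoff = cutoff
        self.min_coverage = min_coverage
        self.k = k
        self.lengths: list[int] = []
        self._capacity = 64  # centroids, grown by doubling
        self._bits = np.zeros((4**k, self._capacity // 8), dtype=np.uint8)

    def add(self, seq: str) -> None:
        idx = len(self.lengths)
        self.lengths.append(len(seq))
        if idx >= self._capacity:
            self._capacity *= 2
            grown = np.zeros((4**self.k, self._capacity // 8), dtype=np.uint8)
            grown[:, : self._bits.shape[1]] = self._bits
            self._bits = grown
        codes = np.unique(_kmer_codes(seq, self.k))
        self._bits[codes, idx // 8] |= np.uint8(1 << (idx % 8))

    def candidates(self, seq: str) -> list[int]:
        n = len(self.lengths)
        if n == 0:
            return []
        codes = _kmer_codes(seq, self.k)
        if codes.size == 0:
            return list(range(n))  # too short to screen; check everything
        rows = self._bits[codes]  # (n_kmers, capacity/8)
        shared = np.unpackbits(rows, axis=1, bitorder="little", count=n).sum(
            axis=0, dtype=np.int64
        )
        la = len(seq)
        k, t, cov = self.k, self.cutoff, self.min_coverage
        lengths = np.asarray(self.lengths, dtype=np.int64)
        min_len = np.minimum(lengths, la)
        min_matches = np.ceil(t * cov * min_len).astype(np.int64)
        budget = ((1.0 - t) * (lengths + la)).astype(np.int64)
        bound = (min_matches - k + 1) - k * budget
        return np.flatnonzero(shared >= bound).tolist()


def greedy_cluster(
    uniques: Sequence[UniqueSeq],
    identity_cutoff: float = DEFAULT_IDENTITY_CUTOFF,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    otu_prefix: str = "OTU",
) -> list[OTU]:
    """Abundance-ordered greedy centroid clustering.

    `uniques` must already be in dereplicate order.  Each unique joins
    the centroid with the highest identity >= cutoff whose alignment
    covers >= min_coverage of the shorter sequence (ties resolved in
    favor of the earliest-created centroid), or founds a new OTU with
    itself as centroid.
    """
    otus: list[OTU] = []
    index = _CentroidIndex(identity_cutoff, min_coverage)
    for u in uniques:
        best_idx, best_id = None, -1.0
        for ci in index.candidates(u.sequence):
            centroid = otus[ci].centroid
            band = band_for_cutoff(len(u.sequence), len(centroid), identity_cutoff)
            score, matches, columns = alignment_stats(
                u.sequence, centroid, band=band
            )
            if columns == 0 or score <= 0:
                continue
            ident = matches / columns
            cov = columns / min(len(u.sequence), len(centroid))
            if ident >= identity_cutoff and cov >= min_coverage and ident > best_id:
                best_idx, best_id = ci, ident
        if best_idx is not None:
            otus[best_idx].members.append(u)
        else:
            otus.append(
                OTU(
                    otu_id=f"{otu_prefix}{len(otus) + 1:05d}",
                    centroid=u.sequence,
                    members=[u],
                )
            )
            index.add(u.sequence)
    return otus


def build_otu_table(otus: Sequence[OTU], samples: Sequence[str]) -> OTUTable:
    """Dense sample x OTU read-count matrix."""
    sample_index = {s: i for i, s in enumerate(samples)}
    counts = np.zeros((len(samples), len(otus)), dtype=np.int64)
    for j, otu in enumerate(otus):
        for sid, c in otu.per_sample_counts.items():
            if sid not in sample_index:
                raise ConsistencyError(f"unknown sample id {sid!r}")
            counts[sample_index[sid], j] = c
    return OTUTable(samples=list(samples), otus=list(otus), counts=counts)


def filter_min_abundance(
    table: OTUTable, min_reads: int = DEFAULT_MIN_OTU_READS
) -> OTUTable:
    """Drop OTUs totalling fewer than `min_reads` reads (default keeps 11+,
    i.e. removes OTUs representing ten or less reads).  Samples are kept
    even if emptied."""
    keep = [j for j, o in enumerate(table.otus) if o.total_reads >= min_reads]
    return OTUTable(
        samples=list(table.samples),
        otus=[table.otus[j] for j in keep],
        counts=table.counts[:, keep].copy(),
    )


def cluster_reads(
    reads_per_sample: Mapping[str, Iterable[str]],
    samples: Sequence[str] | None = None,
    identity_cutoff: float = DEFAULT_IDENTITY_CUTOFF,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    min_otu_reads: int = DEFAULT_MIN_OTU_READS,
    drop_singleton_uniques: bool = False,
) -> OTUTable:
    """Dereplicate -> greedy cluster -> table -> abundance filter."""
    uniques = dereplicate(reads_per_sample)
    if drop_singleton_uniques:
        uniques = [u for u in uniques if u.abundance > 1]
    otus = greedy_cluster(
        uniques, identity_cutoff=identity_cutoff, min_coverage=min_coverage
    )
    if samples is None:
        samples = sorted(reads_per_sample)
    table = build_otu_table(otus, samples)
    return filter_min_abundance(table, min_reads=min_otu_reads)


def centroids_fasta(table: OTUTable) -> str:
    return "".join(
        f">{o.otu_id};size={o.total_reads}\n{o.centroid}\n" for o in table.otus
    )
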