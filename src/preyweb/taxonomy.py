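"""Neighbor-band taxonomic assignment with lowest-common-ancestor consensus.

Each OTU centroid is compared to every reference; all references within
`epsilon` of the best identity form the neighbor set, and the assigned
lineage is the deepest rank prefix on which every neighbor agrees.  The
neighbor-band rule is a declared approximation of query-centric
auto-k-nearest-neighbor selection.  Clade retention keeps only OTUs
resolving to configured target clades (spider predators and
insect/springtail prey by default); everything else — including OTUs too
divergent to assign at all — is discarded and tallied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .align import band_for_cutoff, alignment_stats
from .otu_clustering import OTUTable

RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")

DEFAULT_EPSILON = 0.01
DEFAULT_MIN_IDENTITY = 0.8

# ranks whose names map into the composite prey clade: reference lineages
# rarely carry "Hexapoda" explicitly, so class-level names are translated
DEFAULT_CLADE_MAP = {
    "Insecta": "Hexapoda",
    "Collembola": "Hexapoda",
    "Protura": "Hexapoda",
    "Diplura": "Hexapoda",
}

DEFAULT_TARGETS = frozenset({"Hexapoda", "Araneae"})


class ReferenceError_(ValueError):
    pass


@dataclass(frozen=True)
class Lineage:
    """Rank->name pairs forming a prefix of the canonical rank order."""

    names: tuple[str, ...]  # aligned with RANKS; may be shorter

    def __post_init__(self) -> None:
        if len(self.names) > len(RANKS):
            raise ValueError("lineage deeper than the canonical rank order")
        if any(not n for n in self.names):
            raise ValueError("blank rank inside lineage (gap below absent rank)")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def rank(self, rank_name: str) -> str | None:
        i = RANKS.index(rank_name)
        return self.names[i] if i < len(self.names) else None

    def as_dict(self) -> dict[str, str]:
        return dict(zip(RANKS, self.names))

    def to_string(self) -> str:
        return ";".join(self.names)

    @classmethod
    def from_string(cls, text: str) -> "Lineage":
        names = [n.strip() for n in text.replace(",", ";").split(";")]
        while names and not names[-1]:
            names.pop()
        return cls(tuple(names))


@dataclass(frozen=True)
class ReferenceRecord:
    ref_id: str
    sequence: str
    lineage: Lineage

    def __post_init__(self) -> None:
        if not self.sequence or len(self.lineage) == 0:
            raise ValueError("reference needs a sequence and a lineage")


def parse_reference_fasta(source: str | Path | Iterable[str]) -> list[ReferenceRecord]:
    """Parse `>ref_id;tax=k,p,c,o,f,g,s` style reference FASTA."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            lines = fh.read().splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in source]
    records: list[ReferenceRecord] = []
    ref_id, tax, chunks = None, None, []

    def flush():
        if ref_id is None:
            return
        if tax is None:
            raise ReferenceError_(f"reference {ref_id!r} lacks a tax= field")
        records.append(
            ReferenceRecord(
                ref_id=ref_id,
                sequence="".join(chunks).upper(),
                lineage=Lineage.from_string(tax),
            )
        )

    for ln in lines:
        if ln.startswith(">"):
            flush()
            header = ln[1:].strip()
            parts = header.split(";", 1)
            ref_id = parts[0]
            tax = None
            if len(parts) > 1 and parts[1].startswith("tax="):
                tax = parts[1][4:]
            chunks = []
        elif ln.strip():
            chunks.append(ln.strip())
    flush()
    return records


def lca(lineages: Sequence[Lineage]) -> Lineage:
    """Deepest common rank prefix of the given lineages."""
    if not lineages:
        return Lineage(())
    common: list[str] = []
    for i in range(min(len(l) for l in lineages)):
        names = {l.names[i] for l in lineages}
        if len(names) != 1:
            break
        common.append(next(iter(names)))
    return Lineage(tuple(common))


@dataclass(frozen=True)
class Assignment:
    otu_id: str
    lineage: Lineage | None  # None = unassigned
    best_identity: float
    n_neighbors: int


def assign_taxonomy(
    query: str,
    refs: Sequence[ReferenceRecord],
    epsilon: float = DEFAULT_EPSILON,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> tuple[Lineage | None, float, int]:
    """Assign one centroid: (lineage or None, best identity, n neighbors).

    References within `epsilon` of the best identity vote; the returned
    lineage is their LCA.  Below `min_identity` nothing is assigned.
    """
    if not refs:
        raise ReferenceError_("empty reference set")
    idents: list[float] = []
    for ref in refs:
        band = band_for_cutoff(len(query), len(ref.sequence), min_identity)
        score, matches, columns = alignment_stats(query, ref.sequence, band=band)
        idents.append(matches / columns if columns and score > 0 else 0.0)
    best = max(idents)
    if best < min_identity:
        return None, best, 0
    neighbors = [r for r, i in zip(refs, idents) if i >= best - epsilon]
    consensus = lca([r.lineage for r in neighbors])
    if len(consensus) == 0:
        return None, best, len(neighbors)
    return consensus, best, len(neighbors)


def assign_all(
    table: OTUTable,
    refs: Sequence[ReferenceRecord],
    epsilon: float = DEFAULT_EPSILON,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> dict[str, Assignment]:
    out: dict[str, Assignment] = {}
    for otu in table.otus:
        lineage, best, n = assign_taxonomy(
            otu.centroid, refs, epsilon=epsilon, min_identity=min_identity
        )
        out[otu.otu_id] = Assignment(
            otu_id=otu.otu_id, lineage=lineage, best_identity=best, n_neighbors=n
        )
    return out


def clade_of(
    lineage: Lineage | None,
    targets: frozenset[str] | set[str] = DEFAULT_TARGETS,
    clade_map: Mapping[str, str] = DEFAULT_CLADE_MAP,
) -> str | None:
    """Target clade a lineage resolves to, or None.

    A lineage belongs to a target if any of its rank names is the target
    itself or maps to it through the clade-mapping table.
    """
    if lineage is None:
        return None
    for name in lineage:
        mapped = clade_map.get(name, name)
        if mapped in targets:
            return mapped
    return None


def retain_target_clades(
    table: OTUTable,
    lineages: Mapping[str, Lineage | None],
    targets: frozenset[str] | set[str] = DEFAULT_TARGETS,
    clade_map: Mapping[str, str] = DEFAULT_CLADE_MAP,
) -> tuple[OTUTable, dict[str, int]]:
    """Keep only OTUs resolving to a target clade.

    Returns the filtered table and a discard tally keyed by reason
    ('unassigned' or 'other_clade') plus per-clade retention counts.
    """
    keep: list[int] = []
    report = {"unassigned": 0, "other_clade": 0}
    for t in sorted(targets):
        report[f"retained_{t}"] = 0
    for j, otu in enumerate(table.otus):
        lineage = lineages.get(otu.otu_id)
        clade = clade_of(lineage, targets=targets, clade_map=clade_map)
        if clade is not None:
            keep.append(j)
            report[f"retained_{clade}"] += 1
        elif lineage is None:
            report["unassigned"] += 1
        else:
            report["other_clade"] += 1
    filtered = OTUTable(
        samples=list(table.samples),
        otus=[table.otus[j] for j in keep],
        counts=table.counts[:, keep].copy(),
    )
    return filtered, report


def assignments_tsv(assignments: Mapping[str, Assignment]) -> str:
    lines = ["otu_id\tbest_identity\tn_neighbors\tlineage"]
    for otu_id, a in assignments.items():
        lineage = a.lineage.to_string() if a.lineage else "unassigned"
        lines.append(f"{otu_id}\t{a.best_identity:.4f}\t{a.n_neighbors}\t{lineage}")
    return "\n".join(lines) + "\n"
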