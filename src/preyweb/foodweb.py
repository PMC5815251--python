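"""Predator-prey network construction and per-PCR-setting summaries.

Sample-level OTU tables (already clade-filtered to spider predators and
insect/springtail prey) are turned into predator x prey interaction
matrices whose cells count supporting samples, per-setting sequencing
summaries in the shape of the study's summary table, and rarefaction
curves.  The cross-setting union network deduplicates support by
physical specimen, so one spider scored in several PCR settings counts
once per predator-prey pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .otu_clustering import OTUTable, ConsistencyError
from .read_processing import SampleSheetEntry
from .taxonomy import Lineage, clade_of, DEFAULT_TARGETS, DEFAULT_CLADE_MAP


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal rounding with ties away from zero (reporting convention)."""
    factor = 10.0**decimals
    return math.floor(x * factor + 0.5) / factor


@dataclass
class InteractionMatrix:
    predator_labels: list[str]
    prey_labels: list[str]
    support: dict[tuple[str, str], frozenset[str]]  # pair -> subject ids
    mode: str  # 'by_otu' | 'by_species'
    settings_included: frozenset[str]

    @property
    def cells(self) -> np.ndarray:
        m = np.zeros((len(self.predator_labels), len(self.prey_labels)), dtype=int)
        pi = {p: i for i, p in enumerate(self.predator_labels)}
        hj = {h: j for j, h in enumerate(self.prey_labels)}
        for (p, h), subjects in self.support.items():
            m[pi[p], hj[h]] = len(subjects)
        return m

    def cell(self, predator: str, prey: str) -> int:
        return len(self.support.get((predator, prey), ()))

    def edges(self) -> list[tuple[str, str, int]]:
        return [
            (p, h, len(s))
            for (p, h), s in sorted(self.support.items())
            if s
        ]

    def to_tsv(self) -> str:
        cells = self.cells
        lines = ["predator\t" + "\t".join(self.prey_labels)]
        for i, p in enumerate(self.predator_labels):
            lines.append(p + "\t" + "\t".join(map(str, cells[i])))
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class SettingSummary:
    setting_label: str
    n_samples_with_reads: int
    n_samples_hexapoda: int
    pct_samples_hexapoda: float | None
    mean_hexapoda_reads_per_positive_sample: int | None
    mean_araneae_reads_per_sample: int | None
    total_hexapoda_reads: int
    total_araneae_reads: int
    pct_hexapoda_reads: float | None
    negative_control_read_counts: dict[str, int] = field(default_factory=dict)


def _otu_clades(
    table: OTUTable,
    lineages: Mapping[str, Lineage | None],
    targets=DEFAULT_TARGETS,
    clade_map=DEFAULT_CLADE_MAP,
) -> dict[str, str]:
    clades: dict[str, str] = {}
    for otu in table.otus:
        clade = clade_of(lineages.get(otu.otu_id), targets=targets, clade_map=clade_map)
        if clade is None:
            raise ConsistencyError(
                f"OTU {otu.otu_id} resolves to no target clade; "
                "apply clade filtering before food-web construction"
            )
        clades[otu.otu_id] = clade
    return clades


def interaction_matrix(
    table: OTUTable,
    lineages: Mapping[str, Lineage | None],
    sheet: Sequence[SampleSheetEntry],
    mode: str = "by_otu",
    settings_included: frozenset[str] | None = None,
) -> InteractionMatrix:
    """Predator x prey matrix counting supporting samples.

    For each non-control sample, every (predator entity, prey OTU) pair
    present in the sample contributes that sample's specimen to the
    pair's support; a cell is the support size.  In `by_otu` mode the
    predator entity is an Araneae OTU with reads in the sample; in
    `by_species` mode it is the sample's species label (one contribution
    per sample at most), so prey presence alone suffices.
    """
    if mode not in ("by_otu", "by_species"):
        raise ValueError(f"unknown mode {mode!r}")
    clades = _otu_clades(table, lineages)
    entries = {e.sample_id: e for e in sheet}
    araneae_idx = [j for j, o in enumerate(table.otus) if clades[o.otu_id] == "Araneae"]
    hexapoda_idx = [j for j, o in enumerate(table.otus) if clades[o.otu_id] == "Hexapoda"]

    support: dict[tuple[str, str], set[str]] = {}
    predators: list[str] = []
    prey: list[str] = []
    seen_p: set[str] = set()
    seen_h: set[str] = set()
    settings_seen: set[str] = set()
    for i, sid in enumerate(table.samples):
        entry = entries.get(sid)
        if entry is None or entry.is_negative_control:
            continue
        settings_seen.add(entry.setting_label)
        row = table.counts[i]
        sample_prey = [table.otus[j].otu_id for j in hexapoda_idx if row[j] > 0]
        if not sample_prey:
            continue
        if mode == "by_species":
            sample_predators = [entry.species_label]
        else:
            sample_predators = [table.otus[j].otu_id for j in araneae_idx if row[j] > 0]
        for p in sample_predators:
            if p not in seen_p:
                seen_p.add(p)
                predators.append(p)
            for h in sample_prey:
                if h not in seen_h:
                    seen_h.add(h)
                    prey.append(h)
                support.setdefault((p, h), set()).add(entry.subject_id)
    return InteractionMatrix(
        predator_labels=predators,
        prey_labels=prey,
        support={k: frozenset(v) for k, v in support.items()},
        mode=mode,
        settings_included=(
            frozenset(settings_seen) if settings_included is None else settings_included
        ),
    )


def union_across_settings(
    matrices: Sequence[InteractionMatrix],
) -> InteractionMatrix:
    """Combine per-setting matrices; support is deduplicated by specimen.

    A physical sample backing a pair in several settings counts once;
    a cell is the number of distinct specimens supporting the pair in
    any setting.
    """
    if not matrices:
        raise ValueError("no matrices to combine")
    modes = {m.mode for m in matrices}
    if len(modes) != 1:
        raise ValueError(f"mode mismatch across matrices: {sorted(modes)}")
    support: dict[tuple[str, str], set[str]] = {}
    predators: list[str] = []
    prey: list[str] = []
    seen_p: set[str] = set()
    seen_h: set[str] = set()
    settings: set[str] = set()
    for m in matrices:
        settings |= m.settings_included
        for p in m.predator_labels:
            if p not in seen_p:
                seen_p.add(p)
                predators.append(p)
        for h in m.prey_labels:
            if h not in seen_h:
                seen_h.add(h)
                prey.append(h)
        for pair, subjects in m.support.items():
            support.setdefault(pair, set()).update(subjects)
    return InteractionMatrix(
        predator_labels=predators,
        prey_labels=prey,
        support={k: frozenset(v) for k, v in support.items()},
        mode=modes.pop(),
        settings_included=frozenset(settings),
    )


def setting_summary(
    table: OTUTable,
    lineages: Mapping[str, Lineage | None],
    sheet: Sequence[SampleSheetEntry],
    setting_label: str = "",
) -> SettingSummary:
    """Per-setting sequencing summary.

    Means use the study's reporting rule: prey (Hexapoda) reads are
    averaged over prey-positive samples, predator (Araneae) reads over
    all samples with reads; both rounded to the nearest integer.
    Percentages are rounded half-up to one decimal.  Zero-denominator
    fields are None.
    """
    clades = _otu_clades(table, lineages)
    entries = {e.sample_id: e for e in sheet}
    hex_cols = [j for j, o in enumerate(table.otus) if clades[o.otu_id] == "Hexapoda"]
    ara_cols = [j for j, o in enumerate(table.otus) if clades[o.otu_id] == "Araneae"]

    n_with_reads = n_hex_samples = 0
    total_hex = total_ara = 0
    neg_counts = {"Hexapoda": 0, "Araneae": 0}
    for i, sid in enumerate(table.samples):
        entry = entries.get(sid)
        row = table.counts[i]
        hex_reads = int(row[hex_cols].sum()) if hex_cols else 0
        ara_reads = int(row[ara_cols].sum()) if ara_cols else 0
        if entry is not None and entry.is_negative_control:
            neg_counts["Hexapoda"] += hex_reads
            neg_counts["Araneae"] += ara_reads
            continue
        if hex_reads + ara_reads > 0:
            n_with_reads += 1
        if hex_reads > 0:
            n_hex_samples += 1
        total_hex += hex_reads
        total_ara += ara_reads

    pct_samples = (
        round_half_up(100.0 * n_hex_samples / n_with_reads, 1)
        if n_with_reads
        else None
    )
    mean_hex = (
        int(round_half_up(total_hex / n_hex_samples)) if n_hex_samples else None
    )
    mean_ara = int(round_half_up(total_ara / n_with_reads)) if n_with_reads else None
    pct_reads = (
        round_half_up(100.0 * total_hex / (total_hex + total_ara), 2)
        if (total_hex + total_ara)
        else None
    )
    return SettingSummary(
        setting_label=setting_label,
        n_samples_with_reads=n_with_reads,
        n_samples_hexapoda=n_hex_samples,
        pct_samples_hexapoda=pct_samples,
        mean_hexapoda_reads_per_positive_sample=mean_hex,
        mean_araneae_reads_per_sample=mean_ara,
        total_hexapoda_reads=total_hex,
        total_araneae_reads=total_ara,
        pct_hexapoda_reads=pct_reads,
        negative_control_read_counts=neg_counts,
    )


def summaries_by_setting(
    table: OTUTable,
    lineages: Mapping[str, Lineage | None],
    sheet: Sequence[SampleSheetEntry],
) -> list[SettingSummary]:
    settings: list[str] = []
    for e in sheet:
        if e.setting_label not in settings:
            settings.append(e.setting_label)
    out = []
    for setting in settings:
        sample_ids = [
            e.sample_id for e in sheet
            if e.setting_label == setting and e.sample_id in table.samples
        ]
        sub = table.subset_samples(sample_ids)
        out.append(setting_summary(sub, lineages, sheet, setting_label=setting))
    return out


def rarefaction_curve(
    counts: Sequence[int], depths: Sequence[int]
) -> list[float]:
    """Expected OTU richness at each rarefied depth.

    E[S at n] = sum_i (1 - C(N - N_i, n) / C(N, n)) over OTUs with
    N_i > 0 reads, evaluated with log-gamma for numerical stability.
    """
    c = np.asarray([x for x in counts if x > 0], dtype=np.int64)
    n_total = int(c.sum())
    out: list[float] = []
    for depth in depths:
        if depth > n_total:
            raise ValueError(f"depth {depth} exceeds sample total {n_total}")
        if depth < 0:
            raise ValueError("negative depth")
        # log C(N-Ni, n) - log C(N, n); C(N-Ni, n) = 0 when N-Ni < n
        feasible = (n_total - c) >= depth
        terms = np.zeros(len(c))
        if feasible.any():
            nf = n_total - c[feasible]
            lognum = gammaln(nf + 1) - gammaln(depth + 1) - gammaln(nf - depth + 1)
            logden = (
                gammaln(n_total + 1)
                - gammaln(depth + 1)
                - gammaln(n_total - depth + 1)
            )
            terms[feasible] = np.exp(lognum - logden)
        out.append(float(np.sum(1.0 - terms)))
    return out


def summaries_tsv(summaries: Sequence[SettingSummary]) -> str:
    def fmt(x):
        return "NA" if x is None else str(x)

    lines = [
        "setting\tn_samples_with_reads\tn_samples_hexapoda\tpct_samples_hexapoda"
        "\tmean_hexapoda_reads\tmean_araneae_reads\ttotal_hexapoda_reads"
        "\ttotal_araneae_reads\tpct_hexapoda_reads"
    ]
    for s in summaries:
        lines.append(
            "\t".join(
                [
                    s.setting_label,
                    str(s.n_samples_with_reads),
                    str(s.n_samples_hexapoda),
                    fmt(s.pct_samples_hexapoda),
                    fmt(s.mean_hexapoda_reads_per_positive_sample),
                    fmt(s.mean_araneae_reads_per_sample),
                    str(s.total_hexapoda_reads),
                    str(s.total_araneae_reads),
                    fmt(s.pct_hexapoda_reads),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def edge_list_tsv(matrix: InteractionMatrix) -> str:
    lines = ["predator\tprey\tn_samples\tsettings"]
    settings = ",".join(sorted(matrix.settings_included))
    for p, h, n in matrix.edges():
        lines.append(f"{p}\t{h}\t{n}\t{settings}")
    return "\n".join(lines) + "\n"
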