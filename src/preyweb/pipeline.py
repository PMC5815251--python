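"""End-to-end convenience wiring: QC -> clustering -> taxonomy -> food web."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from . import foodweb as fw
from . import otu_clustering as oc
from . import read_processing as rp
from . import taxonomy as tax


@dataclass
class PipelineResult:
    filter_stats: rp.FilterStats
    otu_table: oc.OTUTable  # clade-filtered
    assignments: dict[str, tax.Assignment]
    discard_report: dict[str, int]
    summaries: list[fw.SettingSummary]
    per_setting_matrices: dict[str, fw.InteractionMatrix]
    union_matrix: fw.InteractionMatrix | None

    @property
    def lineages(self) -> dict[str, tax.Lineage | None]:
        return {oid: a.lineage for oid, a in self.assignments.items()}


def run_pipeline(
    reads: Iterable[rp.Read],
    sheet: Sequence[rp.SampleSheetEntry],
    refs: Sequence[tax.ReferenceRecord],
    mode: str = "by_species",
    identity_cutoff: float = oc.DEFAULT_IDENTITY_CUTOFF,
    min_otu_reads: int = oc.DEFAULT_MIN_OTU_READS,
    epsilon: float = tax.DEFAULT_EPSILON,
    min_identity: float = tax.DEFAULT_MIN_IDENTITY,
    qc_kwargs: Mapping | None = None,
) -> PipelineResult:
    """Run QC, pooled clustering, taxonomy, clade filter, and food webs."""
    kept, stats = rp.process_to_sequences(reads, sheet, **(qc_kwargs or {}))
    samples = [e.sample_id for e in sheet]
    table = oc.cluster_reads(
        kept,
        samples=samples,
        identity_cutoff=identity_cutoff,
        min_otu_reads=min_otu_reads,
    )
    assignments = tax.assign_all(table, refs, epsilon=epsilon, min_identity=min_identity)
    lineages = {oid: a.lineage for oid, a in assignments.items()}
    table, discard = tax.retain_target_clades(table, lineages)

    summaries = fw.summaries_by_setting(table, lineages, sheet)
    settings: list[str] = []
    for e in sheet:
        if e.setting_label not in settings:
            settings.append(e.setting_label)
    matrices: dict[str, fw.InteractionMatrix] = {}
    for setting in settings:
        sample_ids = [e.sample_id for e in sheet if e.setting_label == setting]
        sub = table.subset_samples([s for s in sample_ids if s in table.samples])
        matrices[setting] = fw.interaction_matrix(
            sub, lineages, sheet, mode=mode, settings_included=frozenset({setting})
        )
    union = (
        fw.union_across_settings(list(matrices.values())) if matrices else None
    )
    return PipelineResult(
        filter_stats=stats,
        otu_table=table,
        assignments=assignments,
        discard_report=discard,
        summaries=summaries,
        per_setting_matrices=matrices,
        union_matrix=union,
    )
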