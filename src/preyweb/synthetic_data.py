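"""Ground-truthed amplicon simulator for the whole pipeline.

Emulates the study design the toolkit targets: per-spider samples whose
template pools are dominated by predator ITS2 copies (several intragenomic
variants per species), a minority of consumed-prey templates, four PCR
settings whose blocking primers suppress predator amplification by a
per-setting efficiency beta, per-base substitution error with a 3'-decaying
quality profile, and dual 8-mer indexing with occasional low-quality index
bases.  Every random draw flows from one explicit seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .read_processing import Read, SampleSheetEntry, encode_quals
from .taxonomy import Lineage

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_SETTINGS = (
    ("blockA", 0.90),
    ("blockB", 0.85),
    ("blockAB", 0.95),
    ("noblock", 0.0),
)


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class PredatorSpecies:
    name: str
    lineage: Lineage
    variants: tuple[str, ...]  # intragenomic ITS2 copies, pairwise >= 97% id


@dataclass(frozen=True)
class PreyTaxon:
    name: str
    lineage: Lineage
    template: str


@dataclass(frozen=True)
class SimSetting:
    label: str
    beta: float  # blocking efficiency in [0, 1]


@dataclass
class TruthSet:
    predator_species: list[PredatorSpecies]
    prey_taxa: list[PreyTaxon]
    diet_matrix: np.ndarray  # (n_predators, n_prey) probabilities
    per_sample_truth: dict[str, tuple[str, frozenset[str]]]  # subject -> (species, prey)
    settings: list[SimSetting]

    def true_edges(self) -> set[tuple[str, str]]:
        """(species, prey taxon) pairs realized in at least one sample."""
        edges: set[tuple[str, str]] = set()
        for species, consumed in self.per_sample_truth.values():
            for prey in consumed:
                edges.add((species, prey))
        return edges

    def reference_records(self) -> list[tuple[str, str, Lineage]]:
        """(ref_id, sequence, lineage) for a reference database covering
        every prey taxon and every predator variant."""
        refs = []
        for p in self.predator_species:
            for i, v in enumerate(p.variants):
                refs.append((f"{p.name}_v{i + 1}", v, p.lineage))
        for t in self.prey_taxa:
            refs.append((t.name, t.template, t.lineage))
        return refs

    def reference_fasta(self) -> str:
        return "".join(
            f">{rid};tax={lin.to_string()}\n{seq}\n"
            for rid, seq, lin in self.reference_records()
        )


@dataclass(frozen=True)
class SimParams:
    n_samples: int = 50
    reads_per_sample: int = 1000
    predator_template_weight: float = 0.99
    per_base_error_rate: float = 0.005
    mean_quality: float = 37.0
    quality_decay: float = 0.01  # Phred lost per base toward the 3' end
    quality_sd: float = 2.0
    chimera_rate: float = 0.0
    bad_index_rate: float = 0.01
    n_negative_controls: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("predator_template_weight", "per_base_error_rate",
                     "chimera_rate", "bad_index_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")


_PREY_ORDERS = (
    ("Collembola", "Entomobryidae"),
    ("Coleoptera", "Curculionidae"),
    ("Diptera", "Sciaridae"),
    ("Hemiptera", "Cicadellidae"),
    ("Hymenoptera", "Braconidae"),
    ("Lepidoptera", "Tortricidae"),
    ("Thysanoptera", "Thripidae"),
)

_SPIDER_FAMILIES = ("Araneidae", "Theridiidae", "Salticidae", "Clubionidae")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(BASES[rng.integers(0, 4, size=length)]).decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.shape[0]) < rate)
    for i in hits:
        choices = BASES[BASES != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return bytes(arr).decode()


def simulate_truth(
    n_predators: int = 15,
    n_prey: int = 50,
    n_samples: int = 50,
    seed: int = 0,
    connectance: float = 0.12,
    template_length: tuple[int, int] = (300, 340),
    max_variants: int = 3,
    variant_divergence: float = 0.008,
    settings: Sequence[tuple[str, float]] = DEFAULT_SETTINGS,
) -> TruthSet:
    """Draw predator/prey templates, a diet network, and per-sample truth.

    Prey templates are independent random sequences (mutually far below
    the 97% OTU cutoff at these lengths); each predator species carries
    1..max_variants intragenomic variants within ~2*variant_divergence of
    each other so they co-cluster by construction.
    """
    if n_predators < 1 or n_prey < 1:
        raise ParameterError("need at least one predator and one prey taxon")
    lo, hi = template_length
    if lo < 120:
        raise ParameterError(
            "template_length below 120 bp cannot guarantee the identity "
            "structure (distinct prey OTUs, co-clustering variants)"
        )
    rng = np.random.default_rng(seed)

    predators: list[PredatorSpecies] = []
    for i in range(n_predators):
        base = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        n_var = int(rng.integers(1, max_variants + 1))
        variants = [base]
        tries = 0
        while len(variants) < n_var:
            tries += 1
            if tries > 1000:
                raise ParameterError(
                    "variant_divergence too high to keep intragenomic "
                    "variants within the 97% co-clustering constraint"
                )
            cand = _mutate(rng, base, variant_divergence)
            # keep intragenomic variants pairwise well above the 97% OTU
            # cutoff so they co-cluster by construction
            max_subs = int(0.02 * len(base))
            if all(
                sum(a != b for a, b in zip(cand, v)) <= max_subs
                for v in variants
            ):
                variants.append(cand)
        family = _SPIDER_FAMILIES[i % len(_SPIDER_FAMILIES)]
        name = f"Spider_sp{i + 1:02d}"
        lineage = Lineage(
            ("Eukaryota", "Arthropoda", "Arachnida", "Araneae", family,
             f"Genus{family[:4]}", name)
        )
        predators.append(
            PredatorSpecies(name=name, lineage=lineage, variants=tuple(variants))
        )

    prey: list[PreyTaxon] = []
    for i in range(n_prey):
        order, fam = _PREY_ORDERS[i % len(_PREY_ORDERS)]
        klass = "Collembola" if order == "Collembola" else "Insecta"
        name = f"Prey_{order}_{i + 1:03d}"
        lineage = Lineage(
            ("Eukaryota", "Arthropoda", klass, order, fam, f"Genus{fam[:4]}", name)
        )
        prey.append(
            PreyTaxon(
                name=name,
                lineage=lineage,
                template=_random_seq(rng, int(rng.integers(lo, hi + 1))),
            )
        )

    diet = np.zeros((n_predators, n_prey))
    edge_mask = rng.random(diet.shape) < connectance
    # every predator gets at least one potential prey so no species is trivial
    for i in range(n_predators):
        if not edge_mask[i].any():
            edge_mask[i, rng.integers(0, n_prey)] = True
    diet[edge_mask] = rng.uniform(0.3, 0.9, size=int(edge_mask.sum()))

    per_sample: dict[str, tuple[str, frozenset[str]]] = {}
    for s in range(n_samples):
        sp_idx = s % n_predators  # every species sampled when n_samples >= n_predators
        species = predators[sp_idx]
        consumed = frozenset(
            prey[j].name
            for j in range(n_prey)
            if rng.random() < diet[sp_idx, j]
        )
        per_sample[f"ind{s + 1:04d}"] = (species.name, consumed)

    return TruthSet(
        predator_species=predators,
        prey_taxa=prey,
        diet_matrix=diet,
        per_sample_truth=per_sample,
        settings=[SimSetting(label=l, beta=b) for l, b in settings],
    )


def build_sample_sheet(truth: TruthSet, params: SimParams) -> list[SampleSheetEntry]:
    """One library per (specimen, setting) plus per-setting negative
    controls; unique dual 8-mer index pairs (one forward index per
    specimen, one reverse per setting, mirroring dual-index designs)."""
    rng = np.random.default_rng(params.seed + 1)
    subjects = list(truth.per_sample_truth)
    n_fwd = len(subjects) + params.n_negative_controls
    fwd_pool = _unique_indexes(rng, n_fwd)
    rev_pool = _unique_indexes(rng, len(truth.settings))
    entries: list[SampleSheetEntry] = []
    species_of = {s: sp for s, (sp, _) in truth.per_sample_truth.items()}
    for si, setting in enumerate(truth.settings):
        for fi, subject in enumerate(subjects):
            entries.append(
                SampleSheetEntry(
                    sample_id=f"{subject}.{setting.label}",
                    species_label=species_of[subject],
                    setting_label=setting.label,
                    fwd_index=fwd_pool[fi],
                    rev_index=rev_pool[si],
                    is_negative_control=False,
                    subject_id=subject,
                )
            )
        for nc in range(params.n_negative_controls):
            entries.append(
                SampleSheetEntry(
                    sample_id=f"NC{nc + 1:02d}.{setting.label}",
                    species_label="negative_control",
                    setting_label=setting.label,
                    fwd_index=fwd_pool[len(subjects) + nc],
                    rev_index=rev_pool[si],
                    is_negative_control=True,
                    subject_id=f"NC{nc + 1:02d}",
                )
            )
    return entries


def _unique_indexes(rng: np.random.Generator, n: int) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        idx = _random_seq(rng, 8)
        if idx not in seen:
            seen.add(idx)
            out.append(idx)
    return out


def _library_pool(
    truth: TruthSet, subject: str, setting: SimSetting, w_p: float
) -> tuple[list[str], np.ndarray]:
    """Template sequences and normalized weights for one library."""
    species_name, consumed = truth.per_sample_truth[subject]
    species = next(p for p in truth.predator_species if p.name == species_name)
    templates: list[str] = []
    weights: list[float] = []
    pred_w = w_p * (1.0 - setting.beta)
    for v in species.variants:
        templates.append(v)
        weights.append(pred_w / len(species.variants))
    prey_w = 1.0 - w_p
    consumed_sorted = sorted(consumed)
    for name in consumed_sorted:
        taxon = next(t for t in truth.prey_taxa if t.name == name)
        templates.append(taxon.template)
        weights.append(prey_w / len(consumed_sorted))
    w = np.asarray(weights)
    total = w.sum()
    if total <= 0:
        return templates, np.zeros_like(w)
    return templates, w / total


def generate_reads(
    truth: TruthSet, params: SimParams
) -> tuple[Iterator[Read], list[SampleSheetEntry]]:
    """Stream simulated indexed forward reads for every library.

    Per library the template pool mixes predator variants (weight w_p
    scaled by 1-beta for the library's setting) with consumed prey
    (weight 1-w_p split uniformly); read counts are multinomial, bases
    are flipped independently at the per-base error rate, and qualities
    follow the Gaussian profile with linear 3' decay.  Optional chimeras
    join two pool templates at a uniform breakpoint.  Negative-control
    libraries emit no reads.
    """
    sheet = build_sample_sheet(truth, params)

    def _reads() -> Iterator[Read]:
        rng = np.random.default_rng(params.seed)
        entry_by_id = {e.sample_id: e for e in sheet}
        counter = itertools.count(1)
        for setting in truth.settings:
            for subject in truth.per_sample_truth:
                entry = entry_by_id[f"{subject}.{setting.label}"]
                templates, weights = _library_pool(
                    truth, subject, setting, params.predator_template_weight
                )
                if weights.sum() <= 0:
                    continue
                counts = rng.multinomial(params.reads_per_sample, weights)
                for t_idx, n_copies in enumerate(counts):
                    for _ in range(n_copies):
                        template = templates[t_idx]
                        if params.chimera_rate and rng.random() < params.chimera_rate:
                            other = templates[rng.integers(0, len(templates))]
                            bp = rng.integers(1, min(len(template), len(other)))
                            template = template[:bp] + other[bp:]
                        yield _make_read(
                            rng, next(counter), template, entry, params
                        )

    return _reads(), sheet


def _make_read(
    rng: np.random.Generator,
    serial: int,
    template: str,
    entry: SampleSheetEntry,
    params: SimParams,
) -> Read:
    arr = np.frombuffer(template.encode(), dtype=np.uint8).copy()
    errs = np.flatnonzero(rng.random(arr.shape[0]) < params.per_base_error_rate)
    for i in errs:
        choices = BASES[BASES != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    positions = np.arange(arr.shape[0])
    q = (
        params.mean_quality
        - params.quality_decay * positions
        + rng.normal(0.0, params.quality_sd, size=arr.shape[0])
    )
    quals = tuple(int(x) for x in np.clip(np.rint(q), 2, 41))
    iq_f = [35] * 8
    iq_r = [35] * 8
    if rng.random() < params.bad_index_rate:
        iq_f[int(rng.integers(0, 8))] = int(rng.integers(2, 30))
    return Read(
        read_id=f"sim{serial:08d}",
        bases=bytes(arr).decode(),
        quals=quals,
        fwd_index=entry.fwd_index,
        rev_index=entry.rev_index,
        fwd_index_quals=tuple(iq_f),
        rev_index_quals=tuple(iq_r),
    )


def write_run(
    truth: TruthSet, params: SimParams, outdir: str | Path
) -> dict[str, Path]:
    """Materialize a run on disk: FASTQ, sample sheet, references, truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reads, sheet = generate_reads(truth, params)

    fastq = outdir / "reads.fastq"
    with open(fastq, "w") as fh:
        from .read_processing import write_fastq

        write_fastq(reads, fh)

    sheet_path = outdir / "sample_sheet.tsv"
    with open(sheet_path, "w") as fh:
        fh.write(
            "sample_id\tspecies\tsetting\tfwd_index\trev_index"
            "\tis_negative_control\tsubject_id\n"
        )
        for e in sheet:
            fh.write(
                f"{e.sample_id}\t{e.species_label}\t{e.setting_label}"
                f"\t{e.fwd_index}\t{e.rev_index}"
                f"\t{int(e.is_negative_control)}\t{e.subject_id}\n"
            )

    refs_path = outdir / "references.fasta"
    refs_path.write_text(truth.reference_fasta())

    diet_path = outdir / "diet_truth.tsv"
    with open(diet_path, "w") as fh:
        fh.write("subject_id\tspecies\tconsumed_prey\n")
        for subject, (species, consumed) in truth.per_sample_truth.items():
            fh.write(f"{subject}\t{species}\t{','.join(sorted(consumed))}\n")

    return {
        "fastq": fastq,
        "sheet": sheet_path,
        "references": refs_path,
        "diet_truth": diet_path,
    }
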