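"""Cohort-level aggregation: mutation spectrum, hotspots, loads, homoplasmy.

Two counting modes coexist and are kept explicit: spectrum/region/substitution
totals count *distinct mutation types* (a mutation shared by k patients counts
once), whereas mutational loads count *per-patient occurrences* divided by
group size. Percentages are half-up integers; loads are reported to one
decimal.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence

from .exceptions import ValidationError
from .somatic import HOMOPLASMIC, SomaticMutation
from .util import MutationKey, percent, round_half_up
from .variants_io import KnownVariantTable

# The 12 ordered substitution classes.
SUBSTITUTION_CLASSES = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)

PerPatient = Mapping[str, Sequence[SomaticMutation]]


@dataclass
class FrequencyEntry:
    count: int
    fraction: float
    percent: int


@dataclass
class CohortSummary:
    """All aggregate statistics of one cohort run."""

    n_patients: int = 0
    n_distinct_mutations: int = 0
    coding_count: int = 0
    noncoding_count: int = 0
    region_counts: dict[str, int] = field(default_factory=dict)  # control/rRNA/tRNA/intergenic
    gene_counts: dict[str, int] = field(default_factory=dict)
    complex_counts: dict[str, int] = field(default_factory=dict)
    substitution_counts: dict[str, int] = field(default_factory=dict)
    transition_count: int = 0
    transversion_count: int = 0
    homoplasmic_count: int = 0
    novel_keys: tuple[MutationKey, ...] = ()
    pathogenic_keys: tuple[MutationKey, ...] = ()
    novel_by_complex: dict[str, int] = field(default_factory=dict)
    pathogenic_by_complex: dict[str, int] = field(default_factory=dict)
    frequencies: dict[MutationKey, FrequencyEntry] = field(default_factory=dict)
    hotspot_panel: tuple[MutationKey, ...] = ()
    group_loads: dict[str, float] = field(default_factory=dict)
    group_sizes: dict[str, int] = field(default_factory=dict)

    # -- derived shares (half-up integer percents of distinct mutations) --
    def share(self, count: int) -> int:
        return percent(count, self.n_distinct_mutations)

    @property
    def coding_share(self) -> int:
        return self.share(self.coding_count)

    @property
    def noncoding_share(self) -> int:
        return self.share(self.noncoding_count)

    @property
    def transition_share(self) -> int:
        return self.share(self.transition_count)

    @property
    def transversion_share(self) -> int:
        return self.share(self.transversion_count)

    @property
    def homoplasmic_share(self) -> int:
        return self.share(self.homoplasmic_count)

    def complex_share(self, complex_: str) -> int:
        return self.share(self.complex_counts.get(complex_, 0))

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "n_distinct_mutations": self.n_distinct_mutations,
            "coding_count": self.coding_count,
            "noncoding_count": self.noncoding_count,
            "coding_share_percent": self.coding_share,
            "noncoding_share_percent": self.noncoding_share,
            "region_counts": dict(self.region_counts),
            "gene_counts": dict(self.gene_counts),
            "complex_counts": dict(self.complex_counts),
            "complex_share_percent": {
                c: self.complex_share(c) for c in ("RCI", "RCIII", "RCIV", "RCV")
            },
            "substitution_counts": dict(self.substitution_counts),
            "transition_count": self.transition_count,
            "transversion_count": self.transversion_count,
            "transition_share_percent": self.transition_share,
            "transversion_share_percent": self.transversion_share,
            "homoplasmic_count": self.homoplasmic_count,
            "homoplasmic_share_percent": self.homoplasmic_share,
            "novel": [str(k) for k in self.novel_keys],
            "pathogenic": [str(k) for k in self.pathogenic_keys],
            "novel_by_complex": dict(self.novel_by_complex),
            "pathogenic_by_complex": dict(self.pathogenic_by_complex),
            "frequencies": {
                str(k): {"count": e.count, "percent": e.percent}
                for k, e in sorted(self.frequencies.items())
            },
            "hotspot_panel": [str(k) for k in self.hotspot_panel],
            "group_loads": dict(self.group_loads),
            "group_sizes": dict(self.group_sizes),
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _distinct(per_patient: PerPatient) -> dict[MutationKey, SomaticMutation]:
    """Distinct mutation types with a deterministic representative each.

    Patients are visited in sorted order; annotation fields are taken from the
    first carrier seen, except homoplasmy, which is 'homoplasmic' if the
    mutation is homoplasmic in at least one carrier.
    """
    reps: dict[MutationKey, SomaticMutation] = {}
    for pid in sorted(per_patient):
        for m in per_patient[pid]:
            prior = reps.get(m.key)
            if prior is None:
                reps[m.key] = m
            elif prior.heteroplasmy != HOMOPLASMIC and m.heteroplasmy == HOMOPLASMIC:
                reps[m.key] = replace(prior, heteroplasmy=HOMOPLASMIC)
    return reps


def spectrum_summary(per_patient: PerPatient) -> CohortSummary:
    """Region, complex, substitution and homoplasmy spectrum over distinct keys."""
    reps = _distinct(per_patient)
    summary = CohortSummary(
        n_patients=len(per_patient), n_distinct_mutations=len(reps)
    )
    region = Counter()
    genes = Counter()
    complexes = Counter()
    subs = Counter({c: 0 for c in SUBSTITUTION_CLASSES})
    for key in sorted(reps):
        m = reps[key]
        if m.region_class == "coding":
            summary.coding_count += 1
            complexes[m.complex] += 1
        else:
            summary.noncoding_count += 1
            if m.gene == "CONTROL":
                region["control"] += 1
            elif m.gene.startswith("RNR"):
                region["rRNA"] += 1
            elif m.gene.startswith("TRN"):
                region["tRNA"] += 1
            else:
                region["intergenic"] += 1
        genes[m.gene] += 1
        subs[f"{m.ref_base}>{m.alt_base}"] += 1
        if m.substitution_class == "transition":
            summary.transition_count += 1
        else:
            summary.transversion_count += 1
        if m.heteroplasmy == HOMOPLASMIC:
            summary.homoplasmic_count += 1
    summary.region_counts = dict(region)
    summary.gene_counts = dict(genes)
    summary.complex_counts = dict(complexes)
    summary.substitution_counts = dict(subs)
    summary.novel_keys = tuple(k for k in sorted(reps) if reps[k].novel)
    summary.pathogenic_keys = tuple(k for k in sorted(reps) if reps[k].pathogenic)
    summary.novel_by_complex = dict(
        Counter(reps[k].complex for k in summary.novel_keys)
    )
    summary.pathogenic_by_complex = dict(
        Counter(reps[k].complex for k in summary.pathogenic_keys)
    )
    return summary


def mutation_frequency(
    per_patient: PerPatient, n_patients: Optional[int] = None
) -> dict[MutationKey, FrequencyEntry]:
    """Per-mutation carrier counts as a fraction/percent of the cohort."""
    if n_patients is None:
        n_patients = len(per_patient)
    if n_patients <= 0:
        raise ValidationError("n_patients must be positive")
    carriers = Counter()
    for pid, muts in per_patient.items():
        for key in {m.key for m in muts}:
            carriers[key] += 1
    out: dict[MutationKey, FrequencyEntry] = {}
    for key in sorted(carriers):
        count = carriers[key]
        if count > n_patients:
            raise ValidationError(
                f"{key}: carrier count {count} exceeds n_patients {n_patients}"
            )
        out[key] = FrequencyEntry(
            count=count,
            fraction=count / n_patients,
            percent=percent(count, n_patients),
        )
    return out


def hotspot_panel(
    frequencies: Mapping[MutationKey, FrequencyEntry],
    min_frequency: float = 0.19,
) -> tuple[MutationKey, ...]:
    """Recurrent mutations at or above the cohort-frequency cutoff.

    Ordered by descending frequency, then position. The default cutoff of
    0.19 reproduces a "detected in >=19% of patients" panel definition.
    """
    if not 0 < min_frequency <= 1:
        raise ValidationError("min_frequency must be in (0, 1]")
    eligible = [
        (e.fraction, k) for k, e in frequencies.items() if e.fraction >= min_frequency - 1e-12
    ]
    eligible.sort(key=lambda t: (-t[0], t[1].position, t[1]))
    return tuple(k for _, k in eligible)


def flag_known(
    mutations: Sequence[SomaticMutation], known: KnownVariantTable
) -> list[SomaticMutation]:
    """Re-derive novelty/pathogenicity flags from a known-variant table."""
    return [
        replace(
            m,
            novel=not known.is_reported(m.key),
            pathogenic=known.is_pathogenic(m.key),
        )
        for m in mutations
    ]


RegionFilter = Optional[Callable[[SomaticMutation], bool]]


def complex_filter(complex_: str) -> Callable[[SomaticMutation], bool]:
    return lambda m: m.complex == complex_


def gene_filter(gene: str) -> Callable[[SomaticMutation], bool]:
    target = gene.upper()
    return lambda m: m.gene.upper() in (target, f"MT-{target}")


def homoplasmic_filter(m: SomaticMutation) -> bool:
    return m.heteroplasmy == HOMOPLASMIC


def mutational_load(
    per_patient: PerPatient,
    patient_groups: Mapping[str, str],
    region_filter: RegionFilter = None,
    ndigits: Optional[int] = 1,
) -> dict[str, float]:
    """Mutations per patient by group, optionally region-restricted.

    A mutation is counted once per patient carrying it; the group total is
    divided by the group size. ``ndigits=None`` disables rounding (useful for
    exact additivity checks).
    """
    missing = set(per_patient) - set(patient_groups)
    if missing:
        raise ValidationError(f"patients without group assignment: {sorted(missing)}")
    group_sizes = Counter(patient_groups[pid] for pid in per_patient)
    if not group_sizes:
        raise ValidationError("empty cohort: no patients to compute loads over")
    counts = Counter()
    for pid, muts in per_patient.items():
        selected = {m.key for m in muts if region_filter is None or region_filter(m)}
        counts[patient_groups[pid]] += len(selected)
    loads = {}
    for group, size in sorted(group_sizes.items()):
        load = counts[group] / size
        loads[group] = load if ndigits is None else round_half_up(load, ndigits)
    return loads


def summarize_cohort(
    per_patient: PerPatient,
    known: Optional[KnownVariantTable] = None,
    patient_groups: Optional[Mapping[str, str]] = None,
    n_patients: Optional[int] = None,
    hotspot_min_frequency: float = 0.19,
) -> CohortSummary:
    """One-stop aggregation: spectrum + frequencies + hotspot panel + loads."""
    if known is not None:
        per_patient = {
            pid: flag_known(muts, known) for pid, muts in per_patient.items()
        }
    summary = spectrum_summary(per_patient)
    if per_patient:
        summary.frequencies = mutation_frequency(per_patient, n_patients)
        summary.hotspot_panel = hotspot_panel(
            summary.frequencies, hotspot_min_frequency
        )
    if patient_groups:
        summary.group_loads = mutational_load(per_patient, patient_groups)
        summary.group_sizes = dict(
            Counter(patient_groups[pid] for pid in per_patient)
        )
    return summary
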