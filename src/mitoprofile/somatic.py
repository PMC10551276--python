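"""Read filters, matched tumor/normal somatic calling, MAF, heteroplasmy.

A variant is somatic when it is present in the tumor but absent from the
matched normal profile, the reference, and the haplogroup-marker list
(inherited lineage variants used for haplotyping). Matching is allele-level:
the exact (position, ref, alt) triple must coincide — a normal-side variant at
the same position with a different alt does not suppress a tumor variant.

Two allele-level quantities are carried per mutation:

* ``maf_percent`` — mutant reads / wild-type reads × 100, the study's ratio
  definition. It is unbounded and undefined (None) at fully mutant sites.
* ``alt_fraction`` — mutant / (mutant + wild-type), the conventional bounded
  fraction, used for heteroplasmy/homoplasmy classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .exceptions import MissingNormalError, ValidationError
from .mitogenome import DEFAULT_MAP, MitoGeneMap, classify_substitution
from .util import MutationKey
from .variants_io import (
    KnownVariantTable,
    SampleProfile,
    VariantObservation,
)

HOMOPLASMIC = "homoplasmic"
HETEROPLASMIC = "heteroplasmic"


@dataclass(frozen=True)
class FilterConfig:
    """Read-support thresholds.

    min_sample_coverage: fold-coverage a sample must *exceed* (strict >) to be
        analyzed at all; default 1000.
    min_variant_reads: variants supported by fewer mutant reads are discarded;
        default 100 (exactly 100 reads is kept).
    homoplasmy_threshold: alt fraction at or above which a mutation is called
        homoplasmic; default 0.95. The threshold is a documented package
        choice, not a literature constant.
    """

    min_sample_coverage: float = 1000.0
    min_variant_reads: int = 100
    homoplasmy_threshold: float = 0.95

    def __post_init__(self) -> None:
        if self.min_sample_coverage < 0 or self.min_variant_reads < 0:
            raise ValidationError("filter thresholds must be non-negative")
        if not 0 < self.homoplasmy_threshold <= 1:
            raise ValidationError("homoplasmy_threshold must be in (0, 1]")


@dataclass
class FilterReport:
    """Outcome of sample-level and variant-level filtering."""

    sample_id: str
    sample_excluded: bool = False
    mean_coverage: float = 0.0
    n_input: int = 0
    n_removed_low_reads: int = 0
    n_kept: int = 0


@dataclass
class SomaticMutation:
    """An annotated tumor-only (or EV-only) substitution for one patient."""

    patient_id: str
    position: int
    ref_base: str
    alt_base: str
    gene: str
    region_class: str
    complex: str
    substitution_class: str
    maf_percent: Optional[float]
    alt_fraction: float
    heteroplasmy: str
    novel: bool = False
    pathogenic: bool = False
    source_tissues: frozenset[str] = field(default_factory=lambda: frozenset({"tumor"}))

    @property
    def key(self) -> MutationKey:
        return MutationKey(self.position, self.ref_base, self.alt_base)


def apply_read_filters(
    profile: SampleProfile, config: FilterConfig = FilterConfig()
) -> tuple[SampleProfile, FilterReport]:
    """Drop low-support variants; flag whole samples below the coverage bar.

    Filtering is total: an excluded sample is returned with a report whose
    ``sample_excluded`` flag is set, and downstream calling treats it as
    absent.
    """
    report = FilterReport(
        sample_id=profile.sample_id,
        mean_coverage=profile.mean_coverage,
        n_input=len(profile.observations),
    )
    if not profile.mean_coverage > config.min_sample_coverage:
        report.sample_excluded = True
    kept = tuple(
        o for o in profile.observations if o.alt_reads >= config.min_variant_reads
    )
    report.n_removed_low_reads = report.n_input - len(kept)
    report.n_kept = len(kept)
    return replace(profile, observations=kept), report


def compute_maf(alt_reads: int, ref_reads: int) -> Optional[float]:
    """Mutant/wild-type read ratio × 100; None when fully mutant (ref = 0)."""
    if alt_reads < 0 or ref_reads < 0:
        raise ValidationError("read counts must be non-negative")
    if alt_reads == 0 and ref_reads == 0:
        raise ValidationError("no read evidence: both counts are zero")
    if alt_reads == 0:
        return 0.0
    if ref_reads == 0:
        return None  # undefined (fully mutant); mutation is retained
    return 100.0 * alt_reads / ref_reads


def classify_heteroplasmy(
    alt_fraction: float, config: FilterConfig = FilterConfig()
) -> str:
    if not 0 <= alt_fraction <= 1:
        raise ValidationError(f"alt fraction {alt_fraction} outside [0, 1]")
    return HOMOPLASMIC if alt_fraction >= config.homoplasmy_threshold else HETEROPLASMIC


def annotate_observation(
    obs: VariantObservation,
    patient_id: str,
    known: KnownVariantTable,
    config: FilterConfig = FilterConfig(),
    gene_map: MitoGeneMap = DEFAULT_MAP,
    source: str = "tumor",
) -> SomaticMutation:
    """Turn a raw observation into a fully annotated mutation record."""
    assignment = gene_map.locate(obs.position)
    key = obs.key
    return SomaticMutation(
        patient_id=patient_id,
        position=obs.position,
        ref_base=obs.ref_base,
        alt_base=obs.alt_base,
        gene=assignment.primary_feature,
        region_class=assignment.region_class,
        complex=assignment.complex,
        substitution_class=classify_substitution(obs.ref_base, obs.alt_base),
        maf_percent=compute_maf(obs.alt_reads, obs.ref_reads),
        alt_fraction=obs.alt_fraction,
        heteroplasmy=classify_heteroplasmy(obs.alt_fraction, config),
        novel=not known.is_reported(key),
        pathogenic=known.is_pathogenic(key),
        source_tissues=frozenset({source}),
    )


def call_somatic(
    tumor: SampleProfile,
    normal: Optional[SampleProfile],
    known: KnownVariantTable,
    config: FilterConfig = FilterConfig(),
    gene_map: MitoGeneMap = DEFAULT_MAP,
    patient_id: Optional[str] = None,
) -> list[SomaticMutation]:
    """Call somatic mutations from a matched tumor/normal pair.

    Both profiles are re-filtered here so the function is safe to call
    directly; an excluded sample raises, because calling without adequate
    coverage on either side is meaningless.
    """
    if normal is None:
        raise MissingNormalError(
            "somatic calling requires the matched normal profile"
        )
    if tumor.tissue != "tumor" or normal.tissue != "normal":
        raise ValidationError(
            f"expected (tumor, normal) profiles, got ({tumor.tissue}, {normal.tissue})"
        )
    tumor_f, tumor_rep = apply_read_filters(tumor, config)
    normal_f, normal_rep = apply_read_filters(normal, config)
    for rep in (tumor_rep, normal_rep):
        if rep.sample_excluded:
            raise ValidationError(
                f"sample {rep.sample_id} excluded: mean coverage "
                f"{rep.mean_coverage:.0f} not above {config.min_sample_coverage:.0f}"
            )
    pid = patient_id if patient_id is not None else tumor.sample_id
    normal_keys = normal_f.keys
    calls: list[SomaticMutation] = []
    for obs in sorted(tumor_f.observations, key=lambda o: (o.position, o.alt_base)):
        key = obs.key
        if key in normal_keys:
            continue  # present in matched normal: germline/shared, not somatic
        if known.is_haplogroup_marker(key):
            continue  # inherited lineage marker, excluded by definition
        calls.append(
            annotate_observation(obs, pid, known, config, gene_map, source="tumor")
        )
    return calls


def somatic_relevant_keys(
    profile: SampleProfile,
    normal: SampleProfile,
    known: KnownVariantTable,
    config: FilterConfig = FilterConfig(),
) -> frozenset[MutationKey]:
    """Filtered keys of a profile minus matched-normal and haplogroup keys.

    Used for EV profiles, where the same germline-exclusion logic applies as
    in tumor somatic calling.
    """
    filtered, _ = apply_read_filters(profile, config)
    normal_f, _ = apply_read_filters(normal, config)
    return frozenset(
        k
        for k in filtered.keys
        if k not in normal_f.keys and not known.is_haplogroup_marker(k)
    )
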