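"""End-to-end orchestration: filters → somatic calls → aggregates → concordance."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .cohort import CohortSummary, summarize_cohort
from .ev import (
    ConcordanceResult,
    PanelDetection,
    panel_detection_rate,
    traceability,
)
from .exceptions import MissingNormalError, ValidationError
from .mitogenome import DEFAULT_MAP, MitoGeneMap
from .somatic import (
    FilterConfig,
    FilterReport,
    SomaticMutation,
    annotate_observation,
    apply_read_filters,
    call_somatic,
)
from .util import MutationKey
from .variants_io import KnownVariantTable, PatientRecord


@dataclass
class PipelineResult:
    """Everything one cohort run produces."""

    per_patient: dict[str, list[SomaticMutation]] = field(default_factory=dict)
    ev_exclusive: dict[str, list[SomaticMutation]] = field(default_factory=dict)
    summary: Optional[CohortSummary] = None
    concordance: Optional[ConcordanceResult] = None
    panel_detection: Optional[PanelDetection] = None
    excluded_patients: dict[str, str] = field(default_factory=dict)
    filter_reports: list[FilterReport] = field(default_factory=list)

    def all_mutations(self) -> list[SomaticMutation]:
        """Flat catalog: somatic calls plus EV-exclusive records."""
        out: list[SomaticMutation] = []
        for pid in sorted(self.per_patient):
            out.extend(self.per_patient[pid])
        for pid in sorted(self.ev_exclusive):
            out.extend(self.ev_exclusive[pid])
        return out


def profile_cohort(
    patients: Sequence[PatientRecord],
    known: Optional[KnownVariantTable] = None,
    config: FilterConfig = FilterConfig(),
    gene_map: MitoGeneMap = DEFAULT_MAP,
    hotspot_min_frequency: float = 0.19,
) -> PipelineResult:
    """Run the full mutation-profiling analysis over a cohort.

    Patients lacking a tumor or matched normal profile, or whose profiles
    fail the sample-coverage bar, are excluded (with a recorded reason) rather
    than partially analyzed. EV profiles are optional; when present, the same
    read filters and germline/haplogroup exclusions apply before concordance.
    """
    known = known if known is not None else KnownVariantTable.empty()
    result = PipelineResult()
    tumor_sets: dict[str, set[MutationKey]] = {}
    ev_sets: dict[str, set[MutationKey]] = {}

    for patient in sorted(patients, key=lambda p: p.patient_id):
        pid = patient.patient_id
        tumor = patient.profile("tumor")
        normal = patient.profile("normal")
        if tumor is None:
            result.excluded_patients[pid] = "missing tumor profile"
            continue
        if normal is None:
            result.excluded_patients[pid] = "missing matched normal profile"
            continue
        tumor_f, tumor_rep = apply_read_filters(tumor, config)
        normal_f, normal_rep = apply_read_filters(normal, config)
        result.filter_reports.extend([tumor_rep, normal_rep])
        if tumor_rep.sample_excluded or normal_rep.sample_excluded:
            bad = tumor_rep if tumor_rep.sample_excluded else normal_rep
            result.excluded_patients[pid] = (
                f"sample {bad.sample_id} below coverage threshold"
            )
            continue
        try:
            calls = call_somatic(tumor, normal, known, config, gene_map, patient_id=pid)
        except (MissingNormalError, ValidationError) as exc:
            result.excluded_patients[pid] = str(exc)
            continue

        ev = patient.profile("EV")
        if ev is not None:
            ev_f, ev_rep = apply_read_filters(ev, config)
            result.filter_reports.append(ev_rep)
            if not ev_rep.sample_excluded:
                normal_keys = normal_f.keys
                relevant = {
                    o.key: o
                    for o in ev_f.observations
                    if o.key not in normal_keys
                    and not known.is_haplogroup_marker(o.key)
                }
                ev_sets[pid] = set(relevant)
                called_keys = {m.key for m in calls}
                # mark tumor calls that are also seen in the EV
                calls = [
                    replace(m, source_tissues=frozenset({"tumor", "EV"}))
                    if m.key in ev_sets[pid]
                    else m
                    for m in calls
                ]
                result.ev_exclusive[pid] = [
                    annotate_observation(obs, pid, known, config, gene_map, source="EV")
                    for key, obs in sorted(relevant.items())
                    if key not in called_keys
                ]
        result.per_patient[pid] = calls
        tumor_sets[pid] = {m.key for m in calls}

    groups = {
        p.patient_id: p.ancestry
        for p in patients
        if p.patient_id in result.per_patient
    }
    result.summary = summarize_cohort(
        result.per_patient,
        known=None,  # flags already attached during calling
        patient_groups=groups or None,
        hotspot_min_frequency=hotspot_min_frequency,
    )
    if ev_sets:
        result.concordance = traceability(tumor_sets, ev_sets)
        if result.summary.hotspot_panel:
            result.panel_detection = panel_detection_rate(
                result.summary.hotspot_panel, ev_sets
            )
    return result
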