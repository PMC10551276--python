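"""Tumor–EV concordance: traceability, hotspot detection, EV-exclusive calls.

Circulating extracellular vesicles (EVs) carry mitochondrial DNA fragments;
if a tumor's somatic mutations are detectable in serum-derived EVs they can
serve as a liquid-biopsy readout. This module quantifies (a) how many tumor
somatic mutations are traceable in the matched EV profile, (b) what share of a
hotspot panel is detectable in at least one EV, and (c) mutations present
exclusively in EVs (absent from tumor and normal), which may originate from
tumor clones not represented in the sequenced tissue block.

EV mutations matching the patient's matched normal are treated as germline
carry-over and excluded from both the traceable and the exclusive sets,
in parallel with the somatic-calling definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Set

from .exceptions import ValidationError
from .mitogenome import DEFAULT_MAP, MitoGeneMap, classify_substitution
from .util import MutationKey, percent
from .variants_io import KnownVariantTable


@dataclass
class PatientConcordance:
    tumor_mutation_count: int
    ev_detected_count: int
    traceable: frozenset[MutationKey]
    has_detection: bool  # at least one tumor mutation found in the EV


@dataclass
class ConcordanceResult:
    per_patient: dict[str, PatientConcordance] = field(default_factory=dict)
    pooled_tumor: frozenset[MutationKey] = frozenset()
    pooled_traceable: frozenset[MutationKey] = frozenset()
    traceability_percent: int = 0

    @property
    def all_patients_detected(self) -> bool:
        return all(p.has_detection for p in self.per_patient.values())


def traceability(
    tumor_sets: Mapping[str, Set[MutationKey]],
    ev_sets: Mapping[str, Set[MutationKey]],
    normal_sets: Optional[Mapping[str, Set[MutationKey]]] = None,
) -> ConcordanceResult:
    """Pooled and per-patient traceability of tumor mutations in EVs.

    Pooled traceability is |union of traceable| / |union of tumor| x 100 over
    the EV-bearing patients (the union view, not a mean of per-patient
    fractions, which are available in ``per_patient``).
    """
    if not ev_sets:
        raise ValidationError("no EV-bearing patients: traceability undefined")
    missing = set(ev_sets) - set(tumor_sets)
    if missing:
        raise ValidationError(f"EV profiles without tumor sets: {sorted(missing)}")
    result = ConcordanceResult()
    pooled_tumor: set[MutationKey] = set()
    pooled_traceable: set[MutationKey] = set()
    for pid in sorted(ev_sets):
        tumor = frozenset(tumor_sets[pid])
        germline = frozenset(normal_sets.get(pid, frozenset())) if normal_sets else frozenset()
        ev = frozenset(ev_sets[pid]) - germline
        traceable = ev & tumor
        result.per_patient[pid] = PatientConcordance(
            tumor_mutation_count=len(tumor),
            ev_detected_count=len(traceable),
            traceable=traceable,
            has_detection=bool(traceable),
        )
        pooled_tumor |= tumor
        pooled_traceable |= traceable
    result.pooled_tumor = frozenset(pooled_tumor)
    result.pooled_traceable = frozenset(pooled_traceable)
    result.traceability_percent = percent(len(pooled_traceable), len(pooled_tumor))
    return result


@dataclass
class PanelDetection:
    panel: tuple[MutationKey, ...]
    detected: frozenset[MutationKey]
    percent: int


def panel_detection_rate(
    panel: Sequence[MutationKey],
    ev_sets: Mapping[str, Set[MutationKey]] | Sequence[Set[MutationKey]],
) -> PanelDetection:
    """Share of panel mutations detectable in at least one EV profile."""
    panel = tuple(panel)
    if not panel:
        raise ValidationError("empty hotspot panel")
    if isinstance(ev_sets, Mapping):
        profiles = list(ev_sets.values())
    else:
        profiles = list(ev_sets)
    pooled: set[MutationKey] = set()
    for keys in profiles:
        pooled |= set(keys)
    detected = frozenset(k for k in panel if k in pooled)
    return PanelDetection(panel, detected, percent(len(detected), len(panel)))


@dataclass(frozen=True)
class AnnotatedKey:
    """A mutation key with gene-map annotation and a novelty flag."""

    key: MutationKey
    gene: str
    region_class: str
    complex: str
    substitution_class: str
    novel: bool


def ev_exclusive(
    ev_set: Set[MutationKey],
    tumor_set: Set[MutationKey],
    normal_set: Set[MutationKey],
    known: Optional[KnownVariantTable] = None,
    gene_map: MitoGeneMap = DEFAULT_MAP,
) -> list[AnnotatedKey]:
    """EV mutations absent from both the tumor and the matched normal."""
    known = known if known is not None else KnownVariantTable.empty()
    exclusive = set(ev_set) - set(tumor_set) - set(normal_set)
    out = []
    for key in sorted(exclusive):
        assignment = gene_map.locate(key.position)
        out.append(
            AnnotatedKey(
                key=key,
                gene=assignment.primary_feature,
                region_class=assignment.region_class,
                complex=assignment.complex,
                substitution_class=classify_substitution(key.ref, key.alt),
                novel=not known.is_reported(key),
            )
        )
    return out
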