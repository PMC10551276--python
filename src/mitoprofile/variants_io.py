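"""Reading and writing variant observations, manifests and mutation catalogs.

Input is either VCF (one sample per call, AD/DP-style depth fields) or a flat
TSV catalog; output is an annotated per-(patient, mutation) catalog that
round-trips losslessly. Raw reads are never consumed here — upstream alignment
and variant calling are a different tool's job.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .exceptions import FormatError, ValidationError
from .util import GENOME_LENGTH, VALID_BASES, MutationKey, make_key

logger = logging.getLogger(__name__)

TISSUES = ("normal", "tumor", "EV")

# VCF dialects disagree on the mitochondrial contig name.
MT_CONTIG_ALIASES = frozenset({"chrm", "chrmt", "mt", "m", "nc_012920.1"})

CATALOG_COLUMNS = [
    "sample_id",
    "tissue",
    "position",
    "ref",
    "alt",
    "total_depth",
    "ref_reads",
    "alt_reads",
]

ANNOTATED_COLUMNS = [
    "patient_id",
    "mutation",
    "position",
    "ref",
    "alt",
    "gene",
    "region_class",
    "complex",
    "substitution_class",
    "maf_percent",
    "alt_fraction",
    "heteroplasmy",
    "novel",
    "pathogenic",
    "source_tissues",
    "ev_exclusive",
]


def _normalize_tissue(value: str) -> str:
    v = str(value).strip()
    lowered = v.lower()
    if lowered == "ev":
        return "EV"
    if lowered in ("normal", "tumor"):
        return lowered
    raise ValidationError(f"unknown tissue label {value!r}; expected normal/tumor/EV")


@dataclass(frozen=True)
class VariantObservation:
    """One sample's read evidence for one substitution."""

    sample_id: str
    position: int
    ref_base: str
    alt_base: str
    total_depth: int
    ref_reads: int
    alt_reads: int

    def __post_init__(self) -> None:
        make_key(self.position, self.ref_base, self.alt_base)  # validates
        for name in ("total_depth", "ref_reads", "alt_reads"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.alt_reads + self.ref_reads > self.total_depth:
            raise ValidationError(
                f"alt_reads + ref_reads exceed total_depth at {self.position}"
            )

    @property
    def key(self) -> MutationKey:
        return MutationKey(self.position, self.ref_base, self.alt_base)

    @property
    def alt_fraction(self) -> float:
        denom = self.alt_reads + self.ref_reads
        return self.alt_reads / denom if denom else 0.0


@dataclass
class SampleProfile:
    """All variant observations of one sequenced sample."""

    sample_id: str
    tissue: str
    mean_coverage: float
    observations: tuple[VariantObservation, ...] = ()

    def __post_init__(self) -> None:
        self.tissue = _normalize_tissue(self.tissue)
        self.observations = tuple(self.observations)

    @property
    def keys(self) -> frozenset[MutationKey]:
        return frozenset(o.key for o in self.observations)


@dataclass
class PatientRecord:
    """Patient metadata plus its tissue→profile mapping."""

    patient_id: str
    ancestry: str = "other"
    stage: str = "unknown"
    age: Optional[float] = None
    samples: dict[str, SampleProfile] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tissue in self.samples:
            _normalize_tissue(tissue)

    def profile(self, tissue: str) -> Optional[SampleProfile]:
        return self.samples.get(_normalize_tissue(tissue))


class KnownVariantTable:
    """Lookup of previously reported variants keyed by (position, ref, alt).

    Carries three flags per record: ``reported`` (seen in variant databases —
    its absence defines novelty), ``pathogenic``, and ``haplogroup_marker``
    (inherited lineage-defining variants that must never be called somatic).
    """

    def __init__(self, records: Optional[Mapping[MutationKey, dict]] = None):
        self._records: dict[MutationKey, dict] = {}
        if records:
            for key, flags in records.items():
                self.add(key, **flags)

    @classmethod
    def empty(cls) -> "KnownVariantTable":
        return cls()

    def add(
        self,
        key: MutationKey,
        reported: bool = True,
        pathogenic: bool = False,
        haplogroup_marker: bool = False,
    ) -> None:
        key = make_key(*key)
        if key in self._records:
            raise ValidationError(f"duplicate known-variant key {key}")
        self._records[key] = {
            "reported": bool(reported),
            "pathogenic": bool(pathogenic),
            "haplogroup_marker": bool(haplogroup_marker),
        }

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, key: MutationKey) -> bool:
        return key in self._records

    def is_reported(self, key: MutationKey) -> bool:
        rec = self._records.get(key)
        return bool(rec and rec["reported"])

    def is_pathogenic(self, key: MutationKey) -> bool:
        rec = self._records.get(key)
        return bool(rec and rec["pathogenic"])

    def is_haplogroup_marker(self, key: MutationKey) -> bool:
        rec = self._records.get(key)
        return bool(rec and rec["haplogroup_marker"])

    def haplogroup_markers(self) -> frozenset[MutationKey]:
        return frozenset(k for k, r in self._records.items() if r["haplogroup_marker"])

    @classmethod
    def from_tsv(cls, path) -> "KnownVariantTable":
        table = cls()
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"position", "ref", "alt"}
        if not required.issubset(df.columns):
            raise FormatError(f"known-variant table needs columns {sorted(required)}")
        yes = {"yes", "true", "1"}
        for i, row in df.iterrows():
            try:
                key = make_key(int(row["position"]), row["ref"], row["alt"])
                table.add(
                    key,
                    reported=str(row.get("reported", "yes")).strip().lower() in yes,
                    pathogenic=str(row.get("pathogenic", "no")).strip().lower() in yes,
                    haplogroup_marker=str(row.get("haplogroup_marker", "no")).strip().lower()
                    in yes,
                )
            except (ValueError, ValidationError) as exc:
                raise FormatError(f"known-variant table row {i + 2}: {exc}") from exc
        return table

    def to_tsv(self, path) -> None:
        rows = []
        for key in sorted(self._records):
            rec = self._records[key]
            rows.append(
                {
                    "position": key.position,
                    "ref": key.ref,
                    "alt": key.alt,
                    "reported": "yes" if rec["reported"] else "no",
                    "pathogenic": "yes" if rec["pathogenic"] else "no",
                    "haplogroup_marker": "yes" if rec["haplogroup_marker"] else "no",
                }
            )
        pd.DataFrame(
            rows,
            columns=["position", "ref", "alt", "reported", "pathogenic", "haplogroup_marker"],
        ).to_csv(path, sep="\t", index=False)


@dataclass
class VcfReadReport:
    """Bookkeeping from a VCF read: what was kept and what was skipped."""

    n_observations: int = 0
    n_skipped_non_snv: int = 0
    n_skipped_contig: int = 0


def read_vcf(
    path,
    sample_id: str,
    tissue: str,
    mean_coverage: Optional[float] = None,
) -> tuple[SampleProfile, VcfReadReport]:
    """Read one sample's observations from a VCF.

    One observation is emitted per ALT allele of every SNV record on the
    mitochondrial contig; multi-allelic records are split, non-SNV records are
    skipped and counted. ref_reads comes from AD[0] when present, otherwise
    DP − sum(alt depths). When ``mean_coverage`` is not supplied it is
    estimated as the mean total depth of the kept observations.
    """
    report = VcfReadReport()
    observations: list[VariantObservation] = []
    vcf = VCF(str(path))
    if sample_id not in vcf.samples:
        raise FormatError(f"sample {sample_id!r} not present in {path}")
    sidx = vcf.samples.index(sample_id)
    for var in vcf:
        if str(var.CHROM).lower() not in MT_CONTIG_ALIASES:
            report.n_skipped_contig += 1
            logger.warning("skipping record on non-mitochondrial contig %s", var.CHROM)
            continue
        ad = var.format("AD")
        if ad is None:
            raise FormatError(
                f"record at {var.CHROM}:{var.POS} lacks the AD depth field"
            )
        ad_row = np.asarray(ad)[sidx]
        dp = var.format("DP")
        if dp is not None:
            total_depth = int(np.asarray(dp)[sidx].item())
        else:
            total_depth = int(ad_row[ad_row >= 0].sum())
        ref = str(var.REF).upper()
        ref_ad = int(ad_row[0]) if len(ad_row) > 0 and ad_row[0] >= 0 else None
        alt_depths = [int(x) if x >= 0 else 0 for x in ad_row[1:]]
        for i, alt in enumerate(var.ALT):
            alt = str(alt).upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in VALID_BASES or alt not in VALID_BASES:
                report.n_skipped_non_snv += 1
                continue
            alt_reads = alt_depths[i] if i < len(alt_depths) else 0
            ref_reads = ref_ad if ref_ad is not None else max(total_depth - sum(alt_depths), 0)
            observations.append(
                VariantObservation(
                    sample_id=sample_id,
                    position=int(var.POS),
                    ref_base=ref,
                    alt_base=alt,
                    total_depth=max(total_depth, alt_reads + ref_reads),
                    ref_reads=ref_reads,
                    alt_reads=alt_reads,
                )
            )
    report.n_observations = len(observations)
    if mean_coverage is None:
        mean_coverage = (
            float(np.mean([o.total_depth for o in observations])) if observations else 0.0
        )
    profile = SampleProfile(sample_id, tissue, mean_coverage, tuple(observations))
    return profile, report


def read_catalog_tsv(path) -> dict[str, SampleProfile]:
    """Read a flat observation catalog; returns profiles keyed by sample id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"catalog is missing columns {missing}")
    per_sample: dict[str, list[VariantObservation]] = {}
    tissue_of: dict[str, str] = {}
    for i, row in df.iterrows():
        rownum = i + 2  # 1-based with header
        try:
            tissue = _normalize_tissue(row["tissue"])
            obs = VariantObservation(
                sample_id=str(row["sample_id"]),
                position=int(row["position"]),
                ref_base=str(row["ref"]).upper(),
                alt_base=str(row["alt"]).upper(),
                total_depth=int(row["total_depth"]),
                ref_reads=int(row["ref_reads"]),
                alt_reads=int(row["alt_reads"]),
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"catalog row {rownum}: {exc}") from exc
        prior = tissue_of.setdefault(obs.sample_id, tissue)
        if prior != tissue:
            raise ValidationError(
                f"catalog row {rownum}: sample {obs.sample_id} labelled both "
                f"{prior} and {tissue}"
            )
        per_sample.setdefault(obs.sample_id, []).append(obs)
    profiles = {}
    for sid, obs_list in per_sample.items():
        mean_cov = float(np.mean([o.total_depth for o in obs_list]))
        profiles[sid] = SampleProfile(sid, tissue_of[sid], mean_cov, tuple(obs_list))
    return profiles


def write_catalog_tsv(profiles: Iterable[SampleProfile], path) -> None:
    rows = []
    for profile in profiles:
        for o in profile.observations:
            rows.append(
                {
                    "sample_id": o.sample_id,
                    "tissue": profile.tissue,
                    "position": o.position,
                    "ref": o.ref_base,
                    "alt": o.alt_base,
                    "total_depth": o.total_depth,
                    "ref_reads": o.ref_reads,
                    "alt_reads": o.alt_reads,
                }
            )
    pd.DataFrame(rows, columns=CATALOG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    """Read the patient manifest (patient/ancestry/stage/age/sample/tissue)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"patient_id", "sample_id", "tissue"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"manifest is missing columns {sorted(missing)}")
    df["tissue"] = df["tissue"].map(_normalize_tissue)
    dup = df.duplicated(subset=["patient_id", "tissue"])
    if dup.any():
        bad = df.loc[dup, ["patient_id", "tissue"]].iloc[0]
        raise ValidationError(
            f"patient {bad['patient_id']} has more than one {bad['tissue']} sample"
        )
    return df


def assemble_cohort(
    manifest: pd.DataFrame, profiles: Mapping[str, SampleProfile]
) -> list[PatientRecord]:
    """Join a manifest with per-sample profiles into PatientRecords."""
    records: dict[str, PatientRecord] = {}
    for _, row in manifest.iterrows():
        pid = str(row["patient_id"])
        rec = records.get(pid)
        if rec is None:
            age = row.get("age")
            rec = PatientRecord(
                patient_id=pid,
                ancestry=str(row.get("ancestry", "other") or "other"),
                stage=str(row.get("stage", "unknown") or "unknown"),
                age=float(age) if age not in (None, "", "unknown") and not pd.isna(age) else None,
            )
            records[pid] = rec
        sid = str(row["sample_id"])
        if sid in profiles:
            profile = profiles[sid]
            if profile.tissue != row["tissue"]:
                profile = replace(profile, tissue=row["tissue"])
            rec.samples[row["tissue"]] = profile
    return list(records.values())


def write_annotated_catalog(mutations: Sequence, path) -> None:
    """Write annotated somatic mutations as a TSV (lossless round-trip)."""
    rows = []
    for m in mutations:
        source = ",".join(sorted(m.source_tissues))
        rows.append(
            {
                "patient_id": m.patient_id,
                "mutation": str(m.key),
                "position": m.position,
                "ref": m.ref_base,
                "alt": m.alt_base,
                "gene": m.gene,
                "region_class": m.region_class,
                "complex": m.complex,
                "substitution_class": m.substitution_class,
                "maf_percent": "NA" if m.maf_percent is None else repr(float(m.maf_percent)),
                "alt_fraction": repr(float(m.alt_fraction)),
                "heteroplasmy": m.heteroplasmy,
                "novel": "yes" if m.novel else "no",
                "pathogenic": "yes" if m.pathogenic else "no",
                "source_tissues": source,
                "ev_exclusive": "yes" if set(m.source_tissues) == {"EV"} else "no",
            }
        )
    pd.DataFrame(rows, columns=ANNOTATED_COLUMNS).to_csv(path, sep="\t", index=False)


def read_annotated_catalog(path):
    """Read an annotated catalog back into SomaticMutation records."""
    from .somatic import SomaticMutation  # deferred to avoid a cycle

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotated catalog is missing columns {missing}")
    mutations = []
    for i, row in df.iterrows():
        try:
            mutations.append(
                SomaticMutation(
                    patient_id=str(row["patient_id"]),
                    position=int(row["position"]),
                    ref_base=str(row["ref"]),
                    alt_base=str(row["alt"]),
                    gene=str(row["gene"]),
                    region_class=str(row["region_class"]),
                    complex=str(row["complex"]),
                    substitution_class=str(row["substitution_class"]),
                    maf_percent=None if row["maf_percent"] == "NA" else float(row["maf_percent"]),
                    alt_fraction=float(row["alt_fraction"]),
                    heteroplasmy=str(row["heteroplasmy"]),
                    novel=row["novel"] == "yes",
                    pathogenic=row["pathogenic"] == "yes",
                    source_tissues=frozenset(str(row["source_tissues"]).split(",")),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"annotated catalog row {i + 2}: {exc}") from exc
    return mutations
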