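"""Synthetic matched normal/tumor/EV cohorts with a ground-truth ledger.

The generator emulates the data structure the analysis assumes: each patient
shares a homoplasmic germline/haplogroup background between normal and tumor
(and, as carry-over, EV); the tumor additionally carries private somatic
substitutions (at least 3 per patient) drawn from a heteroplasmy mixture with
a homoplasmic component; deep amplicon-style coverage (~5000x) with
negative-binomial dispersion; EV profiles contain each tumor somatic mutation
with a configurable detection probability plus EV-exclusive mutations.

Every random draw flows from a single numpy Generator, so a seed fixes the
cohort byte-for-byte; the accompanying TruthLedger records what was injected
so pipeline recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .exceptions import ValidationError
from .mitogenome import DEFAULT_MAP, TRANSITIONS, MitoGeneMap
from .util import GENOME_LENGTH, MutationKey, format_mutation, make_key, parse_mutation
from .variants_io import KnownVariantTable, PatientRecord, SampleProfile, VariantObservation

ANCESTRIES = ("African", "European")

REGION_CLASSES = ("RCI", "RCIII", "RCIV", "RCV", "rRNA", "tRNA", "control", "intergenic")

# Region weighting preset shaped like an RCI-dominated tumor cohort
# (~44% of mutations in RCI; none in the control region).
PAPER_LIKE_WEIGHTS = {
    "RCI": 74,
    "RCIII": 11,
    "RCIV": 30,
    "RCV": 8,
    "rRNA": 25,
    "tRNA": 20,
    "control": 0,
    "intergenic": 0,
}

_TRANSVERSION_ALTS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}
_TRANSITION_ALT = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class SimulationConfig:
    """Study-shaped defaults: 32 patients (7 African / 25 European), 9 with
    EV profiles, group mean somatic loads 7.5 / 4.6 with a hard minimum of 3,
    ~5000x coverage, 18% homoplasmic mixture weight, 4:1 transition odds, and
    38% per-mutation EV detection probability."""

    n_patients: int = 32
    african_fraction: float = 7 / 32
    ev_fraction: float = 9 / 32
    germline_mean: float = 30.0
    haplogroup_pool_size: int = 400
    group_load_targets: dict[str, float] = field(
        default_factory=lambda: {"African": 7.5, "European": 4.6}
    )
    min_somatic: int = 3
    depth_mean: float = 5000.0
    depth_dispersion: float = 10.0
    min_depth: int = 1500
    homoplasmic_weight: float = 0.18
    het_fraction_range: tuple[float, float] = (0.15, 0.90)
    hom_fraction_range: tuple[float, float] = (0.97, 1.0)
    ev_detection_prob: float = 0.38
    ev_exclusive_mean: float = 11 / 9
    transition_odds: float = 4.0
    region_weights: str | Mapping[str, float] = "length"
    hotspot_injection: tuple[tuple[MutationKey, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValidationError("n_patients must be positive")
        for name in ("african_fraction", "ev_fraction", "homoplasmic_weight", "ev_detection_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for key, freq in self.hotspot_injection:
            if not 0 <= freq <= 1:
                raise ValidationError(
                    f"hotspot target frequency for {format_mutation(key)} is {freq}; "
                    "must be in [0, 1]"
                )
        for group, target in self.group_load_targets.items():
            if target < self.min_somatic:
                raise ValidationError(
                    f"{group} load target {target} below the minimum somatic count "
                    f"{self.min_somatic}"
                )
        lo, hi = self.het_fraction_range
        if not 0 < lo < hi < 1:
            raise ValidationError("het_fraction_range must satisfy 0 < lo < hi < 1")
        lo, hi = self.hom_fraction_range
        if not 0 < lo <= hi <= 1:
            raise ValidationError("hom_fraction_range must satisfy 0 < lo <= hi <= 1")
        if isinstance(self.region_weights, str) and self.region_weights not in (
            "length",
            "paper-like",
        ):
            raise ValidationError("region_weights preset must be 'length' or 'paper-like'")

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        data = dict(data)
        hotspots = data.pop("hotspot_injection", ())
        parsed = tuple(
            (parse_mutation(k) if isinstance(k, str) else make_key(*k), float(f))
            for k, f in hotspots
        )
        if "het_fraction_range" in data:
            data["het_fraction_range"] = tuple(data["het_fraction_range"])
        if "hom_fraction_range" in data:
            data["hom_fraction_range"] = tuple(data["hom_fraction_range"])
        return cls(hotspot_injection=parsed, **data)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class PatientTruth:
    ancestry: str
    has_ev: bool
    germline: dict[str, float] = field(default_factory=dict)  # notation -> alt fraction
    somatic: dict[str, float] = field(default_factory=dict)
    ev_carried: list[str] = field(default_factory=list)
    ev_exclusive: dict[str, float] = field(default_factory=dict)

    def somatic_keys(self) -> frozenset[MutationKey]:
        return frozenset(parse_mutation(k) for k in self.somatic)

    def germline_keys(self) -> frozenset[MutationKey]:
        return frozenset(parse_mutation(k) for k in self.germline)

    def ev_carried_keys(self) -> frozenset[MutationKey]:
        return frozenset(parse_mutation(k) for k in self.ev_carried)


@dataclass
class TruthLedger:
    patients: dict[str, PatientTruth] = field(default_factory=dict)
    homoplasmic_weight: float = 0.18
    ev_detection_prob: float = 0.38
    transition_odds: float = 4.0
    group_load_targets: dict[str, float] = field(default_factory=dict)
    hotspot_targets: dict[str, float] = field(default_factory=dict)

    def to_json(self, path=None, indent: int = 2) -> str:
        payload = {
            "patients": {pid: asdict(t) for pid, t in sorted(self.patients.items())},
            "homoplasmic_weight": self.homoplasmic_weight,
            "ev_detection_prob": self.ev_detection_prob,
            "transition_odds": self.transition_odds,
            "group_load_targets": self.group_load_targets,
            "hotspot_targets": self.hotspot_targets,
        }
        text = json.dumps(payload, indent=indent, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "TruthLedger":
        with open(path) as fh:
            payload = json.load(fh)
        ledger = cls(
            homoplasmic_weight=payload["homoplasmic_weight"],
            ev_detection_prob=payload["ev_detection_prob"],
            transition_odds=payload["transition_odds"],
            group_load_targets=payload["group_load_targets"],
            hotspot_targets=payload.get("hotspot_targets", {}),
        )
        for pid, data in payload["patients"].items():
            ledger.patients[pid] = PatientTruth(**data)
        return ledger


def synthetic_reference(seed: int = 20240, length: int = GENOME_LENGTH) -> str:
    """A deterministic synthetic stand-in for the mitochondrial reference.

    Random uniform A/C/G/T of rCRS length. It is *not* the real NC_012920.1
    sequence; it exists so codon-effect machinery can be exercised and tested
    end-to-end without shipping the genuine genome sequence.
    """
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _position_classes(gene_map: MitoGeneMap) -> np.ndarray:
    classes = np.empty(GENOME_LENGTH, dtype=object)
    for pos in range(1, GENOME_LENGTH + 1):
        a = gene_map.locate(pos)
        if a.complex != "none":
            classes[pos - 1] = a.complex
        elif a.primary_feature == "CONTROL":
            classes[pos - 1] = "control"
        elif a.primary_feature.startswith("RNR"):
            classes[pos - 1] = "rRNA"
        elif a.primary_feature.startswith("TRN"):
            classes[pos - 1] = "tRNA"
        else:
            classes[pos - 1] = "intergenic"
    return classes


_CLASS_CACHE: dict[int, np.ndarray] = {}


def position_weights(
    region_weights: str | Mapping[str, float], gene_map: MitoGeneMap = DEFAULT_MAP
) -> np.ndarray:
    """Per-position sampling weights (normalized), by region-class preset."""
    if region_weights == "length" or region_weights is None:
        w = np.ones(GENOME_LENGTH)
        return w / w.sum()
    weights = PAPER_LIKE_WEIGHTS if region_weights == "paper-like" else dict(region_weights)
    key = id(gene_map)
    if key not in _CLASS_CACHE:
        _CLASS_CACHE[key] = _position_classes(gene_map)
    classes = _CLASS_CACHE[key]
    # per-position weight = class weight / class size, so class totals follow
    # the requested proportions regardless of region lengths
    w = np.zeros(GENOME_LENGTH)
    for cls in REGION_CLASSES:
        mask = classes == cls
        n = int(mask.sum())
        if n and weights.get(cls, 0) > 0:
            w[mask] = weights[cls] / n
    if w.sum() <= 0:
        raise ValidationError("region weights sum to zero")
    return w / w.sum()


def _draw_substitution(rng, position: int, odds: float, reference: Optional[str]):
    ref = reference[position - 1] if reference else "ACGT"[rng.integers(0, 4)]
    if rng.random() < odds / (odds + 1.0):
        alt = _TRANSITION_ALT[ref]
    else:
        alt = _TRANSVERSION_ALTS[ref][rng.integers(0, 2)]
    return make_key(position, ref, alt)


def _draw_fraction(rng, config: SimulationConfig) -> float:
    if rng.random() < config.homoplasmic_weight:
        lo, hi = config.hom_fraction_range
    else:
        lo, hi = config.het_fraction_range
    return float(rng.uniform(lo, hi))


def _draw_reads(rng, config: SimulationConfig, af: float) -> tuple[int, int, int]:
    r, m = config.depth_dispersion, config.depth_mean
    depth = int(rng.negative_binomial(r, r / (r + m)))
    depth = max(depth, config.min_depth)
    alt = int(rng.binomial(depth, af))
    return depth, depth - alt, alt


def _observation(rng, config, sample_id, key, af) -> VariantObservation:
    depth, ref_reads, alt_reads = _draw_reads(rng, config, af)
    return VariantObservation(
        sample_id=sample_id,
        position=key.position,
        ref_base=key.ref,
        alt_base=key.alt,
        total_depth=depth,
        ref_reads=ref_reads,
        alt_reads=alt_reads,
    )


def _profile(rng, config, sample_id, tissue, variants: Mapping[MutationKey, float]) -> SampleProfile:
    observations = tuple(
        _observation(rng, config, sample_id, key, variants[key])
        for key in sorted(variants)
    )
    mean_cov = (
        float(np.mean([o.total_depth for o in observations]))
        if observations
        else config.depth_mean
    )
    return SampleProfile(sample_id, tissue, mean_cov, observations)


def simulate_cohort(
    config: SimulationConfig,
    seed: Optional[int] = None,
    reference: Optional[str] = None,
    gene_map: MitoGeneMap = DEFAULT_MAP,
) -> tuple[list[PatientRecord], TruthLedger]:
    """Generate matched normal/tumor(/EV) profiles plus the truth ledger.

    When ``reference`` is given, drawn ref bases follow it (so codon-effect
    annotation is consistent); otherwise ref bases are drawn uniformly.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    weights = position_weights(config.region_weights, gene_map)
    n = config.n_patients
    n_af = int(round(n * config.african_fraction))
    n_ev = int(round(n * config.ev_fraction))
    ev_patients = set(rng.choice(n, size=n_ev, replace=False).tolist())
    all_positions = np.arange(1, GENOME_LENGTH + 1)

    # Haplogroup markers are population-level sites shared across lineages:
    # one fixed pool of marker variants for the whole cohort, from which each
    # patient inherits a subset. Somatic/EV-exclusive positions never land on
    # pool sites, mirroring the marker-exclusion step of the caller.
    hotspot_positions = {k.position for k, _ in config.hotspot_injection}
    pool_candidates = np.array(
        [p for p in all_positions if p not in hotspot_positions]
    )
    pool_positions = np.sort(
        rng.choice(pool_candidates, size=config.haplogroup_pool_size, replace=False)
    )
    pool_keys = [
        _draw_substitution(rng, int(pos), config.transition_odds, reference)
        for pos in pool_positions
    ]
    # somatic weights never touch marker sites
    somatic_weights = weights.copy()
    somatic_weights[pool_positions - 1] = 0.0
    somatic_weights = somatic_weights / somatic_weights.sum()

    ledger = TruthLedger(
        homoplasmic_weight=config.homoplasmic_weight,
        ev_detection_prob=config.ev_detection_prob,
        transition_odds=config.transition_odds,
        group_load_targets=dict(config.group_load_targets),
        hotspot_targets={
            format_mutation(k): f for k, f in config.hotspot_injection
        },
    )
    patients: list[PatientRecord] = []
    width = max(2, len(str(n)))

    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        ancestry = "African" if i < n_af else "European"
        truth = PatientTruth(ancestry=ancestry, has_ev=i in ev_patients)

        # germline / haplogroup background: a homoplasmic subset of the
        # cohort marker pool, shared across the patient's tissues
        n_germ = min(int(rng.poisson(config.germline_mean)), len(pool_keys))
        used: set[int] = set()
        germline: dict[MutationKey, float] = {}
        if n_germ:
            picks = rng.choice(len(pool_keys), size=n_germ, replace=False)
            for j in sorted(int(j) for j in picks):
                key = pool_keys[j]
                germline[key] = 1.0
                used.add(key.position)

        # somatic mutations, tumor-private, heteroplasmy mixture
        target = config.group_load_targets.get(ancestry)
        if target is None:
            target = float(np.mean(list(config.group_load_targets.values()) or [config.min_somatic]))
        n_som = config.min_somatic + int(rng.poisson(target - config.min_somatic))
        somatic: dict[MutationKey, float] = {}
        w = somatic_weights.copy()
        w[[p - 1 for p in used]] = 0.0
        w = w / w.sum()
        positions = rng.choice(all_positions, size=n_som, replace=False, p=w)
        for pos in sorted(int(p) for p in positions):
            key = _draw_substitution(rng, pos, config.transition_odds, reference)
            somatic[key] = _draw_fraction(rng, config)
            used.add(pos)
        for key, freq in config.hotspot_injection:
            if rng.random() < freq and key.position not in used:
                somatic[key] = _draw_fraction(rng, config)
                used.add(key.position)

        truth.germline = {format_mutation(k): af for k, af in sorted(germline.items())}
        truth.somatic = {format_mutation(k): af for k, af in sorted(somatic.items())}

        samples: dict[str, SampleProfile] = {}
        samples["normal"] = _profile(rng, config, f"{pid}-N", "normal", germline)
        tumor_variants = {**germline, **somatic}
        samples["tumor"] = _profile(rng, config, f"{pid}-T", "tumor", tumor_variants)

        if truth.has_ev:
            ev_variants: dict[MutationKey, float] = dict(germline)  # carry-over
            carried = []
            for key in sorted(somatic):
                if rng.random() < config.ev_detection_prob:
                    ev_variants[key] = somatic[key]
                    carried.append(key)
            n_excl = int(rng.poisson(config.ev_exclusive_mean))
            exclusive: dict[MutationKey, float] = {}
            if n_excl:
                w = somatic_weights.copy()
                w[[p - 1 for p in used]] = 0.0
                w = w / w.sum()
                positions = rng.choice(all_positions, size=n_excl, replace=False, p=w)
                for pos in sorted(int(p) for p in positions):
                    key = _draw_substitution(rng, pos, config.transition_odds, reference)
                    af = _draw_fraction(rng, config)
                    exclusive[key] = af
                    ev_variants[key] = af
                    used.add(pos)
            truth.ev_carried = [format_mutation(k) for k in carried]
            truth.ev_exclusive = {
                format_mutation(k): af for k, af in sorted(exclusive.items())
            }
            samples["EV"] = _profile(rng, config, f"{pid}-EV", "EV", ev_variants)

        stage = str(rng.choice(["I", "II", "III", "IV"], p=[0.2, 0.5, 0.2, 0.1]))
        age = float(int(np.clip(rng.normal(58, 12), 30, 85)))
        patients.append(
            PatientRecord(
                patient_id=pid,
                ancestry=ancestry,
                stage=stage,
                age=age,
                samples=samples,
            )
        )
        ledger.patients[pid] = truth
    return patients, ledger


def known_variants_from_ledger(ledger: TruthLedger) -> KnownVariantTable:
    """Known-variant table for a simulated cohort: the injected germline set,
    flagged as reported haplogroup markers."""
    table = KnownVariantTable()
    seen = set()
    for truth in ledger.patients.values():
        for notation in truth.germline:
            key = parse_mutation(notation)
            if key not in seen:
                table.add(key, reported=True, haplogroup_marker=True)
                seen.add(key)
    return table


def write_vcf(profile: SampleProfile, path, contig: str = "chrM") -> None:
    """Write one sample's observations as a minimal, valid VCF 4.2 file."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig},length={GENOME_LENGTH}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{profile.sample_id}",
    ]
    for o in sorted(profile.observations, key=lambda o: (o.position, o.alt_base)):
        gt = "1/1" if o.alt_fraction >= 0.95 else "0/1"
        lines.append(
            f"{contig}\t{o.position}\t.\t{o.ref_base}\t{o.alt_base}\t.\tPASS\t.\t"
            f"GT:DP:AD\t{gt}:{o.total_depth}:{o.ref_reads},{o.alt_reads}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_cohort(
    patients: Sequence[PatientRecord], ledger: TruthLedger, outdir
) -> dict[str, Path]:
    """Emit per-sample VCFs, a manifest TSV, a known-variants TSV and the
    ledger JSON into ``outdir``; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for patient in patients:
        for tissue in ("normal", "tumor", "EV"):
            profile = patient.samples.get(tissue)
            if profile is None:
                continue
            vcf_path = outdir / f"{profile.sample_id}.vcf"
            write_vcf(profile, vcf_path)
            manifest_rows.append(
                "\t".join(
                    [
                        patient.patient_id,
                        patient.ancestry,
                        patient.stage,
                        "" if patient.age is None else f"{patient.age:.0f}",
                        profile.sample_id,
                        tissue,
                        vcf_path.name,
                    ]
                )
            )
    manifest_path = outdir / "manifest.tsv"
    manifest_path.write_text(
        "patient_id\tancestry\tstage\tage\tsample_id\ttissue\tvcf\n"
        + "\n".join(manifest_rows)
        + "\n"
    )
    known_path = outdir / "known_variants.tsv"
    known_variants_from_ledger(ledger).to_tsv(known_path)
    ledger_path = outdir / "ledger.json"
    ledger.to_json(ledger_path)
    return {
        "manifest": manifest_path,
        "known_variants": known_path,
        "ledger": ledger_path,
        "outdir": outdir,
    }


@dataclass
class RecoveryReport:
    """Pipeline output scored against the simulation truth ledger."""

    sensitivity: float
    precision: float
    homoplasmic_share_computed: float
    homoplasmic_share_truth: float
    traceability_computed: Optional[float] = None
    traceability_truth: Optional[float] = None
    group_loads_computed: dict[str, float] = field(default_factory=dict)
    group_loads_truth: dict[str, float] = field(default_factory=dict)

    @property
    def homoplasmic_share_error(self) -> float:
        return abs(self.homoplasmic_share_computed - self.homoplasmic_share_truth)

    @property
    def traceability_error(self) -> Optional[float]:
        if self.traceability_computed is None or self.traceability_truth is None:
            return None
        return abs(self.traceability_computed - self.traceability_truth)


def evaluate_recovery(
    per_patient_called: Mapping[str, Sequence],
    ledger: TruthLedger,
    concordance=None,
    homoplasmy_threshold: float = 0.95,
) -> RecoveryReport:
    """Compare called somatic sets and aggregates with the ledger truth.

    Sensitivity and precision pool (patient, mutation) pairs across the
    cohort. Homoplasmic shares are computed over distinct mutation keys with
    the same any-carrier convention the cohort summary uses.
    """
    unknown = set(per_patient_called) - set(ledger.patients)
    if unknown:
        raise ValidationError(f"called patients not in ledger: {sorted(unknown)}")
    tp = fp = fn = 0
    called_hom: dict[MutationKey, bool] = {}
    truth_hom: dict[MutationKey, bool] = {}
    for pid, truth in ledger.patients.items():
        true_keys = truth.somatic_keys()
        called = per_patient_called.get(pid, ())
        called_keys = {m.key for m in called}
        tp += len(called_keys & true_keys)
        fp += len(called_keys - true_keys)
        fn += len(true_keys - called_keys)
        for m in called:
            called_hom[m.key] = called_hom.get(m.key, False) or (
                m.heteroplasmy == "homoplasmic"
            )
        for notation, af in truth.somatic.items():
            key = parse_mutation(notation)
            truth_hom[key] = truth_hom.get(key, False) or af >= homoplasmy_threshold
    sensitivity = tp / (tp + fn) if tp + fn else 1.0
    precision = tp / (tp + fp) if tp + fp else 1.0
    hom_computed = (
        100.0 * sum(called_hom.values()) / len(called_hom) if called_hom else 0.0
    )
    hom_truth = 100.0 * sum(truth_hom.values()) / len(truth_hom) if truth_hom else 0.0

    # truth traceability: pooled union over EV-bearing patients
    ev_truths = [t for t in ledger.patients.values() if t.has_ev]
    trace_truth = None
    if ev_truths:
        pooled_tumor = set().union(*(t.somatic_keys() for t in ev_truths))
        pooled_carried = set().union(*(t.ev_carried_keys() for t in ev_truths))
        trace_truth = (
            100.0 * len(pooled_carried) / len(pooled_tumor) if pooled_tumor else 0.0
        )
    trace_computed = (
        float(concordance.traceability_percent) if concordance is not None else None
    )

    loads_truth: dict[str, float] = {}
    counts: dict[str, list[int]] = {}
    for truth in ledger.patients.values():
        counts.setdefault(truth.ancestry, []).append(len(truth.somatic))
    for group, values in counts.items():
        loads_truth[group] = float(np.mean(values))
    loads_computed: dict[str, float] = {}
    by_group: dict[str, list[int]] = {}
    for pid, called in per_patient_called.items():
        by_group.setdefault(ledger.patients[pid].ancestry, []).append(
            len({m.key for m in called})
        )
    for group, values in by_group.items():
        loads_computed[group] = float(np.mean(values))

    return RecoveryReport(
        sensitivity=sensitivity,
        precision=precision,
        homoplasmic_share_computed=hom_computed,
        homoplasmic_share_truth=hom_truth,
        traceability_computed=trace_computed,
        traceability_truth=trace_truth,
        group_loads_computed=loads_computed,
        group_loads_truth=loads_truth,
    )
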