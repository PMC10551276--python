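"""Worked-example catalogs with the count structure of a published TNBC cohort.

These fixtures reconstruct, at the level of printed counts, the shape of a
32-patient triple-negative breast cancer cohort: 168 distinct somatic mtDNA
mutations (134 transitions / 34 transversions; 123 coding across the four
respiratory complexes, 45 noncoding in rRNA/tRNA features), 31 homoplasmic,
23 novel, 15 potentially pathogenic, a 9-patient EV sub-study with 45 pooled
tumor mutations of which 17 are EV-traceable, an 11-mutation hotspot panel
with 9 members detectable in EVs, and 11 EV-exclusive mutations (8 in RCI).

Individually named mutations (e.g. G3842A, T7953G, T4434G, A10935G, G8519A)
sit at their real rCRS coordinates; the remaining entries are synthetic
placeholders placed inside the correct gene intervals. One hotspot-panel slot
(T9540C, MT-CO3) and the split of undetected panel members are synthetic
choices, since only eight panel members are individually documented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from .mitogenome import DEFAULT_MAP, MitoGeneMap
from .somatic import HETEROPLASMIC, HOMOPLASMIC, SomaticMutation
from .util import MutationKey, make_key, parse_mutation
from .variants_io import KnownVariantTable

N_PATIENTS = 32

# ---------------------------------------------------------------------------
# the 168-mutation catalog
# ---------------------------------------------------------------------------

# distinct mutation counts per gene (coding) and feature (noncoding)
GENE_COUNTS = {
    "MT-ND1": 20,
    "MT-ND2": 7,
    "MT-ND3": 2,
    "MT-ND4": 3,
    "MT-ND4L": 9,
    "MT-ND5": 29,
    "MT-ND6": 4,
    "MT-CYTB": 11,
    "MT-CO1": 10,
    "MT-CO2": 10,
    "MT-CO3": 10,
    "MT-ATP6": 7,
    "MT-ATP8": 1,
    "RNR1": 10,
    "RNR2": 15,
    "TRNM": 1,
    "TRNN": 1,
    "TRNF": 3,
    "TRNV": 3,
    "TRNL1": 3,
    "TRNI": 3,
    "TRNW": 3,
    "TRND": 3,
}

# individually named mutations, keyed by the gene they fall in
NAMED = {
    "MT-ND1": ["A3520C", "T3572A", "T3599A", "T3605A", "T4001C", "G3842A", "A3577C", "A3583C"],
    "MT-ND4": ["A10935G"],
    "MT-ND5": ["T12922G", "T13762G", "A13780G"],
    "MT-CYTB": ["T14894G"],
    "MT-CO1": ["C6340T"],
    "MT-CO2": ["T7953G", "C7758T", "G8078A"],
    "MT-CO3": ["T9540C"],
    "MT-ATP8": ["G8519A"],
    "RNR2": ["G1888A", "A1811G"],
    "TRNM": ["T4434G"],
    "TRNN": ["C5720T"],
}

N_TRANSITIONS = 134
N_TRANSVERSIONS = 34
N_HOMOPLASMIC = 31
N_PATHOGENIC = 15
N_NOVEL = 23

_TS_CYCLE = [("G", "A"), ("T", "C"), ("G", "A"), ("A", "G"), ("G", "A"), ("C", "T")]
_TV_CYCLE = [
    ("T", "G"),
    ("A", "C"),
    ("T", "A"),
    ("C", "G"),
    ("G", "T"),
    ("C", "A"),
    ("A", "T"),
    ("G", "C"),
]


def _gene_position_stream(
    gene: str, gene_map: MitoGeneMap, avoid: set[int]
) -> Iterator[int]:
    """Positions inside ``gene`` whose primary assignment is ``gene``."""
    feature = gene_map.feature(gene)
    for start, end in feature.segments:
        for pos in range(start, end + 1):
            if pos in avoid:
                continue
            if gene_map.locate(pos).primary_feature == feature.name:
                yield pos


def _is_transition(key: MutationKey) -> bool:
    return (key.ref, key.alt) in {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _build_keys(gene_map: MitoGeneMap) -> dict[str, list[MutationKey]]:
    """All 168 distinct keys grouped by gene, with exact class totals."""
    named = {g: [parse_mutation(s) for s in names] for g, names in NAMED.items()}
    named_ts = sum(_is_transition(k) for keys in named.values() for k in keys)
    named_total = sum(len(v) for v in named.values())
    gen_total = sum(GENE_COUNTS.values()) - named_total
    gen_tv = N_TRANSVERSIONS - (named_total - named_ts)
    # spread the generated transversions evenly through the generated stream
    tv_slots = {(j * gen_total) // gen_tv for j in range(gen_tv)}

    keys_by_gene: dict[str, list[MutationKey]] = {}
    gen_index = 0
    ts_i = tv_i = 0
    for gene, count in GENE_COUNTS.items():
        keys = list(named.get(gene, []))
        avoid = {k.position for k in keys}
        stream = _gene_position_stream(gene, gene_map, avoid)
        # space generated positions out a little inside the gene
        positions = []
        while len(positions) < count - len(keys):
            pos = next(stream)
            positions.append(pos)
            for _ in range(6):  # skip ahead; genes are long enough
                next(stream, None)
        for pos in positions:
            if gen_index in tv_slots:
                ref, alt = _TV_CYCLE[tv_i % len(_TV_CYCLE)]
                tv_i += 1
            else:
                ref, alt = _TS_CYCLE[ts_i % len(_TS_CYCLE)]
                ts_i += 1
            keys.append(make_key(pos, ref, alt))
            gen_index += 1
        keys_by_gene[gene] = keys
    return keys_by_gene


@dataclass
class ExampleCatalog:
    """A per-patient somatic catalog plus its known-variant lookup table."""

    per_patient: dict[str, list[SomaticMutation]]
    known: KnownVariantTable
    n_patients: int = N_PATIENTS
    keys_by_gene: dict[str, list[MutationKey]] = field(default_factory=dict)
    homoplasmic: frozenset[MutationKey] = frozenset()
    pathogenic: frozenset[MutationKey] = frozenset()
    novel: frozenset[MutationKey] = frozenset()


def example_catalog(gene_map: MitoGeneMap = DEFAULT_MAP) -> ExampleCatalog:
    """Build the 168-mutation cohort catalog described in the module docstring."""
    keys_by_gene = _build_keys(gene_map)

    def take(gene: str, n: int, exclude: set[MutationKey] = frozenset()) -> list[MutationKey]:
        out = [k for k in keys_by_gene[gene] if k not in exclude][:n]
        assert len(out) == n, f"not enough keys in {gene}"
        return out

    named = {s: parse_mutation(s) for names in NAMED.values() for s in names}

    # homoplasmic: 11 RCI, 5 RCIII, 5 RCIV (incl. the named pathogenic trio),
    # 2 RCV (incl. G8519A), 4 tRNA, 4 rRNA = 31
    homoplasmic: set[MutationKey] = set()
    homoplasmic |= set(take("MT-ND5", 6) + take("MT-ND1", 3, set(named.values())) + take("MT-ND4L", 2))
    homoplasmic |= set(take("MT-CYTB", 5, {named["T14894G"]}))
    homoplasmic |= {named["C6340T"], named["C7758T"], named["G8078A"]}
    homoplasmic |= set(take("MT-CO3", 2, {named["T9540C"]}))
    homoplasmic |= {named["G8519A"]} | set(take("MT-ATP6", 1))
    homoplasmic |= set(take("TRNF", 2) + take("TRNV", 2))
    homoplasmic |= set(take("RNR1", 2) + take("RNR2", 2, set(named.values())))
    assert len(homoplasmic) == N_HOMOPLASMIC

    # pathogenic: 7 RCI, 4 RCIV, 2 RCV, 2 tRNA = 15
    pathogenic: set[MutationKey] = set()
    pathogenic |= {named["G3842A"]} | set(take("MT-ND5", 4, homoplasmic | set(named.values()))) | set(
        take("MT-ND2", 2)
    )
    pathogenic |= {named["C6340T"], named["C7758T"], named["G8078A"]} | set(
        take("MT-CO1", 1, homoplasmic | set(named.values()))
    )
    pathogenic |= {named["G8519A"]} | set(take("MT-ATP6", 1, homoplasmic))
    pathogenic |= {named["C5720T"]} | set(take("TRNL1", 1, homoplasmic))
    assert len(pathogenic) == N_PATHOGENIC

    # novel (absent from databases, so disjoint from pathogenic):
    # 13 RCI, 4 RCIV, 1 RCIII, 5 tRNA = 23
    reserved = pathogenic | set(named.values())
    novel: set[MutationKey] = set()
    novel |= set(
        take("MT-ND5", 7, reserved | homoplasmic)
        + take("MT-ND1", 4, reserved | homoplasmic)
        + take("MT-ND6", 2)
    )
    novel |= set(take("MT-CO2", 2, reserved) + take("MT-CO3", 2, reserved | homoplasmic))
    novel |= set(take("MT-CYTB", 1, reserved | homoplasmic))
    novel |= set(take("TRNI", 3) + take("TRNW", 2))
    assert len(novel) == N_NOVEL

    known = KnownVariantTable()
    all_keys = [k for keys in keys_by_gene.values() for k in keys]
    assert len(all_keys) == len(set(all_keys)) == sum(GENE_COUNTS.values())
    for key in sorted(all_keys):
        if key in novel:
            continue  # novelty = absence from the table
        known.add(key, reported=True, pathogenic=key in pathogenic)

    per_patient: dict[str, list[SomaticMutation]] = {
        f"T{i + 1:02d}": [] for i in range(N_PATIENTS)
    }
    pids = sorted(per_patient)
    for i, key in enumerate(sorted(all_keys)):
        assignment = gene_map.locate(key.position)
        hom = key in homoplasmic
        af = 0.98 if hom else 0.40
        per_patient[pids[i % N_PATIENTS]].append(
            SomaticMutation(
                patient_id=pids[i % N_PATIENTS],
                position=key.position,
                ref_base=key.ref,
                alt_base=key.alt,
                gene=assignment.primary_feature,
                region_class=assignment.region_class,
                complex=assignment.complex,
                substitution_class="transition" if _is_transition(key) else "transversion",
                maf_percent=100.0 * af / (1.0 - af),
                alt_fraction=af,
                heteroplasmy=HOMOPLASMIC if hom else HETEROPLASMIC,
                novel=key in novel,
                pathogenic=key in pathogenic,
            )
        )
    return ExampleCatalog(
        per_patient=per_patient,
        known=known,
        keys_by_gene=keys_by_gene,
        homoplasmic=frozenset(homoplasmic),
        pathogenic=frozenset(pathogenic),
        novel=frozenset(novel),
    )


# ---------------------------------------------------------------------------
# hotspot panel and EV sub-study
# ---------------------------------------------------------------------------

# 11-mutation hotspot panel: 7 RCI + 2 RCIV + 1 RCIII + 1 tRNA.
# The first nine are the EV-detectable members in the example study.
HOTSPOT_PANEL = (
    "A3520C",  # MT-ND1
    "T3572A",  # MT-ND1
    "T3599A",  # MT-ND1
    "T3605A",  # MT-ND1
    "A10935G",  # MT-ND4
    "T12922G",  # MT-ND5
    "A13780G",  # MT-ND5
    "T7953G",  # MT-CO2
    "T4434G",  # TRNM (tRNA-Met)
    "T9540C",  # MT-CO3 — synthetic placeholder slot
    "T14894G",  # MT-CYTB
)


def hotspot_panel_keys() -> tuple[MutationKey, ...]:
    return tuple(parse_mutation(s) for s in HOTSPOT_PANEL)


@dataclass
class EvStudy:
    """Nine EV-bearing patients: tumor/EV mutation key sets plus the panel."""

    tumor_sets: dict[str, frozenset[MutationKey]]
    ev_sets: dict[str, frozenset[MutationKey]]
    normal_sets: dict[str, frozenset[MutationKey]]
    panel: tuple[MutationKey, ...]
    exclusive_by_patient: dict[str, frozenset[MutationKey]]

    @property
    def exclusive_keys(self) -> frozenset[MutationKey]:
        out: set[MutationKey] = set()
        for keys in self.exclusive_by_patient.values():
            out |= keys
        return frozenset(out)


def example_ev_study() -> EvStudy:
    """EV sub-study fixture: 45 pooled tumor mutations over 9 patients, 17 of
    them EV-traceable, 9/11 panel members detected, 11 EV-exclusive mutations
    (8 RCI, 2 RCIV, 1 RCV, including the novel T4001C in MT-ND1)."""
    panel = hotspot_panel_keys()
    pids = [f"E{i + 1}" for i in range(9)]

    # 34 non-panel tumor mutations: synthetic MT-ND2 placeholders
    filler = [make_key(4500 + 3 * j, "G", "A") for j in range(34)]

    tumor: dict[str, set[MutationKey]] = {pid: set() for pid in pids}
    for i in range(9):
        tumor[pids[i]].add(panel[i])
    tumor[pids[0]].add(panel[9])
    tumor[pids[1]].add(panel[10])
    fill_iter = iter(filler)
    for pid in pids:
        while len(tumor[pid]) < 5:
            tumor[pid].add(next(fill_iter))
    assert len(set().union(*tumor.values())) == 45

    # traceable: each patient's panel member (9) + one filler for 8 patients
    traceable: dict[str, set[MutationKey]] = {}
    for i, pid in enumerate(pids):
        t = {panel[i]}
        if i < 8:
            t.add(sorted(tumor[pid] - set(panel))[0])
        traceable[pid] = t
    assert len(set().union(*traceable.values())) == 17

    # 11 EV-exclusive mutations: 8 RCI + 2 RCIV + 1 RCV
    exclusive_all = [
        parse_mutation("T4001C"),  # MT-ND1, the documented novel one
        make_key(10480, "G", "A"),  # MT-ND4L
        make_key(10500, "T", "C"),  # MT-ND4L
        make_key(10520, "A", "G"),  # MT-ND4L
        make_key(14200, "G", "A"),  # MT-ND6
        make_key(14220, "C", "T"),  # MT-ND6
        make_key(14000, "T", "G"),  # MT-ND5
        make_key(14010, "A", "C"),  # MT-ND5
        make_key(6000, "G", "A"),  # MT-CO1 (RCIV)
        make_key(9300, "T", "C"),  # MT-CO3 (RCIV)
        make_key(8700, "C", "T"),  # MT-ATP6 (RCV)
    ]
    exclusive: dict[str, set[MutationKey]] = {pid: set() for pid in pids}
    for j, key in enumerate(exclusive_all):
        exclusive[pids[j % 9]].add(key)

    ev_sets = {pid: frozenset(traceable[pid] | exclusive[pid]) for pid in pids}
    return EvStudy(
        tumor_sets={pid: frozenset(tumor[pid]) for pid in pids},
        ev_sets=ev_sets,
        normal_sets={pid: frozenset() for pid in pids},
        panel=panel,
        exclusive_by_patient={pid: frozenset(exclusive[pid]) for pid in pids},
    )
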