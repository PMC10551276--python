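"""Embedded annotation of the human mitochondrial reference (rCRS, NC_012920.1).

The revised Cambridge Reference Sequence encodes 37 genes — 13 protein subunits
of the OXPHOS respiratory complexes, 22 tRNAs and 2 rRNAs — plus the D-loop
control region, which wraps around the origin (16024–16569 joined to 1–576).
This module is the coordinate authority for every downstream annotation step:
position → feature lookup, feature → respiratory-complex assignment,
transition/transversion classing, and codon-level effect prediction under the
vertebrate mitochondrial genetic code.

Coordinates are 1-based inclusive throughout; mutation notation follows the
field's "<ref><position><alt>" heavy-strand convention (e.g. G1888A).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Data import CodonTable

from .exceptions import (
    CoordinateError,
    NonCodingPositionError,
    ReferenceMismatchError,
    UnknownFeatureError,
    ValidationError,
)
from .util import GENOME_LENGTH, VALID_BASES

HEAVY = "heavy"
LIGHT = "light"

# Respiratory-complex membership of the 13 mtDNA-encoded protein subunits.
COMPLEX_OF_GENE = {
    "MT-ND1": "RCI",
    "MT-ND2": "RCI",
    "MT-ND3": "RCI",
    "MT-ND4": "RCI",
    "MT-ND4L": "RCI",
    "MT-ND5": "RCI",
    "MT-ND6": "RCI",
    "MT-CYTB": "RCIII",
    "MT-CO1": "RCIV",
    "MT-CO2": "RCIV",
    "MT-CO3": "RCIV",
    "MT-ATP6": "RCV",
    "MT-ATP8": "RCV",
}

COMPLEXES = ("RCI", "RCIII", "RCIV", "RCV")


@dataclass(frozen=True)
class GenomeFeature:
    """One annotated feature; the control region carries two segments."""

    name: str
    segments: tuple[tuple[int, int], ...]  # 1-based inclusive
    strand: str  # heavy | light
    category: str  # protein | tRNA | rRNA | control
    complex: str  # RCI | RCIII | RCIV | RCV | none

    def __post_init__(self) -> None:
        for start, end in self.segments:
            if not (1 <= start <= end <= GENOME_LENGTH):
                raise ValidationError(f"{self.name}: bad segment {start}-{end}")
        if self.category == "protein":
            if self.complex not in COMPLEXES:
                raise ValidationError(f"{self.name}: protein without complex")
        elif self.complex != "none":
            raise ValidationError(f"{self.name}: non-protein with complex")

    @property
    def start(self) -> int:
        return self.segments[0][0]

    @property
    def end(self) -> int:
        return self.segments[-1][1]

    @property
    def length(self) -> int:
        return sum(end - start + 1 for start, end in self.segments)

    def contains(self, position: int) -> bool:
        return any(start <= position <= end for start, end in self.segments)


def _f(name, start, end, strand, category):
    complex_ = COMPLEX_OF_GENE.get(name, "none")
    return GenomeFeature(name, ((start, end),), strand, category, complex_)


# NC_012920.1 feature table, embedded verbatim (no download at run time).
# Known gene overlaps (MT-ATP8/MT-ATP6, MT-ND4L/MT-ND4, MT-ATP6/MT-CO3,
# TRNC/TRNY) are preserved, not truncated.
FEATURES: tuple[GenomeFeature, ...] = (
    GenomeFeature("CONTROL", ((16024, 16569), (1, 576)), HEAVY, "control", "none"),
    _f("TRNF", 577, 647, HEAVY, "tRNA"),
    _f("RNR1", 648, 1601, HEAVY, "rRNA"),
    _f("TRNV", 1602, 1670, HEAVY, "tRNA"),
    _f("RNR2", 1671, 3229, HEAVY, "rRNA"),
    _f("TRNL1", 3230, 3304, HEAVY, "tRNA"),
    _f("MT-ND1", 3307, 4262, HEAVY, "protein"),
    _f("TRNI", 4263, 4331, HEAVY, "tRNA"),
    _f("TRNQ", 4329, 4400, LIGHT, "tRNA"),
    _f("TRNM", 4402, 4469, HEAVY, "tRNA"),
    _f("MT-ND2", 4470, 5511, HEAVY, "protein"),
    _f("TRNW", 5512, 5579, HEAVY, "tRNA"),
    _f("TRNA", 5587, 5655, LIGHT, "tRNA"),
    _f("TRNN", 5657, 5729, LIGHT, "tRNA"),
    _f("TRNC", 5761, 5826, LIGHT, "tRNA"),
    _f("TRNY", 5826, 5891, LIGHT, "tRNA"),
    _f("MT-CO1", 5904, 7445, HEAVY, "protein"),
    _f("TRNS1", 7446, 7514, LIGHT, "tRNA"),
    _f("TRND", 7518, 7585, HEAVY, "tRNA"),
    _f("MT-CO2", 7586, 8269, HEAVY, "protein"),
    _f("TRNK", 8295, 8364, HEAVY, "tRNA"),
    _f("MT-ATP8", 8366, 8572, HEAVY, "protein"),
    _f("MT-ATP6", 8527, 9207, HEAVY, "protein"),
    _f("MT-CO3", 9207, 9990, HEAVY, "protein"),
    _f("TRNG", 9991, 10058, HEAVY, "tRNA"),
    _f("MT-ND3", 10059, 10404, HEAVY, "protein"),
    _f("TRNR", 10405, 10469, HEAVY, "tRNA"),
    _f("MT-ND4L", 10470, 10766, HEAVY, "protein"),
    _f("MT-ND4", 10760, 12137, HEAVY, "protein"),
    _f("TRNH", 12138, 12206, HEAVY, "tRNA"),
    _f("TRNS2", 12207, 12265, HEAVY, "tRNA"),
    _f("TRNL2", 12266, 12336, HEAVY, "tRNA"),
    _f("MT-ND5", 12337, 14148, HEAVY, "protein"),
    _f("MT-ND6", 14149, 14673, LIGHT, "protein"),
    _f("TRNE", 14674, 14742, LIGHT, "tRNA"),
    _f("MT-CYTB", 14747, 15887, HEAVY, "protein"),
    _f("TRNT", 15888, 15953, HEAVY, "tRNA"),
    _f("TRNP", 15956, 16023, LIGHT, "tRNA"),
)

INTERGENIC = "INTERGENIC"  # positions covered by no annotated feature


@dataclass(frozen=True)
class FeatureAssignment:
    """Result of a position lookup.

    ``primary_feature`` is the overlap tie-break winner (smallest start
    coordinate); ``all_features`` lists every feature containing the position
    so callers can re-count overlap regions differently if they wish.
    ``region_class`` is "coding" iff the primary feature is a protein gene;
    control region, rRNA, tRNA and intergenic positions are "noncoding".
    """

    primary_feature: str
    all_features: tuple[str, ...]
    region_class: str  # coding | noncoding
    complex: str  # RCI | RCIII | RCIV | RCV | none

    @property
    def coding(self) -> bool:
        return self.region_class == "coding"


class MitoGeneMap:
    """Ordered collection of features covering the 16,569-bp genome."""

    genome_length = GENOME_LENGTH

    def __init__(self, features: Iterable[GenomeFeature] = FEATURES):
        self.features: tuple[GenomeFeature, ...] = tuple(features)
        self._by_name = {f.name.upper(): f for f in self.features}

    def feature(self, name: str) -> GenomeFeature:
        key = name.upper()
        if key in self._by_name:
            return self._by_name[key]
        # tolerate a missing/extra "MT-" prefix ("ND5" vs "MT-ND5")
        alt = key[3:] if key.startswith("MT-") else f"MT-{key}"
        if alt in self._by_name:
            return self._by_name[alt]
        raise UnknownFeatureError(name)

    def locate(self, position: int) -> FeatureAssignment:
        """Map a 1-based rCRS position to its feature(s)."""
        if not isinstance(position, (int,)) or isinstance(position, bool):
            raise CoordinateError(f"position must be an integer, got {position!r}")
        if not 1 <= position <= GENOME_LENGTH:
            raise CoordinateError(
                f"position {position} outside 1..{GENOME_LENGTH}"
            )
        hits = [f for f in self.features if f.contains(position)]
        if not hits:
            return FeatureAssignment(INTERGENIC, (INTERGENIC,), "noncoding", "none")
        hits.sort(key=lambda f: f.start)
        primary = hits[0]
        region = "coding" if primary.category == "protein" else "noncoding"
        return FeatureAssignment(
            primary_feature=primary.name,
            all_features=tuple(f.name for f in hits),
            region_class=region,
            complex=primary.complex,
        )

    def assign_complex(self, feature_name: str) -> str:
        return self.feature(feature_name).complex

    def protein_genes(self) -> tuple[GenomeFeature, ...]:
        return tuple(f for f in self.features if f.category == "protein")

    def to_bed(self, path=None, chrom: str = "chrM") -> str:
        """Export the map as BED (0-based half-open); one line per segment."""
        strand_symbol = {HEAVY: "+", LIGHT: "-"}
        lines = []
        for f in self.features:
            for start, end in f.segments:
                lines.append(
                    f"{chrom}\t{start - 1}\t{end}\t{f.name}\t0\t{strand_symbol[f.strand]}"
                )
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


DEFAULT_MAP = MitoGeneMap()

TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


def classify_substitution(ref_base: str, alt_base: str) -> str:
    """Transition (purine↔purine / pyrimidine↔pyrimidine) or transversion."""
    ref, alt = ref_base.upper(), alt_base.upper()
    if ref not in VALID_BASES or alt not in VALID_BASES:
        raise ValidationError(f"bases must be A/C/G/T, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValidationError("ref and alt bases are identical")
    return "transition" if (ref, alt) in TRANSITIONS else "transversion"


_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Vertebrate mitochondrial genetic code (translation table 2).
_MT_TABLE = CodonTable.unambiguous_dna_by_id[2]


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> Optional[str]:
    """One-letter amino acid under the vertebrate mitochondrial code; "*" for
    stop; None for an incomplete codon (mt genes may end in truncated stops)."""
    codon = codon.upper()
    if len(codon) != 3 or any(b not in VALID_BASES for b in codon):
        return None
    if codon in _MT_TABLE.stop_codons:
        return "*"
    return _MT_TABLE.forward_table[codon]


@dataclass(frozen=True)
class CodingEffect:
    gene: str
    codon_number: int  # 1-based codon index within the CDS
    ref_codon: str
    alt_codon: str
    ref_aa: Optional[str]
    alt_aa: Optional[str]
    synonymous: Optional[bool]


def coding_effect(
    position: int,
    ref_base: str,
    alt_base: str,
    reference_sequence: str,
    gene_map: MitoGeneMap = DEFAULT_MAP,
) -> CodingEffect:
    """Codon-level consequence of a heavy-strand substitution.

    The ref/alt bases are given on the heavy strand regardless of the gene's
    coding strand; light-strand genes (MT-ND6 among the proteins) are
    reverse-complemented before codon extraction. Reading frame starts at the
    gene's first coding base. A trailing incomplete codon (post-transcriptional
    polyadenylation completes several mt stop codons) yields None amino acids.
    """
    if reference_sequence is None:
        raise ValidationError("coding_effect requires a reference sequence")
    seq = str(reference_sequence).upper()
    if len(seq) != GENOME_LENGTH:
        raise ValidationError(
            f"reference sequence must be {GENOME_LENGTH} bp, got {len(seq)}"
        )
    assignment = gene_map.locate(position)
    feature = gene_map.feature(assignment.primary_feature) if assignment.primary_feature != INTERGENIC else None
    if feature is None or feature.category != "protein":
        raise NonCodingPositionError(
            f"position {position} is in {assignment.primary_feature}, not a protein gene"
        )
    ref, alt = ref_base.upper(), alt_base.upper()
    classify_substitution(ref, alt)  # validates bases
    if seq[position - 1] != ref:
        raise ReferenceMismatchError(
            f"reference has {seq[position - 1]} at {position}, observation says {ref}"
        )
    start, end = feature.segments[0]
    gene_seq = seq[start - 1 : end]
    if feature.strand == HEAVY:
        cds = gene_seq
        offset = position - start
        cds_ref, cds_alt = ref, alt
    else:
        cds = reverse_complement(gene_seq)
        offset = end - position
        cds_ref = ref.translate(_COMPLEMENT)
        cds_alt = alt.translate(_COMPLEMENT)
    codon_i = offset // 3
    within = offset % 3
    ref_codon = cds[3 * codon_i : 3 * codon_i + 3]
    if len(ref_codon) < 3:  # truncated terminal codon
        alt_codon = ref_codon[:within] + cds_alt + ref_codon[within + 1 :]
        return CodingEffect(feature.name, codon_i + 1, ref_codon, alt_codon, None, None, None)
    assert ref_codon[within] == cds_ref
    alt_codon = ref_codon[:within] + cds_alt + ref_codon[within + 1 :]
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    synonymous = (ref_aa == alt_aa) if ref_aa is not None and alt_aa is not None else None
    return CodingEffect(feature.name, codon_i + 1, ref_codon, alt_codon, ref_aa, alt_aa, synonymous)


def read_reference(path) -> str:
    """Read a single-record FASTA reference and validate its length."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValidationError(f"expected a single FASTA record, found {len(records)}")
    seq = str(records[0].seq).upper()
    if len(seq) != GENOME_LENGTH:
        raise ValidationError(
            f"reference must be {GENOME_LENGTH} bp (rCRS), got {len(seq)}"
        )
    return seq
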