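"""Gene-map lookup, substitution classing, and codon-effect annotation."""

import numpy as np
import pytest
from Bio.Seq import Seq

from mitoprofile.exceptions import (
    CoordinateError,
    NonCodingPositionError,
    ReferenceMismatchError,
    UnknownFeatureError,
    ValidationError,
)
from mitoprofile.mitogenome import (
    FEATURES,
    INTERGENIC,
    classify_substitution,
    coding_effect,
    read_reference,
    reverse_complement,
)
from mitoprofile.util import GENOME_LENGTH


class TestLocate:
    @pytest.mark.parametrize(
        "position, gene, region, complex_",
        [
            (3842, "MT-ND1", "coding", "RCI"),
            (4434, "TRNM", "noncoding", "none"),
            (10935, "MT-ND4", "coding", "RCI"),
            (1, "CONTROL", "noncoding", "none"),
            (16569, "CONTROL", "noncoding", "none"),
            (7953, "MT-CO2", "coding", "RCIV"),
            (14894, "MT-CYTB", "coding", "RCIII"),
            (1888, "RNR2", "noncoding", "none"),
        ],
    )
    def test_named_positions(self, gene_map, position, gene, region, complex_):
        a = gene_map.locate(position)
        assert a.primary_feature == gene
        assert a.region_class == region
        assert a.complex == complex_
        assert a.primary_feature in a.all_features

    def test_overlap_region_reports_both_genes(self, gene_map):
        a = gene_map.locate(8550)
        assert set(a.all_features) == {"MT-ATP8", "MT-ATP6"}
        # tie-break: smaller start coordinate wins
        assert a.primary_feature == "MT-ATP8"

    @pytest.mark.parametrize("position", [0, -5, 16570, 100000])
    def test_out_of_range(self, gene_map, position):
        with pytest.raises(CoordinateError):
            gene_map.locate(position)

    def test_exhaustive_over_genome(self, gene_map):
        """Every position resolves; feature intervals plus intergenic tile
        the genome exactly."""
        covered = np.zeros(GENOME_LENGTH, dtype=bool)
        for f in FEATURES:
            for start, end in f.segments:
                covered[start - 1 : end] = True
        n_intergenic = 0
        for pos in range(1, GENOME_LENGTH + 1):
            a = gene_map.locate(pos)
            if a.primary_feature == INTERGENIC:
                n_intergenic += 1
                assert not covered[pos - 1]
            else:
                assert covered[pos - 1]
        assert n_intergenic == int((~covered).sum())

    def test_matches_bruteforce_scan(self, gene_map):
        """locate() agrees with an independently built per-position table."""
        oracle = {}
        for f in sorted(FEATURES, key=lambda f: f.start, reverse=True):
            for start, end in f.segments:
                for pos in range(start, end + 1):
                    # later (smaller-start) features overwrite: tie-break oracle
                    oracle[pos] = f.name
        rng = np.random.default_rng(0)
        for pos in rng.integers(1, GENOME_LENGTH + 1, size=1000):
            a = gene_map.locate(int(pos))
            assert a.primary_feature == oracle.get(int(pos), INTERGENIC)


class TestMapStructure:
    def test_gene_count_is_37_plus_control(self):
        assert len(FEATURES) == 38
        by_cat = {}
        for f in FEATURES:
            by_cat.setdefault(f.category, []).append(f)
        assert len(by_cat["protein"]) == 13
        assert len(by_cat["tRNA"]) == 22
        assert len(by_cat["rRNA"]) == 2
        assert len(by_cat["control"]) == 1

    def test_complex_partition(self, gene_map):
        expected = {
            "RCI": {"MT-ND1", "MT-ND2", "MT-ND3", "MT-ND4", "MT-ND4L", "MT-ND5", "MT-ND6"},
            "RCIII": {"MT-CYTB"},
            "RCIV": {"MT-CO1", "MT-CO2", "MT-CO3"},
            "RCV": {"MT-ATP6", "MT-ATP8"},
        }
        got = {}
        for f in FEATURES:
            if f.category == "protein":
                got.setdefault(f.complex, set()).add(f.name)
        assert got == expected

    @pytest.mark.parametrize(
        "name, complex_", [("MT-ND5", "RCI"), ("MT-CYTB", "RCIII"), ("RNR2", "none"), ("ND1", "RCI")]
    )
    def test_assign_complex(self, gene_map, name, complex_):
        assert gene_map.assign_complex(name) == complex_

    def test_assign_complex_unknown(self, gene_map):
        with pytest.raises(UnknownFeatureError):
            gene_map.assign_complex("MT-NADH9")

    def test_control_region_wraps(self, gene_map):
        control = gene_map.feature("CONTROL")
        assert control.segments == ((16024, 16569), (1, 576))
        assert gene_map.locate(16200).primary_feature == "CONTROL"
        assert gene_map.locate(400).primary_feature == "CONTROL"

    def test_bed_export_roundtrip(self, gene_map, tmp_path):
        path = tmp_path / "map.bed"
        gene_map.to_bed(path)
        rows = [line.split("\t") for line in path.read_text().splitlines()]
        assert len(rows) == 39  # 37 genes + 2 control segments
        by_name = {}
        for chrom, start, end, name, score, strand in rows:
            by_name.setdefault(name, []).append((int(start), int(end)))
        # 0-based half-open vs internal 1-based inclusive
        nd1 = gene_map.feature("MT-ND1")
        assert by_name["MT-ND1"] == [(nd1.start - 1, nd1.end)]
        assert by_name["CONTROL"] == [(16023, 16569), (0, 576)]


class TestSubstitutionClass:
    def test_partition_of_12_ordered_pairs(self):
        classes = {
            (r, a): classify_substitution(r, a)
            for r in "ACGT"
            for a in "ACGT"
            if r != a
        }
        assert len(classes) == 12
        assert sum(c == "transition" for c in classes.values()) == 4
        assert sum(c == "transversion" for c in classes.values()) == 8

    @pytest.mark.parametrize(
        "ref, alt, expected",
        [("G", "A", "transition"), ("T", "G", "transversion"), ("C", "T", "transition")],
    )
    def test_examples(self, ref, alt, expected):
        assert classify_substitution(ref, alt) == expected

    @pytest.mark.parametrize("ref, alt", [("A", "A"), ("N", "A"), ("G", "X")])
    def test_invalid(self, ref, alt):
        with pytest.raises(ValidationError):
            classify_substitution(ref, alt)


class TestCodingEffect:
    def test_reverse_complement_involution(self):
        bases = "ACGT"
        for c1 in bases:
            for c2 in bases:
                for c3 in bases:
                    codon = c1 + c2 + c3
                    assert reverse_complement(reverse_complement(codon)) == codon

    @pytest.mark.parametrize("gene", ["MT-ND1", "MT-ND6"])  # heavy + light strand
    def test_against_full_cds_translation_oracle(self, gene_map, reference, gene):
        """Codon effects agree with brute-force whole-CDS translation
        (Biopython, vertebrate mitochondrial table) at every codon position."""
        feature = gene_map.feature(gene)
        start, end = feature.segments[0]
        rng = np.random.default_rng(1)
        checked = 0
        positions = rng.integers(start, end + 1, size=120)
        for pos in (int(p) for p in positions):
            if gene_map.locate(pos).primary_feature != gene:
                continue
            ref = reference[pos - 1]
            alt = "ACGT"[(("ACGT".index(ref)) + 1 + int(rng.integers(0, 3))) % 4]
            eff = coding_effect(pos, ref, alt, reference)
            # oracle: mutate the genome, extract the CDS, translate everything
            mutated = reference[: pos - 1] + alt + reference[pos:]
            for genome, want_attr in ((reference, "ref_aa"), (mutated, "alt_aa")):
                cds = genome[start - 1 : end]
                if feature.strand == "light":
                    cds = str(Seq(cds).reverse_complement())
                trimmed = cds[: len(cds) // 3 * 3]
                protein = str(Seq(trimmed).translate(table=2))
                idx = eff.codon_number - 1
                if idx < len(protein):
                    assert getattr(eff, want_attr) == protein[idx]
            if eff.ref_aa is not None:
                assert eff.synonymous == (eff.ref_aa == eff.alt_aa)
            checked += 1
        assert checked > 50

    def test_third_position_degeneracy_is_synonymous(self, gene_map, reference):
        """Scan for a third-codon-position change preserving the amino acid."""
        feature = gene_map.feature("MT-ND1")
        start, _ = feature.segments[0]
        found = False
        for codon_i in range(40):
            pos = start + 3 * codon_i + 2  # third position of the codon
            ref = reference[pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                eff = coding_effect(pos, ref, alt, reference)
                if eff.synonymous:
                    found = True
                    assert eff.ref_aa == eff.alt_aa
                    break
            if found:
                break
        assert found, "mitochondrial code degeneracy must yield a synonymous change"

    def test_rrna_position_not_applicable(self, reference):
        with pytest.raises(NonCodingPositionError):
            coding_effect(700, reference[699], "A" if reference[699] != "A" else "G", reference)

    def test_reference_mismatch_detected(self, reference):
        pos = 3400
        wrong = "A" if reference[pos - 1] != "A" else "C"
        with pytest.raises(ReferenceMismatchError):
            coding_effect(pos, wrong, "G" if wrong != "G" else "T", reference)


class TestFastaReader:
    def test_reads_and_validates_length(self, tmp_path, reference):
        path = tmp_path / "ref.fa"
        path.write_text(">synthetic_mito_reference\n" + "\n".join(
            reference[i : i + 70] for i in range(0, len(reference), 70)
        ) + "\n")
        assert read_reference(path) == reference

    def test_rejects_wrong_length(self, tmp_path):
        path = tmp_path / "short.fa"
        path.write_text(">x\nACGTACGT\n")
        with pytest.raises(ValidationError):
            read_reference(path)
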