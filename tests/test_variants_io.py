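"""VCF/TSV readers, manifests, known-variant tables, catalog round-trips."""

import pytest

from mitoprofile.datasets import example_catalog
from mitoprofile.exceptions import FormatError, ValidationError
from mitoprofile.simulate import write_vcf
from mitoprofile.somatic import SomaticMutation
from mitoprofile.variants_io import (
    KnownVariantTable,
    SampleProfile,
    VariantObservation,
    assemble_cohort,
    read_annotated_catalog,
    read_catalog_tsv,
    read_manifest,
    read_vcf,
    write_annotated_catalog,
    write_catalog_tsv,
)

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chrM,length=16569>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
"""


def _write(tmp_path, body):
    path = tmp_path / "sample.vcf"
    path.write_text(VCF_HEADER + body)
    return path


class TestVcfReader:
    def test_field_mapping(self, tmp_path):
        path = _write(tmp_path, "chrM\t1888\t.\tG\tA\t.\tPASS\t.\tGT:DP:AD\t0/1:5000:4500,500\n")
        profile, report = read_vcf(path, "S1", "tumor")
        assert report.n_observations == 1
        (obs,) = profile.observations
        assert (obs.position, obs.ref_base, obs.alt_base) == (1888, "G", "A")
        assert (obs.total_depth, obs.ref_reads, obs.alt_reads) == (5000, 4500, 500)

    def test_multiallelic_record_splits(self, tmp_path):
        path = _write(tmp_path, "chrM\t750\t.\tA\tG,C\t.\tPASS\t.\tGT:DP:AD\t0/1:3000:2000,600,400\n")
        profile, report = read_vcf(path, "S1", "tumor")
        assert report.n_observations == 2
        alts = {(o.alt_base, o.alt_reads) for o in profile.observations}
        assert alts == {("G", 600), ("C", 400)}

    def test_indel_skipped_and_counted(self, tmp_path):
        path = _write(
            tmp_path,
            "chrM\t300\t.\tAC\tA\t.\tPASS\t.\tGT:DP:AD\t0/1:2000:1500,500\n"
            "chrM\t310\t.\tG\tA\t.\tPASS\t.\tGT:DP:AD\t0/1:2000:1500,500\n",
        )
        profile, report = read_vcf(path, "S1", "tumor")
        assert report.n_skipped_non_snv == 1
        assert report.n_observations == 1

    def test_other_contig_skipped(self, tmp_path):
        path = _write(tmp_path, "chr1\t300\t.\tG\tA\t.\tPASS\t.\tGT:DP:AD\t0/1:2000:1500,500\n")
        profile, report = read_vcf(path, "S1", "tumor")
        assert report.n_skipped_contig == 1
        assert profile.observations == ()

    def test_never_emits_ref_equal_alt_or_bad_position(self, small_cohort, tmp_path):
        patients, _, _ = small_cohort
        profile = patients[0].samples["tumor"]
        path = tmp_path / "t.vcf"
        write_vcf(profile, path)
        reread, report = read_vcf(path, profile.sample_id, "tumor")
        assert report.n_skipped_non_snv == 0
        for obs in reread.observations:
            assert obs.ref_base != obs.alt_base
            assert 1 <= obs.position <= 16569

    def test_unknown_sample_errors(self, tmp_path):
        path = _write(tmp_path, "chrM\t300\t.\tG\tA\t.\tPASS\t.\tGT:DP:AD\t0/1:2000:1500,500\n")
        with pytest.raises(FormatError):
            read_vcf(path, "NOPE", "tumor")


class TestObservationValidation:
    def test_ref_equals_alt_rejected(self):
        with pytest.raises(ValidationError):
            VariantObservation("s", 100, "A", "A", 1000, 500, 500)

    def test_reads_exceeding_depth_rejected(self):
        with pytest.raises(ValidationError):
            VariantObservation("s", 100, "A", "G", 100, 80, 80)

    def test_position_bounds(self):
        with pytest.raises(ValidationError):
            VariantObservation("s", 16570, "A", "G", 1000, 500, 500)


class TestCatalogTsv:
    def _profiles(self):
        obs = [
            VariantObservation("S1", 1888, "G", "A", 5000, 4500, 500),
            VariantObservation("S1", 7953, "T", "G", 4000, 2000, 2000),
            VariantObservation("S2", 4434, "T", "G", 3000, 100, 2900),
        ]
        return [
            SampleProfile("S1", "tumor", 4500.0, tuple(obs[:2])),
            SampleProfile("S2", "EV", 3000.0, (obs[2],)),
        ]

    def test_roundtrip(self, tmp_path):
        path = tmp_path / "catalog.tsv"
        write_catalog_tsv(self._profiles(), path)
        profiles = read_catalog_tsv(path)
        assert set(profiles) == {"S1", "S2"}
        assert profiles["S1"].tissue == "tumor"
        assert len(profiles["S1"].observations) == 2
        assert profiles["S2"].observations[0].key == (4434, "T", "G")

    def test_unknown_tissue_rejected_with_row_number(self, tmp_path):
        path = tmp_path / "catalog.tsv"
        path.write_text(
            "sample_id\ttissue\tposition\tref\talt\ttotal_depth\tref_reads\talt_reads\n"
            "S1\tserum\t1888\tG\tA\t5000\t4500\t500\n"
        )
        with pytest.raises(ValidationError, match="row 2"):
            read_catalog_tsv(path)

    def test_empty_catalog(self, tmp_path):
        path = tmp_path / "catalog.tsv"
        path.write_text(
            "sample_id\ttissue\tposition\tref\talt\ttotal_depth\tref_reads\talt_reads\n"
        )
        assert read_catalog_tsv(path) == {}


class TestAnnotatedCatalog:
    def test_roundtrip_identity(self, tmp_path):
        catalog = example_catalog()
        mutations = [m for muts in catalog.per_patient.values() for m in muts][:40]
        path = tmp_path / "annotated.tsv"
        write_annotated_catalog(mutations, path)
        reread = read_annotated_catalog(path)
        assert reread == mutations

    def test_ev_exclusive_flagged(self, tmp_path):
        m = SomaticMutation(
            patient_id="P1",
            position=4001,
            ref_base="T",
            alt_base="C",
            gene="MT-ND1",
            region_class="coding",
            complex="RCI",
            substitution_class="transition",
            maf_percent=50.0,
            alt_fraction=1 / 3,
            heteroplasmy="heteroplasmic",
            novel=True,
            source_tissues=frozenset({"EV"}),
        )
        path = tmp_path / "annotated.tsv"
        write_annotated_catalog([m], path)
        text = path.read_text().splitlines()
        header = text[0].split("\t")
        row = dict(zip(header, text[1].split("\t")))
        assert row["ev_exclusive"] == "yes"
        assert read_annotated_catalog(path) == [m]

    def test_empty_catalog_is_header_only(self, tmp_path):
        path = tmp_path / "annotated.tsv"
        write_annotated_catalog([], path)
        assert len(path.read_text().splitlines()) == 1
        assert read_annotated_catalog(path) == []


class TestKnownVariantTable:
    def test_tsv_roundtrip(self, tmp_path):
        table = KnownVariantTable()
        table.add((1888, "G", "A"), reported=True, pathogenic=True)
        table.add((263, "A", "G"), reported=True, haplogroup_marker=True)
        path = tmp_path / "known.tsv"
        table.to_tsv(path)
        reread = KnownVariantTable.from_tsv(path)
        assert reread.is_pathogenic((1888, "G", "A"))
        assert reread.is_haplogroup_marker((263, "A", "G"))
        assert not reread.is_reported((5000, "C", "T"))

    def test_duplicate_key_rejected(self):
        table = KnownVariantTable()
        table.add((100, "A", "G"))
        with pytest.raises(ValidationError):
            table.add((100, "A", "G"))


class TestManifest:
    def test_assemble_cohort(self, tmp_path):
        path = tmp_path / "manifest.tsv"
        path.write_text(
            "patient_id\tancestry\tstage\tage\tsample_id\ttissue\n"
            "P1\tAfrican\tII\t54\tP1-N\tnormal\n"
            "P1\tAfrican\tII\t54\tP1-T\ttumor\n"
        )
        manifest = read_manifest(path)
        profiles = {
            "P1-N": SampleProfile("P1-N", "normal", 5000.0),
            "P1-T": SampleProfile("P1-T", "tumor", 5000.0),
        }
        (patient,) = assemble_cohort(manifest, profiles)
        assert patient.ancestry == "African"
        assert set(patient.samples) == {"normal", "tumor"}

    def test_duplicate_tissue_rejected(self, tmp_path):
        path = tmp_path / "manifest.tsv"
        path.write_text(
            "patient_id\tancestry\tstage\tage\tsample_id\ttissue\n"
            "P1\tAfrican\tII\t54\tP1-T1\ttumor\n"
            "P1\tAfrican\tII\t54\tP1-T2\ttumor\n"
        )
        with pytest.raises(ValidationError):
            read_manifest(path)
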