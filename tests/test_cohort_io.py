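"""I/O layer: VCF parsing, multi-allelic splitting, reference table and
list-file contracts, and round-trip identity."""

from __future__ import annotations

import pytest

from conftest import csq, write_vcf
from lofburden.cohort_io import (
    AnnotationError,
    read_annotated_cohort,
    read_gene_list,
    read_metadata,
    read_pathways,
    read_reference_counts,
    write_reference_counts,
)
from lofburden.pipeline import packaged_data
from lofburden.types import PathwayDefinition, ReferenceVariantRecord, VariantKey


class TestReadAnnotatedCohort:
    def test_toy_cohort_counts(self, toy_vcf):
        variants, observations = read_annotated_cohort(toy_vcf)
        assert len(variants) == 3
        assert len(observations) == 3
        assert {v.gene_symbol for v in variants} == {"G1", "G2", "G3"}
        assert all(o.allele_count == 1 for o in observations)

    def test_multiallelic_split(self, tmp_path):
        entries = ",".join([csq(allele="T", gene="G1"), csq(allele="G", gene="G1")])
        body = f"1\t100\t.\tA\tT,G\t1000\tPASS\tCSQ={entries};DP=100;VAF=0.5;BIDIR=1\tGT\t1/2\t0/1\n"
        variants, observations = read_annotated_cohort(write_vcf(tmp_path / "m.vcf", body))
        assert len(variants) == 2
        assert {v.variant_key.alt for v in variants} == {"T", "G"}
        assert all(
            (v.variant_key.chrom, v.variant_key.pos, v.variant_key.ref) == ("1", 100, "A")
            for v in variants
        )
        # S1 is 1/2 (one copy of each alt), S2 is 0/1
        counts = {(o.sample_id, o.variant_key.alt): o.allele_count for o in observations}
        assert counts == {("S1", "T"): 1, ("S1", "G"): 1, ("S2", "T"): 1}

    def test_split_invariance_vs_presplit(self, tmp_path):
        entries = ",".join([csq(allele="T", gene="G1"), csq(allele="G", gene="G1")])
        multi = f"1\t100\t.\tA\tT,G\t1000\tPASS\tCSQ={entries};DP=100;VAF=0.5;BIDIR=1\tGT\t1/2\t0/1\n"
        split = (
            f"1\t100\t.\tA\tT\t1000\tPASS\tCSQ={csq(allele='T', gene='G1')};DP=100;VAF=0.5;BIDIR=1\tGT\t0/1\t0/1\n"
            f"1\t100\t.\tA\tG\t1000\tPASS\tCSQ={csq(allele='G', gene='G1')};DP=100;VAF=0.5;BIDIR=1\tGT\t0/1\t0/0\n"
        )
        v1, o1 = read_annotated_cohort(write_vcf(tmp_path / "m.vcf", multi))
        v2, o2 = read_annotated_cohort(write_vcf(tmp_path / "s.vcf", split))
        assert set(v1) == set(v2)
        assert set(o1) == set(o2)

    def test_missing_annotation_names_record(self, tmp_path):
        body = "1\t123\t.\tA\tT\t1000\tPASS\tDP=100;VAF=0.5;BIDIR=1\tGT\t0/1\t0/0\n"
        with pytest.raises(AnnotationError, match="1:123"):
            read_annotated_cohort(write_vcf(tmp_path / "x.vcf", body))

    def test_homozygous_and_missing_genotypes(self, tmp_path):
        body = (
            f"1\t100\t.\tA\tT\t1000\tPASS\tCSQ={csq()};DP=100;VAF=0.5;BIDIR=1\tGT\t1/1\t./.\n"
        )
        _, observations = read_annotated_cohort(write_vcf(tmp_path / "h.vcf", body))
        assert len(observations) == 1
        assert observations[0].allele_count == 2

    def test_phase_group_read_from_format(self, tmp_path):
        body = (
            f"1\t100\t.\tA\tT\t1000\tPASS\tCSQ={csq()};DP=100;VAF=0.5;BIDIR=1\tGT:PG\t0/1:h1\t0/0:.\n"
            f"1\t150\t.\tC\tG\t1000\tPASS\tCSQ={csq(allele='G')};DP=100;VAF=0.5;BIDIR=1\tGT:PG\t0/1:h1\t0/0:.\n"
        )
        _, observations = read_annotated_cohort(write_vcf(tmp_path / "p.vcf", body))
        assert [o.phase_group for o in observations] == ["h1", "h1"]


def _ref_record(pos=100, ac=3, an=118190, gene="G1", flags=frozenset()):
    return ReferenceVariantRecord(
        gene_symbol=gene,
        variant_key=VariantKey("1", pos, "A", "T"),
        allele_count=ac,
        allele_number=an,
        allele_frequency=ac / an,
        filter_flags=flags,
    )


class TestReferenceCounts:
    HEADER = (
        "gene\tchrom\tpos\tref\talt\tallele_count\tallele_number"
        "\tallele_frequency\taf_popmax\tfilter_flags\n"
    )

    def test_two_rows(self, tmp_path):
        p = tmp_path / "ref.tsv"
        p.write_text(
            self.HEADER
            + "G1\t1\t100\tA\tT\t3\t118190\t2.538286e-05\t\t\n"
            + "G1\t1\t200\tC\tG\t4\t118190\t3.384381e-05\t\tRF\n"
        )
        records = read_reference_counts(p)
        assert len(records) == 2
        assert records[1].filter_flags == {"RF"}

    def test_ac_exceeding_an_rejected(self, tmp_path):
        p = tmp_path / "ref.tsv"
        p.write_text(self.HEADER + "G1\t1\t100\tA\tT\t5\t4\t1.25\t\t\n")
        with pytest.raises(ValueError):
            read_reference_counts(p)

    def test_empty_with_header(self, tmp_path):
        p = tmp_path / "ref.tsv"
        p.write_text(self.HEADER)
        assert read_reference_counts(p) == []

    def test_duplicate_key_rejected(self, tmp_path):
        row = "G1\t1\t100\tA\tT\t3\t118190\t2.538286e-05\t\t\n"
        p = tmp_path / "ref.tsv"
        p.write_text(self.HEADER + row + row)
        with pytest.raises(ValueError, match="duplicate"):
            read_reference_counts(p)

    def test_round_trip_identity(self, tmp_path):
        records = [
            _ref_record(pos=100, ac=3),
            _ref_record(pos=200, ac=0),
            ReferenceVariantRecord(
                gene_symbol="G2",
                variant_key=VariantKey("2", 5, "G", "C"),
                allele_count=7,
                allele_number=99,
                allele_frequency=7 / 99,
                af_popmax_outbred=0.002,
                filter_flags=frozenset({"RF", "AC0"}),
            ),
        ]
        p = tmp_path / "ref.tsv"
        write_reference_counts(records, p)
        assert read_reference_counts(p) == records


class TestListsAndMetadata:
    def test_packaged_hr_pathway_has_25_genes(self):
        pathways = {p.pathway_name: p for p in read_pathways(packaged_data("pathways.tsv"))}
        hr = pathways["homologous_recombination_repair"]
        assert len(hr.genes) == 25
        assert {"ATM", "MRE11A", "PALB2", "RAD50", "NBN"} <= set(hr.genes)

    def test_empty_pathway_rejected(self):
        with pytest.raises(ValueError):
            PathwayDefinition("empty", ())

    def test_gene_list_ignores_comments(self, tmp_path):
        p = tmp_path / "genes.txt"
        p.write_text("# header\nATM\n\nPALB2\n")
        assert read_gene_list(p) == ("ATM", "PALB2")

    def test_duplicate_sample_id_rejected(self, tmp_path):
        p = tmp_path / "meta.tsv"
        p.write_text(
            "sample_id\thistology\tpersonal_cancer_history\tfamily_history\n"
            "S1\thgs\tnone\tnone_known\n"
            "S1\thgs\tnone\tnone_known\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_metadata(p)

    def test_metadata_preserves_unknown_labels(self, tmp_path):
        p = tmp_path / "meta.tsv"
        p.write_text(
            "sample_id\thistology\tpersonal_cancer_history\tfamily_history\n"
            "S1\tunusual_label\tprior_breast\tfh_breast_and_or_ovarian\n"
        )
        (m,) = read_metadata(p)
        assert m.histology == "unusual_label"
        assert m.personal_cancer_history == "prior_breast"
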