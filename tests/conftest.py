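"""Shared fixtures: variant factories and hand-written toy VCF text.

Toy VCFs are written as literal text, independently of the package's own
VCF writer, so reader tests do not depend on writer correctness.
"""

from __future__ import annotations

from pathlib import Path

import pytest

from lofburden.types import (
    AnnotatedVariant,
    CaseObservation,
    ClinvarClass,
    ImpactClass,
    QCMetrics,
    VariantKey,
)

GOOD_QC = QCMetrics(
    quality_score=1000.0,
    read_depth=120,
    alt_allele_fraction=0.5,
    bidirectional=True,
    caller_filters_passed=True,
)


def make_variant(
    chrom: str = "1",
    pos: int = 100,
    ref: str = "A",
    alt: str = "T",
    gene: str = "GENE1",
    transcript: str = "TR1",
    biotype: str = "protein_coding",
    canonical: bool = True,
    impact: ImpactClass = ImpactClass.HIGH,
    consequence: str = "stop_gained",
    af_total: float = 0.0001,
    af_popmax: float | None = None,
    clinvar: ClinvarClass = ClinvarClass.ABSENT,
    qc: QCMetrics = GOOD_QC,
) -> AnnotatedVariant:
    return AnnotatedVariant(
        variant_key=VariantKey(chrom, pos, ref, alt),
        gene_symbol=gene,
        transcript_id=transcript,
        biotype=biotype,
        canonical=canonical,
        impact_class=impact,
        consequence=consequence,
        af_total=af_total,
        af_popmax_outbred=af_popmax,
        clinvar_class=clinvar,
        qc=qc,
    )


def make_obs(
    sample: str = "S1",
    chrom: str = "1",
    pos: int = 100,
    ref: str = "A",
    alt: str = "T",
    allele_count: int = 1,
    phase_group: str | None = None,
) -> CaseObservation:
    return CaseObservation(
        sample_id=sample,
        variant_key=VariantKey(chrom, pos, ref, alt),
        allele_count=allele_count,
        phase_group=phase_group,
    )


def build_screen_cohort(n_samples: int = 516):
    """A cohort encoding six clinically actionable known-gene findings:
    one MSH6 stop-gain, three RAD51C carriers (frameshift, splice donor,
    multi-source pathogenic missense), one RAD51D stop-gain and one BRIP1
    stop-gain — six distinct carriers among ``n_samples`` samples."""
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    specs = [
        ("MSH6", 1, "stop_gained", ClinvarClass.ABSENT, "S0001"),
        ("RAD51C", 2, "frameshift_variant", ClinvarClass.ABSENT, "S0002"),
        ("RAD51C", 3, "splice_donor_variant", ClinvarClass.ABSENT, "S0003"),
        ("RAD51C", 4, "missense_variant", ClinvarClass.PATHOGENIC_MULTI_SOURCE, "S0004"),
        ("RAD51D", 5, "stop_gained", ClinvarClass.ABSENT, "S0005"),
        ("BRIP1", 6, "stop_gained", ClinvarClass.ABSENT, "S0006"),
    ]
    variants, observations = [], []
    for gene, pos, consequence, clinvar, sample in specs:
        impact = (
            ImpactClass.MODERATE if consequence == "missense_variant" else ImpactClass.HIGH
        )
        variants.append(make_variant(
            pos=pos, gene=gene, consequence=consequence, impact=impact, clinvar=clinvar,
        ))
        observations.append(make_obs(sample=sample, pos=pos))
    return sample_ids, variants, observations


VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=250000000>
##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations. Format: Allele|SYMBOL|Feature|BIOTYPE|CANONICAL|IMPACT|Consequence|AF|AF_popmax|CLIN_SIG">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=VAF,Number=1,Type=Float,Description="Alt allele read fraction">
##INFO=<ID=BIDIR,Number=1,Type=String,Description="Called bidirectionally">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=PG,Number=1,Type=String,Description="Phase group">
"""


def write_vcf(path: Path, body: str, samples: tuple[str, ...] = ("S1", "S2")) -> Path:
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    path.write_text(VCF_HEADER + cols + "\n" + body)
    return path


def csq(
    allele: str = "T",
    gene: str = "GENE1",
    transcript: str = "TR1",
    biotype: str = "protein_coding",
    canonical: str = "YES",
    impact: str = "HIGH",
    consequence: str = "stop_gained",
    af: str = "0.0001",
    af_popmax: str = "",
    clin_sig: str = "",
) -> str:
    return "|".join(
        [allele, gene, transcript, biotype, canonical, impact, consequence,
         af, af_popmax, clin_sig]
    )


@pytest.fixture
def toy_vcf(tmp_path: Path) -> Path:
    """Three biallelic records over two samples, one het carrier each."""
    body = "\n".join([
        f"1\t100\t.\tA\tT\t1000\tPASS\tCSQ={csq(allele='T', gene='G1')};DP=100;VAF=0.5;BIDIR=1\tGT\t0/1\t0/0",
        f"1\t200\t.\tC\tG\t1000\tPASS\tCSQ={csq(allele='G', gene='G2')};DP=100;VAF=0.5;BIDIR=1\tGT\t0/0\t0/1",
        f"1\t300\t.\tT\tA\t1000\tPASS\tCSQ={csq(allele='A', gene='G3')};DP=100;VAF=0.5;BIDIR=1\tGT\t0/1\t0/0",
    ]) + "\n"
    return write_vcf(tmp_path / "toy.vcf", body)
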