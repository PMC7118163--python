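"""Filter cascade on a hand-built set of annotated variants.

Builds ten variants engineered so that each stage of the cascade (impact,
total-population MAF, canonical transcript, caller quality, protein-coding
biotype, outbred popmax) removes exactly one, and prints the per-stage
unique-variant counts. The final kept set is what enters gene collapsing.
"""

import dataclasses

from lofburden.types import (
    AnnotatedVariant, ClinvarClass, ImpactClass, QCMetrics, VariantKey,
)
from lofburden.variant_filter import run_cascade

QC = QCMetrics(quality_score=1000, read_depth=120, alt_allele_fraction=0.5,
               bidirectional=True, caller_filters_passed=True)


def variant(pos, gene, **overrides):
    base = dict(
        variant_key=VariantKey("1", pos, "A", "T"), gene_symbol=gene,
        transcript_id=f"TR_{gene}", biotype="protein_coding", canonical=True,
        impact_class=ImpactClass.HIGH, consequence="stop_gained",
        af_total=1e-4, af_popmax_outbred=None,
        clinvar_class=ClinvarClass.ABSENT, qc=QC,
    )
    base.update(overrides)
    return AnnotatedVariant(**base)


variants = [
    variant(1, "GA"), variant(2, "GB"), variant(3, "GC"), variant(4, "GD"),
    variant(5, "GE", impact_class=ImpactClass.MODERATE,
            consequence="missense_variant"),
    variant(6, "GF", af_total=0.01),                  # common overall
    variant(7, "GG", canonical=False),                # non-canonical transcript
    variant(8, "GH", qc=dataclasses.replace(QC, caller_filters_passed=False)),
    variant(9, "GI", biotype="lincRNA"),              # non-coding RNA
    variant(10, "GJ", af_popmax_outbred=0.02),        # common in one population
]

kept, summary, decisions = run_cascade(variants, [])
print("surviving unique variants after each stage:")
for stage, (n_variants, n_genes) in summary.stage_counts.items():
    print(f"  {stage:<20s} {n_variants:3d} variants in {n_genes} genes")
print(f"kept for burden testing: {[v.gene_symbol for v in kept]}")
# Each stage removed exactly one variant (10 -> 4): only rare, canonical,
# protein-coding, well-called LoF variants survive.
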