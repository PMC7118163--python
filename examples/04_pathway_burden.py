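"""Pathway-grouped burden aggregation.

Pools per-gene case and reference allele counts over the member genes of
each DNA-repair pathway (the packaged catalogue), Fisher-tests the pooled
2x2 table and adds a deduplicated all-unique-genes row. Here the case
side is a small hand-built example.
"""

from lofburden.cohort_io import read_pathways
from lofburden.gene_burden import combined_carrier_frequency
from lofburden.pathway_burden import pathway_burden
from lofburden.pipeline import packaged_data
from lofburden.types import GeneCaseCounts, ReferenceGeneCount

pathways = read_pathways(packaged_data("pathways.tsv"))
hr = next(p for p in pathways if p.pathway_name == "homologous_recombination_repair")
print(f"{hr.pathway_name}: {len(hr.genes)} genes")

# toy case counts: one LoF allele in each of three member genes
case_counts = [GeneCaseCounts(g, 1, 1, 1020) for g in ("RAD52", "GEN1", "RBBP8")]
ref_counts = {
    g: ReferenceGeneCount(g, 60, 118_190, combined_carrier_frequency([60 / 118_190]))
    for g in hr.genes
}
(row, union) = pathway_burden(case_counts, ref_counts, [hr],
                              excluded_genes=("BRCA1", "BRCA2"))
print(f"case alleles {row.case_ac}/{row.case_an} ({row.case_freq:.3%}) "
      f"vs reference {row.ref_ac}/{row.ref_an} ({row.ref_freq:.3%})")
print(f"OR {row.odds_ratio:.2f}, p {row.p_value:.2g}")
# The pathway-level test asks whether LoF burden concentrates in a
# functional gene set even when no single member gene stands out.
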