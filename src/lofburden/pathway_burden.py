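"""Pathway-grouped LoF burden: pooled case vs reference allele counts over
the member genes of each pathway, Fisher-tested, with a deduplicated
"all unique genes" row.

Known predisposition genes already screened out of the cohort are removed
from every pathway before counting, so solved-case exclusions cannot
deflate the case side asymmetrically. Genes belonging to several pathways
count in each; the union row counts every gene once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .config import AnMode, DiscoveryConfig
from .enrichment_stats import gene_fisher
from .types import GeneCaseCounts, PathwayDefinition, ReferenceGeneCount

ALL_UNIQUE_ROW = "all_unique_genes"


@dataclass
class PathwayBurdenRow:
    pathway_name: str
    gene_count: int
    case_ac: int
    case_an: int
    ref_ac: int
    ref_an: int
    case_freq: float
    ref_freq: float
    odds_ratio: float | None
    ci95: tuple[float, float] | None
    p_value: float

    def __post_init__(self) -> None:
        if self.gene_count <= 0:
            raise ValueError(f"pathway {self.pathway_name!r} has no genes")


def pathway_burden(
    case_counts: Sequence[GeneCaseCounts],
    ref_counts: Mapping[str, ReferenceGeneCount],
    pathways: Iterable[PathwayDefinition],
    excluded_genes: Iterable[str] = (),
    case_an_per_gene: int | None = None,
    config: DiscoveryConfig | None = None,
    compute_ci: bool = False,
) -> list[PathwayBurdenRow]:
    """Pooled burden per pathway plus the all-unique-genes union row.

    The case allele number for a pathway is the per-gene case AN times the
    number of member genes; the reference AN is the sum of per-gene
    reference ANs (per-gene mode) or gene_count x global AN (global mode).
    A pathway left empty by the exclusions is a hard error.
    """
    cfg = config or DiscoveryConfig()
    excluded = set(excluded_genes)
    case_by_gene = {gc.gene_symbol: gc for gc in case_counts}
    if case_an_per_gene is None:
        if not case_counts:
            raise ValueError("case_an_per_gene required when case_counts is empty")
        case_an_per_gene = case_counts[0].case_allele_number

    defs = list(pathways)
    rows: list[PathwayBurdenRow] = []
    union: list[str] = []
    seen: set[str] = set()
    for pdef in defs:
        genes = [g for g in pdef.genes if g not in excluded]
        if not genes:
            raise ValueError(
                f"pathway {pdef.pathway_name!r} empty after excluding known genes"
            )
        rows.append(
            _burden_row(pdef.pathway_name, genes, case_by_gene, ref_counts,
                        case_an_per_gene, cfg, compute_ci)
        )
        for g in genes:
            if g not in seen:
                seen.add(g)
                union.append(g)
    if union:
        rows.append(
            _burden_row(ALL_UNIQUE_ROW, union, case_by_gene, ref_counts,
                        case_an_per_gene, cfg, compute_ci)
        )
    return rows


def _burden_row(
    name: str,
    genes: Sequence[str],
    case_by_gene: Mapping[str, GeneCaseCounts],
    ref_counts: Mapping[str, ReferenceGeneCount],
    case_an_per_gene: int,
    cfg: DiscoveryConfig,
    compute_ci: bool,
) -> PathwayBurdenRow:
    case_ac = sum(
        case_by_gene[g].case_allele_count for g in genes if g in case_by_gene
    )
    case_an = case_an_per_gene * len(genes)
    ref_ac = 0
    ref_an = 0
    for g in genes:
        ref = ref_counts.get(g)
        if cfg.an_mode is AnMode.GLOBAL:
            ref_an += cfg.global_ref_an
        else:
            ref_an += ref.ref_allele_number if ref else cfg.global_ref_an
        if ref:
            ref_ac += ref.ref_allele_count
    orr, ci, p = gene_fisher(case_ac, case_an, ref_ac, ref_an, compute_ci=compute_ci)
    return PathwayBurdenRow(
        pathway_name=name,
        gene_count=len(genes),
        case_ac=case_ac,
        case_an=case_an,
        ref_ac=ref_ac,
        ref_an=ref_an,
        case_freq=case_ac / case_an,
        ref_freq=ref_ac / ref_an if ref_an else 0.0,
        odds_ratio=orr,
        ci95=ci,
        p_value=p,
    )
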