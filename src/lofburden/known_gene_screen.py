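"""Screen for pathogenic variants in known and proposed predisposition
genes, removal of solved cases, and the proposed-gene burden table.

LoF variants in a listed gene count as pathogenic unless the clinical
database classes them benign/likely benign; missense variants count only
with a multi-source pathogenic consensus. Samples carrying a pathogenic
finding in a KNOWN-tier gene are considered solved and leave the discovery
cohort; PROPOSED-tier carriers stay in.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .enrichment_stats import gene_fisher
from .types import (
    AnnotatedVariant,
    CaseObservation,
    ClinvarClass,
    VariantKey,
)


class Classification(enum.Enum):
    PATHOGENIC_LOF = "pathogenic_lof"
    PATHOGENIC_MISSENSE = "pathogenic_missense"
    EXCLUDED_BENIGN = "excluded_benign"
    NOT_REPORTABLE = "not_reportable"


class GeneTier(enum.Enum):
    KNOWN = "known"
    PROPOSED = "proposed"


@dataclass(frozen=True)
class ScreenFinding:
    sample_id: str
    gene_symbol: str
    variant_key: VariantKey
    consequence: str
    classification: Classification
    gene_tier: GeneTier

    def __post_init__(self) -> None:
        if (
            self.classification is Classification.PATHOGENIC_MISSENSE
            and self.consequence != "missense_variant"
        ):
            raise ValueError("pathogenic_missense requires a missense consequence")


def classify_variant_in_listed_gene(
    variant: AnnotatedVariant,
    known_genes: Iterable[str],
    proposed_genes: Iterable[str],
) -> Classification:
    """Classify one variant annotated to a listed gene.

    LoF (HIGH impact) -> pathogenic unless the clinical class is benign /
    likely benign; missense -> pathogenic only under the multi-source
    pathogenic consensus class; everything else is not reportable.
    """
    gene = variant.gene_symbol
    if gene not in set(known_genes) | set(proposed_genes):
        raise ValueError(f"gene {gene!r} is not in any screening list")
    if variant.is_lof:
        if variant.clinvar_class is ClinvarClass.BENIGN_OR_LIKELY_BENIGN:
            return Classification.EXCLUDED_BENIGN
        return Classification.PATHOGENIC_LOF
    if variant.consequence == "missense_variant":
        if variant.clinvar_class is ClinvarClass.PATHOGENIC_MULTI_SOURCE:
            return Classification.PATHOGENIC_MISSENSE
    return Classification.NOT_REPORTABLE


def screen_cohort(
    variants: Sequence[AnnotatedVariant],
    observations: Sequence[CaseObservation],
    known_genes: Iterable[str],
    proposed_genes: Iterable[str],
) -> list[ScreenFinding]:
    """All pathogenic findings in listed genes across the cohort."""
    known = frozenset(known_genes)
    proposed = frozenset(proposed_genes)
    by_key: dict[VariantKey, list[AnnotatedVariant]] = defaultdict(list)
    for v in variants:
        if v.gene_symbol in known or v.gene_symbol in proposed:
            by_key[v.variant_key].append(v)
    findings: list[ScreenFinding] = []
    for obs in observations:
        for v in by_key.get(obs.variant_key, ()):
            cls = classify_variant_in_listed_gene(v, known, proposed)
            if cls not in (
                Classification.PATHOGENIC_LOF,
                Classification.PATHOGENIC_MISSENSE,
            ):
                continue
            findings.append(
                ScreenFinding(
                    sample_id=obs.sample_id,
                    gene_symbol=v.gene_symbol,
                    variant_key=v.variant_key,
                    consequence=v.consequence,
                    classification=cls,
                    gene_tier=(
                        GeneTier.KNOWN if v.gene_symbol in known else GeneTier.PROPOSED
                    ),
                )
            )
    return findings


def exclude_solved_cases(
    sample_ids: Iterable[str], findings: Iterable[ScreenFinding]
) -> list[str]:
    """Remove samples with any pathogenic finding in a KNOWN-tier gene;
    proposed-tier carriers are retained."""
    solved = {
        f.sample_id for f in findings if f.gene_tier is GeneTier.KNOWN
    }
    return [s for s in sample_ids if s not in solved]


def proposed_gene_table(
    variants: Sequence[AnnotatedVariant],
    observations: Sequence[CaseObservation],
    discovery_samples: Sequence[str],
    known_genes: Iterable[str],
    proposed_genes: Sequence[str],
    ref_allele_counts: Mapping[str, tuple[int, int]],
    include_empty: bool = False,
) -> list[dict]:
    """Per-proposed-gene pathogenic allele counts and Fisher results.

    The printed allele count includes pathogenic missense findings, but
    the Fisher test uses LoF alleles only; LoF alleles are collapsed with
    the same phase rule as the discovery burden (a known in-cis pair is
    one allele). ``ref_allele_counts`` maps gene -> (qualifying reference
    AC, reference AN). Genes with no findings in the discovery cohort
    produce no row.
    """
    from .gene_burden import collapse_case_counts

    known = frozenset(known_genes)
    proposed = frozenset(proposed_genes)
    discovery = set(discovery_samples)
    case_an = 2 * len(discovery_samples)

    lof_variants = []
    missense_keys: dict[VariantKey, set[str]] = defaultdict(set)
    for v in variants:
        if v.gene_symbol not in proposed:
            continue
        cls = classify_variant_in_listed_gene(v, known, proposed)
        if cls is Classification.PATHOGENIC_LOF:
            lof_variants.append(v)
        elif cls is Classification.PATHOGENIC_MISSENSE:
            missense_keys[v.variant_key].add(v.gene_symbol)

    disc_obs = [o for o in observations if o.sample_id in discovery]
    lof_counts = {
        gc.gene_symbol: gc
        for gc in collapse_case_counts(
            lof_variants, disc_obs, n_samples=len(discovery_samples)
        )
    }
    mis_alleles: dict[str, int] = defaultdict(int)
    mis_carriers: dict[str, set[str]] = defaultdict(set)
    for obs in disc_obs:
        for gene in missense_keys.get(obs.variant_key, ()):
            mis_alleles[gene] += obs.allele_count
            mis_carriers[gene].add(obs.sample_id)

    rows = []
    for gene in proposed_genes:
        gc = lof_counts.get(gene)
        lof = gc.case_allele_count if gc else 0
        mis = mis_alleles.get(gene, 0)
        if lof + mis == 0 and not include_empty:
            continue
        carriers = set(mis_carriers.get(gene, set()))
        if gc:
            carriers |= {s for _, s, _ in gc.variant_list}
        ref_ac, ref_an = ref_allele_counts.get(gene, (0, 0))
        if ref_an > 0:
            orr, ci, p = gene_fisher(lof, case_an, ref_ac, ref_an)
        else:
            orr, ci, p = None, None, 1.0
        rows.append(
            {
                "gene": gene,
                "case_alleles_reported": lof + mis,
                "case_alleles_tested": lof,
                "case_carriers": len(carriers),
                "case_an": case_an,
                "ref_ac": ref_ac,
                "ref_an": ref_an,
                "odds_ratio": orr,
                "ci95": ci,
                "p_value": p,
            }
        )
    return rows
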