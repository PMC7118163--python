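"""Per-gene collapsing of filtered variants into case allele / carrier
counts, and qualifying reference counts with combined carrier frequencies.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Iterable, Sequence

from .config import AnMode, DiscoveryConfig
from .types import (
    AnnotatedVariant,
    CaseObservation,
    GeneCaseCounts,
    ReferenceGeneCount,
    ReferenceVariantRecord,
    consequence_severity_rank,
)


def combined_carrier_frequency(afs: Sequence[float]) -> float:
    """Probability of carrying at least one of several independent alleles.

    Computed as ``1 - prod(1 - AF_i)``; the empty product gives 0. Assumes
    the variant alleles segregate independently (no linkage), the same
    assumption under which per-variant reference frequencies can be
    combined at all.
    """
    for af in afs:
        if not 0.0 <= af <= 1.0:
            raise ValueError(f"allele frequency out of [0, 1]: {af}")
    return 1.0 - math.prod(1.0 - af for af in afs)


def collapse_case_counts(
    kept_variants: Sequence[AnnotatedVariant],
    observations: Iterable[CaseObservation],
    n_samples: int,
) -> list[GeneCaseCounts]:
    """Collapse observations of kept variants into per-gene case counts.

    Allele counting per gene: a sample with several distinct qualifying
    variants contributes the sum of their allele counts, except that
    variants sharing a phase group (known in cis) collapse to a single
    allele — the most severe consequence among them is the one reported.
    Phase-unknown multi-variant samples contribute all alleles. Carriers
    are distinct samples per gene. The allele number is fixed at
    ``2 * n_samples``.
    """
    if n_samples <= 0:
        raise ValueError(f"n_samples must be positive, got {n_samples}")
    an = 2 * n_samples

    variant_gene: dict = defaultdict(set)
    severity: dict = {}
    for v in kept_variants:
        variant_gene[v.variant_key].add(v.gene_symbol)
        key = (v.variant_key, v.gene_symbol)
        severity[key] = min(
            severity.get(key, 99), consequence_severity_rank(v.consequence)
        )

    # (gene, sample) -> list of observations of qualifying variants
    per_gene_sample: dict = defaultdict(list)
    for obs in observations:
        for gene in variant_gene.get(obs.variant_key, ()):
            per_gene_sample[(gene, obs.sample_id)].append(obs)

    per_gene: dict = defaultdict(lambda: {"ac": 0, "carriers": set(), "variants": []})
    for (gene, sample_id), obs_list in sorted(per_gene_sample.items()):
        groups: dict = defaultdict(list)
        singles = []
        for obs in obs_list:
            if obs.phase_group is None:
                singles.append(obs)
            else:
                groups[obs.phase_group].append(obs)
        entry = per_gene[gene]
        entry["carriers"].add(sample_id)
        for obs in singles:
            entry["ac"] += obs.allele_count
            entry["variants"].append((obs.variant_key, sample_id, obs.allele_count))
        for group in groups.values():
            if len(group) == 1:
                obs = group[0]
                entry["ac"] += obs.allele_count
                entry["variants"].append((obs.variant_key, sample_id, obs.allele_count))
            else:
                # known in cis: one haplotype, one allele; report the most
                # severe consequence among the grouped variants
                chosen = min(
                    group,
                    key=lambda o: severity.get((o.variant_key, gene), 99),
                )
                entry["ac"] += 1
                entry["variants"].append((chosen.variant_key, sample_id, 1))

    return [
        GeneCaseCounts(
            gene_symbol=gene,
            case_allele_count=data["ac"],
            case_carrier_count=len(data["carriers"]),
            case_allele_number=an,
            variant_list=data["variants"],
        )
        for gene, data in sorted(per_gene.items())
    ]


def qualifying_reference_counts(
    records: Iterable[ReferenceVariantRecord],
    gene_symbol: str | None = None,
    maf_threshold: float = 0.005,
    excluded_flags: Iterable[str] = ("InbreedingCoeff", "AC0", "RF"),
    an_mode: AnMode = AnMode.PER_GENE,
    global_an: int | None = None,
) -> ReferenceGeneCount:
    """Aggregate one gene's reference rows into a qualifying count.

    Rows failing any of the excluded reference QC filters, or with an
    allele frequency above the rarity threshold, do not qualify and are
    excluded from every figure. The qualifying allele counts are summed;
    the allele number is the maximum AN over qualifying rows (per-gene
    mode) or the configured global AN; the combined carrier frequency is
    ``1 - prod(1 - AF_i)`` over qualifying frequencies.
    """
    excluded = set(excluded_flags)
    rows = list(records)
    if gene_symbol is None:
        genes = {r.gene_symbol for r in rows}
        if len(genes) > 1:
            raise ValueError(f"records span multiple genes: {sorted(genes)}")
        gene_symbol = next(iter(genes)) if genes else ""
    qualifying = [
        r
        for r in rows
        if not (r.filter_flags & excluded) and r.allele_frequency <= maf_threshold
    ]
    ac = sum(r.allele_count for r in qualifying)
    if an_mode is AnMode.GLOBAL:
        if global_an is None:
            raise ValueError("global_an required in GLOBAL an_mode")
        an = global_an
    else:
        an = max((r.allele_number for r in qualifying), default=global_an or 1)
    popmax_afs = [
        r.af_popmax_outbred for r in qualifying if r.af_popmax_outbred is not None
    ]
    return ReferenceGeneCount(
        gene_symbol=gene_symbol,
        ref_allele_count=min(ac, an),
        ref_allele_number=an,
        combined_frequency=combined_carrier_frequency(
            [r.allele_frequency for r in qualifying]
        ),
        popmax_combined_frequency=(
            combined_carrier_frequency(popmax_afs) if popmax_afs else None
        ),
    )


def reference_counts_by_gene(
    records: Iterable[ReferenceVariantRecord],
    config: DiscoveryConfig | None = None,
) -> dict[str, ReferenceGeneCount]:
    """Qualifying counts for every gene in a reference table."""
    cfg = config or DiscoveryConfig()
    by_gene: dict[str, list[ReferenceVariantRecord]] = defaultdict(list)
    for r in records:
        by_gene[r.gene_symbol].append(r)
    return {
        gene: qualifying_reference_counts(
            rows,
            gene_symbol=gene,
            maf_threshold=cfg.maf_threshold,
            excluded_flags=cfg.reference_filter_flags,
            an_mode=cfg.an_mode,
            global_an=cfg.global_ref_an,
        )
        for gene, rows in sorted(by_gene.items())
    }
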