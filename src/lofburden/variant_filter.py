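"""The filtering cascade: raw annotated variants -> rare, high-confidence,
protein-coding LoF variants, with auditable per-stage counts.

Stage order is fixed: predicted impact, total-population MAF, canonical
transcript, sequencing quality, protein-coding biotype, outbred popmax MAF.
Every dropped variant records exactly the first stage it failed, and the
summary tracks unique variants and unique genes surviving each stage.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .config import DiscoveryConfig
from .types import AnnotatedVariant, CaseObservation, ImpactClass, VariantKey


class FilterStage(enum.Enum):
    IMPACT = "impact"
    MAF_TOTAL = "maf_total"
    NON_CANONICAL = "non_canonical"
    QUALITY = "quality"
    NON_PROTEIN_CODING = "non_protein_coding"
    MAF_POPMAX = "maf_popmax"
    NONE = "none"


#: Cascade order (NONE excluded).
CASCADE_STAGES: tuple[FilterStage, ...] = (
    FilterStage.IMPACT,
    FilterStage.MAF_TOTAL,
    FilterStage.NON_CANONICAL,
    FilterStage.QUALITY,
    FilterStage.NON_PROTEIN_CODING,
    FilterStage.MAF_POPMAX,
)


@dataclass(frozen=True)
class FilterDecision:
    variant_key: VariantKey
    transcript_id: str
    kept: bool
    stage_failed: FilterStage
    qc_flagged_for_review: bool

    def __post_init__(self) -> None:
        if self.kept != (self.stage_failed is FilterStage.NONE):
            raise ValueError("kept must hold exactly when no stage failed")


@dataclass
class FilterSummary:
    """Unique variant / gene counts after each cascade stage.

    ``stage_counts`` maps stage name -> (n_unique_variants, n_unique_genes)
    surviving after that stage, with an ``input`` entry for the raw data.
    """

    stage_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    n_samples_retained: int = 0

    def as_rows(self) -> list[dict]:
        return [
            {"stage": stage, "n_variants": nv, "n_genes": ng}
            for stage, (nv, ng) in self.stage_counts.items()
        ]


def impact_filter(variant: AnnotatedVariant) -> bool:
    """Keep only HIGH-impact (classic LoF) annotations."""
    return variant.impact_class is ImpactClass.HIGH


def frequency_filter_total(
    variant: AnnotatedVariant, maf_threshold: float = 0.005
) -> bool:
    """Keep variants rare in the reference total population (MAF <= threshold).

    A variant absent from the reference carries af_total 0 and is kept:
    unseen implies rare.
    """
    return variant.af_total <= maf_threshold


def transcript_filter(variant: AnnotatedVariant) -> tuple[bool, bool]:
    """(canonical?, protein-coding biotype?) — applied at separate stages."""
    return variant.canonical, variant.biotype == "protein_coding"


def popmax_filter(variant: AnnotatedVariant, maf_threshold: float = 0.005) -> bool:
    """Keep variants rare in every major outbred reference sub-population.

    The popmax annotation is taken to already exclude bottlenecked
    populations (Finnish, Ashkenazi Jewish) and the "other" catch-all;
    a missing popmax means the variant is absent from all of them.
    """
    return variant.af_popmax_outbred is None or variant.af_popmax_outbred <= maf_threshold


def quality_flag(variant: AnnotatedVariant, config: DiscoveryConfig | None = None) -> bool:
    """True when the variant's metrics warrant manual (bam-level) review.

    Flag conditions: quality score below 500, read depth below 60, alt
    allele read fraction below 0.35, or the call not made bidirectionally.
    Flagged variants are not dropped unless ``config.drop_flagged`` is set;
    they mirror the manual curation queue. Thresholds are inclusive on the
    keep side (quality exactly 500 etc. is not flagged).
    """
    cfg = config or DiscoveryConfig()
    qc = variant.qc
    return (
        qc.quality_score < cfg.min_quality_score
        or qc.read_depth < cfg.min_read_depth
        or qc.alt_allele_fraction < cfg.min_alt_fraction
        or qc.bidirectional is False
    )


def _stage_failed(
    variant: AnnotatedVariant, config: DiscoveryConfig
) -> FilterStage:
    if not impact_filter(variant):
        return FilterStage.IMPACT
    if not frequency_filter_total(variant, config.maf_threshold):
        return FilterStage.MAF_TOTAL
    canonical, protein_coding = transcript_filter(variant)
    if not canonical:
        return FilterStage.NON_CANONICAL
    if not variant.qc.caller_filters_passed:
        return FilterStage.QUALITY
    if config.drop_flagged and quality_flag(variant, config):
        return FilterStage.QUALITY
    if not protein_coding:
        return FilterStage.NON_PROTEIN_CODING
    if not popmax_filter(variant, config.maf_threshold):
        return FilterStage.MAF_POPMAX
    return FilterStage.NONE


def run_cascade(
    variants: Sequence[AnnotatedVariant],
    observations: Iterable[CaseObservation],
    config: DiscoveryConfig | None = None,
) -> tuple[list[AnnotatedVariant], FilterSummary, list[FilterDecision]]:
    """Apply the full cascade and account for every variant.

    Returns the kept annotations (order-stable by input), the per-stage
    summary over unique variant keys and gene symbols, and one
    :class:`FilterDecision` per input annotation. The summary's sample
    count is the number of distinct samples still carrying at least one
    kept variant.
    """
    cfg = config or DiscoveryConfig()
    decisions: list[FilterDecision] = []
    kept: list[AnnotatedVariant] = []
    failures: list[FilterStage] = []
    for v in variants:
        stage = _stage_failed(v, cfg)
        failures.append(stage)
        decisions.append(
            FilterDecision(
                variant_key=v.variant_key,
                transcript_id=v.transcript_id,
                kept=stage is FilterStage.NONE,
                stage_failed=stage,
                qc_flagged_for_review=quality_flag(v, cfg),
            )
        )
        if stage is FilterStage.NONE:
            kept.append(v)

    summary = FilterSummary()
    surviving = list(zip(variants, failures))
    summary.stage_counts["input"] = _unique_counts(v for v, _ in surviving)
    for i, stage in enumerate(CASCADE_STAGES):
        later = CASCADE_STAGES[i + 1 :]
        surviving = [
            (v, s)
            for v, s in surviving
            if s is FilterStage.NONE or s in later
        ]
        summary.stage_counts[stage.value] = _unique_counts(v for v, _ in surviving)

    kept_keys = {v.variant_key for v in kept}
    summary.n_samples_retained = len(
        {o.sample_id for o in observations if o.variant_key in kept_keys}
    )
    return kept, summary, decisions


def _unique_counts(variants: Iterable[AnnotatedVariant]) -> tuple[int, int]:
    keys = set()
    genes = set()
    for v in variants:
        keys.add(v.variant_key)
        genes.add(v.gene_symbol)
    return len(keys), len(genes)
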