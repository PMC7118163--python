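"""Domain types shared across the burden-discovery pipeline.

The pipeline compares per-gene counts of rare, high-confidence
loss-of-function (LoF) alleles in a sequenced case cohort against
per-variant allele counts from a large external reference population
(gnomAD-style summary data). These dataclasses are the normalised,
validated in-memory representation every module operates on.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import NamedTuple


class VariantKey(NamedTuple):
    """Identity of one alternate allele: 1-based VCF coordinates."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


class ImpactClass(enum.Enum):
    """VEP-style predicted impact of a consequence annotation."""

    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    MODIFIER = "MODIFIER"


class ClinvarClass(enum.Enum):
    """Pre-resolved clinical classification consumed as an input annotation.

    ``PATHOGENIC_MULTI_SOURCE`` marks a pathogenic assertion with multiple
    supporting submitters and consensus — the only grade under which a
    missense variant is reportable in the known-gene screen.
    """

    PATHOGENIC_MULTI_SOURCE = "pathogenic_multi_source"
    PATHOGENIC = "pathogenic"
    UNCERTAIN = "uncertain"
    BENIGN_OR_LIKELY_BENIGN = "benign_or_likely_benign"
    ABSENT = "absent"


#: LoF consequence terms eligible for burden counting ("classic" LoF).
LOF_CONSEQUENCES = frozenset(
    {
        "stop_gained",
        "frameshift_variant",
        "splice_donor_variant",
        "splice_acceptor_variant",
        "start_lost",
    }
)

#: Severity order used to pick the reported variant when two variants known
#: to lie in cis are collapsed to a single allele (most severe first).
CONSEQUENCE_SEVERITY = (
    "frameshift_variant",
    "stop_gained",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "start_lost",
    "missense_variant",
)


def consequence_severity_rank(consequence: str) -> int:
    """Lower rank = more severe; unknown terms sort last."""
    try:
        return CONSEQUENCE_SEVERITY.index(consequence)
    except ValueError:
        return len(CONSEQUENCE_SEVERITY)


@dataclass(frozen=True)
class QCMetrics:
    """Per-variant sequencing quality metrics used for curation flagging.

    ``bidirectional`` may be ``None`` ("unknown") when strand information
    was not exported by the caller; all other fields are mandatory.
    """

    quality_score: float
    read_depth: int
    alt_allele_fraction: float
    bidirectional: bool | None
    caller_filters_passed: bool

    def __post_init__(self) -> None:
        if self.quality_score < 0:
            raise ValueError(f"quality_score must be >= 0, got {self.quality_score}")
        if self.read_depth < 0:
            raise ValueError(f"read_depth must be >= 0, got {self.read_depth}")
        if not 0.0 <= self.alt_allele_fraction <= 1.0:
            raise ValueError(
                f"alt_allele_fraction must be in [0, 1], got {self.alt_allele_fraction}"
            )


def _check_fraction(name: str, value: float | None) -> None:
    if value is not None and not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class AnnotatedVariant:
    """One alternate allele with one transcript annotation.

    A multi-allelic VCF record contributes one instance per alt allele, and
    a multi-transcript annotation one instance per transcript, so
    (variant_key, transcript_id) is the natural identity.

    ``af_total`` is the reference total-population allele frequency;
    ``af_popmax_outbred`` the maximum frequency over the major outbred
    reference sub-populations (bottlenecked populations and the "other"
    catch-all excluded), or ``None`` when the variant is absent from all
    of them.
    """

    variant_key: VariantKey
    gene_symbol: str
    transcript_id: str
    biotype: str
    canonical: bool
    impact_class: ImpactClass
    consequence: str
    af_total: float
    af_popmax_outbred: float | None
    clinvar_class: ClinvarClass
    qc: QCMetrics

    def __post_init__(self) -> None:
        if self.variant_key.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.variant_key.pos}")
        if self.variant_key.ref == self.variant_key.alt:
            raise ValueError(f"ref == alt at {self.variant_key}")
        _check_fraction("af_total", self.af_total)
        _check_fraction("af_popmax_outbred", self.af_popmax_outbred)

    @property
    def is_lof(self) -> bool:
        return self.impact_class is ImpactClass.HIGH


@dataclass(frozen=True)
class CaseObservation:
    """A (sample, variant) carriage link.

    ``allele_count`` is 1 (heterozygous) or 2 (homozygous alt).
    ``phase_group``: observations in the same sample and gene that share a
    label are known to lie in cis; ``None`` means phase unknown.
    """

    sample_id: str
    variant_key: VariantKey
    allele_count: int
    phase_group: str | None = None

    def __post_init__(self) -> None:
        if self.allele_count not in (1, 2):
            raise ValueError(f"allele_count must be 1 or 2, got {self.allele_count}")


@dataclass(frozen=True)
class ReferenceVariantRecord:
    """Per-variant allele count row from the reference population table."""

    gene_symbol: str
    variant_key: VariantKey
    allele_count: int
    allele_number: int
    allele_frequency: float
    af_popmax_outbred: float | None = None
    filter_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.allele_number <= 0:
            raise ValueError(f"allele_number must be > 0 at {self.variant_key}")
        if not 0 <= self.allele_count <= self.allele_number:
            raise ValueError(
                f"allele_count {self.allele_count} out of range for "
                f"allele_number {self.allele_number} at {self.variant_key}"
            )
        _check_fraction("allele_frequency", self.allele_frequency)
        _check_fraction("af_popmax_outbred", self.af_popmax_outbred)
        # AF must agree with AC/AN up to printing/rounding noise.
        if not math.isclose(
            self.allele_frequency,
            self.allele_count / self.allele_number,
            abs_tol=1e-6,
            rel_tol=1e-3,
        ):
            raise ValueError(
                f"allele_frequency {self.allele_frequency} inconsistent with "
                f"{self.allele_count}/{self.allele_number} at {self.variant_key}"
            )


class FamilyHistory(enum.Enum):
    BREAST_AND_OR_OVARIAN = "fh_breast_and_or_ovarian"
    NONE_KNOWN = "none_known"


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample clinical descriptors.

    Histology and personal-history labels are retained verbatim; only the
    family-history axis is coerced to the two-level factor the candidate
    carrier association test uses, with the finer sub-category kept in
    ``family_history_detail``.
    """

    sample_id: str
    histology: str
    personal_cancer_history: str
    family_history: FamilyHistory
    family_history_detail: str = ""


@dataclass(frozen=True)
class PathwayDefinition:
    """A named, ordered set of member gene symbols."""

    pathway_name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.pathway_name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate gene symbols in pathway {self.pathway_name!r}")


@dataclass
class GeneCaseCounts:
    """Collapsed per-gene counts on the case side.

    ``case_allele_number`` is fixed at twice the discovery cohort size; no
    per-sample missingness adjustment is applied. ``variant_list`` keeps the
    (variant, sample, alleles-counted) triples that built the counts, after
    phase collapsing, for reporting.
    """

    gene_symbol: str
    case_allele_count: int
    case_carrier_count: int
    case_allele_number: int
    variant_list: list[tuple[VariantKey, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (
            0
            <= self.case_carrier_count
            <= self.case_allele_count
            <= self.case_allele_number
        ):
            raise ValueError(
                f"inconsistent counts for {self.gene_symbol}: carriers "
                f"{self.case_carrier_count}, alleles {self.case_allele_count}, "
                f"AN {self.case_allele_number}"
            )

    @property
    def case_frequency(self) -> float:
        return self.case_allele_count / self.case_allele_number


@dataclass
class ReferenceGeneCount:
    """Qualifying reference counts for one gene.

    ``ref_allele_number`` is the maximum AN over the gene's qualifying
    variants (per-gene mode) or a configured global AN; ``combined_frequency``
    is 1 - prod(1 - AF_i) over qualifying variant frequencies, i.e. the
    probability a reference haplotype set carries at least one of them.
    """

    gene_symbol: str
    ref_allele_count: int
    ref_allele_number: int
    combined_frequency: float
    popmax_combined_frequency: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.ref_allele_count <= self.ref_allele_number:
            raise ValueError(
                f"ref counts out of range for {self.gene_symbol}: "
                f"{self.ref_allele_count}/{self.ref_allele_number}"
            )
        if not 0.0 <= self.combined_frequency < 1.0:
            raise ValueError(
                f"combined_frequency must be in [0, 1), got {self.combined_frequency}"
            )

    @property
    def ref_frequency(self) -> float:
        return self.ref_allele_count / self.ref_allele_number
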