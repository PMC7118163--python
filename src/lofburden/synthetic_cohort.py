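"""Synthetic cohort and reference-table generator with known ground truth.

The real study data is controlled-access, so every end-to-end exercise of
the pipeline runs on simulated inputs that emulate its shape: a cohort of
~500 cases carrying rare LoF alleles whose per-variant reference
frequencies follow a log-uniform distribution over [1e-6, 5e-3], a
gnomAD-style per-variant reference count table at a global allele number
of 118,190 (2 x 59,095 individuals), a minority of genes planted at a
specified fold-enrichment in the cases, pathogenic carriers of known
predisposition genes injected at ~1% of samples, and configurable
corruption of QC metrics / transcript annotations / impact classes /
popmax frequencies so every branch of the filter cascade is exercised.

Case alleles are independent per-variant Bernoulli draws per chromosome
(allele count ~ Binomial(2, fold x AF), capped at probability 1): no
linkage and no diploid dependence, exactly the independence assumption
under which the combined carrier frequency 1 - prod(1 - AF_i) is the
carrier probability.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import pysam

from .cohort_io import DEFAULT_CSQ_COLUMNS, write_metadata, write_reference_counts
from .config import DiscoveryConfig
from .gene_burden import (
    collapse_case_counts,
    combined_carrier_frequency,
    reference_counts_by_gene,
)
from .known_gene_screen import exclude_solved_cases, screen_cohort
from .types import (
    AnnotatedVariant,
    CaseObservation,
    ClinvarClass,
    FamilyHistory,
    ImpactClass,
    QCMetrics,
    ReferenceVariantRecord,
    SampleMetadata,
    VariantKey,
)
from .variant_filter import run_cascade

_LOF_CHOICES = (
    "stop_gained",
    "frameshift_variant",
    "splice_donor_variant",
    "splice_acceptor_variant",
)

DEFAULT_KNOWN_GENES = ("MSH6", "RAD51C", "RAD51D", "BRIP1")


@dataclass
class SimulationSpec:
    """Study conditions for one simulated cohort + reference pair.

    Defaults emulate the discovery setting: 500 cases against a reference
    of 59,095 individuals (AN 118,190); a gene carries Poisson(3) rare
    LoF variants with log-uniform AFs in [1e-6, 5e-3]; planted genes are
    enriched ``fold``-fold in the cases and guaranteed a combined carrier
    frequency of at least ``planted_min_combined_af`` (1e-3) so a planted
    signal is a realistic multi-carrier one; known-gene pathogenic
    carriers appear in ~1% of cases. Corruption rates default to zero;
    raise them to exercise individual filter branches.
    """

    seed: int
    n_cases: int = 500
    n_genes: int = 200
    variants_per_gene_mean: float = 3.0
    af_range: tuple[float, float] = (1e-6, 5e-3)
    global_ref_an: int = 118_190
    planted_genes: tuple[tuple[str, float], ...] = ()
    planted_min_combined_af: float = 1e-3
    known_gene_carrier_rate: float = 0.01
    known_genes: tuple[str, ...] = DEFAULT_KNOWN_GENES
    qc_fail_rate: float = 0.0
    noncanonical_rate: float = 0.0
    moderate_impact_rate: float = 0.0
    popmax_common_rate: float = 0.0
    ref_flag_rate: float = 0.0
    family_history_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for gene, fold in self.planted_genes:
            if fold < 1:
                raise ValueError(f"planted fold for {gene} must be >= 1, got {fold}")
        for name in (
            "known_gene_carrier_rate",
            "qc_fail_rate",
            "noncanonical_rate",
            "moderate_impact_rate",
            "popmax_common_rate",
            "ref_flag_rate",
            "family_history_rate",
        ):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if self.n_cases <= 0 or self.n_genes <= 0:
            raise ValueError("n_cases and n_genes must be positive")

    @property
    def gene_names(self) -> tuple[str, ...]:
        return tuple(f"G{i:04d}" for i in range(self.n_genes))

    def fold_for(self, gene: str) -> float:
        return dict(self.planted_genes).get(gene, 1.0)


@dataclass
class SimulatedVariant:
    """Internal bookkeeping for one simulated site."""

    gene: str
    key: VariantKey
    generative_af: float
    ref_ac: int
    ref_an: int
    qc_fail: bool = False
    noncanonical: bool = False
    moderate: bool = False
    popmax_common: bool = False
    ref_flagged: bool = False

    @property
    def realized_af(self) -> float:
        return self.ref_ac / self.ref_an

    @property
    def qualifies(self) -> bool:
        """Would this variant survive the case-side filter cascade?"""
        return not (
            self.noncanonical or self.moderate or self.popmax_common
        )


@dataclass
class TruthRow:
    gene: str
    fold: float
    generative_combined_af: float
    qualifying_combined_af: float
    ref_ac: int
    ref_an: int
    case_ac: int
    case_carriers: int


@dataclass
class SimulatedCohort:
    """In-memory simulation output; ``write`` emits the file dialects the
    readers consume."""

    spec: SimulationSpec
    variants: list[AnnotatedVariant]
    observations: list[CaseObservation]
    reference: list[ReferenceVariantRecord]
    metadata: list[SampleMetadata]
    truth: list[TruthRow]
    sample_ids: list[str]
    solved_samples: list[str]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(t) for t in self.truth])

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": out / "cohort.vcf",
            "reference": out / "reference_counts.tsv",
            "metadata": out / "metadata.tsv",
            "truth": out / "truth.tsv",
        }
        _write_vcf(self, paths["vcf"])
        write_reference_counts(self.reference, paths["reference"])
        write_metadata(self.metadata, paths["metadata"])
        self.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _draw_site_afs(
    rng: np.random.Generator, spec: SimulationSpec, planted: bool
) -> list[float]:
    lo, hi = spec.af_range
    n = int(rng.poisson(spec.variants_per_gene_mean))
    if planted:
        n = max(n, 1)
    afs = list(np.exp(rng.uniform(np.log(lo), np.log(hi), size=n)))
    if planted:
        # guarantee a plantable signal: pad with mid-frequency sites until
        # the combined carrier frequency clears the configured floor
        while combined_carrier_frequency(afs) < spec.planted_min_combined_af:
            afs.append(8e-4)
    return afs


def simulate_reference(
    spec: SimulationSpec,
) -> tuple[list[ReferenceVariantRecord], dict[str, list[SimulatedVariant]]]:
    """Draw the reference table and the per-gene site frequency truth.

    Reference allele counts are ``round(AF x AN)``, so the realized
    reference AF can differ from the generative AF at very rare sites
    (including dropping to zero); both are retained in the truth.
    Deterministic under the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    an = spec.global_ref_an
    records: list[ReferenceVariantRecord] = []
    sites: dict[str, list[SimulatedVariant]] = {}
    planted = {g for g, _ in spec.planted_genes}
    for gi, gene in enumerate(spec.gene_names):
        afs = _draw_site_afs(rng, spec, gene in planted)
        gene_sites: list[SimulatedVariant] = []
        for vi, af in enumerate(afs):
            ac = int(round(af * an))
            sv = SimulatedVariant(
                gene=gene,
                key=VariantKey("1", gi * 1000 + vi + 1, "A", "T"),
                generative_af=float(af),
                ref_ac=ac,
                ref_an=an,
                qc_fail=bool(rng.random() < spec.qc_fail_rate),
                noncanonical=bool(rng.random() < spec.noncanonical_rate),
                moderate=bool(rng.random() < spec.moderate_impact_rate),
                popmax_common=bool(rng.random() < spec.popmax_common_rate),
                ref_flagged=bool(rng.random() < spec.ref_flag_rate),
            )
            gene_sites.append(sv)
            records.append(
                ReferenceVariantRecord(
                    gene_symbol=gene,
                    variant_key=sv.key,
                    allele_count=ac,
                    allele_number=an,
                    allele_frequency=ac / an,
                    af_popmax_outbred=0.02 if sv.popmax_common else None,
                    filter_flags=frozenset({"RF"}) if sv.ref_flagged else frozenset(),
                )
            )
        sites[gene] = gene_sites
    return records, sites


def simulate_cohort(spec: SimulationSpec) -> SimulatedCohort:
    """Full simulation: reference table, annotated case variants,
    per-sample observations, metadata and the ground-truth table."""
    reference, sites = simulate_reference(spec)
    rng = np.random.default_rng((spec.seed, 1))
    n = spec.n_cases
    sample_ids = [f"S{i:04d}" for i in range(n)]

    variants: list[AnnotatedVariant] = []
    observations: list[CaseObservation] = []
    truth: list[TruthRow] = []

    for gene in spec.gene_names:
        fold = spec.fold_for(gene)
        gene_sites = sites[gene]
        if not gene_sites:
            truth.append(TruthRow(gene, fold, 0.0, 0.0, 0, spec.global_ref_an, 0, 0))
            continue
        probs = np.clip(
            [fold * sv.generative_af for sv in gene_sites], 0.0, 1.0
        )
        # allele count per sample/site ~ Binomial(2, fold x AF)
        geno = rng.binomial(2, probs, size=(n, len(gene_sites)))
        case_ac = 0
        carriers: set[str] = set()
        for vi, sv in enumerate(gene_sites):
            variants.append(_annotate(sv))
            carriers_idx = np.nonzero(geno[:, vi])[0]
            for si in carriers_idx:
                observations.append(
                    CaseObservation(
                        sample_id=sample_ids[si],
                        variant_key=sv.key,
                        allele_count=int(geno[si, vi]),
                    )
                )
            if sv.qualifies:
                case_ac += int(geno[:, vi].sum())
                carriers.update(sample_ids[si] for si in carriers_idx)
        qual_afs = [sv.generative_af for sv in gene_sites if sv.qualifies]
        truth.append(
            TruthRow(
                gene=gene,
                fold=fold,
                generative_combined_af=combined_carrier_frequency(
                    [sv.generative_af for sv in gene_sites]
                ),
                qualifying_combined_af=combined_carrier_frequency(qual_afs),
                ref_ac=sum(sv.ref_ac for sv in gene_sites),
                ref_an=spec.global_ref_an,
                case_ac=case_ac,
                case_carriers=len(carriers),
            )
        )

    solved: list[str] = []
    if spec.known_genes and spec.known_gene_carrier_rate > 0:
        carriers_mask = rng.random(n) < spec.known_gene_carrier_rate
        gene_pick = rng.integers(0, len(spec.known_genes), size=n)
        known_keys = {}
        for ki, kgene in enumerate(spec.known_genes):
            key = VariantKey("2", (ki + 1) * 100, "G", "C")
            known_keys[ki] = key
            variants.append(
                AnnotatedVariant(
                    variant_key=key,
                    gene_symbol=kgene,
                    transcript_id=f"TR_{kgene}",
                    biotype="protein_coding",
                    canonical=True,
                    impact_class=ImpactClass.HIGH,
                    consequence="stop_gained",
                    af_total=1e-5,
                    af_popmax_outbred=None,
                    clinvar_class=ClinvarClass.PATHOGENIC,
                    qc=_GOOD_QC,
                )
            )
        for si in np.nonzero(carriers_mask)[0]:
            observations.append(
                CaseObservation(
                    sample_id=sample_ids[si],
                    variant_key=known_keys[int(gene_pick[si])],
                    allele_count=1,
                )
            )
            solved.append(sample_ids[si])

    fh = rng.random(n) < spec.family_history_rate
    metadata = [
        SampleMetadata(
            sample_id=sid,
            histology="high_grade_serous",
            personal_cancer_history="none",
            family_history=(
                FamilyHistory.BREAST_AND_OR_OVARIAN if fh[i] else FamilyHistory.NONE_KNOWN
            ),
        )
        for i, sid in enumerate(sample_ids)
    ]
    return SimulatedCohort(
        spec=spec,
        variants=variants,
        observations=observations,
        reference=reference,
        metadata=metadata,
        truth=truth,
        sample_ids=sample_ids,
        solved_samples=sorted(set(solved)),
    )


_GOOD_QC = QCMetrics(
    quality_score=1000.0,
    read_depth=120,
    alt_allele_fraction=0.5,
    bidirectional=True,
    caller_filters_passed=True,
)
_BAD_QC = QCMetrics(
    quality_score=200.0,
    read_depth=30,
    alt_allele_fraction=0.2,
    bidirectional=False,
    caller_filters_passed=True,
)


def _annotate(sv: SimulatedVariant) -> AnnotatedVariant:
    consequence = (
        "missense_variant"
        if sv.moderate
        else _LOF_CHOICES[sv.key.pos % len(_LOF_CHOICES)]
    )
    return AnnotatedVariant(
        variant_key=sv.key,
        gene_symbol=sv.gene,
        transcript_id=f"TR_{sv.gene}",
        biotype="protein_coding",
        canonical=not sv.noncanonical,
        impact_class=ImpactClass.MODERATE if sv.moderate else ImpactClass.HIGH,
        consequence=consequence,
        af_total=sv.realized_af,
        af_popmax_outbred=0.02 if sv.popmax_common else None,
        clinvar_class=ClinvarClass.ABSENT,
        qc=_BAD_QC if sv.qc_fail else _GOOD_QC,
    )


def _write_vcf(cohort: SimulatedCohort, path: Path) -> None:
    """Emit the annotated multi-sample VCF dialect ``read_annotated_cohort``
    consumes (uncompressed text)."""
    header = pysam.VariantHeader()
    header.add_line("##source=lofburden-synthetic")
    for contig in ("1", "2"):
        header.add_line(f"##contig=<ID={contig},length=250000000>")
    fmt = "|".join(DEFAULT_CSQ_COLUMNS)
    header.add_line(
        f'##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence '
        f'annotations. Format: {fmt}">'
    )
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line(
        '##INFO=<ID=VAF,Number=1,Type=Float,Description="Alt allele read fraction">'
    )
    header.add_line(
        '##INFO=<ID=BIDIR,Number=1,Type=String,Description="Called bidirectionally">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=PG,Number=1,Type=String,Description="Phase group">')
    for sid in cohort.sample_ids:
        header.add_sample(sid)

    by_key: dict[VariantKey, list[AnnotatedVariant]] = {}
    for v in cohort.variants:
        by_key.setdefault(v.variant_key, []).append(v)
    obs_by_key: dict[VariantKey, dict[str, CaseObservation]] = {}
    for o in cohort.observations:
        obs_by_key.setdefault(o.variant_key, {})[o.sample_id] = o

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for key in sorted(by_key, key=lambda k: (k.chrom, k.pos, k.alt)):
            annos = by_key[key]
            rec = out.new_record(
                contig=key.chrom,
                start=key.pos - 1,
                alleles=(key.ref, key.alt),
            )
            rec.qual = annos[0].qc.quality_score
            rec.filter.add("PASS")
            rec.info["DP"] = annos[0].qc.read_depth
            rec.info["VAF"] = annos[0].qc.alt_allele_fraction
            rec.info["BIDIR"] = (
                "." if annos[0].qc.bidirectional is None
                else ("1" if annos[0].qc.bidirectional else "0")
            )
            rec.info["CSQ"] = tuple(_csq_entry(v) for v in annos)
            carriers = obs_by_key.get(key, {})
            for sid in cohort.sample_ids:
                o = carriers.get(sid)
                if o is None:
                    rec.samples[sid]["GT"] = (0, 0)
                else:
                    rec.samples[sid]["GT"] = (1, 1) if o.allele_count == 2 else (0, 1)
                    if o.phase_group is not None:
                        rec.samples[sid]["PG"] = o.phase_group
            out.write(rec)


def _csq_entry(v: AnnotatedVariant) -> str:
    values = {
        "Allele": v.variant_key.alt,
        "SYMBOL": v.gene_symbol,
        "Feature": v.transcript_id,
        "BIOTYPE": v.biotype,
        "CANONICAL": "YES" if v.canonical else "",
        "IMPACT": v.impact_class.value,
        "Consequence": v.consequence,
        "AF": repr(v.af_total),
        "AF_popmax": "" if v.af_popmax_outbred is None else repr(v.af_popmax_outbred),
        "CLIN_SIG": v.clinvar_class.value if v.clinvar_class.value != "absent" else "",
    }
    return "|".join(values[c] for c in DEFAULT_CSQ_COLUMNS)


@dataclass
class RecoveryReport:
    """Outcome of one simulate -> discover -> compare cycle."""

    planted: list[str]
    prioritized: list[str]
    recovered: list[str]
    sensitivity: float
    n_false_positive: int
    specificity: float
    bh_threshold: float | None
    n_discovery_samples: int
    results: list = field(default_factory=list)


def recovery_experiment(
    spec: SimulationSpec, config: DiscoveryConfig | None = None
) -> RecoveryReport:
    """Run the full discovery pipeline on one simulated pair and score
    ``prioritize`` against the planted truth."""
    from .enrichment_stats import bh_discovery_threshold, prioritize, rank_genes

    cfg = config or DiscoveryConfig()
    cohort = simulate_cohort(spec)
    findings = screen_cohort(
        cohort.variants, cohort.observations, spec.known_genes, ()
    )
    discovery = exclude_solved_cases(cohort.sample_ids, findings)
    discovery_set = set(discovery)
    kept, _, _ = run_cascade(cohort.variants, cohort.observations, cfg)
    kept = [v for v in kept if v.gene_symbol not in set(spec.known_genes)]
    obs = [o for o in cohort.observations if o.sample_id in discovery_set]
    case_counts = collapse_case_counts(kept, obs, n_samples=len(discovery))
    ref_counts = reference_counts_by_gene(cohort.reference, cfg)
    results = rank_genes(case_counts, ref_counts, cfg)
    chosen = prioritize(results, cfg)

    planted = [g for g, _ in spec.planted_genes]
    prioritized = [r.gene_symbol for r in chosen]
    recovered = [g for g in planted if g in set(prioritized)]
    n_fp = len(set(prioritized) - set(planted))
    n_true_neg_pool = spec.n_genes - len(planted)
    thresh = (
        bh_discovery_threshold([r.p_value for r in results], cfg.fdr)
        if results
        else None
    )
    return RecoveryReport(
        planted=planted,
        prioritized=prioritized,
        recovered=recovered,
        sensitivity=(len(recovered) / len(planted)) if planted else float("nan"),
        n_false_positive=n_fp,
        specificity=(
            (n_true_neg_pool - n_fp) / n_true_neg_pool if n_true_neg_pool else 1.0
        ),
        bh_threshold=thresh,
        n_discovery_samples=len(discovery),
        results=results,
    )
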