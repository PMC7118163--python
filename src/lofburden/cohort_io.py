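"""Readers and writers for the pipeline's external formats.

Formats handled: consequence-annotated multi-sample VCF 4.x (per-transcript
annotation in a pipe-delimited INFO subfield, CSQ-style), the reference
population per-variant count TSV, gene-list text files, pathway TSVs and
the sample metadata TSV. Everything is normalised into the domain types in
:mod:`lofburden.types`; nothing downstream touches a file format directly.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .types import (
    AnnotatedVariant,
    CaseObservation,
    ClinvarClass,
    FamilyHistory,
    ImpactClass,
    PathwayDefinition,
    QCMetrics,
    ReferenceVariantRecord,
    SampleMetadata,
    VariantKey,
)

#: Default pipe-separated column order of the annotation INFO subfield.
DEFAULT_CSQ_COLUMNS = (
    "Allele",
    "SYMBOL",
    "Feature",
    "BIOTYPE",
    "CANONICAL",
    "IMPACT",
    "Consequence",
    "AF",
    "AF_popmax",
    "CLIN_SIG",
)

_CLINVAR_MAP = {
    "pathogenic_multi_source": ClinvarClass.PATHOGENIC_MULTI_SOURCE,
    "pathogenic": ClinvarClass.PATHOGENIC,
    "uncertain": ClinvarClass.UNCERTAIN,
    "benign_or_likely_benign": ClinvarClass.BENIGN_OR_LIKELY_BENIGN,
    "": ClinvarClass.ABSENT,
    ".": ClinvarClass.ABSENT,
    "absent": ClinvarClass.ABSENT,
}


class AnnotationError(ValueError):
    """Raised when a VCF record lacks or mangles the annotation subfield."""


def _csq_columns_from_header(
    header: pysam.VariantHeader, annotation_field: str
) -> tuple[str, ...] | None:
    """Recover the subfield column order from the INFO description, VEP-style
    (``Description="... Format: Allele|SYMBOL|..."``)."""
    rec = header.info.get(annotation_field)
    if rec is None or not rec.description:
        return None
    m = re.search(r"Format:\s*([\w|]+)", rec.description)
    if m:
        return tuple(m.group(1).split("|"))
    return None


def _parse_fraction(token: str) -> float | None:
    if token in ("", "."):
        return None
    return float(token)


def _parse_annotation(
    token: str, columns: Sequence[str]
) -> dict[str, str]:
    fields = token.split("|")
    if len(fields) != len(columns):
        raise AnnotationError(
            f"annotation entry has {len(fields)} fields, expected {len(columns)}"
        )
    return dict(zip(columns, fields))


def read_annotated_cohort(
    vcf_source: str | Path,
    annotation_field: str = "CSQ",
    annotation_columns: Sequence[str] | None = None,
) -> tuple[list[AnnotatedVariant], list[CaseObservation]]:
    """Parse an annotated multi-sample VCF into variants and observations.

    Multi-allelic records are split into one :class:`AnnotatedVariant` per
    (alt allele, transcript annotation) pair. Each sample genotype carrying
    an alt contributes one :class:`CaseObservation` with allele_count 1
    (het) or 2 (hom alt); genotypes with missing alleles contribute none.
    Phase groups are read from the per-sample ``PG`` FORMAT field when
    present.

    Raises
    ------
    AnnotationError
        If a record lacks the named annotation subfield (the error names
        the offending chrom:pos) or an entry has the wrong arity.
    """
    path = str(vcf_source)
    variants: list[AnnotatedVariant] = []
    observations: list[CaseObservation] = []
    with pysam.VariantFile(path) as vcf:
        columns = tuple(
            annotation_columns
            or _csq_columns_from_header(vcf.header, annotation_field)
            or DEFAULT_CSQ_COLUMNS
        )
        for rec in vcf:
            if annotation_field not in rec.info:
                raise AnnotationError(
                    f"record {rec.chrom}:{rec.pos} lacks annotation field "
                    f"{annotation_field!r}"
                )
            raw = rec.info[annotation_field]
            entries = [
                _parse_annotation(tok, columns)
                for tok in (raw if isinstance(raw, tuple) else (raw,))
            ]
            filters = list(rec.filter.keys())
            qc = QCMetrics(
                quality_score=float(rec.qual if rec.qual is not None else 0.0),
                read_depth=int(rec.info.get("DP", 0)),
                alt_allele_fraction=float(rec.info.get("VAF", 0.0)),
                bidirectional=_parse_bidir(rec.info.get("BIDIR")),
                caller_filters_passed=(filters in ([], ["PASS"])),
            )
            for alt_index, alt in enumerate(rec.alts or (), start=1):
                key = VariantKey(rec.chrom, rec.pos, rec.ref, alt)
                matched = [e for e in entries if e.get("Allele", alt) == alt]
                for entry in matched:
                    variants.append(
                        AnnotatedVariant(
                            variant_key=key,
                            gene_symbol=entry["SYMBOL"],
                            transcript_id=entry["Feature"],
                            biotype=entry["BIOTYPE"],
                            canonical=entry["CANONICAL"] in ("YES", "1"),
                            impact_class=ImpactClass(entry["IMPACT"]),
                            consequence=entry["Consequence"],
                            af_total=_parse_fraction(entry.get("AF", "")) or 0.0,
                            af_popmax_outbred=_parse_fraction(
                                entry.get("AF_popmax", "")
                            ),
                            clinvar_class=_CLINVAR_MAP.get(
                                entry.get("CLIN_SIG", "").lower(),
                                ClinvarClass.ABSENT,
                            ),
                            qc=qc,
                        )
                    )
                for sample_name, sample in rec.samples.items():
                    gt = sample.get("GT")
                    if gt is None:
                        raise AnnotationError(
                            f"record {rec.chrom}:{rec.pos} sample {sample_name}: "
                            "unparsable genotype"
                        )
                    alleles = [a for a in gt if a is not None]
                    count = sum(1 for a in alleles if a == alt_index)
                    if count == 0:
                        continue
                    pg = sample.get("PG")
                    observations.append(
                        CaseObservation(
                            sample_id=sample_name,
                            variant_key=key,
                            allele_count=count,
                            phase_group=None if pg in (None, ".", "") else str(pg),
                        )
                    )
    return variants, observations


def _parse_bidir(value) -> bool | None:
    if value is None:
        return None
    return str(value) in ("1", "True", "true", "YES")


_REF_COLUMNS = [
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "allele_count",
    "allele_number",
    "allele_frequency",
    "af_popmax",
    "filter_flags",
]


def read_reference_counts(tsv_source: str | Path) -> list[ReferenceVariantRecord]:
    """Read the reference-population per-variant count table.

    Rows are keyed by (gene, variant); duplicates and allele counts
    exceeding the allele number are hard errors.
    """
    df = pd.read_csv(tsv_source, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_REF_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"reference table missing columns: {sorted(missing)}")
    records: list[ReferenceVariantRecord] = []
    seen: set[tuple[str, VariantKey]] = set()
    for row in df.itertuples(index=False):
        key = VariantKey(row.chrom, int(row.pos), row.ref, row.alt)
        ident = (row.gene, key)
        if ident in seen:
            raise ValueError(f"duplicate reference row for {row.gene} {key}")
        seen.add(ident)
        records.append(
            ReferenceVariantRecord(
                gene_symbol=row.gene,
                variant_key=key,
                allele_count=int(row.allele_count),
                allele_number=int(row.allele_number),
                allele_frequency=float(row.allele_frequency),
                af_popmax_outbred=(
                    None if row.af_popmax in ("", ".") else float(row.af_popmax)
                ),
                filter_flags=frozenset(
                    f for f in row.filter_flags.split(",") if f and f != "."
                ),
            )
        )
    return records


def write_reference_counts(
    records: Iterable[ReferenceVariantRecord], path: str | Path
) -> None:
    rows = [
        {
            "gene": r.gene_symbol,
            "chrom": r.variant_key.chrom,
            "pos": r.variant_key.pos,
            "ref": r.variant_key.ref,
            "alt": r.variant_key.alt,
            "allele_count": r.allele_count,
            "allele_number": r.allele_number,
            "allele_frequency": repr(r.allele_frequency),
            "af_popmax": (
                "" if r.af_popmax_outbred is None else repr(r.af_popmax_outbred)
            ),
            "filter_flags": ",".join(sorted(r.filter_flags)),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_REF_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> tuple[str, ...]:
    """One gene symbol per line; blank lines and ``#`` comments ignored."""
    symbols: list[str] = []
    for line in Path(path).read_text().splitlines():
        token = line.strip()
        if token and not token.startswith("#"):
            symbols.append(token)
    return tuple(symbols)


def read_gene_lists(paths: Mapping[str, str | Path]) -> dict[str, frozenset[str]]:
    """Map list-name -> gene set for a collection of gene-list files."""
    return {name: frozenset(read_gene_list(p)) for name, p in paths.items()}


def read_pathways(path: str | Path) -> list[PathwayDefinition]:
    """Two-column TSV (``pathway<TAB>gene``); rows grouped in file order."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"pathway", "gene"} <= set(df.columns):
        raise ValueError("pathway table needs columns: pathway, gene")
    defs: list[PathwayDefinition] = []
    for name, group in df.groupby("pathway", sort=False):
        defs.append(PathwayDefinition(name, tuple(group["gene"])))
    return defs


def read_metadata(tsv_source: str | Path) -> list[SampleMetadata]:
    """Sample metadata TSV; duplicate sample ids are a hard error.

    Unknown histology / history labels are preserved verbatim; only the
    family-history column is coerced to its two-level factor.
    """
    df = pd.read_csv(tsv_source, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "histology", "personal_cancer_history", "family_history"}
    if not required <= set(df.columns):
        raise ValueError(f"metadata table needs columns: {sorted(required)}")
    dupes = df["sample_id"][df["sample_id"].duplicated()]
    if not dupes.empty:
        raise ValueError(f"duplicate sample ids: {sorted(set(dupes))}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SampleMetadata(
                sample_id=row.sample_id,
                histology=row.histology,
                personal_cancer_history=row.personal_cancer_history,
                family_history=FamilyHistory(row.family_history),
                family_history_detail=getattr(row, "family_history_detail", ""),
            )
        )
    return out


def write_metadata(samples: Iterable[SampleMetadata], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "histology": s.histology,
            "personal_cancer_history": s.personal_cancer_history,
            "family_history": s.family_history.value,
            "family_history_detail": s.family_history_detail,
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
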