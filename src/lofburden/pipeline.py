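"""Single-command pipeline driver: screen -> filter -> burden -> ranking ->
prioritisation -> pathway burden, with plain-text TSV intermediates so
every stage is independently runnable and diffable, plus a run manifest.

Each stage function reads the previous stage's TSV outputs and writes its
own; :func:`run_discovery` simply composes them over one output directory,
so a stage-wise run reproduces the single-command run exactly.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from . import __version__
from .cohort_io import (
    read_annotated_cohort,
    read_gene_list,
    read_metadata,
    read_pathways,
    read_reference_counts,
)
from .config import DiscoveryConfig
from .enrichment_stats import (
    bh_discovery_threshold,
    carrier_histogram,
    family_history_test,
    global_burden_test,
    or_direction_test,
    prioritize,
    rank_genes,
    waterfall_data,
)
from .gene_burden import collapse_case_counts, reference_counts_by_gene
from .known_gene_screen import (
    exclude_solved_cases,
    proposed_gene_table,
    screen_cohort,
)
from .pathway_burden import pathway_burden
from .types import (
    AnnotatedVariant,
    CaseObservation,
    ClinvarClass,
    FamilyHistory,
    ImpactClass,
    QCMetrics,
    VariantKey,
)
from .variant_filter import run_cascade


def packaged_data(name: str) -> Path:
    """Path to a gene-list / pathway file shipped with the package."""
    return Path(resources.files("lofburden.data") / name)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# ---------------------------------------------------------------- serde

_VARIANT_COLS = [
    "chrom", "pos", "ref", "alt", "gene", "transcript", "biotype",
    "canonical", "impact", "consequence", "af_total", "af_popmax",
    "clinvar", "quality_score", "read_depth", "alt_fraction",
    "bidirectional", "caller_pass",
]


def write_variants_tsv(variants: Iterable[AnnotatedVariant], path: Path) -> None:
    rows = []
    for v in variants:
        rows.append({
            "chrom": v.variant_key.chrom,
            "pos": v.variant_key.pos,
            "ref": v.variant_key.ref,
            "alt": v.variant_key.alt,
            "gene": v.gene_symbol,
            "transcript": v.transcript_id,
            "biotype": v.biotype,
            "canonical": int(v.canonical),
            "impact": v.impact_class.value,
            "consequence": v.consequence,
            "af_total": repr(v.af_total),
            "af_popmax": "" if v.af_popmax_outbred is None else repr(v.af_popmax_outbred),
            "clinvar": v.clinvar_class.value,
            "quality_score": v.qc.quality_score,
            "read_depth": v.qc.read_depth,
            "alt_fraction": v.qc.alt_allele_fraction,
            "bidirectional": "" if v.qc.bidirectional is None else int(v.qc.bidirectional),
            "caller_pass": int(v.qc.caller_filters_passed),
        })
    pd.DataFrame(rows, columns=_VARIANT_COLS).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path: Path) -> list[AnnotatedVariant]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for r in df.itertuples(index=False):
        out.append(AnnotatedVariant(
            variant_key=VariantKey(r.chrom, int(r.pos), r.ref, r.alt),
            gene_symbol=r.gene,
            transcript_id=r.transcript,
            biotype=r.biotype,
            canonical=bool(int(r.canonical)),
            impact_class=ImpactClass(r.impact),
            consequence=r.consequence,
            af_total=float(r.af_total),
            af_popmax_outbred=None if r.af_popmax == "" else float(r.af_popmax),
            clinvar_class=ClinvarClass(r.clinvar),
            qc=QCMetrics(
                quality_score=float(r.quality_score),
                read_depth=int(float(r.read_depth)),
                alt_allele_fraction=float(r.alt_fraction),
                bidirectional=None if r.bidirectional == "" else bool(int(r.bidirectional)),
                caller_filters_passed=bool(int(r.caller_pass)),
            ),
        ))
    return out


def write_observations_tsv(obs: Iterable[CaseObservation], path: Path) -> None:
    rows = [{
        "sample_id": o.sample_id,
        "chrom": o.variant_key.chrom,
        "pos": o.variant_key.pos,
        "ref": o.variant_key.ref,
        "alt": o.variant_key.alt,
        "allele_count": o.allele_count,
        "phase_group": o.phase_group or "",
    } for o in obs]
    cols = ["sample_id", "chrom", "pos", "ref", "alt", "allele_count", "phase_group"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_observations_tsv(path: Path) -> list[CaseObservation]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        CaseObservation(
            sample_id=r.sample_id,
            variant_key=VariantKey(r.chrom, int(r.pos), r.ref, r.alt),
            allele_count=int(r.allele_count),
            phase_group=r.phase_group or None,
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------- stages

def stage_screen(
    vcf: Path,
    known_genes_path: Path,
    proposed_genes_path: Path,
    out_dir: Path,
    config: DiscoveryConfig,
) -> dict[str, Path]:
    """Known/proposed-gene screen; writes the findings table and the
    retained discovery sample list."""
    out_dir.mkdir(parents=True, exist_ok=True)
    variants, observations = read_annotated_cohort(vcf, config.annotation_field)
    known = read_gene_list(known_genes_path)
    proposed = read_gene_list(proposed_genes_path)
    findings = screen_cohort(variants, observations, known, proposed)
    all_samples = _vcf_samples(vcf)
    discovery = exclude_solved_cases(all_samples, findings)

    findings_path = out_dir / "screen_findings.tsv"
    pd.DataFrame([{
        "sample_id": f.sample_id,
        "gene": f.gene_symbol,
        "variant": str(f.variant_key),
        "consequence": f.consequence,
        "classification": f.classification.value,
        "tier": f.gene_tier.value,
    } for f in findings], columns=[
        "sample_id", "gene", "variant", "consequence", "classification", "tier",
    ]).to_csv(findings_path, sep="\t", index=False)
    samples_path = out_dir / "discovery_samples.txt"
    samples_path.write_text("".join(s + "\n" for s in discovery))
    return {"findings": findings_path, "discovery_samples": samples_path}


def stage_filter(vcf: Path, out_dir: Path, config: DiscoveryConfig) -> dict[str, Path]:
    """Filter cascade; writes kept variants, observations of kept variants
    and the per-stage summary."""
    out_dir.mkdir(parents=True, exist_ok=True)
    variants, observations = read_annotated_cohort(vcf, config.annotation_field)
    kept, summary, decisions = run_cascade(variants, observations, config)
    kept_keys = {v.variant_key for v in kept}

    paths = {
        "kept_variants": out_dir / "kept_variants.tsv",
        "observations": out_dir / "observations.tsv",
        "filter_summary": out_dir / "filter_summary.tsv",
        "filter_decisions": out_dir / "filter_decisions.tsv",
    }
    write_variants_tsv(kept, paths["kept_variants"])
    write_observations_tsv(
        [o for o in observations if o.variant_key in kept_keys],
        paths["observations"],
    )
    pd.DataFrame(summary.as_rows()).to_csv(paths["filter_summary"], sep="\t", index=False)
    pd.DataFrame([{
        "variant": str(d.variant_key),
        "transcript": d.transcript_id,
        "kept": int(d.kept),
        "stage_failed": d.stage_failed.value,
        "qc_flagged": int(d.qc_flagged_for_review),
    } for d in decisions], columns=[
        "variant", "transcript", "kept", "stage_failed", "qc_flagged",
    ]).to_csv(paths["filter_decisions"], sep="\t", index=False)
    return paths


def stage_rank(
    kept_variants: Path,
    observations: Path,
    discovery_samples: Path,
    reference: Path,
    known_genes_path: Path,
    out_dir: Path,
    config: DiscoveryConfig,
) -> dict[str, Path]:
    """Collapse, Fisher-test, rank and prioritise; writes the burden table,
    ranked results, candidate list, waterfall and carrier-histogram data."""
    out_dir.mkdir(parents=True, exist_ok=True)
    variants = read_variants_tsv(kept_variants)
    known = set(read_gene_list(known_genes_path))
    variants = [v for v in variants if v.gene_symbol not in known]
    obs = read_observations_tsv(observations)
    discovery = [s for s in discovery_samples.read_text().split() if s]
    discovery_set = set(discovery)
    obs = [o for o in obs if o.sample_id in discovery_set]

    case_counts = collapse_case_counts(variants, obs, n_samples=len(discovery))
    ref_records = read_reference_counts(reference)
    ref_counts = reference_counts_by_gene(ref_records, config)
    results = rank_genes(case_counts, ref_counts, config)
    candidates = prioritize(results, config)

    paths = {
        "burden": out_dir / "gene_burden.tsv",
        "results": out_dir / "ranked_genes.tsv",
        "candidates": out_dir / "candidate_genes.tsv",
        "waterfall": out_dir / "waterfall.tsv",
        "carrier_histogram": out_dir / "carrier_histogram.tsv",
        "cohort_tests": out_dir / "cohort_tests.json",
    }
    pd.DataFrame([{
        "gene": gc.gene_symbol,
        "case_ac": gc.case_allele_count,
        "case_carriers": gc.case_carrier_count,
        "case_an": gc.case_allele_number,
        "ref_ac": ref_counts[gc.gene_symbol].ref_allele_count if gc.gene_symbol in ref_counts else 0,
        "ref_an": ref_counts[gc.gene_symbol].ref_allele_number if gc.gene_symbol in ref_counts else config.global_ref_an,
        "case_freq": repr(gc.case_frequency),
        "ref_combined_freq": repr(ref_counts[gc.gene_symbol].combined_frequency) if gc.gene_symbol in ref_counts else "0.0",
    } for gc in case_counts], columns=[
        "gene", "case_ac", "case_carriers", "case_an", "ref_ac", "ref_an",
        "case_freq", "ref_combined_freq",
    ]).to_csv(paths["burden"], sep="\t", index=False)

    pd.DataFrame([_result_row(r) for r in results], columns=_RESULT_COLS).to_csv(
        paths["results"], sep="\t", index=False
    )
    pd.DataFrame([_result_row(r) for r in candidates], columns=_RESULT_COLS).to_csv(
        paths["candidates"], sep="\t", index=False
    )
    pd.DataFrame(waterfall_data(results), columns=["gene", "signed_log10_p"]).to_csv(
        paths["waterfall"], sep="\t", index=False
    )
    hist = carrier_histogram(results)
    pd.DataFrame(
        [{"carriers": k, "n_genes": v} for k, v in hist.items()],
        columns=["carriers", "n_genes"],
    ).to_csv(paths["carrier_histogram"], sep="\t", index=False)

    total_case_ac = sum(gc.case_allele_count for gc in case_counts)
    total_ref_ac = sum(rc.ref_allele_count for rc in ref_counts.values())
    case_an = 2 * len(discovery)
    n_genes_ref = len(ref_counts)
    enriched = sum(
        1 for r in results
        if (r.odds_ratio or 0) > 1 and r.p_value < config.p_report_cut
    )
    depleted = sum(
        1 for r in results
        if r.odds_ratio is not None and r.odds_ratio < 1 and r.p_value < config.p_report_cut
    )
    tests = {
        "global_burden_p": global_burden_test(
            total_case_ac,
            case_an * max(n_genes_ref, 1),
            total_ref_ac,
            sum(rc.ref_allele_number for rc in ref_counts.values()) or config.global_ref_an,
        ),
        "n_genes_enriched_at_cut": enriched,
        "n_genes_depleted_at_cut": depleted,
        "or_direction_p": (
            or_direction_test(enriched, depleted) if enriched + depleted else None
        ),
        "bh_threshold": bh_discovery_threshold(
            [r.p_value for r in results], config.fdr
        ) if results else None,
        "n_genes_tested": len(results),
        "n_candidates": len(candidates),
    }
    paths["cohort_tests"].write_text(json.dumps(tests, indent=2))
    return paths


_RESULT_COLS = [
    "gene", "rank", "case_ac", "case_an", "ref_ac", "ref_an", "case_freq",
    "ref_combined_freq", "odds_ratio", "ci95_low", "ci95_high", "p_value",
    "risk_ratio", "case_carriers", "passes_discovery_threshold",
    "passes_fold", "passes_min_carriers",
]


def _result_row(r) -> dict:
    a, b, c, d = r.contingency
    return {
        "gene": r.gene_symbol,
        "rank": r.rank,
        "case_ac": a,
        "case_an": a + b,
        "ref_ac": c,
        "ref_an": c + d,
        "case_freq": repr(r.case_frequency),
        "ref_combined_freq": repr(r.ref_combined_frequency),
        "odds_ratio": "" if r.odds_ratio is None else repr(r.odds_ratio),
        "ci95_low": "" if r.ci95 is None else repr(r.ci95[0]),
        "ci95_high": "" if r.ci95 is None else repr(r.ci95[1]),
        "p_value": repr(r.p_value),
        "risk_ratio": "" if r.risk_ratio is None else repr(r.risk_ratio),
        "case_carriers": r.case_carrier_count,
        "passes_discovery_threshold": int(r.passes_discovery_threshold),
        "passes_fold": int(r.passes_fold),
        "passes_min_carriers": int(r.passes_min_carriers),
    }


def stage_pathways(
    burden: Path,
    reference: Path,
    pathways_path: Path,
    known_genes_path: Path,
    out_dir: Path,
    config: DiscoveryConfig,
) -> dict[str, Path]:
    """Pathway-grouped burden on the collapsed gene counts."""
    out_dir.mkdir(parents=True, exist_ok=True)
    from .types import GeneCaseCounts

    df = pd.read_csv(burden, sep="\t", dtype=str, keep_default_na=False)
    case_counts = [
        GeneCaseCounts(
            gene_symbol=r.gene,
            case_allele_count=int(r.case_ac),
            case_carrier_count=int(r.case_carriers),
            case_allele_number=int(r.case_an),
        )
        for r in df.itertuples(index=False)
    ]
    case_an = case_counts[0].case_allele_number if case_counts else 2
    ref_counts = reference_counts_by_gene(read_reference_counts(reference), config)
    rows = pathway_burden(
        case_counts,
        ref_counts,
        read_pathways(pathways_path),
        excluded_genes=read_gene_list(known_genes_path),
        case_an_per_gene=case_an,
        config=config,
    )
    path = out_dir / "pathway_burden.tsv"
    pd.DataFrame([{
        "pathway": r.pathway_name,
        "gene_count": r.gene_count,
        "case_ac": r.case_ac,
        "case_an": r.case_an,
        "ref_ac": r.ref_ac,
        "ref_an": r.ref_an,
        "case_freq": repr(r.case_freq),
        "ref_freq": repr(r.ref_freq),
        "odds_ratio": "" if r.odds_ratio is None else repr(r.odds_ratio),
        "p_value": repr(r.p_value),
    } for r in rows]).to_csv(path, sep="\t", index=False)
    return {"pathway_burden": path}


def _vcf_samples(vcf: Path) -> list[str]:
    import pysam

    with pysam.VariantFile(str(vcf)) as f:
        return list(f.header.samples)


# ----------------------------------------------------------- run_discovery

def run_discovery(
    config: DiscoveryConfig,
    vcf: str | Path,
    reference: str | Path,
    out_dir: str | Path,
    known_genes: str | Path | None = None,
    proposed_genes: str | Path | None = None,
    pathways: str | Path | None = None,
    metadata: str | Path | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Execute the full cascade and write every declared output.

    Returns a mapping of output name to path; also writes ``manifest.json``
    listing a digest for every output file, the config snapshot, input
    digests, stage counts and versions. Any stage failure is re-raised as
    :class:`StageError` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vcf = Path(vcf)
    reference = Path(reference)
    known_genes = Path(known_genes) if known_genes else packaged_data("known_genes.txt")
    proposed_genes = (
        Path(proposed_genes) if proposed_genes else packaged_data("proposed_genes.txt")
    )
    pathways = Path(pathways) if pathways else packaged_data("pathways.tsv")

    outputs: dict[str, Path] = {}
    stage = "screen"
    try:
        outputs.update(stage_screen(vcf, known_genes, proposed_genes, out, config))
        stage = "filter"
        outputs.update(stage_filter(vcf, out, config))
        stage = "rank"
        outputs.update(stage_rank(
            outputs["kept_variants"], outputs["observations"],
            outputs["discovery_samples"], reference, known_genes, out, config,
        ))
        stage = "proposed_gene_table"
        outputs["proposed_genes_table"] = _write_proposed_table(
            vcf, reference, known_genes, proposed_genes, out, config
        )
        stage = "pathways"
        outputs.update(stage_pathways(
            outputs["burden"], reference, pathways, known_genes, out, config,
        ))
        stage = "family_history"
        if metadata is not None:
            outputs["family_history"] = _write_family_history(
                Path(metadata), outputs["candidates"], outputs["observations"],
                outputs["kept_variants"], outputs["discovery_samples"], out,
            )
    except Exception as exc:  # noqa: BLE001 - abort names the stage
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": config.to_dict(),
        "inputs": {
            str(p): _digest(p)
            for p in [vcf, reference, known_genes, proposed_genes, pathways]
            + ([Path(metadata)] if metadata else [])
        },
        "outputs": {name: _digest(p) for name, p in outputs.items()},
        "stage_counts": pd.read_csv(outputs["filter_summary"], sep="\t")
        .to_dict(orient="records"),
        "versions": {"lofburden": __version__, "pandas": pd.__version__},
        "seed": seed,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    outputs["manifest"] = manifest_path
    return outputs


def _write_proposed_table(
    vcf: Path, reference: Path, known_genes: Path, proposed_genes: Path,
    out: Path, config: DiscoveryConfig,
) -> Path:
    variants, observations = read_annotated_cohort(vcf, config.annotation_field)
    known = read_gene_list(known_genes)
    proposed = read_gene_list(proposed_genes)
    findings = screen_cohort(variants, observations, known, proposed)
    discovery = exclude_solved_cases(_vcf_samples(vcf), findings)
    ref_counts = reference_counts_by_gene(read_reference_counts(reference), config)
    ref_ac_an = {
        g: (rc.ref_allele_count, rc.ref_allele_number) for g, rc in ref_counts.items()
    }
    rows = proposed_gene_table(
        variants, observations, discovery, known, proposed, ref_ac_an
    )
    path = out / "proposed_genes_table.tsv"
    pd.DataFrame([{
        "gene": r["gene"],
        "case_alleles_reported": r["case_alleles_reported"],
        "case_alleles_tested": r["case_alleles_tested"],
        "case_carriers": r["case_carriers"],
        "case_an": r["case_an"],
        "ref_ac": r["ref_ac"],
        "ref_an": r["ref_an"],
        "odds_ratio": "" if r["odds_ratio"] is None else repr(r["odds_ratio"]),
        "p_value": repr(r["p_value"]),
    } for r in rows], columns=[
        "gene", "case_alleles_reported", "case_alleles_tested", "case_carriers",
        "case_an", "ref_ac", "ref_an", "odds_ratio", "p_value",
    ]).to_csv(path, sep="\t", index=False)
    return path


def _write_family_history(
    metadata: Path, candidates: Path, observations: Path, kept_variants: Path,
    discovery_samples: Path, out: Path,
) -> Path:
    meta = read_metadata(metadata)
    cand = pd.read_csv(candidates, sep="\t", dtype=str, keep_default_na=False)
    cand_genes = set(cand["gene"]) if not cand.empty else set()
    variants = read_variants_tsv(kept_variants)
    keys_in_cand = {
        v.variant_key for v in variants if v.gene_symbol in cand_genes
    }
    obs = read_observations_tsv(observations)
    carriers = {o.sample_id for o in obs if o.variant_key in keys_in_cand}
    discovery = [s for s in discovery_samples.read_text().split() if s]
    meta_by_id = {m.sample_id: m for m in meta}
    flags = [(s in carriers,
              meta_by_id[s].family_history is FamilyHistory.BREAST_AND_OR_OVARIAN)
             for s in discovery if s in meta_by_id]
    path = out / "family_history_test.json"
    if not flags or not any(c for c, _ in flags):
        path.write_text(json.dumps({"odds_ratio": None, "p_value": None,
                                    "n_carriers": 0, "n_samples": len(flags)}))
        return path
    orr, p = family_history_test([c for c, _ in flags], [f for _, f in flags])
    path.write_text(json.dumps({
        "odds_ratio": orr if orr is None or orr != float("inf") else "inf",
        "p_value": p,
        "n_carriers": sum(c for c, _ in flags),
        "n_samples": len(flags),
    }, indent=2))
    return path


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
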