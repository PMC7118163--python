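"""Per-gene enrichment testing, ranking, discovery thresholding and
prioritisation, plus the cohort-level pooled tests.

Each gene is a 2x2 allele table: (case qualifying alleles, remaining case
alleles) vs (reference qualifying alleles, remaining reference alleles).
The two-sided Fisher's exact p-value ranks genes; the reported odds ratio
is the sample (cross-product) estimate ad/bc, not the conditional MLE —
the two differ noticeably for sparse tables and published gene-level ORs
follow the cross-product convention. The confidence interval is the exact
conditional 95% interval. Two-sidedness is the sum of hypergeometric table
probabilities not exceeding that of the observed table (the R convention);
a doubling rule is available via ``two_sided_rule``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.stats.contingency import odds_ratio as _conditional_or

from .config import DiscoveryConfig, FoldCheckMode
from .types import GeneCaseCounts, ReferenceGeneCount


@dataclass
class GeneBurdenResult:
    """One gene's burden comparison between cases and the reference."""

    gene_symbol: str
    contingency: tuple[int, int, int, int]  # a, b, c, d
    odds_ratio: float | None
    ci95: tuple[float, float] | None
    p_value: float
    risk_ratio: float | None
    case_carrier_count: int
    case_frequency: float
    ref_combined_frequency: float
    popmax_combined_frequency: float | None = None
    rank: int = 0
    passes_discovery_threshold: bool = False
    passes_fold: bool = False
    passes_min_carriers: bool = False
    variant_list: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")


def gene_fisher(
    a: int,
    case_an: int,
    c: int,
    ref_an: int,
    compute_ci: bool = True,
    two_sided_rule: str = "minlike",
) -> tuple[float | None, tuple[float, float] | None, float]:
    """Two-sided Fisher's exact test on one gene's 2x2 allele table.

    Parameters are the qualifying allele count and total allele number on
    each side. Returns ``(odds_ratio, ci95, p_value)`` where the odds
    ratio is the sample cross-product estimate: ``inf`` when bc == 0 with
    ad > 0, ``None`` (undefined, p = 1) for the empty a = c = 0 table.
    ``two_sided_rule``: "minlike" sums hypergeometric probabilities <=
    observed; "double" doubles the smaller one-sided tail (capped at 1).
    """
    if min(a, c) < 0 or a > case_an or c > ref_an:
        raise ValueError(f"invalid counts: a={a}/{case_an}, c={c}/{ref_an}")
    b, d = case_an - a, ref_an - c
    table = [[a, b], [c, d]]

    if a == 0 and c == 0:
        return None, None, 1.0
    if b * c == 0:
        orr: float | None = math.inf if a * d > 0 else 0.0
        if a * d == 0 and b * c == 0:  # degenerate margins
            orr = None
    else:
        orr = (a * d) / (b * c)

    if two_sided_rule == "minlike":
        _, p = stats.fisher_exact(table, alternative="two-sided")
    elif two_sided_rule == "double":
        _, p_less = stats.fisher_exact(table, alternative="less")
        _, p_greater = stats.fisher_exact(table, alternative="greater")
        p = min(1.0, 2.0 * min(p_less, p_greater))
    else:
        raise ValueError(f"unknown two_sided_rule: {two_sided_rule!r}")
    p = float(min(1.0, p))

    ci: tuple[float, float] | None = None
    if compute_ci:
        res = _conditional_or(table, kind="conditional")
        interval = res.confidence_interval(confidence_level=0.95)
        ci = (float(interval.low), float(interval.high))
    return orr, ci, p


def risk_ratio(case_freq: float, ref_combined_freq: float) -> float:
    """Ratio of the case carrier frequency to the reference combined
    carrier frequency; 0 when cases carry nothing, +inf when only the
    reference frequency is zero."""
    if case_freq < 0 or ref_combined_freq < 0:
        raise ValueError("frequencies must be non-negative")
    if case_freq == 0:
        return 0.0
    if ref_combined_freq == 0:
        return math.inf
    return case_freq / ref_combined_freq


def global_burden_test(
    total_case_ac: int, case_an_total: int, total_ref_ac: int, ref_an_total: int
) -> float:
    """Pooled chi-squared test (1 df, no continuity correction) on the
    all-genes 2x2 allele table."""
    table = np.array(
        [
            [total_case_ac, case_an_total - total_case_ac],
            [total_ref_ac, ref_an_total - total_ref_ac],
        ]
    )
    if table.min() < 0:
        raise ValueError("negative cell in pooled table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p) if stat > 0 else 1.0


def or_direction_test(n_enriched: int, n_depleted: int) -> float:
    """Chi-squared goodness of fit of the (OR > 1, OR < 1) gene counts at
    the reporting p cut against an equal split."""
    if n_enriched < 0 or n_depleted < 0:
        raise ValueError("counts must be non-negative")
    total = n_enriched + n_depleted
    if total == 0:
        raise ValueError("empty test: no genes in either direction")
    stat, p = stats.chisquare([n_enriched, n_depleted])
    return float(p) if stat > 0 else 1.0


def bh_discovery_threshold(
    p_values: Sequence[float], fdr: float
) -> float | None:
    """Benjamini-Hochberg discovery threshold.

    Sort the m p-values ascending and find the largest k (1-based) with
    ``p_(k) <= (k / m) * fdr``; the threshold is that p_(k), or ``None``
    when no k qualifies.
    """
    if len(p_values) == 0:
        raise ValueError("p_values must be non-empty")
    ps = np.asarray(p_values, dtype=float)
    if ps.min() < 0 or ps.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    order = np.sort(ps)
    m = len(order)
    k = np.arange(1, m + 1)
    qualifying = np.nonzero(order <= k / m * fdr)[0]
    if qualifying.size == 0:
        return None
    return float(order[qualifying[-1]])


def rank_genes(
    case_counts: Sequence[GeneCaseCounts],
    ref_counts: Mapping[str, ReferenceGeneCount],
    config: DiscoveryConfig | None = None,
    compute_ci: bool = False,
) -> list[GeneBurdenResult]:
    """Fisher-test every gene with retained case variants and rank.

    Genes absent from the reference table get a zero qualifying reference
    count at the configured global AN. Ordering: ascending p, ties broken
    by descending odds ratio then gene symbol; ``rank`` is 1-based.
    """
    cfg = config or DiscoveryConfig()
    results: list[GeneBurdenResult] = []
    for gc in case_counts:
        ref = ref_counts.get(gc.gene_symbol)
        if ref is None:
            ref = ReferenceGeneCount(
                gene_symbol=gc.gene_symbol,
                ref_allele_count=0,
                ref_allele_number=cfg.global_ref_an,
                combined_frequency=0.0,
            )
        a = gc.case_allele_count
        c = ref.ref_allele_count
        orr, ci, p = gene_fisher(
            a, gc.case_allele_number, c, ref.ref_allele_number, compute_ci=compute_ci
        )
        results.append(
            GeneBurdenResult(
                gene_symbol=gc.gene_symbol,
                contingency=(
                    a,
                    gc.case_allele_number - a,
                    c,
                    ref.ref_allele_number - c,
                ),
                odds_ratio=orr,
                ci95=ci,
                p_value=p,
                risk_ratio=risk_ratio(gc.case_frequency, ref.combined_frequency),
                case_carrier_count=gc.case_carrier_count,
                case_frequency=gc.case_frequency,
                ref_combined_frequency=ref.combined_frequency,
                popmax_combined_frequency=ref.popmax_combined_frequency,
                variant_list=list(gc.variant_list),
            )
        )
    results.sort(key=_rank_key)
    threshold = bh_discovery_threshold([r.p_value for r in results], cfg.fdr) if results else None
    for i, r in enumerate(results, start=1):
        r.rank = i
        r.passes_discovery_threshold = threshold is not None and r.p_value <= threshold
        r.passes_min_carriers = r.case_carrier_count >= cfg.min_carriers
        r.passes_fold = _passes_fold(r, cfg)
    return results


def _rank_key(r: GeneBurdenResult):
    orr = r.odds_ratio if r.odds_ratio is not None else -math.inf
    return (r.p_value, -orr, r.gene_symbol)


def _passes_fold(r: GeneBurdenResult, cfg: DiscoveryConfig) -> bool:
    if r.risk_ratio is None or r.risk_ratio < cfg.fold_threshold:
        return False
    if cfg.fold_check_mode is FoldCheckMode.ALL_OUTBRED:
        # no major outbred sub-population may come within `fold` of the
        # case frequency; missing popmax means absent everywhere outbred
        if (
            r.popmax_combined_frequency is not None
            and r.popmax_combined_frequency > r.case_frequency / cfg.fold_threshold
        ):
            return False
    return True


def prioritize(
    results: Iterable[GeneBurdenResult], config: DiscoveryConfig | None = None
) -> list[GeneBurdenResult]:
    """Candidate genes: >= min_carriers case carriers, p at or below the
    BH discovery threshold, and fold-enrichment satisfied; ordered by
    ascending p (ties: descending OR, then symbol)."""
    cfg = config or DiscoveryConfig()
    chosen = [
        r
        for r in results
        if r.passes_min_carriers and r.passes_discovery_threshold and r.passes_fold
    ]
    chosen.sort(key=_rank_key)
    return chosen


def carrier_histogram(
    results: Iterable[GeneBurdenResult], only_fold_enriched: bool = True
) -> dict[int, int]:
    """Map carrier count -> number of genes, by default among the
    fold-enriched genes (the published histogram's population)."""
    hist: dict[int, int] = {}
    for r in results:
        if only_fold_enriched and not r.passes_fold:
            continue
        hist[r.case_carrier_count] = hist.get(r.case_carrier_count, 0) + 1
    return dict(sorted(hist.items()))


def family_history_test(
    carrier_flags: Sequence[bool], family_history_flags: Sequence[bool]
) -> tuple[float | None, float]:
    """Fisher's exact test of candidate-gene carriage against family
    history, on the sample-level 2x2 table."""
    if len(carrier_flags) != len(family_history_flags):
        raise ValueError("flag vectors must align")
    carrier = np.asarray(carrier_flags, dtype=bool)
    fh = np.asarray(family_history_flags, dtype=bool)
    a = int(np.sum(carrier & fh))
    b = int(np.sum(~carrier & fh))
    c = int(np.sum(carrier & ~fh))
    d = int(np.sum(~carrier & ~fh))
    if (a + c) == 0 and (b + d) == 0:
        raise ValueError("empty table")
    orr = (a * d) / (b * c) if b * c > 0 else (math.inf if a * d > 0 else None)
    _, p = stats.fisher_exact([[a, b], [c, d]])
    return orr, float(p)


def waterfall_data(
    results: Iterable[GeneBurdenResult],
) -> list[tuple[str, float]]:
    """Per-gene signed -log10 p for the waterfall chart: positive when the
    odds ratio exceeds 1, ordered by decreasing signed value."""
    rows = []
    for r in results:
        mag = -math.log10(r.p_value) if r.p_value > 0 else math.inf
        sign = 1.0 if (r.odds_ratio or 0) > 1 else -1.0
        rows.append((r.gene_symbol, sign * mag))
    rows.sort(key=lambda t: (-t[1], t[0]))
    return rows
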