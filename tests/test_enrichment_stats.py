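"""Gene-level Fisher testing, ranking, BH thresholding, prioritisation and
cohort-level tests, checked against independent brute-force oracles."""

from __future__ import annotations

import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lofburden.config import DiscoveryConfig, FoldCheckMode
from lofburden.enrichment_stats import (
    bh_discovery_threshold,
    carrier_histogram,
    family_history_test,
    gene_fisher,
    global_burden_test,
    or_direction_test,
    prioritize,
    rank_genes,
    risk_ratio,
    waterfall_data,
)
from lofburden.gene_burden import combined_carrier_frequency
from lofburden.types import GeneCaseCounts, ReferenceGeneCount


def brute_force_fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by explicit hypergeometric enumeration."""
    r1, r2, n1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, n1 - r2), min(r1, n1)
    denom = comb(n, n1)
    probs = {k: comb(r1, k) * comb(r2, n1 - k) / denom for k in range(lo, hi + 1)}
    observed = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= observed * (1 + 1e-10)))


def brute_force_bh(ps: list[float], fdr: float) -> float | None:
    best = None
    m = len(ps)
    for k, p in enumerate(sorted(ps), start=1):
        if p <= k / m * fdr:
            best = p
    return best


class TestGeneFisher:
    def test_proposed_gene_worked_examples(self):
        orr, _, p = gene_fisher(5, 1020, 195, 118190)
        assert round(orr, 2) == 2.98
        assert float(f"{p:.2g}") == 0.030
        orr, _, p = gene_fisher(3, 1020, 57, 118190)
        assert round(orr, 2) == 6.11
        assert float(f"{p:.2g}") == 0.015

    def test_empty_table_contract(self):
        orr, ci, p = gene_fisher(0, 1020, 0, 118190)
        assert orr is None and ci is None and p == 1.0

    def test_zero_reference_count_gives_infinite_or(self):
        orr, _, p = gene_fisher(2, 100, 0, 1000)
        assert orr == math.inf and p < 1

    def test_zero_case_count_gives_zero_or(self):
        orr, _, _ = gene_fisher(0, 100, 5, 1000)
        assert orr == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            gene_fisher(-1, 10, 0, 10)

    def test_doubling_rule_at_least_minlike(self):
        _, _, p_min = gene_fisher(3, 50, 10, 500)
        _, _, p_dbl = gene_fisher(3, 50, 10, 500, two_sided_rule="double")
        assert p_dbl >= p_min - 1e-12

    def test_exact_conditional_ci_covers_or(self):
        orr, (lo, hi), _ = gene_fisher(5, 1020, 195, 118190)
        assert lo < orr < hi

    @given(
        st.integers(min_value=0, max_value=12),
        st.integers(min_value=0, max_value=12),
        st.integers(min_value=0, max_value=12),
        st.integers(min_value=0, max_value=12),
    )
    @settings(max_examples=200, deadline=None)
    def test_p_matches_brute_force_enumeration(self, a, b, c, d):
        if a + c == 0 and b + d == 0:
            return
        _, _, p = gene_fisher(a, a + b, c, c + d, compute_ci=False)
        if a == 0 and c == 0:
            assert p == 1.0
        else:
            assert p == pytest.approx(brute_force_fisher_p(a, b, c, d), rel=1e-9)


class TestRiskRatioAndCohortTests:
    def test_printed_frequency_ratio(self):
        assert round(risk_ratio(0.0059, 0.00046), 2) == 12.83

    def test_identity_and_edges(self):
        assert risk_ratio(0.001, 0.001) == 1.0
        assert risk_ratio(0.0, 0.001) == 0.0
        assert risk_ratio(0.001, 0.0) == math.inf

    def test_global_burden_equal_proportions(self):
        assert global_burden_test(10, 1000, 100, 10000) == 1.0

    def test_global_burden_matches_textbook_formula(self):
        a, b, c, d = 30, 70, 20, 80
        n = a + b + c + d
        expected = [[(a + b) * (a + c) / n, (a + b) * (b + d) / n],
                    [(c + d) * (a + c) / n, (c + d) * (b + d) / n]]
        stat = sum(
            (obs - exp) ** 2 / exp
            for row, erow in zip([[a, b], [c, d]], expected)
            for obs, exp in zip(row, erow)
        )
        from scipy.stats import chi2

        assert global_burden_test(a, a + b, c, c + d) == pytest.approx(
            float(chi2.sf(stat, df=1)), rel=1e-9
        )

    def test_global_burden_detects_large_enrichment(self):
        assert global_burden_test(200, 100000, 10000, 10000000) < 1e-4

    def test_or_direction_published_counts(self):
        assert or_direction_test(133, 19) < 1e-4

    def test_or_direction_balanced_and_empty(self):
        assert or_direction_test(10, 10) == 1.0
        with pytest.raises(ValueError):
            or_direction_test(0, 0)


class TestBHThreshold:
    def test_three_value_example(self):
        assert bh_discovery_threshold([0.001, 0.002, 0.9], 0.3) == 0.002

    def test_all_ones_gives_none(self):
        assert bh_discovery_threshold([1.0, 1.0, 1.0], 0.3) is None

    def test_single_value_at_fdr(self):
        assert bh_discovery_threshold([0.2], 0.3) == 0.2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bh_discovery_threshold([], 0.3)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40),
           st.floats(min_value=0.01, max_value=0.99))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force(self, ps, fdr):
        assert bh_discovery_threshold(ps, fdr) == brute_force_bh(ps, fdr)


def _case(gene, ac, carriers, an=1020):
    return GeneCaseCounts(gene, ac, carriers, an)


def _ref(gene, ac, an=118190, popmax=None):
    return ReferenceGeneCount(
        gene_symbol=gene,
        ref_allele_count=ac,
        ref_allele_number=an,
        combined_frequency=combined_carrier_frequency(
            [1 / an] * ac
        ),
        popmax_combined_frequency=popmax,
    )


class TestRankingAndPrioritisation:
    def _results(self, cfg=None):
        cases = [
            _case("STRONG", 8, 5),       # strongly enriched, many carriers
            _case("FEWCARRIER", 8, 2),   # enriched but only 2 carriers
            _case("WEAK", 2, 2),         # weak signal
            _case("COMMONREF", 6, 6),    # high reference count -> low fold
        ]
        refs = {
            "STRONG": _ref("STRONG", 20),
            "FEWCARRIER": _ref("FEWCARRIER", 20),
            "WEAK": _ref("WEAK", 150),
            "COMMONREF": _ref("COMMONREF", 2000),
        }
        return rank_genes(cases, refs, cfg or DiscoveryConfig())

    def test_rank_is_ascending_p(self):
        results = self._results()
        ps = [r.p_value for r in results]
        assert ps == sorted(ps)
        assert [r.rank for r in results] == [1, 2, 3, 4]

    def test_prioritize_requires_carriers_threshold_and_fold(self):
        results = self._results()
        chosen = prioritize(results, DiscoveryConfig())
        names = [r.gene_symbol for r in chosen]
        assert "STRONG" in names
        assert "FEWCARRIER" not in names  # p tiny but only 2 carriers
        assert "WEAK" not in names        # p above threshold
        assert "COMMONREF" not in names   # below 3-fold

    def test_prioritize_input_order_invariant(self):
        results = self._results()
        assert [r.gene_symbol for r in prioritize(results)] == [
            r.gene_symbol for r in prioritize(list(reversed(results)))
        ]

    def test_popmax_population_blocks_fold(self):
        cfg = DiscoveryConfig(fold_check_mode=FoldCheckMode.ALL_OUTBRED)
        cases = [_case("G", 8, 5)]
        refs = {"G": _ref("G", 20, popmax=0.005)}  # common in some population
        results = rank_genes(cases, refs, cfg)
        assert not results[0].passes_fold
        cfg2 = DiscoveryConfig(fold_check_mode=FoldCheckMode.PRIMARY)
        assert rank_genes(cases, refs, cfg2)[0].passes_fold

    def test_missing_reference_gene_gets_zero_counts(self):
        results = rank_genes([_case("NOV", 3, 3)], {}, DiscoveryConfig())
        assert results[0].contingency[2] == 0
        assert results[0].odds_ratio == math.inf

    def test_carrier_histogram_bookkeeping(self):
        results = self._results()
        hist = carrier_histogram(results, only_fold_enriched=False)
        assert hist == {2: 2, 5: 1, 6: 1}
        assert carrier_histogram([]) == {}

    def test_waterfall_signed_and_ordered(self):
        rows = waterfall_data(self._results())
        values = [v for _, v in rows]
        assert values == sorted(values, reverse=True)
        assert values[0] > 0


class TestFamilyHistoryTest:
    def test_identical_proportions_give_p_one(self):
        carriers = [True] * 10 + [False] * 90 + [True] * 10 + [False] * 90
        fh = [True] * 100 + [False] * 100
        orr, p = family_history_test(carriers, fh)
        assert orr == pytest.approx(1.0)
        assert p == 1.0

    def test_null_p_values_conservative(self):
        # random carrier labels at the cohort scale: P(p <= alpha) <= alpha
        rng = np.random.default_rng(2024)
        n = 516
        ps = []
        for _ in range(400):
            carriers = rng.random(n) < 0.25
            fh = rng.random(n) < 0.5
            _, p = family_history_test(carriers, fh)
            ps.append(p)
        ps = np.array(ps)
        for alpha in (0.05, 0.1, 0.25, 0.5):
            frac = (ps <= alpha).mean()
            se = math.sqrt(alpha * (1 - alpha) / len(ps))
            assert frac <= alpha + 3 * se
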