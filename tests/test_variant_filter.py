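"""Filter cascade: per-stage predicates, boundary behaviour, ordering and
audit invariants."""

from __future__ import annotations

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import GOOD_QC, make_obs, make_variant
from lofburden.config import DiscoveryConfig
from lofburden.types import ImpactClass
from lofburden.variant_filter import (
    FilterStage,
    frequency_filter_total,
    impact_filter,
    popmax_filter,
    quality_flag,
    run_cascade,
    transcript_filter,
)


class TestStagePredicates:
    @pytest.mark.parametrize(
        "consequence,impact,kept",
        [
            ("stop_gained", ImpactClass.HIGH, True),
            ("splice_donor_variant", ImpactClass.HIGH, True),
            ("missense_variant", ImpactClass.MODERATE, False),
            ("synonymous_variant", ImpactClass.LOW, False),
            ("intron_variant", ImpactClass.MODIFIER, False),
        ],
    )
    def test_impact(self, consequence, impact, kept):
        v = make_variant(consequence=consequence, impact=impact)
        assert impact_filter(v) is kept

    @pytest.mark.parametrize(
        "af,kept", [(0.0049, True), (0.005, True), (0.0051, False), (0.0, True)]
    )
    def test_total_maf_boundary(self, af, kept):
        assert frequency_filter_total(make_variant(af_total=af)) is kept

    def test_transcript_predicates(self):
        assert transcript_filter(make_variant()) == (True, True)
        assert transcript_filter(make_variant(biotype="lincRNA")) == (True, False)
        assert transcript_filter(make_variant(canonical=False)) == (False, True)

    @pytest.mark.parametrize(
        "popmax,kept", [(0.02, False), (0.004, True), (None, True), (0.005, True)]
    )
    def test_popmax_boundary(self, popmax, kept):
        assert popmax_filter(make_variant(af_popmax=popmax)) is kept

    @pytest.mark.parametrize(
        "qc_override,flagged",
        [
            ({"read_depth": 59}, True),
            ({"quality_score": 499.9}, True),
            ({"alt_allele_fraction": 0.34}, True),
            ({"bidirectional": False}, True),
            # every metric exactly at threshold: inclusive keep side
            (
                {
                    "quality_score": 500.0,
                    "read_depth": 60,
                    "alt_allele_fraction": 0.35,
                    "bidirectional": True,
                },
                False,
            ),
            ({"bidirectional": None}, False),  # unknown strand is not a flag
        ],
    )
    def test_quality_flag_boundaries(self, qc_override, flagged):
        qc = dataclasses.replace(GOOD_QC, **qc_override)
        assert quality_flag(make_variant(qc=qc)) is flagged


def _toy_set():
    """Ten variants: one fails each cascade stage, four pass everything."""
    fail_caller = dataclasses.replace(GOOD_QC, caller_filters_passed=False)
    return [
        make_variant(pos=1, gene="GA"),
        make_variant(pos=2, gene="GB"),
        make_variant(pos=3, gene="GC"),
        make_variant(pos=4, gene="GD"),
        make_variant(pos=5, gene="GE", impact=ImpactClass.MODERATE,
                     consequence="missense_variant"),
        make_variant(pos=6, gene="GF", af_total=0.01),
        make_variant(pos=7, gene="GG", canonical=False),
        make_variant(pos=8, gene="GH", qc=fail_caller),
        make_variant(pos=9, gene="GI", biotype="lincRNA"),
        make_variant(pos=10, gene="GJ", af_popmax=0.02),
    ]


class TestCascade:
    def test_each_stage_removes_exactly_one(self):
        kept, summary, decisions = run_cascade(_toy_set(), [])
        assert [nv for nv, _ in summary.stage_counts.values()] == [10, 9, 8, 7, 6, 5, 4]
        assert len(kept) == 4
        failed = {d.stage_failed for d in decisions if not d.kept}
        assert failed == set(FilterStage) - {FilterStage.NONE}

    def test_empty_input(self):
        kept, summary, decisions = run_cascade([], [])
        assert kept == [] and decisions == []
        assert all(c == (0, 0) for c in summary.stage_counts.values())

    def test_all_passing_kept_unchanged(self):
        variants = [make_variant(pos=i, gene=f"G{i}") for i in range(1, 6)]
        kept, _, _ = run_cascade(variants, [])
        assert kept == variants

    def test_flagged_not_dropped_by_default_but_dropped_when_configured(self):
        low_depth = dataclasses.replace(GOOD_QC, read_depth=30)
        v = make_variant(qc=low_depth)
        kept, _, decisions = run_cascade([v], [])
        assert kept == [v] and decisions[0].qc_flagged_for_review
        kept2, _, decisions2 = run_cascade([v], [], DiscoveryConfig(drop_flagged=True))
        assert kept2 == [] and decisions2[0].stage_failed is FilterStage.QUALITY

    def test_caller_fail_dropped_at_quality_regardless(self):
        fail = dataclasses.replace(GOOD_QC, caller_filters_passed=False)
        _, _, decisions = run_cascade([make_variant(qc=fail)], [])
        assert decisions[0].stage_failed is FilterStage.QUALITY

    def test_sample_retention_counted_on_kept_variants(self):
        variants = [make_variant(pos=1), make_variant(pos=2, af_total=0.5)]
        obs = [make_obs(sample="S1", pos=1), make_obs(sample="S2", pos=2)]
        _, summary, _ = run_cascade(variants, obs)
        assert summary.n_samples_retained == 1

    @given(st.permutations(range(10)))
    @settings(max_examples=25, deadline=None)
    def test_kept_set_order_invariant(self, perm):
        base = _toy_set()
        shuffled = [base[i] for i in perm]
        kept, _, _ = run_cascade(shuffled, [])
        expected, _, _ = run_cascade(base, [])
        assert {v.variant_key for v in kept} == {v.variant_key for v in expected}

    @given(st.floats(min_value=1e-6, max_value=0.005))
    @settings(max_examples=25, deadline=None)
    def test_tightening_maf_never_grows_kept_set(self, threshold):
        base = _toy_set()
        default_kept, _, _ = run_cascade(base, [], DiscoveryConfig())
        tight_kept, _, _ = run_cascade(
            base, [], DiscoveryConfig(maf_threshold=threshold)
        )
        assert {v.variant_key for v in tight_kept} <= {
            v.variant_key for v in default_kept
        }

    def test_every_dropped_variant_has_exactly_one_stage(self):
        _, _, decisions = run_cascade(_toy_set(), [])
        for d in decisions:
            assert d.kept == (d.stage_failed is FilterStage.NONE)

    def test_counts_non_increasing_along_cascade(self):
        _, summary, _ = run_cascade(_toy_set(), [])
        counts = list(summary.stage_counts.values())
        assert all(a >= b for (a, _), (b, _) in zip(counts, counts[1:]))
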