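"""Somatic filter and deep-seq validation rules against worked examples and
monotonicity/completeness properties."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from clonarch import filters
from clonarch.filters import (
    MissingExomeMembershipError,
    ZeroDepthError,
    filter_exome_indel,
    filter_exome_snv,
    validate_deepseq_indel,
    validate_deepseq_snv,
    validation_rate,
)
from conftest import make_variant


class TestExomeSnv:
    def test_five_alt_reads_fail_min_read_rule(self):
        d = filter_exome_snv(make_variant(t_alt=5, t_ref=45, n_alt=0, n_ref=50))
        assert not d.passed and d.failed_rules == [filters.R_MIN_ALT_READS]

    def test_low_vaf_needs_tenfold_ratio_over_normal(self):
        # tumor VAF 0.10 vs normal VAF 0.02: ratio 5 < 10
        d = filter_exome_snv(make_variant(t_alt=10, t_ref=90, n_alt=2, n_ref=98))
        assert not d.passed and d.failed_rules == [filters.R_LOW_VAF_RATIO]

    def test_clean_somatic_passes(self):
        assert filter_exome_snv(make_variant(t_alt=50, t_ref=50, n_alt=0)).passed

    def test_contaminated_normal_fails(self):
        d = filter_exome_snv(make_variant(t_alt=50, t_ref=50, n_alt=6, n_ref=54))
        assert filters.R_NORMAL_ALT_COUNT in d.failed_rules
        assert filters.R_NORMAL_VAF in d.failed_rules

    def test_zero_depth_is_an_error(self):
        with pytest.raises(ZeroDepthError):
            filter_exome_snv(make_variant(t_alt=0, t_ref=0))


class TestExomeIndel:
    @pytest.mark.parametrize(
        "t_alt,t_ref,ok",
        [
            (4, 16, False),   # four supporting reads is not enough
            (5, 37, True),    # 5 reads at VAF 0.12
            (20, 203, False),  # plenty of reads but VAF 0.09 < 0.1
        ],
    )
    def test_read_and_vaf_floors(self, t_alt, t_ref, ok):
        d = filter_exome_indel(
            make_variant(variant_class="DEL", ref="AT", alt="A",
                         t_alt=t_alt, t_ref=t_ref, n_alt=0)
        )
        assert d.passed is ok


class TestDeepseqSnv:
    def kw(self, **kwargs):
        base = dict(assay="deepseq", n_alt=0, n_ref=400)
        base.update(kwargs)
        return make_variant(**base)

    def test_nine_alt_reads_fail(self):
        d = validate_deepseq_snv(self.kw(t_alt=9, t_ref=91), exome_called=True)
        assert not d.passed and filters.R_MIN_ALT_READS in d.failed_rules

    def test_low_vaf_needs_fifteen_reads(self):
        low = validate_deepseq_snv(self.kw(t_alt=12, t_ref=288), exome_called=True)
        assert not low.passed and low.failed_rules == [filters.R_LOW_VAF_ALT_READS]
        ok = validate_deepseq_snv(self.kw(t_alt=16, t_ref=384), exome_called=True)
        assert ok.passed

    def test_tumor_vaf_must_be_five_times_normal(self):
        d = validate_deepseq_snv(
            self.kw(t_alt=20, t_ref=80, n_alt=5, n_ref=95), exome_called=True
        )
        assert not d.passed and d.failed_rules == [filters.R_TUMOR_NORMAL_RATIO]

    def test_non_exome_call_fails_membership(self):
        d = validate_deepseq_snv(self.kw(t_alt=100, t_ref=100), exome_called=False)
        assert d.failed_rules == [filters.R_EXOME_MEMBERSHIP]

    def test_missing_membership_flag_raises(self):
        with pytest.raises(MissingExomeMembershipError):
            validate_deepseq_snv(self.kw(t_alt=100, t_ref=100), exome_called=None)

    def test_zero_normal_vaf_passes_ratio_rule(self):
        d = validate_deepseq_snv(
            self.kw(t_alt=100, t_ref=100, n_alt=0, n_ref=0), exome_called=True
        )
        assert d.passed


class TestDeepseqIndel:
    def kw(self, **kwargs):
        base = dict(assay="deepseq", variant_class="DEL", ref="AT", alt="A",
                    n_alt=0, n_ref=400)
        base.update(kwargs)
        return make_variant(**base)

    def test_strand_bias_over_90_percent_fails(self):
        d = validate_deepseq_indel(
            self.kw(t_alt=20, t_ref=380, alt_fwd=19, alt_rev=1)
        )
        assert d.failed_rules == [filters.R_STRAND_BIAS]

    def test_balanced_low_frequency_indel_passes(self):
        d = validate_deepseq_indel(
            self.kw(t_alt=10, t_ref=190, alt_fwd=5, alt_rev=5, n_alt=1, n_ref=199)
        )
        assert d.passed

    def test_below_vaf_floor_fails(self):
        d = validate_deepseq_indel(
            self.kw(t_alt=50, t_ref=2450, alt_fwd=25, alt_rev=25)
        )
        assert d.failed_rules == [filters.R_MIN_VAF]

    def test_zero_alt_reads_fails_with_rule_not_crash(self):
        d = validate_deepseq_indel(self.kw(t_alt=0, t_ref=400, alt_fwd=0, alt_rev=0))
        assert not d.passed and filters.R_STRAND_BIAS in d.failed_rules


def test_validation_rate_arithmetic():
    calls = [make_variant(pos=i, sector_id="S1") for i in range(1, 21)]
    decisions = {}
    for i, c in enumerate(calls):
        decisions[(c.key, "S1")] = filters.FilterDecision(
            key=c.key, sector_id="S1", passed=i < 17,
            failed_rules=[] if i < 17 else ["min_alt_reads"],
        )
    rates = validation_rate(calls, decisions)
    assert rates["snv_rate"] == pytest.approx(0.85)
    assert math.isnan(rates["indel_rate"])  # none attempted


def test_validation_rate_all_validated_and_none_attempted():
    call = make_variant()
    d = filters.FilterDecision(key=call.key, sector_id="S1", passed=True)
    assert validation_rate([call], {(call.key, "S1"): d})["snv_rate"] == 1.0
    assert math.isnan(validation_rate([call], {})["snv_rate"])


@settings(derandomize=True, max_examples=200, deadline=None)
@given(
    t_alt=st.integers(0, 200),
    extra=st.integers(0, 100),
    t_ref=st.integers(1, 500),
    n_alt=st.integers(0, 5),
    n_ref=st.integers(50, 500),
)
def test_more_alt_reads_never_flip_pass_to_fail(t_alt, extra, t_ref, n_alt, n_ref):
    """Adding alt reads (holding ref reads fixed) can only help: the min-read
    rules are monotone and every VAF threshold is a lower bound."""
    lo = make_variant(t_alt=t_alt, t_ref=t_ref, n_alt=n_alt, n_ref=n_ref)
    hi = make_variant(t_alt=t_alt + extra, t_ref=t_ref, n_alt=n_alt, n_ref=n_ref)
    if filter_exome_snv(lo).passed:
        assert filter_exome_snv(hi).passed


@settings(derandomize=True, max_examples=100, deadline=None)
@given(
    t_alt=st.integers(0, 300),
    t_ref=st.integers(1, 3000),
    n_alt=st.integers(0, 30),
    n_ref=st.integers(100, 3000),
)
def test_every_fail_names_a_rule(t_alt, t_ref, n_alt, n_ref):
    v = make_variant(assay="deepseq", t_alt=t_alt, t_ref=t_ref,
                     n_alt=n_alt, n_ref=n_ref)
    d = validate_deepseq_snv(v, exome_called=True)
    assert d.passed == (not d.failed_rules)
    if not d.passed:
        assert all(isinstance(r, str) and r for r in d.failed_rules)
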