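"""Ploidy, GII/adGII, feature mapping, LOH and SCNA-level ITH."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clonarch import scna
from clonarch.scna import (
    FeatureCN,
    RelativeCall,
    detect_loh,
    instability_scores,
    map_to_features,
    median_integer_ploidy,
    relative_calls,
    scna_ith,
)
from clonarch.types import Feature, Segment, SectorProfile
from conftest import make_profile, random_profile


class TestPloidy:
    def test_diploid_and_tetraploid(self):
        assert median_integer_ploidy(make_profile([(100, 1, 1)] * 5)) == 2
        assert median_integer_ploidy(make_profile([(100, 2, 2)] * 5)) == 4

    def test_weighted_median_prefers_heavier_state(self):
        # 60% of weight at total CN 3, 40% at CN 2
        p = make_profile([(60, 2, 1), (40, 1, 1)])
        assert median_integer_ploidy(p) == 3

    def test_exact_tie_breaks_to_lower_integer(self):
        p = make_profile([(50, 2, 1), (50, 1, 1)])
        assert median_integer_ploidy(p) == 2

    def test_snp_weights_used_when_complete(self):
        # lengths favor CN 2, SNP counts favor CN 3
        p = make_profile([(90, 1, 1, 10), (10, 2, 1, 90)])
        assert median_integer_ploidy(p) == 3

    def test_mixed_snp_weights_fall_back_to_length(self):
        p = make_profile([(90, 1, 1, None), (10, 2, 1, 90)])
        assert median_integer_ploidy(p) == 2

    def test_empty_profile_is_an_error(self):
        with pytest.raises(ValueError, match="empty profile"):
            median_integer_ploidy(SectorProfile("S", 0.5, []))


class TestInstability:
    def test_no_deviation_is_zero(self):
        s = instability_scores(make_profile([(100, 1, 1)] * 10))
        assert (s.gii, s.adgii) == (0.0, 0.0)

    def test_thirty_percent_low_gain(self):
        p = make_profile([(30, 2, 1), (70, 1, 1)])
        s = instability_scores(p)
        assert s.gii == pytest.approx(0.30)
        assert s.adgii == 0.0

    def test_mixed_high_and_low_copy(self):
        p = make_profile([(10, 3, 1), (20, 1, 0), (70, 1, 1)])
        s = instability_scores(p)
        assert s.gii == pytest.approx(0.30)
        assert s.adgii == pytest.approx(0.10)

    def test_copy_neutral_loh_does_not_count(self):
        p = make_profile([(50, 2, 0), (50, 1, 1)])
        assert instability_scores(p).gii == 0.0

    def test_sex_chromosomes_excluded_by_default(self):
        segs = [
            Segment("S", "1", 1, 100, 1, 1),
            Segment("S", "X", 1, 100, 5, 5),
        ]
        p = SectorProfile("S", 0.5, segs)
        assert instability_scores(p).gii == 0.0

    def test_segment_split_invariance_exact(self, rng):
        for _ in range(10):
            p = random_profile(rng)
            halves = []
            for s in p.segments:
                mid = (s.start + s.end) // 2
                halves.append(Segment(s.sector_id, s.chrom, s.start, mid,
                                      s.n_major, s.n_minor))
                halves.append(Segment(s.sector_id, s.chrom, mid + 1, s.end,
                                      s.n_major, s.n_minor))
            q = SectorProfile(p.sector_id, p.purity, halves)
            a, b = instability_scores(p), instability_scores(q)
            assert a.gii == b.gii and a.adgii == b.adgii
            assert median_integer_ploidy(p) == median_integer_ploidy(q)


@settings(derandomize=True, max_examples=200, deadline=None)
@given(seed=st.integers(0, 100_000))
def test_gii_dominates_adgii_on_random_profiles(seed):
    p = random_profile(np.random.default_rng(seed))
    s = instability_scores(p)
    assert 0.0 <= s.adgii <= s.gii <= 1.0


def test_doubling_preserves_alteration_direction_and_gii(rng):
    """Doubling every allele doubles the median ploidy, so each segment's
    gain/loss direction — and hence GII — is unchanged (magnitudes scale)."""
    for _ in range(10):
        p = random_profile(rng)
        doubled = SectorProfile(
            p.sector_id,
            p.purity,
            [Segment(s.sector_id, s.chrom, s.start, s.end,
                     2 * s.n_major, 2 * s.n_minor) for s in p.segments],
        )
        assert median_integer_ploidy(doubled) == 2 * median_integer_ploidy(p)
        for a, b in zip(relative_calls(p), relative_calls(doubled)):
            assert np.sign(a.delta) == np.sign(b.delta)
            assert b.delta == 2 * a.delta
        assert instability_scores(doubled).gii == instability_scores(p).gii


class TestRelativeCalls:
    @pytest.mark.parametrize(
        "delta,cls",
        [(-3, "loss2"), (-2, "loss2"), (-1, "loss1"), (0, "neutral"),
         (1, "gain1"), (2, "gain2plus"), (4, "gain2plus")],
    )
    def test_class_boundaries(self, delta, cls):
        assert RelativeCall.class_of(delta) == cls


class TestFeatureMapping:
    def seg(self, start, end, major=2, minor=1):
        return Segment("S1", "1", start, end, major, minor)

    def test_gene_inside_single_segment(self):
        p = SectorProfile("S1", 0.5, [self.seg(1, 1000, 3, 1)])
        (fc,) = map_to_features(p, [Feature("G", "1", 100, 200, "gene")])
        assert fc.assigned and fc.total_cn == 4

    def test_largest_qualifying_overlap_wins(self):
        # gene 1..100; segments cover 60% and 40%
        p = SectorProfile("S1", 0.5, [self.seg(1, 60, 3, 1), self.seg(61, 300, 1, 0)])
        (fc,) = map_to_features(p, [Feature("G", "1", 1, 100, "gene")])
        assert fc.assigned and (fc.n_major, fc.n_minor) == (3, 1)

    def test_no_segment_reaching_25_percent_leaves_unassigned(self):
        # gene 1..100; overlaps of 20% and 15%, remainder uncovered
        p = SectorProfile("S1", 0.5, [self.seg(1, 20, 3, 1), self.seg(86, 300, 1, 0)])
        (fc,) = map_to_features(p, [Feature("G", "1", 1, 100, "gene")])
        assert not fc.assigned and fc.total_cn is None

    def test_single_small_overlap_still_assigns(self):
        # the 25% floor only arbitrates between multiple segments
        p = SectorProfile("S1", 0.5, [self.seg(1, 10, 3, 1)])
        (fc,) = map_to_features(p, [Feature("G", "1", 1, 100, "gene")])
        assert fc.assigned


class TestLoh:
    def test_copy_neutral_loh_flagged(self):
        p = make_profile([(25, 2, 0), (75, 1, 1)])
        loh = detect_loh(p)
        assert loh.flags == [True, False]
        assert loh.genome_fraction == pytest.approx(0.25)

    def test_heterozygous_not_loh(self):
        assert detect_loh(make_profile([(100, 1, 1)])).genome_fraction == 0.0


class TestScnaIth:
    def fc(self, feature, sector, cn):
        return FeatureCN(feature=feature, sector_id=sector, assigned=True,
                         total_cn=cn, n_major=cn, n_minor=0)

    def test_truncal_late_and_unaltered(self):
        ploidies = {"S1": 2, "S2": 2, "S3": 2}
        feature_cn = {
            s: [self.fc("gained_all", s, 3),
                self.fc("gained_some", s, 3 if s != "S3" else 2),
                self.fc("conflict", s, {"S1": 3, "S2": 1, "S3": 3}[s]),
                self.fc("flat", s, 2)]
            for s in ploidies
        }
        res = scna_ith(feature_cn, ploidies, min_sectors=3)
        assert res.labels == {
            "gained_all": "truncal",
            "gained_some": "late",
            "conflict": "late",
            "flat": "unaltered",
        }
        assert res.late_fraction == pytest.approx(2 / 4)

    def test_too_few_sectors_raises(self):
        with pytest.raises(ValueError, match=">= 3 sectors"):
            scna_ith({"S1": [], "S2": []}, {"S1": 2, "S2": 2})
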