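"""Log2 ratio track, Fig-S2-style ratio-Brick filters and rank-sum tests."""

import itertools

import numpy as np
import pytest

from fourcbricks.differential import (
    interval_change_summary,
    log2_ratio,
    ranksum_test,
    ratio_bricks,
    region_count_test,
    remove_cross_overlaps,
    subtract_gaps_from_bricks,
)
from fourcbricks.domainogram import Brick, InteractingRegion, ShortRangeWindow
from fourcbricks.fragmap import CountTrack, FragmentMap, ViewpointSpec
from fourcbricks.signal import SignalTrack


def make_map(n: int, frag: int = 1_000) -> FragmentMap:
    bounds = np.arange(n + 1) * frag
    return FragmentMap(chrom="chrT", starts=bounds[:-1], ends=bounds[1:])


def make_track(values, condition="case", stage="smoothed") -> SignalTrack:
    values = np.asarray(values, dtype=float)
    fmap = make_map(values.size)
    vp = ViewpointSpec("VP", "chrT", 500, exclusion_k=0)
    return SignalTrack(
        fmap=fmap, viewpoint=vp, condition=condition, stage=stage, values=values
    )


def brick(start_frag, end_frag, p=1e-6, sign="positive", frag=1_000):
    return Brick(
        chrom="chrT",
        start=start_frag * frag,
        end=end_frag * frag,
        start_frag=start_frag,
        end_frag=end_frag,
        window_w=end_frag - start_frag,
        p_value=p,
        tier="short_range",
        sign=sign,
    )


class TestLog2Ratio:
    def test_identical_tracks_give_zero(self, rng):
        v = rng.uniform(1, 10, size=30)
        r = log2_ratio(make_track(v), make_track(v, "ctrl"))
        np.testing.assert_allclose(r.values, 0.0)

    def test_halved_signal_is_minus_one(self):
        ctrl = np.full(20, 1_000.0)
        r = log2_ratio(make_track(ctrl / 2), make_track(ctrl, "ctrl"), eps=1e-6)
        np.testing.assert_allclose(r.values, -1.0, atol=1e-6)

    def test_swap_negates_exactly(self, rng):
        a = rng.uniform(0, 5, size=40)
        b = rng.uniform(0, 5, size=40)
        r1 = log2_ratio(make_track(a), make_track(b, "ctrl"), eps=0.3)
        r2 = log2_ratio(make_track(b), make_track(a, "ctrl"), eps=0.3)
        np.testing.assert_allclose(r1.values, -r2.values)

    def test_default_pseudocount_is_five_percent_of_median(self, rng):
        a = rng.uniform(1, 9, size=50)
        b = rng.uniform(1, 9, size=50)
        r = log2_ratio(make_track(a), make_track(b, "ctrl"))
        assert np.isclose(r.pseudocount, 0.05 * np.median(np.concatenate([a, b])))

    def test_nonpositive_eps_rejected(self):
        with pytest.raises(ValueError):
            log2_ratio(make_track([1.0]), make_track([1.0], "ctrl"), eps=0.0)


class TestRanksumOracle:
    @staticmethod
    def exact_two_sided(a, b):
        """Enumerate every split of the pooled sample (tie-free samples)."""
        pooled = np.concatenate([a, b])
        na = len(a)
        u_obs = sum(1 for x in a for y in b if x > y)
        us = []
        for comb in itertools.combinations(range(len(pooled)), na):
            ga = pooled[list(comb)]
            gb = np.delete(pooled, list(comb))
            us.append(sum(1 for x in ga for y in gb if x > y))
        us = np.array(us)
        p = 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs))
        return min(p, 1.0)

    def test_spec_example_most_extreme_split(self):
        a, b = np.array([10.0, 11.0, 12.0]), np.array([1.0, 2.0, 3.0])
        _, p, method = ranksum_test(a, b)
        assert method == "exact"
        assert np.isclose(p, 0.1)
        assert np.isclose(self.exact_two_sided(a, b), 0.1)

    @pytest.mark.parametrize("na", [2, 3, 4, 5, 6])
    def test_matches_exhaustive_split_enumeration(self, na, rng):
        nb = 12 - na
        vals = rng.permutation(np.arange(1.0, 13.0))
        a, b = vals[:na], vals[na:]
        _, p, method = ranksum_test(a, b)
        assert method == "exact"
        assert np.isclose(p, self.exact_two_sided(a, b))

    def test_identical_multisets_give_p_one(self):
        a = np.array([1.0, 2.0, 3.0])
        _, p, _ = ranksum_test(a, a.copy())
        assert p == 1.0

    def test_degenerate_all_tied(self):
        with pytest.warns(UserWarning, match="tied"):
            _, p, method = ranksum_test(np.ones(5), np.ones(7))
        assert p == 1.0 and method == "degenerate"


class TestRegionCountTest:
    def _fixture(self, region_counts, outside_counts):
        n = 5 * (len(region_counts) + len(outside_counts))
        fmap = make_map(n)
        vp = ViewpointSpec("VP", "chrT", 100, exclusion_k=0)
        counts = np.zeros(n, dtype=int)
        regions, bricks = [], []
        for i, c in enumerate(region_counts + outside_counts):
            f0 = 5 * i + 1
            counts[f0] = c
            b = brick(f0, f0 + 1)
            bricks.append(b)
            if i < len(region_counts):
                regions.append(
                    InteractingRegion(
                        chrom="chrT",
                        start=b.start,
                        end=b.end,
                        start_frag=b.start_frag,
                        end_frag=b.end_frag,
                        member_bricks=[b],
                    )
                )
        track = CountTrack.from_raw_counts(counts, fmap, vp)
        return track, regions, bricks

    def test_high_count_regions_detected(self):
        track, regions, bricks = self._fixture([500, 600, 700, 800], [5, 6, 7, 8, 9, 10])
        res = region_count_test(track, track, regions, bricks)
        assert res.p_value < 0.05
        assert res.n_regions == 4 and res.n_outside_bricks == 6

    def test_identical_distributions_not_significant(self):
        track, regions, bricks = self._fixture([50, 50, 50], [50, 50, 50])
        res = region_count_test(track, track, regions, bricks)
        assert res.p_value == 1.0

    def test_requires_both_samples(self):
        track, regions, bricks = self._fixture([10, 20], [30])
        with pytest.raises(ValueError):
            region_count_test(track, track, regions, [])


class TestIntervalChangeSummary:
    def test_constant_track(self):
        r = log2_ratio(make_track(np.full(30, 5.0)), make_track(np.full(30, 10.0), "ctrl"), eps=1e-9)
        med, lo, hi = interval_change_summary(r, (0, 30_000), n_boot=200)
        assert np.isclose(med, -1.0, atol=1e-6)
        assert np.isclose(lo, hi, atol=1e-6)

    def test_no_change_interval_near_zero(self, rng):
        v = rng.uniform(5, 6, size=60)
        r = log2_ratio(make_track(v * (1 + rng.normal(0, 0.01, 60))), make_track(v, "ctrl"))
        med, lo, hi = interval_change_summary(r, (0, 60_000), n_boot=200)
        assert abs(med) < 0.1

    def test_too_few_fragments_rejected(self):
        r = log2_ratio(make_track(np.ones(30)), make_track(np.ones(30), "ctrl"))
        with pytest.raises(ValueError):
            interval_change_summary(r, (0, 3_000))


class TestCrossOverlapFilter:
    def test_half_overlapping_pair_removed_from_both(self):
        pos = [brick(0, 10, sign="positive")]
        neg = [brick(5, 15, sign="negative")]
        p2, n2 = remove_cross_overlaps(pos, neg)
        assert p2 == [] and n2 == []

    def test_tiny_overlap_tolerated(self):
        pos = [brick(0, 100, sign="positive")]
        neg = [brick(96, 200, sign="negative")]  # 4% of the shorter
        p2, n2 = remove_cross_overlaps(pos, neg, threshold=0.05)
        assert len(p2) == 1 and len(n2) == 1

    def test_reciprocal_mode_spares_asymmetric_pair(self):
        pos = [brick(0, 10, sign="positive")]  # 40% of this one
        neg = [brick(6, 106, sign="negative")]  # 4% of this one
        p2, n2 = remove_cross_overlaps(pos, neg, mode="reciprocal")
        assert len(p2) == 1 and len(n2) == 1
        p2, n2 = remove_cross_overlaps(pos, neg, mode="shorter")
        assert p2 == [] and n2 == []


class TestGapSubtraction:
    def test_bisected_brick_splits(self):
        fmap = make_map(30)
        out = subtract_gaps_from_bricks(
            [brick(5, 20)], np.array([[10_000, 12_000]]), fmap
        )
        assert [(b.start, b.end) for b in out] == [(5_000, 10_000), (12_000, 20_000)]

    def test_swallowed_brick_removed(self):
        fmap = make_map(30)
        out = subtract_gaps_from_bricks(
            [brick(5, 8)], np.array([[4_000, 9_000]]), fmap
        )
        assert out == []


class TestRatioBricks:
    def test_zero_ratio_gives_empty_sets(self):
        r = log2_ratio(make_track(np.full(300, 4.0)), make_track(np.full(300, 4.0), "ctrl"))
        rset = ratio_bricks(r, [brick(0, 300)], [], gaps=np.empty((0, 2)))
        assert rset.positive == [] and rset.negative == []

    def test_planted_loss_inside_anchored_region(self, rng):
        n = 600
        ctrl = rng.uniform(9, 11, size=n)
        case = ctrl * (1 + rng.normal(0, 0.02, n))
        case[200:260] *= 0.5  # two-fold loss
        r = log2_ratio(make_track(case), make_track(ctrl, "ctrl"), eps=0.05)
        srw = ShortRangeWindow("chrT", 0, n * 1_000)
        rset = ratio_bricks(
            r,
            ctrl_bricks=[brick(190, 270)],
            case_bricks=[],
            gaps=np.empty((0, 2)),
            short_range=srw,
        )
        assert any(b.start < 260_000 and b.end > 200_000 for b in rset.negative)

    def test_swap_antisymmetry(self, rng):
        n = 500
        ctrl = rng.uniform(5, 15, size=n)
        case = ctrl * np.exp(rng.normal(0, 0.3, n))
        anchors = [brick(0, n)]
        srw = ShortRangeWindow("chrT", 0, n * 1_000)
        kw = dict(gaps=np.empty((0, 2)), short_range=srw)
        fwd = ratio_bricks(
            log2_ratio(make_track(case), make_track(ctrl, "ctrl"), eps=0.2),
            anchors, [], **kw,
        )
        rev = ratio_bricks(
            log2_ratio(make_track(ctrl), make_track(case, "ctrl"), eps=0.2),
            [], anchors, **kw,
        )
        assert [(b.start, b.end) for b in fwd.positive] == [
            (b.start, b.end) for b in rev.negative
        ]
        assert [(b.start, b.end) for b in fwd.negative] == [
            (b.start, b.end) for b in rev.positive
        ]

    def test_unanchored_candidates_dropped(self, rng):
        n = 400
        ctrl = rng.uniform(9, 11, size=n)
        case = ctrl.copy()
        case[100:150] *= 0.5
        r = log2_ratio(make_track(case), make_track(ctrl, "ctrl"), eps=0.05)
        srw = ShortRangeWindow("chrT", 0, n * 1_000)
        rset = ratio_bricks(
            r, ctrl_bricks=[brick(300, 320)], case_bricks=[],
            gaps=np.empty((0, 2)), short_range=srw,
        )
        assert rset.negative == []
        assert rset.provenance["unanchored_removed"][1] >= 1
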