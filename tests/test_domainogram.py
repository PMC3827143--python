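"""Rank transform, multi-scale window scoring and Brick calling."""

import itertools

import numpy as np
import pytest
from scipy import stats

from fourcbricks.domainogram import (
    Brick,
    ShortRangeWindow,
    _irwin_hall_sf,
    call_bricks,
    merge_bricks,
    rank_transform,
    window_pvalues,
)
from fourcbricks.fragmap import FragmentMap


def make_map(n: int, frag: int = 1_000) -> FragmentMap:
    bounds = np.arange(n + 1) * frag
    return FragmentMap(chrom="chrT", starts=bounds[:-1], ends=bounds[1:])


class TestRankTransform:
    def test_strictly_increasing_values(self):
        u = rank_transform(np.arange(5, dtype=float))
        np.testing.assert_allclose(u, [0.2, 0.4, 0.6, 0.8, 1.0])

    def test_all_equal_values_get_average_rank(self):
        n = 8
        u = rank_transform(np.full(n, 3.0))
        np.testing.assert_allclose(u, (n + 1) / (2 * n))

    def test_matches_argsort_oracle(self, rng):
        v = rng.normal(size=50)
        u = rank_transform(v)
        order = np.argsort(np.argsort(v)) + 1  # no ties almost surely
        np.testing.assert_allclose(u, order / 50)

    def test_missing_fragments_excluded(self):
        v = np.array([3.0, np.nan, 1.0, 2.0])
        u = rank_transform(v)
        assert np.isnan(u[1])
        np.testing.assert_allclose(u[[0, 2, 3]], [1.0, 1 / 3, 2 / 3])

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            rank_transform(np.array([np.nan, np.nan]))


class TestWindowPvalues:
    def test_top_rank_single_fragment_closed_form(self):
        u = rank_transform(np.arange(10, dtype=float))
        scores = window_pvalues(u, wmax=1)
        # top-ranked fragment: z = 0.5*sqrt(12), p ~ 0.0416
        assert np.isclose(scores.pvalues[-1], stats.norm.sf(np.sqrt(3.0)))
        assert 0.041 < scores.pvalues[-1] < 0.042

    def test_central_mean_rank_gives_half(self):
        u = np.array([0.2, 0.8, 0.5, 0.6, 0.4])
        scores = window_pvalues(u, wmax=5)
        sel = (scores.widths == 2) & (scores.starts == 0)  # mean 0.5
        assert np.isclose(scores.pvalues[sel][0], 0.5)

    @pytest.mark.parametrize("n,w", [(7, 3), (8, 2), (8, 3), (8, 4)])
    def test_normal_approximation_vs_exhaustive_enumeration(self, n, w):
        """Exact tail from enumerating all ordered rank w-tuples of n.

        Agreement is asserted over the decision-relevant upper tail
        (exact p <= 0.1); in the bulk the discrete null's tie mass makes
        any continuous approximation diverge at this tiny n.
        """
        tuples = itertools.permutations(np.arange(1, n + 1) / n, w)
        means = np.array([np.mean(t) for t in tuples])
        checked = 0
        for m in np.unique(means):
            exact = np.mean(means >= m - 1e-12)
            if exact > 0.1:
                continue
            p_norm = float(stats.norm.sf((m - 0.5) * np.sqrt(12 * w)))
            assert abs(p_norm - exact) <= 0.05
            checked += 1
        assert checked >= 2

    def test_missing_fragment_windows_skipped(self):
        u = np.array([0.5, np.nan, 0.25, 0.75, 1.0])
        scores = window_pvalues(u, wmax=3)
        spans = set(zip(scores.starts.tolist(), scores.widths.tolist()))
        assert (0, 2) not in spans and (1, 1) not in spans
        assert (2, 3) in spans

    def test_pvalue_monotone_in_mean_rank_at_fixed_width(self, rng):
        u = rank_transform(rng.normal(size=60))
        scores = window_pvalues(u, wmax=10)
        for w in (1, 5, 10):
            sel = scores.widths == w
            order = np.argsort(scores.mean_ranks[sel])
            assert np.all(np.diff(scores.pvalues[sel][order]) <= 1e-12)

    def test_exact_tail_below_normal_saturation(self):
        # a 7-fragment window of top ranks: normal z saturates near
        # 0.5*sqrt(12*7) ~ 4.6 but the exact tail is astronomically smaller
        p = _irwin_hall_sf(6.97, 7)
        assert p is not None and p < 1e-12
        # moderate tail defers to the normal approximation
        assert _irwin_hall_sf(3.6, 7) is None

    def test_exact_tail_matches_simulation(self, rng):
        # P(sum of 4 uniforms >= 3.5) = 0.5^4/4! ~ 2.6e-3, checkable by MC
        p = _irwin_hall_sf(3.5, 4)
        draws = rng.random((200_000, 4)).sum(axis=1)
        assert abs(p - np.mean(draws >= 3.5)) < 3e-4


class TestCallBricks:
    def test_null_track_yields_nothing_at_stringent_fdr(self, rng):
        total = 0
        for _ in range(30):
            u = rank_transform(rng.normal(size=500))
            scores = window_pvalues(u, wmax=100)
            total += len(call_bricks(scores, make_map(500)))
        assert total == 0

    def test_planted_top_rank_block_found(self, rng):
        found = 0
        n_sim = 30
        for _ in range(n_sim):
            v = rng.normal(size=1_000)
            v[400:420] += 10.0  # top ranks by construction
            u = rank_transform(v)
            scores = window_pvalues(u, wmax=50)
            srw = ShortRangeWindow("chrT", 0, 1_000_000)
            bricks = call_bricks(
                scores, make_map(1_000), short_range=srw, fdr_short=0.1
            )
            overlapping = [b for b in bricks if b.start < 420_000 and b.end > 400_000]
            found += len(overlapping) >= 1
        assert found >= int(0.9 * n_sim)

    def test_bricks_disjoint_and_tiered(self, rng):
        v = rng.normal(size=800)
        v[100:140] += 5.0
        v[600:630] += 5.0
        u = rank_transform(v)
        scores = window_pvalues(u, wmax=80)
        srw = ShortRangeWindow("chrT", 0, 300_000)
        bricks = call_bricks(scores, make_map(800), short_range=srw)
        for a, b in itertools.combinations(bricks, 2):
            assert min(a.end, b.end) <= max(a.start, b.start)
        for b in bricks:
            expected = "short_range" if b.end <= 300_000 else "long_range"
            assert b.tier == expected

    def test_shift_invariance_of_calls(self, rng):
        v = rng.normal(size=600)
        v[200:230] += 6.0
        fmap = make_map(600)

        def call(values):
            scores = window_pvalues(rank_transform(values), wmax=60)
            return [
                (b.start_frag, b.end_frag)
                for b in call_bricks(
                    scores, fmap, short_range=ShortRangeWindow("chrT", 0, 600_000)
                )
            ]

        assert call(v) == call(v + 123.4)

    def test_bh_mode_also_finds_planted_block(self, rng):
        v = rng.normal(size=500)
        v[100:130] += 8.0
        scores = window_pvalues(rank_transform(v), wmax=50)
        bricks = call_bricks(
            scores,
            make_map(500),
            short_range=ShortRangeWindow("chrT", 0, 500_000),
            method="bh",
        )
        assert any(b.start < 130_000 and b.end > 100_000 for b in bricks)


def brick(start_frag, end_frag, p=1e-6, frag=1_000):
    return Brick(
        chrom="chrT",
        start=start_frag * frag,
        end=end_frag * frag,
        start_frag=start_frag,
        end_frag=end_frag,
        window_w=end_frag - start_frag,
        p_value=p,
        tier="long_range",
    )


class TestMergeBricks:
    def test_adjacent_bricks_merge(self):
        regions = merge_bricks([brick(0, 5), brick(5, 9)])
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (0, 9_000)
        assert regions[0].summary_p == 1e-6

    def test_distant_bricks_stay_separate(self):
        regions = merge_bricks([brick(0, 5), brick(10, 12)], merge_gap=1)
        assert len(regions) == 2

    def test_idempotence_on_random_sets(self, rng):
        for _ in range(20):
            starts = np.unique(rng.integers(0, 200, size=10))
            bricks = []
            prev_end = 0
            for s in starts:
                if s < prev_end:
                    continue
                e = s + int(rng.integers(1, 6))
                bricks.append(brick(s, e))
                prev_end = e
            once = merge_bricks(bricks, merge_gap=2)
            again = merge_bricks(
                [brick(r.start_frag, r.end_frag, r.summary_p) for r in once],
                merge_gap=2,
            )
            assert [(r.start_frag, r.end_frag) for r in once] == [
                (r.start_frag, r.end_frag) for r in again
            ]

    def test_overlapping_input_rejected(self):
        with pytest.raises(ValueError):
            merge_bricks([brick(0, 5), brick(3, 8)])
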