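"""Differential interaction analysis between two conditions.

The case/control contrast is a per-fragment log2 ratio of the smoothed
tracks (the power-law background is identical in both conditions and cancels
in the ratio, so a hemizygous deletion shows up directly as log2 ~ -1).
Ratio Bricks — interactions significantly gained or lost in the case — are
called by running the domainogram twice on the ratio track, once on the
natural ordering (gains) and once on the reversed ordering (losses), then
filtered: cross-set overlaps removed, genome gaps subtracted, and candidates
anchored to a Brick selected in at least one condition.  A Wilcoxon rank-sum
test checks that selected regions carry more reads than the remaining
Bricks, and interval-level change is summarized as a bootstrap median CI.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .domainogram import (
    Brick,
    InteractingRegion,
    ShortRangeWindow,
    call_bricks,
    merge_bricks,
    rank_transform,
    window_pvalues,
)
from .enrichment import subtract_intervals
from .fragmap import CountTrack, FragmentMap
from .signal import SignalTrack

logger = logging.getLogger(__name__)

__all__ = [
    "RatioTrack",
    "RatioBrickSet",
    "RegionTestResult",
    "log2_ratio",
    "ratio_bricks",
    "remove_cross_overlaps",
    "subtract_gaps_from_bricks",
    "ranksum_test",
    "region_count_test",
    "interval_change_summary",
]


@dataclass
class RatioTrack:
    """Per-fragment log2(case/control), pseudocount-stabilized."""

    fmap: FragmentMap
    values: np.ndarray
    pseudocount: float
    case_condition: str
    ctrl_condition: str
    input_stage: str


@dataclass
class RatioBrickSet:
    """Signed differential Bricks plus per-filter provenance counts."""

    positive: list[Brick]
    negative: list[Brick]
    provenance: dict = field(default_factory=dict)

    @property
    def all_bricks(self) -> list[Brick]:
        return sorted(self.positive + self.negative, key=lambda b: b.start)


@dataclass
class RegionTestResult:
    statistic: float
    p_value: float
    n_regions: int
    n_outside_bricks: int
    method: str


def default_pseudocount(*tracks: SignalTrack) -> float:
    """5% of the median positive signal over the supplied tracks."""
    pooled = np.concatenate([t.values for t in tracks])
    pos = pooled[np.isfinite(pooled) & (pooled > 0)]
    if pos.size == 0:
        raise ValueError("no positive signal to derive a pseudocount from")
    return 0.05 * float(np.median(pos))


def log2_ratio(
    case: SignalTrack,
    ctrl: SignalTrack,
    eps: float | None = None,
) -> RatioTrack:
    """log2((max(case,0)+eps) / (max(ctrl,0)+eps)) per fragment.

    Negative residuals are floored at zero before the ratio so the
    pseudocount keeps every value finite.  ``eps`` defaults to 5% of the
    pooled median positive signal.  Swapping case and control negates the
    track exactly.
    """
    if case.values.size != ctrl.values.size:
        raise ValueError("case and control tracks differ in length")
    if case.stage != ctrl.stage:
        raise ValueError("case and control tracks must be at the same stage")
    if eps is None:
        eps = default_pseudocount(case, ctrl)
    if eps <= 0:
        raise ValueError("pseudocount eps must be > 0")
    a = np.maximum(case.values, 0.0) + eps
    b = np.maximum(ctrl.values, 0.0) + eps
    r = np.log2(a / b)
    r[~(np.isfinite(case.values) & np.isfinite(ctrl.values))] = np.nan
    return RatioTrack(
        fmap=case.fmap,
        values=r,
        pseudocount=eps,
        case_condition=case.condition,
        ctrl_condition=ctrl.condition,
        input_stage=case.stage,
    )


def _bricks_to_intervals(bricks: list[Brick]) -> np.ndarray:
    return np.asarray([[b.start, b.end] for b in bricks], dtype=np.int64).reshape(-1, 2)


def _regions_as_bricks(regions: list[InteractingRegion], sign: str) -> list[Brick]:
    return [
        Brick(
            chrom=r.chrom,
            start=r.start,
            end=r.end,
            start_frag=r.start_frag,
            end_frag=r.end_frag,
            window_w=r.end_frag - r.start_frag,
            p_value=r.summary_p,
            tier=r.member_bricks[0].tier,
            sign=sign,
        )
        for r in regions
    ]


def _overlap_len(a: Brick, b: Brick) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def ratio_bricks(
    ratio: RatioTrack,
    ctrl_bricks: list[Brick],
    case_bricks: list[Brick],
    gaps=None,
    short_range: ShortRangeWindow | None = None,
    fdr_short: float = 0.1,
    fdr_long: float = 0.001,
    wmax: int = 200,
    merge_gap: int = 1,
    overlap_threshold: float = 0.05,
    overlap_mode: str = "shorter",
) -> RatioBrickSet:
    """Call and filter signed differential Bricks on a log2-ratio track.

    Steps: (1) domainogram Brick calling on the ratio track with natural
    ordering (candidate gains) and reversed ordering (candidate losses),
    each grouped into consecutive runs; (2) any gain/loss pair overlapping
    by more than ``overlap_threshold`` of the shorter member (or
    reciprocally, with ``overlap_mode="reciprocal"``) is dropped from both
    sets; (3) genome gaps are subtracted from Brick spans, splitting
    bisected Bricks; (4) candidates with no overlap with a Brick selected in
    either condition are discarded.
    """
    fmap = ratio.fmap

    def _call(values: np.ndarray, sign: str) -> list[Brick]:
        u = rank_transform(values)
        scores = window_pvalues(u, wmax=min(wmax, u.size))
        bricks = call_bricks(
            scores,
            fmap,
            short_range=short_range,
            fdr_short=fdr_short,
            fdr_long=fdr_long,
            sign=sign,
        )
        return _regions_as_bricks(merge_bricks(bricks, merge_gap=merge_gap), sign)

    positive = _call(ratio.values, "positive")
    negative = _call(-ratio.values, "negative")
    provenance = {"candidates": (len(positive), len(negative))}

    # step 2: cross-set overlap removal
    n_pos, n_neg = len(positive), len(negative)
    positive, negative = remove_cross_overlaps(
        positive, negative, threshold=overlap_threshold, mode=overlap_mode
    )
    provenance["cross_overlap_removed"] = (n_pos - len(positive), n_neg - len(negative))

    # step 3: gap subtraction (splits bisected Bricks)
    if gaps is None:
        logger.warning("no genome-gap intervals supplied; gap filter skipped")
        provenance["gap_filter"] = "skipped"
    else:
        positive = subtract_gaps_from_bricks(positive, gaps, fmap)
        negative = subtract_gaps_from_bricks(negative, gaps, fmap)
        provenance["gap_filter"] = "applied"

    # step 4: anchor to condition Bricks
    anchors = ctrl_bricks + case_bricks
    n_before = (len(positive), len(negative))
    positive = [b for b in positive if any(_overlap_len(b, a) > 0 for a in anchors)]
    negative = [b for b in negative if any(_overlap_len(b, a) > 0 for a in anchors)]
    provenance["unanchored_removed"] = (
        n_before[0] - len(positive),
        n_before[1] - len(negative),
    )
    return RatioBrickSet(positive=positive, negative=negative, provenance=provenance)


def remove_cross_overlaps(
    positive: list[Brick],
    negative: list[Brick],
    threshold: float = 0.05,
    mode: str = "shorter",
) -> tuple[list[Brick], list[Brick]]:
    """Drop every gain/loss pair overlapping by more than the threshold.

    ``mode="shorter"``: overlap measured as a fraction of the shorter
    member; ``mode="reciprocal"``: the fraction must exceed the threshold
    for both members.  Conflicting Bricks are removed from both sets.
    """
    drop_pos, drop_neg = set(), set()
    for i, p in enumerate(positive):
        for j, n in enumerate(negative):
            ov = _overlap_len(p, n)
            if ov == 0:
                continue
            len_p = p.end - p.start
            len_n = n.end - n.start
            if mode == "shorter":
                conflict = ov / min(len_p, len_n) > threshold
            elif mode == "reciprocal":
                conflict = (ov / len_p > threshold) and (ov / len_n > threshold)
            else:
                raise ValueError(f"unknown overlap mode {mode!r}")
            if conflict:
                drop_pos.add(i)
                drop_neg.add(j)
    return (
        [p for i, p in enumerate(positive) if i not in drop_pos],
        [n for j, n in enumerate(negative) if j not in drop_neg],
    )


def subtract_gaps_from_bricks(
    bricks: list[Brick], gaps, fmap: FragmentMap
) -> list[Brick]:
    out: list[Brick] = []
    for b in bricks:
        pieces = subtract_intervals(np.array([[b.start, b.end]]), gaps)
        for s, e in pieces:
            s, e = int(s), int(e)
            out.append(
                Brick(
                    chrom=b.chrom,
                    start=s,
                    end=e,
                    start_frag=fmap.locate(s),
                    end_frag=fmap.locate(e - 1) + 1,
                    window_w=b.window_w,
                    p_value=b.p_value,
                    tier=b.tier,
                    sign=b.sign,
                )
            )
    out.sort(key=lambda b: b.start)
    return out


def ranksum_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney).

    Uses the exact null when the smaller sample has <= 10 observations and
    there are no cross-sample ties, the tie-corrected normal approximation
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        warnings.warn("all observations tied; rank-sum p set to 1")
        return 0.0, 1.0, "degenerate"
    ties = np.unique(pooled).size < pooled.size
    if min(a.size, b.size) <= 10 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0)), method


def region_count_test(
    ctrl_counts: CountTrack,
    case_counts: CountTrack,
    ratio_regions: list[InteractingRegion],
    all_bricks: list[Brick],
) -> RegionTestResult:
    """Do selected ratio regions carry more reads than the other Bricks?

    Sample A: per-region mean over member Bricks of log(ctrl+case reads + 1);
    sample B: the same per-Brick quantity for Bricks outside every region.
    """
    combined = ctrl_counts.counts + case_counts.counts

    def brick_log_count(b: Brick) -> float:
        return float(np.log(combined[b.start_frag : b.end_frag].sum() + 1.0))

    sample_a = np.array(
        [np.mean([brick_log_count(b) for b in r.member_bricks]) for r in ratio_regions]
    )
    outside = [
        b
        for b in all_bricks
        if not any(
            b.start_frag < r.end_frag and r.start_frag < b.end_frag
            for r in ratio_regions
        )
    ]
    sample_b = np.array([brick_log_count(b) for b in outside])
    if sample_a.size == 0 or sample_b.size == 0:
        raise ValueError("need at least one region and one outside Brick")
    statistic, p, method = ranksum_test(sample_a, sample_b)
    return RegionTestResult(
        statistic=statistic,
        p_value=p,
        n_regions=int(sample_a.size),
        n_outside_bricks=int(sample_b.size),
        method=method,
    )


def interval_change_summary(
    ratio: RatioTrack,
    interval: tuple[int, int],
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Median log2 change over an interval with a 95% bootstrap CI.

    Fragments whose midpoint falls in the interval contribute; the CI is the
    percentile interval of the median over ``n_boot`` fragment-level
    resamples.
    """
    start, end = interval
    mid = ratio.fmap.midpoints
    vals = ratio.values[(mid >= start) & (mid < end)]
    vals = vals[np.isfinite(vals)]
    if vals.size < 5:
        raise ValueError(
            f"interval [{start}, {end}) covers only {vals.size} usable fragments"
        )
    median = float(np.median(vals))
    rng = np.random.default_rng(seed)
    boots = np.median(
        rng.choice(vals, size=(n_boot, vals.size), replace=True), axis=1
    )
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return median, float(lo), float(hi)
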