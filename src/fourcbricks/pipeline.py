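"""Convenience orchestration of the per-viewpoint analysis chain."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .differential import RatioTrack, log2_ratio
from .domainogram import (
    Brick,
    InteractingRegion,
    ShortRangeWindow,
    call_bricks,
    merge_bricks,
    rank_transform,
    window_pvalues,
)
from .fragmap import CountTrack
from .signal import (
    SignalTrack,
    average_replicates,
    fit_background,
    normalize,
    profile_correct,
    running_mean,
)

__all__ = ["ConditionTracks", "process_condition", "call_regions", "condition_ratio"]


@dataclass
class ConditionTracks:
    """All processing stages for one viewpoint/condition.

    ``smoothed`` and ``corrected`` follow the display/ratio chain
    (normalize -> 19-fragment running mean -> replicate average ->
    background subtraction).  ``calling`` is the track the domainogram
    scores: per-fragment significance of the pooled *unsmoothed* replicate
    counts against the fitted background.  Pre-smoothing correlates
    neighboring ranks (the multi-scale windows themselves are the
    smoother), and plain subtraction leaves residual scale and skewness
    varying with distance, so neither yields the exchangeable null ranks
    the window statistic needs — see :func:`process_condition`.
    """

    smoothed: SignalTrack
    corrected: SignalTrack
    calling: SignalTrack
    model: "object" = None


def process_condition(
    tracks: list[CountTrack],
    scale: float = 1e6,
    smooth_w: int = 19,
    fit_range: tuple[float, float] | None = None,
    calling_statistic: str = "quantile",
    calling_seed: int = 0,
) -> ConditionTracks:
    """normalize -> smooth -> average replicates -> profile-correct.

    The Brick-calling track is built from the pooled replicate counts and
    the fitted background as randomized quantile (probability-integral)
    residuals of the Poisson null: z_i = Phi^-1(F(T_i - 1) + U_i f(T_i))
    with T_i the pooled count and F, f the Poisson cdf/pmf at the expected
    pooled count.  Under the null these are iid standard normal for every
    fragment regardless of its expected depth, which is exactly the
    exchangeability the rank-window statistic assumes; subtraction- or
    Pearson-style residuals leave count-class artifacts (for a fixed count,
    the residual varies monotonically with distance) that masquerade as
    coherent distal signal.  ``calling_statistic="pearson"`` gives
    (T - m) / sqrt(m) instead; the randomization uses ``calling_seed``.
    """
    normalized = [normalize(t, scale=scale) for t in tracks]
    smoothed = average_replicates([running_mean(t, w=smooth_w) for t in normalized])
    # fit on the unsmoothed average: pre-smoothing correlates neighboring
    # fragments, cutting the effective sample size of the robust floor
    # estimate ~w-fold without changing its expectation
    model = fit_background(average_replicates(normalized), fit_range=fit_range)
    corrected = profile_correct(smoothed, model)

    fmap = tracks[0].fmap
    vp = tracks[0].viewpoint
    d = np.maximum(np.abs(fmap.midpoints - vp.position), 1.0)
    expected_norm = model.expected(d)
    total = np.sum([t.counts for t in tracks], axis=0).astype(np.int64)
    m = expected_norm * sum(t.library_size for t in tracks) / scale
    m = np.maximum(m, 1e-12)
    if calling_statistic == "quantile":
        rng = np.random.default_rng(calling_seed)
        u = stats.poisson.cdf(total - 1, m) + rng.random(m.size) * stats.poisson.pmf(
            total, m
        )
        values = stats.norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))
    elif calling_statistic == "pearson":
        values = (total - m) / np.sqrt(m)
    else:
        raise ValueError(f"unknown calling_statistic {calling_statistic!r}")
    values[vp.exclusion_mask(fmap)] = np.nan
    calling = SignalTrack(
        fmap=fmap,
        viewpoint=vp,
        condition=tracks[0].condition,
        stage="corrected",
        values=values,
        scale_factor=scale,
    )
    return ConditionTracks(
        smoothed=smoothed, corrected=corrected, calling=calling, model=model
    )


def call_regions(
    corrected: SignalTrack,
    short_range: ShortRangeWindow | None = None,
    fdr_short: float = 0.1,
    fdr_long: float = 0.001,
    wmax: int = 200,
    merge_gap: int = 1,
) -> tuple[list[Brick], list[InteractingRegion]]:
    """Domainogram scoring, Brick calling and merging on a corrected track."""
    u = rank_transform(corrected.values)
    scores = window_pvalues(u, wmax=min(wmax, u.size))
    bricks = call_bricks(
        scores,
        corrected.fmap,
        short_range=short_range,
        fdr_short=fdr_short,
        fdr_long=fdr_long,
    )
    return bricks, merge_bricks(bricks, merge_gap=merge_gap)


def condition_ratio(
    case: ConditionTracks, ctrl: ConditionTracks, eps: float | None = None
) -> RatioTrack:
    """Default condition contrast: log2 ratio of the smoothed tracks.

    The distance-decay background is common to both conditions and cancels
    in the ratio, so copy-number effects (a hemizygous deletion is an
    expected two-fold drop) appear directly as log2 = -1.
    """
    return log2_ratio(case.smoothed, ctrl.smoothed, eps=eps)
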