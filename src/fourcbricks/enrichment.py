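"""Permutation enrichment of interacting regions in genomic features.

Implements shuffleBed-style random placement of regions on the chromosome
(outside excluded gaps, lengths preserved, overlaps among shuffled regions
allowed), sweep-based overlap statistics, gene density of region unions and
the per-viewpoint coverage/overlap matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FeatureSet",
    "EnrichmentResult",
    "merge_intervals",
    "intersect_intervals",
    "subtract_intervals",
    "total_length",
    "shuffle_regions",
    "overlap_statistic",
    "permutation_enrichment",
    "gene_density",
    "coverage_matrix",
]


@dataclass
class FeatureSet:
    """Named interval set on one chromosome (0-based half-open).

    Intervals are kept sorted by start; they may overlap each other
    (e.g. nested gene isoforms).
    """

    name: str
    chrom: str
    intervals: np.ndarray  # (n, 2)
    kind: str = "genes"  # genes | marks | regulatory | gaps

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=np.int64).reshape(-1, 2)
        if iv.size and np.any(iv[:, 1] <= iv[:, 0]):
            raise ValueError("intervals must have positive length")
        self.intervals = iv[np.argsort(iv[:, 0], kind="stable")]

    def __len__(self) -> int:
        return int(self.intervals.shape[0])


@dataclass
class EnrichmentResult:
    """Observed overlap vs its permutation null."""

    observed: float
    null_draws: np.ndarray
    n_permutations: int
    seed: int
    mode: str
    alternative: str

    @property
    def p_empirical(self) -> float:
        if self.alternative == "greater":
            extreme = np.sum(self.null_draws >= self.observed)
        else:
            extreme = np.sum(self.null_draws <= self.observed)
        return float((1 + extreme) / (self.n_permutations + 1))


def _as_intervals(x) -> np.ndarray:
    if isinstance(x, FeatureSet):
        return x.intervals
    iv = np.asarray(x, dtype=np.int64).reshape(-1, 2)
    return iv[np.argsort(iv[:, 0], kind="stable")]


def merge_intervals(intervals) -> np.ndarray:
    """Union of intervals as a sorted non-overlapping set."""
    iv = _as_intervals(intervals)
    if iv.shape[0] == 0:
        return iv
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def intersect_intervals(a, b) -> np.ndarray:
    """Intersection of two interval unions (sorted sweep)."""
    A = merge_intervals(a)
    B = merge_intervals(b)
    out = []
    i = j = 0
    while i < len(A) and j < len(B):
        s = max(A[i, 0], B[j, 0])
        e = min(A[i, 1], B[j, 1])
        if s < e:
            out.append((s, e))
        if A[i, 1] <= B[j, 1]:
            i += 1
        else:
            j += 1
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def subtract_intervals(a, b) -> np.ndarray:
    """Parts of each interval of ``a`` not covered by union ``b``.

    Intervals of ``a`` are processed independently (no merging), so a
    bisected interval splits into pieces.
    """
    B = merge_intervals(b)
    out = []
    for s, e in _as_intervals(a):
        cur = s
        for bs, be in B:
            if be <= cur:
                continue
            if bs >= e:
                break
            if bs > cur:
                out.append((cur, min(bs, e)))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def total_length(intervals) -> int:
    m = merge_intervals(intervals)
    if m.shape[0] == 0:
        return 0
    return int((m[:, 1] - m[:, 0]).sum())


def _hits(query, targets) -> np.ndarray:
    """Boolean: which query intervals overlap the union of targets."""
    Q = _as_intervals(query)
    T = merge_intervals(targets)
    if Q.shape[0] == 0 or T.shape[0] == 0:
        return np.zeros(Q.shape[0], dtype=bool)
    # target starting before query end ...
    k = np.searchsorted(T[:, 0], Q[:, 1], side="left") - 1
    hit = np.zeros(Q.shape[0], dtype=bool)
    valid = k >= 0
    hit[valid] = T[k[valid], 1] > Q[valid, 0]  # ... and ending after query start
    return hit


def overlap_statistic(regions, features, mode: str = "region_hits") -> float:
    """Overlap of a region set with a feature set.

    ``region_hits``: number of regions touching >=1 feature;
    ``feature_hits``: number of features touching >=1 region;
    ``bp``: intersection length of the two unions (symmetric).
    """
    if mode == "region_hits":
        return float(_hits(regions, features).sum())
    if mode == "feature_hits":
        return float(_hits(features, regions).sum())
    if mode == "bp":
        inter = intersect_intervals(regions, features)
        return float(0 if inter.shape[0] == 0 else (inter[:, 1] - inter[:, 0]).sum())
    raise ValueError(f"unknown overlap mode {mode!r}")


def shuffle_regions(
    regions,
    chrom_length: int,
    excluded=None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Place each region independently and uniformly outside excluded gaps.

    Lengths are preserved and shuffled regions may overlap each other
    (shuffleBed default semantics).  Valid start offsets are enumerated
    exactly, so every admissible placement is equally likely; a region
    longer than every allowed stretch raises.
    """
    rng = rng if rng is not None else np.random.default_rng()
    iv = _as_intervals(regions)
    if excluded is not None and len(_as_intervals(excluded)):
        allowed = subtract_intervals(
            np.array([[0, chrom_length]]), _as_intervals(excluded)
        )
    else:
        allowed = np.array([[0, chrom_length]], dtype=np.int64)
    out = np.empty_like(iv)
    for r, (s, e) in enumerate(iv):
        length = e - s
        slots = np.maximum(allowed[:, 1] - allowed[:, 0] - length + 1, 0)
        total = int(slots.sum())
        if total <= 0:
            raise ValueError(
                f"region of length {length} does not fit in any allowed stretch"
            )
        t = int(rng.integers(total))
        k = int(np.searchsorted(np.cumsum(slots), t, side="right"))
        offset = t - (int(np.cumsum(slots)[k - 1]) if k else 0)
        start = int(allowed[k, 0]) + offset
        out[r] = (start, start + length)
    return out


def permutation_enrichment(
    regions,
    features,
    chrom_length: int,
    n_permutations: int = 10_000,
    mode: str = "region_hits",
    excluded=None,
    seed: int = 0,
    alternative: str = "greater",
) -> EnrichmentResult:
    """Empirical one-sided enrichment test with +1 smoothing.

    p = (1 + #{null >= observed}) / (N + 1), never exactly zero.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    observed = overlap_statistic(regions, features, mode=mode)
    null = np.empty(n_permutations)
    for k in range(n_permutations):
        shuffled = shuffle_regions(regions, chrom_length, excluded=excluded, rng=rng)
        null[k] = overlap_statistic(shuffled, features, mode=mode)
    return EnrichmentResult(
        observed=observed,
        null_draws=null,
        n_permutations=n_permutations,
        seed=seed,
        mode=mode,
        alternative=alternative,
    )


def gene_density(regions, genes) -> float:
    """Genes (any overlap with the region union) per kilobase of union."""
    union = merge_intervals(regions)
    length = total_length(union)
    if length == 0:
        raise ValueError("region union has zero length")
    n_genes = int(_hits(genes, union).sum())
    return n_genes / (length / 1000.0)


def coverage_matrix(brick_sets: dict[str, np.ndarray], chrom_length: int) -> np.ndarray:
    """Percent chromosome coverage (diagonal) and pairwise shared coverage.

    ``brick_sets`` maps viewpoint name to its Brick intervals; entry (a, b)
    is 100 * bp(union_a intersect union_b) / chrom_length, so the matrix is
    symmetric with per-viewpoint coverage on the diagonal.
    """
    names = list(brick_sets)
    if len(names) < 2:
        raise ValueError("need at least two viewpoints")
    unions = [merge_intervals(brick_sets[n]) for n in names]
    k = len(names)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            if i == j:
                bp = total_length(unions[i])
            else:
                bp = overlap_statistic(unions[i], unions[j], mode="bp")
            mat[i, j] = mat[j, i] = 100.0 * bp / chrom_length
    return mat
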