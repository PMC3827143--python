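"""Restriction-fragment coordinate system for 4C-seq.

4C-seq signal lives on the virtual library of restriction fragments produced
by digesting the genome with the primary cutter (BglII, ``AGATCT``, in the
assay this package models).  This module builds that coordinate system from
sequence, assigns aligned-read positions to fragments, and applies the
self-ligation / undigested-circle filter around the viewpoint.

All coordinates are 0-based half-open (BED convention).  Cuts are placed at
the motif start: the analysis only requires a consistent tiling, not the
in-vitro overhang position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BGLII_MOTIF = "AGATCT"

__all__ = [
    "BGLII_MOTIF",
    "FragmentMap",
    "ViewpointSpec",
    "CountTrack",
    "digest_genome",
    "assign_reads",
    "read_count_table",
    "write_count_table",
]


class FormatError(ValueError):
    """A file did not conform to the expected tabular layout."""


@dataclass(frozen=True)
class FragmentMap:
    """Ordered, gap-free tiling of one chromosome by restriction fragments.

    Parameters
    ----------
    chrom
        Chromosome name.
    starts, ends
        Fragment boundaries, 0-based half-open.  ``starts[0] == 0``,
        ``ends[-1]`` equals the chromosome length, and
        ``ends[i] == starts[i+1]`` for every internal boundary.
    enzyme_motif
        Recognition sequence of the cutter used to build the map.
    """

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    enzyme_motif: str = BGLII_MOTIF

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=np.int64)
        ends = np.asarray(self.ends, dtype=np.int64)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        if starts.size == 0:
            raise ValueError("FragmentMap needs at least one fragment")
        if starts.size != ends.size:
            raise ValueError("starts and ends differ in length")
        if starts[0] != 0:
            raise ValueError("first fragment must start at 0")
        if np.any(ends <= starts):
            raise ValueError("fragments must have positive length")
        if np.any(starts[1:] != ends[:-1]):
            raise ValueError("fragments must tile the chromosome without gaps")

    @property
    def n_fragments(self) -> int:
        return int(self.starts.size)

    def __len__(self) -> int:
        return self.n_fragments

    @property
    def chrom_length(self) -> int:
        return int(self.ends[-1])

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def midpoints(self) -> np.ndarray:
        """Fragment midpoints, the distance reference for decay models."""
        return (self.starts + self.ends) / 2.0

    def locate(self, position: int) -> int:
        """Index of the fragment containing ``position`` (half-open)."""
        if position < 0 or position >= self.chrom_length:
            raise ValueError(
                f"position {position} outside chromosome "
                f"[0, {self.chrom_length}) of {self.chrom}"
            )
        return int(np.searchsorted(self.starts, position, side="right") - 1)

    def to_frame(self) -> pd.DataFrame:
        """BED4-style table (chrom, start, end, fragment_id)."""
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.starts,
                "end": self.ends,
                "name": [f"frag_{i}" for i in range(self.n_fragments)],
            }
        )


@dataclass(frozen=True)
class ViewpointSpec:
    """A 4C bait: the fragment anchoring the experiment.

    ``exclusion_k`` fragments on each side of the viewpoint fragment are
    masked as self-ligation / undigested-circle artifacts.
    """

    name: str
    chrom: str
    position: int
    exclusion_k: int = 2

    def __post_init__(self) -> None:
        if self.exclusion_k < 0:
            raise ValueError("exclusion_k must be >= 0")

    def fragment_index(self, fmap: FragmentMap) -> int:
        if fmap.chrom != self.chrom:
            raise ValueError(
                f"viewpoint on {self.chrom} but fragment map is {fmap.chrom}"
            )
        return fmap.locate(self.position)

    def excluded_fragments(self, fmap: FragmentMap) -> tuple[int, int]:
        """Half-open fragment-index range masked around the viewpoint."""
        vp = self.fragment_index(fmap)
        lo = max(0, vp - self.exclusion_k)
        hi = min(fmap.n_fragments, vp + self.exclusion_k + 1)
        return lo, hi

    def exclusion_mask(self, fmap: FragmentMap) -> np.ndarray:
        mask = np.zeros(fmap.n_fragments, dtype=bool)
        lo, hi = self.excluded_fragments(fmap)
        mask[lo:hi] = True
        return mask


@dataclass
class CountTrack:
    """Per-fragment read counts for one viewpoint/condition/replicate.

    Counts at the masked viewpoint-adjacent fragments are zero and
    ``library_size`` is the sum of the retained counts.
    """

    fmap: FragmentMap
    viewpoint: ViewpointSpec
    condition: str
    replicate: str
    counts: np.ndarray
    library_size: int = field(init=False)
    n_discarded_viewpoint: int = 0
    n_out_of_bounds: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.size != self.fmap.n_fragments:
            raise ValueError(
                f"{counts.size} counts for {self.fmap.n_fragments} fragments"
            )
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        self.counts = counts
        self.library_size = int(counts.sum())
        if self.library_size == 0:
            logger.warning(
                "empty count track for viewpoint %s (%s/%s)",
                self.viewpoint.name,
                self.condition,
                self.replicate,
            )

    @classmethod
    def from_raw_counts(
        cls,
        raw_counts: np.ndarray,
        fmap: FragmentMap,
        viewpoint: ViewpointSpec,
        condition: str = "cond",
        replicate: str = "rep1",
    ) -> "CountTrack":
        """Apply the viewpoint artifact filter to unfiltered counts."""
        raw = np.asarray(raw_counts, dtype=np.int64)
        mask = viewpoint.exclusion_mask(fmap)
        filtered = raw.copy()
        filtered[mask] = 0
        return cls(
            fmap=fmap,
            viewpoint=viewpoint,
            condition=condition,
            replicate=replicate,
            counts=filtered,
            n_discarded_viewpoint=int(raw[mask].sum()),
        )


def _validate_motif(motif: str) -> str:
    if not motif:
        raise ValueError("motif must be non-empty")
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    return motif


def find_motif_starts(sequence: str, motif: str) -> list[int]:
    """All (possibly overlapping) occurrence starts of ``motif``."""
    hits = []
    pos = sequence.find(motif)
    while pos != -1:
        hits.append(pos)
        pos = sequence.find(motif, pos + 1)
    return hits


def digest_genome(
    sequences: dict[str, str], motif: str = BGLII_MOTIF
) -> dict[str, FragmentMap]:
    """In-silico digestion: one FragmentMap per chromosome.

    A cut is placed at each motif start.  A motif at position 0 yields a
    zero-length leading piece which is trimmed, so the first fragment always
    starts at 0; the last fragment ends at the sequence length, hence
    fragment lengths always sum to the chromosome length.
    """
    motif = _validate_motif(motif)
    out: dict[str, FragmentMap] = {}
    for chrom, seq in sequences.items():
        if not seq:
            raise ValueError(f"empty sequence for {chrom}")
        seq = seq.upper()
        cuts = [p for p in find_motif_starts(seq, motif) if 0 < p < len(seq)]
        bounds = [0, *cuts, len(seq)]
        starts = np.asarray(bounds[:-1], dtype=np.int64)
        ends = np.asarray(bounds[1:], dtype=np.int64)
        out[chrom] = FragmentMap(chrom=chrom, starts=starts, ends=ends, enzyme_motif=motif)
    return out


def assign_reads(
    read_positions: np.ndarray,
    fmap: FragmentMap,
    viewpoint: ViewpointSpec,
    condition: str = "cond",
    replicate: str = "rep1",
) -> CountTrack:
    """Count reads per fragment, discarding viewpoint-zone artifacts.

    ``read_positions`` is either a 1-D array of 5' coordinates or an (n, 2)
    array of intervals, in which case the 5' coordinate (interval start) is
    used.  Boundary ties resolve to the fragment starting at that coordinate
    (half-open convention).  Reads outside the chromosome are skipped and
    counted in ``n_out_of_bounds``.
    """
    pos = np.asarray(read_positions)
    if pos.ndim == 2:
        pos = pos[:, 0]
    pos = pos.astype(np.int64)

    in_bounds = (pos >= 0) & (pos < fmap.chrom_length)
    n_oob = int((~in_bounds).sum())
    if n_oob:
        logger.warning(
            "%d reads outside %s [0, %d) skipped", n_oob, fmap.chrom, fmap.chrom_length
        )
    pos = pos[in_bounds]

    idx = np.searchsorted(fmap.starts, pos, side="right") - 1
    raw = np.bincount(idx, minlength=fmap.n_fragments).astype(np.int64)
    track = CountTrack.from_raw_counts(
        raw, fmap, viewpoint, condition=condition, replicate=replicate
    )
    track.n_out_of_bounds = n_oob
    return track


def write_count_table(track: CountTrack, path) -> None:
    """Write a bedGraph-compatible TSV (chrom, start, end, count)."""
    fmap = track.fmap
    df = pd.DataFrame(
        {
            "chrom": fmap.chrom,
            "start": fmap.starts,
            "end": fmap.ends,
            "count": track.counts,
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_count_table(
    path,
    fmap: FragmentMap,
    viewpoint: ViewpointSpec,
    condition: str = "cond",
    replicate: str = "rep1",
) -> CountTrack:
    """Read a per-fragment bedGraph TSV written by :func:`write_count_table`.

    Rows must be in fragment order and match the FragmentMap exactly.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "count"],
            dtype={"chrom": str},
        )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if len(df) != fmap.n_fragments:
        raise FormatError(
            f"{path}: {len(df)} rows for a map of {fmap.n_fragments} fragments"
        )
    for col in ("start", "end", "count"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise FormatError(f"{path}: malformed numeric value in column "
                              f"{col!r} at line {line}")
    starts = df["start"].to_numpy(dtype=np.int64)
    ends = df["end"].to_numpy(dtype=np.int64)
    if not (np.array_equal(starts, fmap.starts) and np.array_equal(ends, fmap.ends)):
        raise FormatError(f"{path}: fragment coordinates do not match the map")
    counts = df["count"].to_numpy(dtype=np.int64)
    return CountTrack.from_raw_counts(
        counts, fmap, viewpoint, condition=condition, replicate=replicate
    )
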