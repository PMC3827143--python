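"""Plain-text genomic file plumbing: FASTA, BED and bedGraph."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .domainogram import Brick, InteractingRegion
from .fragmap import FragmentMap
from .signal import SignalTrack

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed_intervals",
    "write_fragment_bed",
    "read_fragment_bed",
    "write_bedgraph",
    "write_bricks_bed",
]


def read_fasta(path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, rebuild=False)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path) -> dict[str, np.ndarray]:
    """Chromosome -> (n, 2) interval arrays from a BED3+ file."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={"chrom": str},
    )
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        out[chrom] = sub[["start", "end"]].to_numpy(dtype=np.int64)
    return out


def write_bed_intervals(chrom: str, intervals, path, names=None) -> None:
    iv = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    df = pd.DataFrame({"chrom": chrom, "start": iv[:, 0], "end": iv[:, 1]})
    if names is not None:
        df["name"] = list(names)
    df.to_csv(path, sep="\t", header=False, index=False)


def write_fragment_bed(fmap: FragmentMap, path) -> None:
    fmap.to_frame().to_csv(path, sep="\t", header=False, index=False)


def read_fragment_bed(path) -> FragmentMap:
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={"chrom": str},
    )
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("fragment BED must cover exactly one chromosome")
    return FragmentMap(
        chrom=chroms[0],
        starts=df["start"].to_numpy(np.int64),
        ends=df["end"].to_numpy(np.int64),
    )


def write_bedgraph(track: SignalTrack, path) -> None:
    fmap = track.fmap
    pd.DataFrame(
        {
            "chrom": fmap.chrom,
            "start": fmap.starts,
            "end": fmap.ends,
            "value": track.values,
        }
    ).to_csv(path, sep="\t", header=False, index=False, na_rep="nan")


def write_bricks_bed(items: list[Brick] | list[InteractingRegion], path) -> None:
    """BED6: name = tier (or sign for ratio Bricks), score = -log10 p."""
    rows = []
    for it in items:
        if isinstance(it, InteractingRegion):
            name, p = "region", it.summary_p
        else:
            name = it.tier if it.sign == "positive" else f"{it.tier}_{it.sign}"
            p = it.p_value
        rows.append(
            (it.chrom, it.start, it.end, name, round(-np.log10(max(p, 1e-300)), 3), ".")
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
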