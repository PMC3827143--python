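"""Synthetic 4C-seq data with known ground truth.

The generator encodes the minimal structure the analysis statistics assume:
a power-law distance decay of contact frequency around the viewpoint (slope
-1 in log-log space), a uniform background floor from random ligation,
multiplicative planted interaction peaks, replicate sampling noise (Poisson
or negative-binomial), and an optional hemizygous deletion in which the case
condition loses one allele's contacts — an expected two-fold signal drop —
inside the deleted interval.

Defaults model one ~4.1 Mb chromosome cut into ~1000 fragments by a 6-bp
cutter (expected spacing 4^6 = 4096 bp), a viewpoint at 500 kb, three
planted peaks of 4-6 fold, an optional 300 kb deletion starting 0.8 Mb
downstream of the viewpoint that contains one of the peaks, and a library
of 1e5 reads per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .enrichment import FeatureSet
from .fragmap import BGLII_MOTIF, CountTrack, FragmentMap, ViewpointSpec, digest_genome

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_fragment_map",
    "simulate_genome",
    "simulate_counts",
    "simulate_features",
    "default_viewpoint",
    "write_manifest",
]

#: two interaction blocks inside the default deletion interval (the deleted
#: interval interacts extensively with its flanks before the rearrangement)
#: and two outside
DEFAULT_PEAKS = (
    (1_330_000, 1_400_000, 4.0),
    (1_450_000, 1_550_000, 4.0),
    (2_500_000, 2_600_000, 6.0),
    (3_400_000, 3_500_000, 5.0),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated 4C experiment."""

    chrom: str = "chrSim"
    chrom_length: int = 4_100_000
    mean_fragment_length: int = 4096
    viewpoint_position: int = 500_000
    decay_constant: float = 1.0  # c in expected signal c/d
    noise_floor: float = 1e-7  # uniform random-ligation weight per bp-distance unit
    peaks: tuple[tuple[int, int, float], ...] = DEFAULT_PEAKS
    deletion: tuple[int, int] | None = None
    library_size: int = 100_000
    replicates: int = 2
    dispersion: str = "poisson"  # "poisson" | "nb"
    nb_size: float = 10.0
    exclusion_k: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.chrom_length < 10 * self.mean_fragment_length:
            raise ValueError("chromosome too short for the fragment scale")
        for s, e, fold in self.peaks:
            if not (0 <= s < e <= self.chrom_length):
                raise ValueError(f"peak ({s}, {e}) outside chromosome")
            if fold < 1:
                raise ValueError("peak fold must be >= 1")
        if self.deletion is not None:
            s, e = self.deletion
            if not (0 <= s < e <= self.chrom_length):
                raise ValueError("deletion outside chromosome")
        if self.dispersion not in ("poisson", "nb"):
            raise ValueError("dispersion must be 'poisson' or 'nb'")

    def with_deletion(self, start: int = 1_300_000, end: int = 1_600_000):
        """The same experiment with a hemizygous deletion in the case.

        The default interval starts 0.8 Mb from the viewpoint (the real
        viewpoints sit 0.7-1 Mb from the deletion border) and spans ~7% of
        the simulated chromosome, so the deleted interval — as in the real
        chromosome — holds only a small share of the chromosome-wide contact
        mass and total-read normalization is not distorted by its loss.
        """
        return SimulationConfig(
            **{**self.__dict__, "deletion": (start, end)}
        )


@dataclass
class SyntheticTruth:
    """What was planted: peaks, deletion and per-fragment intensities.

    Intensities are relative contact propensities before library scaling;
    inside the deletion the case intensity is exactly half the control
    (one allele lost), outside they are equal.
    """

    peaks: tuple[tuple[int, int, float], ...]
    deletion: tuple[int, int] | None
    expected_control: np.ndarray
    expected_case: np.ndarray

    def peak_mask(self, fmap: FragmentMap, min_fold: float = 1.0) -> np.ndarray:
        mid = fmap.midpoints
        mask = np.zeros(fmap.n_fragments, dtype=bool)
        for s, e, fold in self.peaks:
            if fold >= min_fold:
                mask |= (mid >= s) & (mid < e)
        return mask


def default_viewpoint(config: SimulationConfig) -> ViewpointSpec:
    return ViewpointSpec(
        name="VP",
        chrom=config.chrom,
        position=config.viewpoint_position,
        exclusion_k=config.exclusion_k,
    )


def simulate_fragment_map(config: SimulationConfig) -> FragmentMap:
    """Random restriction map with ~exponential fragment lengths.

    Deterministic in ``config.seed``; the same map underlies every
    condition and replicate of a run.
    """
    rng = np.random.default_rng([config.seed, 1])
    min_len = len(BGLII_MOTIF) + 4  # room to plant non-overlapping motifs
    bounds = [0]
    while True:
        gap = max(min_len, int(rng.exponential(config.mean_fragment_length)))
        nxt = bounds[-1] + gap
        if nxt >= config.chrom_length - min_len:
            break
        bounds.append(nxt)
    bounds.append(config.chrom_length)
    starts = np.asarray(bounds[:-1], dtype=np.int64)
    ends = np.asarray(bounds[1:], dtype=np.int64)
    return FragmentMap(chrom=config.chrom, starts=starts, ends=ends)


def simulate_genome(config: SimulationConfig) -> tuple[str, FragmentMap]:
    """Random sequence whose digestion reproduces the simulated map exactly.

    Accidental cutter motifs in the random background are disrupted, then
    the motif is planted at every internal fragment boundary, so
    ``digest_genome`` on the emitted sequence returns exactly the map.
    """
    fmap = simulate_fragment_map(config)
    rng = np.random.default_rng([config.seed, 2])
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = rng.choice(alphabet, size=config.chrom_length)
    motif = np.frombuffer(BGLII_MOTIF.encode(), dtype=np.uint8)
    planted = fmap.starts[1:]  # internal boundaries are motif starts
    for _ in range(50):
        text = seq.tobytes().decode()
        hits = []
        pos = text.find(BGLII_MOTIF)
        while pos != -1:
            hits.append(pos)
            pos = text.find(BGLII_MOTIF, pos + 1)
        stray = [h for h in hits if h not in set(planted.tolist())]
        if not stray:
            break
        planted_footprint = set()
        for b in planted:
            planted_footprint.update(range(b, b + motif.size))
        for h in stray:
            # mutate a stray position that is not inside a planted motif
            free = [p for p in range(h, h + motif.size) if p not in planted_footprint]
            p = free[0]
            base = seq[p]
            choices = alphabet[alphabet != base]
            seq[p] = rng.choice(choices)
        for b in planted:
            seq[b : b + motif.size] = motif
    else:
        raise RuntimeError("could not stabilize planted motifs")
    # first pass may never have planted; ensure planting happened
    for b in planted:
        seq[b : b + motif.size] = motif
    text = seq.tobytes().decode()
    check = digest_genome({config.chrom: text})[config.chrom]
    if not (
        np.array_equal(check.starts, fmap.starts)
        and np.array_equal(check.ends, fmap.ends)
    ):
        raise RuntimeError("digest of emitted sequence does not match the map")
    return text, fmap


def _intensity(
    config: SimulationConfig, fmap: FragmentMap, condition: str
) -> np.ndarray:
    """Relative per-fragment contact intensity (unnormalized)."""
    mid = fmap.midpoints
    d = np.maximum(np.abs(mid - config.viewpoint_position), 1.0)
    lam = config.decay_constant / d + config.noise_floor
    for s, e, fold in config.peaks:
        lam[(mid >= s) & (mid < e)] *= fold
    if condition == "case" and config.deletion is not None:
        s, e = config.deletion
        lam[(mid >= s) & (mid < e)] *= 0.5
    return lam


def simulate_counts(
    config: SimulationConfig,
    condition: str = "control",
    fmap: FragmentMap | None = None,
) -> tuple[list[CountTrack], SyntheticTruth]:
    """Replicate count tracks plus the planted truth for one condition.

    Expected fragment intensity is (c/d + floor) x peak fold x allele factor
    (0.5 inside the deletion for the case), scaled to the library size;
    replicate counts are Poisson (or negative-binomial) draws.  Fragments in
    the viewpoint exclusion zone receive counts too, so the self-ligation
    filter is genuinely exercised; ``CountTrack`` then masks them.
    """
    if condition not in ("control", "case"):
        raise ValueError("condition must be 'control' or 'case'")
    if fmap is None:
        fmap = simulate_fragment_map(config)
    vp = default_viewpoint(config)
    intensity = _intensity(config, fmap, condition)
    lam = config.library_size * intensity / intensity.sum()
    cond_idx = 0 if condition == "control" else 1
    rng = np.random.default_rng([config.seed, 3, cond_idx])
    tracks = []
    for rep in range(config.replicates):
        if config.dispersion == "poisson":
            raw = rng.poisson(lam)
        else:  # gamma-Poisson mixture = negative binomial with mean lam
            shape = config.nb_size
            raw = rng.poisson(rng.gamma(shape, lam / shape))
        tracks.append(
            CountTrack.from_raw_counts(
                raw, fmap, vp, condition=condition, replicate=f"rep{rep + 1}"
            )
        )
    truth = SyntheticTruth(
        peaks=config.peaks,
        deletion=config.deletion,
        expected_control=_intensity(config, fmap, "control"),
        expected_case=_intensity(config, fmap, "case"),
    )
    return tracks, truth


def simulate_features(
    fmap: FragmentMap,
    truth: SyntheticTruth,
    n_genes: int = 50,
    enrich_prob: float = 0.0,
    seed: int = 0,
    feature_length: int = 2000,
) -> FeatureSet:
    """Feature intervals placed inside planted peaks with prob ``enrich_prob``.

    At ``enrich_prob=0`` features are independent of the truth, giving the
    null for enrichment calibration.
    """
    if not 0.0 <= enrich_prob <= 1.0:
        raise ValueError("enrich_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    L = fmap.chrom_length
    intervals = []
    peaks = [(s, e) for s, e, _ in truth.peaks]
    for _ in range(n_genes):
        if peaks and rng.random() < enrich_prob:
            s, e = peaks[rng.integers(len(peaks))]
            span = max(1, e - s - feature_length)
            start = int(s + rng.integers(span))
        else:
            start = int(rng.integers(max(1, L - feature_length)))
        intervals.append((start, min(start + feature_length, L)))
    return FeatureSet(
        name="sim_genes", chrom=fmap.chrom, intervals=np.asarray(intervals)
    )


def write_manifest(config: SimulationConfig, path) -> None:
    """YAML record of the generating parameters and seed."""
    doc = dict(config.__dict__)
    doc["peaks"] = [list(p) for p in config.peaks]
    if config.deletion is not None:
        doc["deletion"] = list(config.deletion)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
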