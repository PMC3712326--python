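"""Synthetic copy-number profiles with known breakpoints plus annotations.

Profiles are piecewise-constant logratio signals with Gaussian noise on a
small genome of fixed-length chromosomes.  Truth breakpoints are recorded
as midpoints between the flanking probes, matching the breakpoint
extraction convention, so a perfect smoother can recover them exactly.

Two annotation protocols are emulated: ``systematic`` places the same fixed
regions on every profile and labels them [0,0] or [1,inf); ``any`` places
random non-overlapping regions per profile and can also emit exact-count
[1,1] labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cnsmooth.core_data import UNBOUNDED, AnnotatedRegion, ProbeSeries, Profile

#: Per-chromosome minimum probes per segment (relaxed on tiny chromosomes).
_MIN_SEGMENT_PROBES = 5

_MAX_PLACEMENT_RETRIES = 100


def _chromosome_lengths(chrom_count: int) -> dict[str, int]:
    # fixed decreasing lengths so systematic regions coincide across profiles
    return {str(c + 1): int(2.0e8 * 0.75 ** c) for c in range(chrom_count)}


@dataclass(frozen=True)
class ChromosomeTruth:
    """True segmentation of one chromosome of one profile."""

    chromosome: str
    length_bp: int
    boundaries: np.ndarray  # breakpoint positions in bp (probe midpoints)
    means: np.ndarray       # one logratio mean per segment
    m: int

    def __post_init__(self) -> None:
        if len(self.means) != len(self.boundaries) + 1:
            raise ValueError("need exactly one more mean than boundary")


@dataclass
class SyntheticTruth:
    """Ground-truth segmentations for a simulated profile collection."""

    noise_sd: float
    seed: int
    segments: dict[tuple[str, str], ChromosomeTruth] = field(default_factory=dict)

    def breakpoints(self, profile_id: str, chromosome: str) -> np.ndarray:
        return self.segments[(profile_id, chromosome)].boundaries

    def count_in(self, profile_id: str, chromosome: str,
                 start: float, end: float) -> int:
        b = self.breakpoints(profile_id, chromosome)
        return int(np.count_nonzero((b >= start) & (b <= end)))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (pid, chrom, float(pos))
            for (pid, chrom), truth in sorted(self.segments.items())
            for pos in truth.boundaries
        ]
        return pd.DataFrame(rows, columns=["profile_id", "chromosome", "position"])


def _draw_positions(rng: np.random.Generator, m: int, length: int) -> np.ndarray:
    positions = np.unique(rng.integers(1, length + 1, size=m))
    while positions.size < m:
        extra = rng.integers(1, length + 1, size=m - positions.size)
        positions = np.unique(np.concatenate([positions, extra]))
    return positions[:m]


def _draw_cuts(rng: np.random.Generator, m: int, k: int) -> np.ndarray:
    """k-1 sorted probe gap indices with a minimum segment length."""
    if k == 1:
        return np.array([], dtype=np.int64)
    min_seg = max(1, min(_MIN_SEGMENT_PROBES, m // (2 * k)))
    if k * min_seg > m:
        raise ValueError(f"cannot place {k} segments on {m} probes")
    for _ in range(_MAX_PLACEMENT_RETRIES):
        cuts = np.sort(rng.choice(np.arange(1, m), size=k - 1, replace=False))
        seg_sizes = np.diff(np.concatenate([[0], cuts, [m]]))
        if np.all(seg_sizes >= min_seg):
            return cuts
    raise ValueError(f"cannot place {k} segments on {m} probes")


def _draw_means(rng: np.random.Generator, k: int, jump_min: float) -> np.ndarray:
    means = [0.0]
    for _ in range(k - 1):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        means.append(means[-1] + sign * jump_min * (1.0 + rng.random()))
    return np.asarray(means)


def simulate_profiles(
    n_profiles: int,
    chrom_count: int = 4,
    m_range: tuple[int, int] = (150, 250),
    jump_min: float = 1.0,
    noise_sd: float = 0.25,
    segments_per_chrom_range: tuple[int, int] = (1, 4),
    seed: int = 1,
) -> tuple[list[Profile], SyntheticTruth]:
    """Simulate noisy piecewise-constant profiles with recorded truth.

    Probe positions are uniform random (sorted, deduplicated); probe counts
    are drawn per chromosome from ``m_range``; adjacent segment means
    differ by at least ``jump_min``.
    """
    if jump_min <= 0:
        raise ValueError("jump_min must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not (8 <= m_range[0] <= m_range[1] <= 10 ** 5):
        raise ValueError("m_range must lie within [8, 1e5]")
    k_lo, k_hi = segments_per_chrom_range
    if k_lo < 1 or k_lo > k_hi:
        raise ValueError("invalid segments_per_chrom_range")

    rng = np.random.default_rng(seed)
    lengths = _chromosome_lengths(chrom_count)
    truth = SyntheticTruth(noise_sd=noise_sd, seed=seed)
    profiles = []
    width = len(str(n_profiles))
    for i in range(n_profiles):
        pid = f"P{i + 1:0{width}d}"
        chromosomes = {}
        for chrom, length in lengths.items():
            m = int(rng.integers(m_range[0], m_range[1] + 1))
            k = int(rng.integers(k_lo, k_hi + 1))
            positions = _draw_positions(rng, m, length)
            cuts = _draw_cuts(rng, m, k)
            means = _draw_means(rng, k, jump_min)
            signal = np.empty(m)
            bounds = np.concatenate([[0], cuts, [m]]).astype(int)
            for s, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
                signal[lo:hi] = means[s]
            values = signal + rng.normal(0.0, noise_sd, size=m)
            boundaries = (positions[cuts - 1] + positions[cuts]) / 2.0
            chromosomes[chrom] = ProbeSeries(
                chromosome=chrom, positions=positions, values=values,
                length_bp=length)
            truth.segments[(pid, chrom)] = ChromosomeTruth(
                chromosome=chrom, length_bp=length, boundaries=boundaries,
                means=means, m=m)
        profiles.append(Profile(profile_id=pid, chromosomes=chromosomes))
    return profiles, truth


def _label_from_count(count: int, exact_counts: bool) -> tuple[int, float]:
    if count == 0:
        return 0, 0
    if count == 1 and exact_counts:
        return 1, 1
    return 1, UNBOUNDED


def _systematic_regions(lengths: dict[str, int], n_regions: int,
                        region_width: float) -> list[tuple[str, int, int]]:
    """The same fixed regions for every profile, round-robin over
    chromosomes, evenly spaced within each chromosome."""
    chroms = sorted(lengths)
    per_chrom: dict[str, int] = {c: 0 for c in chroms}
    for j in range(n_regions):
        per_chrom[chroms[j % len(chroms)]] += 1
    regions = []
    for chrom in chroms:
        slots = per_chrom[chrom]
        length = lengths[chrom]
        if slots and region_width >= length:
            raise ValueError(f"region_width does not fit chromosome {chrom}")
        for s in range(slots):
            center = length * (s + 1) / (slots + 1)
            start = max(1, int(round(center - region_width / 2)))
            end = min(length, int(round(center + region_width / 2)))
            regions.append((chrom, start, end))
    return regions


def annotate_from_truth(
    truth: SyntheticTruth,
    protocol: str,
    n_regions: int = 6,
    region_width: float = 1.5e7,
    exact_counts: bool = False,
    seed: int = 1,
) -> list[AnnotatedRegion]:
    """Generate truth-consistent annotations under one of two protocols.

    ``systematic`` ignores ``seed`` and ``exact_counts`` apart from
    labeling: the same ``n_regions`` fixed regions are labeled [0,0] or
    [1,inf) on every profile.  ``any`` places ``n_regions`` random
    non-overlapping regions per profile and labels them [0,0], [1,1] (when
    ``exact_counts``) or [1,inf).
    """
    if protocol not in ("systematic", "any"):
        raise ValueError(f"unknown annotation protocol: {protocol!r}")
    profile_ids = sorted({pid for pid, _ in truth.segments})
    lengths = {chrom: t.length_bp
               for (_, chrom), t in truth.segments.items()}

    annotations = []
    if protocol == "systematic":
        regions = _systematic_regions(lengths, n_regions, region_width)
        for pid in profile_ids:
            for chrom, start, end in regions:
                count = truth.count_in(pid, chrom, start, end)
                lo, hi = (0, 0) if count == 0 else (1, UNBOUNDED)
                annotations.append(AnnotatedRegion(
                    profile_id=pid, chromosome=chrom, start=start, end=end,
                    min_breakpoints=lo, max_breakpoints=hi))
        return annotations

    rng = np.random.default_rng(seed)
    chroms = sorted(lengths)
    for pid in profile_ids:
        placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
        for _ in range(n_regions):
            for attempt in range(_MAX_PLACEMENT_RETRIES):
                chrom = chroms[int(rng.integers(len(chroms)))]
                length = lengths[chrom]
                if region_width >= length:
                    raise ValueError(
                        f"region_width does not fit chromosome {chrom}")
                center = rng.uniform(region_width / 2, length - region_width / 2)
                start = max(1, int(round(center - region_width / 2)))
                end = min(length, int(round(center + region_width / 2)))
                if all(end < s or start > e for s, e in placed[chrom]):
                    placed[chrom].append((start, end))
                    break
            else:
                raise ValueError(
                    f"could not place {n_regions} non-overlapping regions "
                    f"on profile {pid}")
            count = truth.count_in(pid, chrom, start, end)
            lo, hi = _label_from_count(count, exact_counts)
            annotations.append(AnnotatedRegion(
                profile_id=pid, chromosome=chrom, start=start, end=end,
                min_breakpoints=lo, max_breakpoints=hi))
    return annotations


def default_benchmark(seed: int = 1):
    """The standard synthetic fixture: 50 profiles, 4 chromosomes, m=200,
    1-4 segments per chromosome, jump 1.0, noise sd 0.25, 6 systematic +
    4 any-protocol regions per profile.

    Returns ``(profiles, truth, annotations)``.
    """
    profiles, truth = simulate_profiles(
        n_profiles=50, chrom_count=4, m_range=(200, 200), jump_min=1.0,
        noise_sd=0.25, segments_per_chrom_range=(1, 4), seed=seed)
    annotations = annotate_from_truth(
        truth, "systematic", n_regions=6, region_width=1.5e7)
    annotations += annotate_from_truth(
        truth, "any", n_regions=4, region_width=1.5e7, exact_counts=True,
        seed=seed + 1)
    return profiles, truth, annotations
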