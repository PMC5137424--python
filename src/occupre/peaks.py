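"""Threshold-and-cluster peak calling.

Significantly immunoprecipitated regions are clusters of per-base
coordinates whose values exceed three standard deviations above the
genomic mean, merged when successive qualifying coordinates are separated
by a gap of at most 500 bp of sub-threshold bases.  The peak summit is the
center of the six consecutive coordinates with the highest read counts
inside the region.  Peaks with no neighboring summit within 10 kb are
flagged "isolated" and suit uncontaminated profile averaging.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .intervals import GenomicInterval
from .tracks import CoverageTrack

logger = logging.getLogger(__name__)


@dataclass
class PeakCall:
    """A significant region with its summit coordinate."""

    region: GenomicInterval
    summit: int
    summit_score: float
    isolated: bool = False

    def __post_init__(self) -> None:
        if not self.region.start <= self.summit < self.region.end:
            raise ValueError(
                f"summit {self.summit} outside region "
                f"{self.region.chrom}:{self.region.start}-{self.region.end}"
            )


def genomic_background(track: CoverageTrack) -> tuple[float, float]:
    """Mean and population SD of per-base values over the whole analyzed
    track, zero-coverage bases included."""
    vals = track.values
    return float(vals.mean()), float(vals.std(ddof=0))


def significant_regions(
    track: CoverageTrack,
    mean: float,
    sd: float,
    k_sd: float = 3.0,
    max_gap: int = 500,
) -> list[GenomicInterval]:
    """Supra-threshold coordinate clusters as half-open intervals.

    A coordinate qualifies when its value exceeds ``mean + k_sd * sd``;
    qualifying coordinates separated by at most ``max_gap`` sub-threshold
    bases belong to one cluster.  Each returned interval spans the first to
    the last qualifying coordinate of its cluster.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    threshold = mean + k_sd * sd
    if sd == 0:
        warnings.warn(
            "zero genomic SD; falling back to mean as threshold", stacklevel=2
        )
        threshold = mean
    qualifying = np.flatnonzero(track.values > threshold)
    if qualifying.size == 0:
        return []
    # gap between successive supra-threshold bases = diff - 1
    breaks = np.flatnonzero(np.diff(qualifying) - 1 > max_gap) + 1
    regions = []
    for chunk in np.split(qualifying, breaks):
        start = int(chunk[0]) + track.origin
        end = int(chunk[-1]) + 1 + track.origin
        regions.append(GenomicInterval(chrom=track.chrom, start=start, end=end))
    logger.info(
        "%d significant regions on %s (threshold %.4g)",
        len(regions), track.chrom, threshold,
    )
    return regions


def summit(track: CoverageTrack, region: GenomicInterval, window: int = 6) -> int:
    """Center of the maximal-sum ``window`` consecutive coordinates inside
    the region (leftmost window wins ties; center = floor of window
    midpoint).  Regions shorter than the window get their midpoint."""
    seg = track.segment(region.start, region.end)
    if seg.size < window:
        warnings.warn(
            f"region {region.chrom}:{region.start}-{region.end} shorter than "
            f"summit window {window}; using region midpoint",
            stacklevel=2,
        )
        return region.start + seg.size // 2
    sums = np.convolve(seg, np.ones(window), mode="valid")
    offset = int(np.argmax(sums))  # argmax returns the leftmost maximum
    return region.start + offset + window // 2


def call_peaks(
    track: CoverageTrack,
    k_sd: float = 3.0,
    max_gap: int = 500,
    window: int = 6,
    isolation_distance: int = 10_000,
) -> list[PeakCall]:
    """Full threshold-and-cluster peak call on one track.

    Clusters containing fewer than ``window`` supra-threshold coordinates
    are discarded: the summit is defined as the center of ``window``
    consecutive coordinates with the highest counts, which a sparser
    cluster cannot support (such clusters are stray noise coordinates).
    """
    mean, sd = genomic_background(track)
    threshold = mean + k_sd * sd if sd > 0 else mean
    regions = significant_regions(track, mean, sd, k_sd=k_sd, max_gap=max_gap)
    peaks = []
    n_sparse = 0
    for region in regions:
        seg = track.segment(region.start, region.end)
        if (seg > threshold).sum() < window:
            n_sparse += 1
            continue
        s = summit(track, region, window=window)
        score = float(np.convolve(seg, np.ones(window), "valid").max() / window)
        peaks.append(PeakCall(region=region, summit=s, summit_score=score))
    if n_sparse:
        logger.info(
            "discarded %d clusters with < %d supra-threshold coordinates",
            n_sparse, window,
        )
    mark_isolated(peaks, min_distance=isolation_distance)
    return peaks


def mark_isolated(peaks: Sequence[PeakCall], min_distance: int = 10_000) -> None:
    """Set the ``isolated`` flag in place: a peak is isolated when its
    nearest-neighbor summit on the same chromosome is strictly more than
    ``min_distance`` away (a lone peak on its chromosome is isolated)."""
    by_chrom: dict[str, list[PeakCall]] = {}
    for p in peaks:
        by_chrom.setdefault(p.region.chrom, []).append(p)
    for group in by_chrom.values():
        group.sort(key=lambda p: p.summit)
        for i, p in enumerate(group):
            dists = []
            if i > 0:
                dists.append(p.summit - group[i - 1].summit)
            if i < len(group) - 1:
                dists.append(group[i + 1].summit - p.summit)
            p.isolated = (not dists) or min(dists) > min_distance


def isolated_peaks(
    peaks: Sequence[PeakCall], min_distance: int = 10_000
) -> list[PeakCall]:
    """Subset of peaks whose nearest-neighbor summit distance exceeds
    ``min_distance`` (strict inequality)."""
    peaks = list(peaks)
    mark_isolated(peaks, min_distance=min_distance)
    return [p for p in peaks if p.isolated]


def write_peaks(peaks: Sequence[PeakCall], path) -> None:
    """Write peaks as BED6+ (narrowPeak-style 0-based summit offset,
    summit score and isolation flag as extra columns)."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            fh.write(
                f"{p.region.chrom}\t{p.region.start}\t{p.region.end}\t"
                f"peak_{i + 1}\t{p.summit_score:g}\t.\t"
                f"{p.summit - p.region.start}\t{int(p.isolated)}\n"
            )


def read_peaks(path) -> list[PeakCall]:
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            region = GenomicInterval(chrom=f[0], start=int(f[1]), end=int(f[2]))
            peaks.append(
                PeakCall(
                    region=region,
                    summit=region.start + int(f[6]),
                    summit_score=float(f[4]),
                    isolated=bool(int(f[7])),
                )
            )
    return peaks
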