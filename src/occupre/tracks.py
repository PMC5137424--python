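"""Per-base coverage tracks: bedGraph I/O, fragment-size estimation and
read extension.

A :class:`CoverageTrack` is a dense per-base array of non-negative read
density over one chromosome.  Dense arrays (rather than run-length trees)
are used because every downstream statistic — 6-bp window means, 3-SD
thresholds, 100-bp bins — is per-base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class CoverageTrack:
    """Dense per-base read density over one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    values : ndarray
        Per-base density, all values >= 0.
    origin : int
        Genome coordinate of ``values[0]`` (0-based).
    total_depth : float, optional
        Total mapped reads the track derives from.  When unset, the sum of
        the values is used for depth normalization.
    """

    chrom: str
    values: np.ndarray
    origin: int = 0
    total_depth: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("track values must be a nonempty 1-D array")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be non-negative")

    def __len__(self) -> int:
        return self.values.size

    @property
    def depth(self) -> float:
        """Depth used for normalization (total_depth, else sum of values)."""
        if self.total_depth is not None:
            if self.total_depth <= 0:
                raise ValueError("total_depth must be > 0 for normalization")
            return float(self.total_depth)
        s = float(self.values.sum())
        if s <= 0:
            raise ValueError("track has zero total signal; cannot normalize")
        return s

    def segment(self, start: int, end: int) -> np.ndarray:
        """Per-base values on genome coordinates [start, end); out-of-track
        bases are zero."""
        if end <= start:
            raise ValueError(f"empty segment [{start}, {end})")
        out = np.zeros(end - start, dtype=float)
        lo = max(start, self.origin)
        hi = min(end, self.origin + len(self))
        if hi > lo:
            out[lo - start : hi - start] = self.values[lo - self.origin : hi - self.origin]
        return out

    def normalized(self, scale: float = 1e6) -> "CoverageTrack":
        """Depth-normalized copy (values x scale / depth)."""
        d = self.depth
        return CoverageTrack(
            chrom=self.chrom,
            values=self.values * (scale / d),
            origin=self.origin,
            total_depth=None,
        )


def average_tracks(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Base-wise mean of same-chromosome, same-origin tracks."""
    if not tracks:
        raise ValueError("no tracks to average")
    chroms = {t.chrom for t in tracks}
    if len(chroms) > 1:
        raise ValueError(f"cannot average tracks from different chromosomes: {chroms}")
    if len({t.origin for t in tracks}) > 1 or len({len(t) for t in tracks}) > 1:
        raise ValueError("tracks must share origin and length to be averaged")
    vals = np.mean([t.values for t in tracks], axis=0)
    return CoverageTrack(chrom=tracks[0].chrom, values=vals, origin=tracks[0].origin)


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def read_bedgraph(path) -> dict[str, CoverageTrack]:
    """Read a bedGraph file into per-chromosome dense tracks.

    Bases not covered by any record are 0.  Records may be unsorted;
    overlapping records with conflicting values are a format error.
    """
    try:
        df = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
            skiprows=_bedgraph_header_rows(path),
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end", "value"])
    if df.empty:
        logger.warning("bedGraph %s contains no records", path)
        return {}
    if (df["value"] < 0).any():
        raise ValueError(f"bedGraph {path}: negative coverage values")
    tracks: dict[str, CoverageTrack] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values(["start", "end"]).reset_index(drop=True)
        length = int(grp["end"].max())
        values = np.zeros(length, dtype=float)
        filled = np.zeros(length, dtype=bool)
        for start, end, value in zip(grp["start"], grp["end"], grp["value"]):
            s, e = int(start), int(end)
            if s < 0 or e <= s:
                raise ValueError(f"bedGraph {path}: invalid interval {chrom}:{s}-{e}")
            region = slice(s, e)
            clash = filled[region] & (values[region] != value)
            if clash.any():
                raise ValueError(
                    f"bedGraph {path}: overlapping records with conflicting values "
                    f"around {chrom}:{s}-{e}"
                )
            values[region] = value
            filled[region] = True
        tracks[str(chrom)] = CoverageTrack(chrom=str(chrom), values=values)
    logger.info("read %d bedGraph records (%d chromosomes) from %s", len(df), len(tracks), path)
    return tracks


def _bedgraph_header_rows(path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "browser")):
                n += 1
            else:
                break
    return n


def write_bedgraph(track: CoverageTrack, path, write_zero_runs: bool = False) -> None:
    """Write a track as bedGraph, one line per constant-coverage run.

    Zero-coverage runs are omitted by default (a reader restores them).
    """
    vals = track.values
    change = np.flatnonzero(np.diff(vals)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [vals.size]))
    n = 0
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            v = vals[s]
            if v == 0 and not write_zero_runs:
                continue
            fh.write(f"{track.chrom}\t{s + track.origin}\t{e + track.origin}\t{v:g}\n")
            n += 1
    logger.info("wrote %d bedGraph records to %s", n, path)


def read_bigwig(path) -> dict[str, CoverageTrack]:
    """Read a bigWig file into per-chromosome dense tracks (convenience)."""
    import pyBigWig

    tracks = {}
    with pyBigWig.open(str(path)) as bw:
        for chrom, length in bw.chroms().items():
            vals = np.nan_to_num(
                np.asarray(bw.values(chrom, 0, length), dtype=float), nan=0.0
            )
            tracks[chrom] = CoverageTrack(chrom=chrom, values=vals)
    return tracks


# ---------------------------------------------------------------------------
# Fragment-size estimation and read extension
# ---------------------------------------------------------------------------


def _five_prime_density(
    reads: Sequence[GenomicInterval], length: int
) -> tuple[np.ndarray, np.ndarray]:
    plus = np.zeros(length)
    minus = np.zeros(length)
    for r in reads:
        if r.strand == "+":
            if r.start < length:
                plus[r.start] += 1
        elif r.strand == "-":
            if 0 <= r.end - 1 < length:
                minus[r.end - 1] += 1
        else:
            raise ValueError(f"read {r} carries no strand; cannot correlate strands")
    return plus, minus


def estimate_fragment_length(
    reads: Sequence[GenomicInterval], max_shift: int = 500
) -> int:
    """Estimate fragment length by strand cross-correlation.

    Shifts the minus-strand 5' end density leftwards and returns the shift
    in ``[0, max_shift]`` maximizing the Pearson correlation with the
    plus-strand 5' end density (smallest shift wins ties).
    """
    strands = {r.strand for r in reads}
    for s in ("+", "-"):
        if s not in strands:
            raise ValueError(f"cannot estimate fragment length: no {s!r}-strand reads")
    length = max(r.end for r in reads) + 1
    plus, minus = _five_prime_density(reads, length)
    if max_shift <= 0:
        return 0
    best_shift, best_r = 0, -np.inf
    for shift in range(0, min(max_shift, length - 2) + 1):
        a = plus[: length - shift]
        b = minus[shift:]
        if a.std() == 0 or b.std() == 0:
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        if r > best_r:
            best_shift, best_r = shift, r
    logger.info("strand correlation maximal at shift %d (r=%.3f)", best_shift, best_r)
    return best_shift


def extend_reads(
    reads: Sequence[GenomicInterval],
    fragment_length: int,
    chrom_length: int | None = None,
) -> CoverageTrack:
    """Extend each read to ``fragment_length`` from its 5' end in strand
    direction and pile up the fragments into a coverage track.

    Coverage at a base is the count of overlapping fragments; fragments are
    clipped to ``[0, chrom_length)``.  ``total_depth`` is the read count.
    """
    if not reads:
        raise ValueError("no reads to extend")
    read_len = max(len(r) for r in reads)
    if fragment_length < read_len:
        raise ValueError(
            f"fragment_length {fragment_length} shorter than read length {read_len}"
        )
    if chrom_length is None:
        chrom_length = max(r.start + fragment_length for r in reads)
        chrom_length = max(chrom_length, max(r.end for r in reads))
    diff = np.zeros(chrom_length + 1)
    for r in reads:
        if r.strand == "-":
            s, e = r.end - fragment_length, r.end
        else:
            s, e = r.start, r.start + fragment_length
        s = max(s, 0)
        e = min(e, chrom_length)
        if e > s:
            diff[s] += 1
            diff[e] -= 1
    values = np.cumsum(diff[:-1])
    chrom = reads[0].chrom
    logger.info("extended %d reads to %d bp fragments on %s", len(reads), fragment_length, chrom)
    return CoverageTrack(chrom=chrom, values=values, total_depth=float(len(reads)))
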