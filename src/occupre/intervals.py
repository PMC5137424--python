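"""Genomic intervals and BED6 input/output.

All coordinates are 0-based, half-open (BED convention) throughout the
package; bedGraph is read and written in the same convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}; expected one of {STRANDS}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def overlaps_any(interval: GenomicInterval, others: Iterable[GenomicInterval]) -> bool:
    return any(interval.overlaps(o) for o in others)


def read_bed(path) -> list[GenomicInterval]:
    """Read a BED3/BED6 file into a list of intervals."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            dtype={0: str},
        )
    except pd.errors.EmptyDataError:
        return []
    out = []
    for row in df.itertuples(index=False):
        row = tuple(row)
        name = str(row[3]) if len(row) > 3 and not pd.isna(row[3]) else None
        score = float(row[4]) if len(row) > 4 and not pd.isna(row[4]) else None
        strand = str(row[5]) if len(row) > 5 and row[5] in STRANDS else "."
        out.append(
            GenomicInterval(
                chrom=str(row[0]),
                start=int(row[1]),
                end=int(row[2]),
                strand=strand,
                name=name,
                score=score,
            )
        )
    return out


def write_bed(intervals: Sequence[GenomicInterval], path) -> None:
    """Write intervals as BED6 (score 0 and strand '.' where unset)."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            score = iv.score if iv.score is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n")


def intervals_to_frame(intervals: Sequence[GenomicInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "name": [iv.name for iv in intervals],
            "strand": [iv.strand for iv in intervals],
        }
    )


def overlap_mask(
    intervals: Sequence[GenomicInterval], exclusions: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean array marking intervals that overlap any exclusion by >= 1 bp."""
    return np.array([overlaps_any(iv, exclusions) for iv in intervals], dtype=bool)
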