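"""Minimal genomic interval algebra: slop, intersect, nearest distance.

Intervals are 0-based half-open (BED convention).  Point sites from the
calling modules are 1-based; the explicit converters below are the only
place the two conventions meet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np


class IntervalError(ValueError):
    pass


@dataclass(frozen=True)
class GenomicInterval:
    contig: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise IntervalError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.contig != other.contig:
            return 0
        return min(self.end, other.end) - max(self.start, other.start)


def site_to_interval(contig: str, position: int, strand: str = ".",
                     label: str = "") -> GenomicInterval:
    """Convert a 1-based point position to a 1-bp BED interval."""
    return GenomicInterval(contig, position - 1, position, strand, label)


def interval_midpoint_position(iv: GenomicInterval) -> int:
    """1-based midpoint of an interval."""
    return (iv.start + iv.end - 1) // 2 + 1


def slop(intervals: Sequence[GenomicInterval], flank: int,
         contig_lengths: Mapping[str, int] | None = None
         ) -> list[GenomicInterval]:
    """Expand each interval by ``flank`` bp both ways, clamped to the contig."""
    if flank < 0:
        raise IntervalError(f"flank must be >= 0, got {flank}")
    out = []
    for iv in intervals:
        if contig_lengths is not None and iv.contig not in contig_lengths:
            raise IntervalError(f"contig {iv.contig!r} not in contig lengths")
        start = max(0, iv.start - flank)
        end = iv.end + flank
        if contig_lengths is not None:
            end = min(contig_lengths[iv.contig], end)
        out.append(replace(iv, start=start, end=end))
    return out


@dataclass
class IntersectResult:
    pairs: list[tuple[GenomicInterval, GenomicInterval, int]]
    common: list[GenomicInterval]   # A-intervals with >=1 reported pair
    unique: list[GenomicInterval]   # the rest of A


def intersect(set_a: Sequence[GenomicInterval], set_b: Sequence[GenomicInterval],
              min_overlap: int = 1) -> IntersectResult:
    """All (a, b, overlap_bp) pairs with overlap >= ``min_overlap``.

    Partition of A into common/unique preserves A's order.  The default
    min_overlap of 1 (>= 1 bp) matches the behaviour of the interval tool
    the published analysis used; pass 2 to require > 1 bp.
    """
    if min_overlap < 1:
        raise IntervalError(f"min_overlap must be >= 1, got {min_overlap}")
    by_b: dict[str, list[GenomicInterval]] = {}
    for b in set_b:
        by_b.setdefault(b.contig, []).append(b)
    for lst in by_b.values():
        lst.sort(key=lambda iv: iv.start)
    starts = {c: np.array([iv.start for iv in lst], dtype=np.int64)
              for c, lst in by_b.items()}

    pairs = []
    common, unique = [], []
    for a in set_a:
        lst = by_b.get(a.contig, [])
        hit = False
        if lst:
            # candidates must start before a.end - (min_overlap - 1)
            hi = int(np.searchsorted(starts[a.contig], a.end - min_overlap,
                                     side="right"))
            for b in lst[:hi]:
                ov = min(a.end, b.end) - max(a.start, b.start)
                if ov >= min_overlap:
                    pairs.append((a, b, ov))
                    hit = True
        (common if hit else unique).append(a)
    return IntersectResult(pairs=pairs, common=common, unique=unique)


def nearest_distance(query: GenomicInterval | tuple[str, int],
                     subjects: Sequence[GenomicInterval]) -> float:
    """Minimal gap (bp) from query to any subject on the same contig.

    0 when overlapping; ``math.inf`` when no subject shares the contig.
    A ``(contig, position)`` tuple is interpreted as a 1-based point.
    """
    if isinstance(query, tuple):
        query = site_to_interval(*query)
    best = math.inf
    for s in subjects:
        if s.contig != query.contig:
            continue
        if query.overlap(s) > 0:
            return 0
        # distance between closest covered base pairs, so book-ended
        # intervals ([0,5),[5,9)) are 1 bp apart and only overlap gives 0
        if s.start >= query.end:
            gap = s.start - query.end + 1
        else:
            gap = query.start - s.end + 1
        best = min(best, gap)
    return best


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def read_bed(path: str) -> list[GenomicInterval]:
    """Read BED3/BED6; later columns are ignored."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise IntervalError(f"{path}: line {lineno}: need >= 3 columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise IntervalError(f"{path}: line {lineno}: {exc}") from None
            label = f[3] if len(f) > 3 else ""
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(f[0], start, end, strand, label))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str,
              score: int = 0) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.label}"
                     f"\t{score}\t{iv.strand}\n")


def read_genome_file(path: str) -> dict[str, int]:
    """Read a ``contig<TAB>length`` file."""
    lengths = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            contig, length = line.split("\t")[:2]
            lengths[contig] = int(length)
    return lengths
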