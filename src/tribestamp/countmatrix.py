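"""Per-genomic-position nucleotide count matrices.

The matrix records, for every covered reference position, how many aligned
reads carried an A, C, G, or T at that position (reference-forward base
identities).  Positions are 1-based in memory and on disk; genomic intervals
exchanged with :mod:`tribestamp.intervals` are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class CountMatrixError(ValueError):
    """Raised for malformed count-matrix inputs."""


@dataclass(frozen=True)
class BaseCounts:
    """Base tallies at one genomic position (1-based)."""

    contig: str
    position: int
    counts: tuple[int, int, int, int]  # A, C, G, T

    def __post_init__(self) -> None:
        if self.position < 1:
            raise CountMatrixError(f"position must be >= 1, got {self.position}")
        if any(c < 0 for c in self.counts):
            raise CountMatrixError(f"negative count at {self.contig}:{self.position}")

    @property
    def coverage(self) -> int:
        return int(sum(self.counts))

    def count(self, base: str) -> int:
        return self.counts[BASE_INDEX[base]]


@dataclass
class ContigCounts:
    """Sorted per-contig arrays: positions (1-based) and an (n, 4) count block."""

    positions: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64).reshape(-1, 4)
        if len(self.positions) != len(self.counts):
            raise CountMatrixError("positions/counts length mismatch")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise CountMatrixError("positions must be strictly increasing")
        if np.any(self.counts < 0):
            raise CountMatrixError("negative counts")

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class CountMatrix:
    """Per-contig ordered base-count arrays for one sequencing sample."""

    contigs: dict[str, ContigCounts] = field(default_factory=dict)
    sample_label: str = ""
    library_mapped_reads: int | None = None

    def lookup(self, contig: str, position: int) -> BaseCounts | None:
        """Return the tallies at ``contig:position`` (1-based), or None."""
        cc = self.contigs.get(contig)
        if cc is None or not len(cc):
            return None
        i = int(np.searchsorted(cc.positions, position))
        if i < len(cc) and cc.positions[i] == position:
            return BaseCounts(contig, position, tuple(int(x) for x in cc.counts[i]))
        return None

    def __iter__(self) -> Iterator[BaseCounts]:
        for contig in self.contigs:
            cc = self.contigs[contig]
            for pos, row in zip(cc.positions, cc.counts):
                yield BaseCounts(contig, int(pos), tuple(int(x) for x in row))

    def n_positions(self) -> int:
        return sum(len(cc) for cc in self.contigs.values())

    def total_coverage(self) -> int:
        return int(sum(cc.counts.sum() for cc in self.contigs.values()))

    def restrict(self, regions: Sequence[tuple[str, int, int]]) -> "CountMatrix":
        """Subset to 0-based half-open ``(contig, start, end)`` regions."""
        out: dict[str, ContigCounts] = {}
        for contig, cc in self.contigs.items():
            mask = np.zeros(len(cc), dtype=bool)
            for rc, start, end in regions:
                if rc != contig:
                    continue
                # positions are 1-based; region is 0-based half-open
                lo = int(np.searchsorted(cc.positions, start + 1))
                hi = int(np.searchsorted(cc.positions, end, side="right"))
                mask[lo:hi] = True
            if mask.any():
                out[contig] = ContigCounts(cc.positions[mask], cc.counts[mask])
        return CountMatrix(out, self.sample_label, self.library_mapped_reads)


def matrix_from_rows(
    rows: Iterable[tuple[str, int, Sequence[int]]],
    sample_label: str = "",
    library_mapped_reads: int | None = None,
) -> CountMatrix:
    """Build a CountMatrix from ``(contig, position, [A,C,G,T])`` rows."""
    acc: dict[str, list[tuple[int, Sequence[int]]]] = {}
    for contig, pos, counts in rows:
        acc.setdefault(contig, []).append((pos, counts))
    contigs = {}
    for contig, items in acc.items():
        items.sort(key=lambda t: t[0])
        positions = np.array([p for p, _ in items], dtype=np.int64)
        counts = np.array([list(c) for _, c in items], dtype=np.int64)
        contigs[contig] = ContigCounts(positions, counts)
    return CountMatrix(contigs, sample_label, library_mapped_reads)


# ---------------------------------------------------------------------------
# Pileup from alignments
# ---------------------------------------------------------------------------

def pileup_counts(
    alignments: str,
    reference,
    regions: Sequence[tuple[str, int, int]] | None = None,
    min_base_quality: int = 0,
    min_mapping_quality: int = 0,
    sample_label: str = "",
) -> CountMatrix:
    """Tally aligned read bases per reference position from a SAM/BAM file.

    Only match/mismatch-aligned bases contribute (soft clips, insertions and
    deletion/skip gaps do not); ``N`` read bases are ignored.  The input must
    be coordinate-sorted.  ``reference`` is a FASTA path, a
    :class:`pyfaidx.Fasta`, or a mapping of contig name to sequence; every
    alignment contig must be present in it.

    Quality filters default to 0 (off), matching the published behaviour.
    """
    import pysam

    ref_contigs = _reference_contigs(reference)

    n_mapped = 0
    acc: dict[str, dict[int, list[int]]] = {}
    last_key: tuple[int, int] | None = None
    order: dict[str, int] = {}

    with pysam.AlignmentFile(alignments, require_index=False) as af:
        for read in af:
            if read.is_unmapped or read.query_sequence is None:
                continue
            if read.mapping_quality < min_mapping_quality:
                continue
            contig = read.reference_name
            if contig not in ref_contigs:
                raise CountMatrixError(
                    f"alignment contig {contig!r} absent from reference"
                )
            cid = order.setdefault(contig, len(order))
            key = (cid, read.reference_start)
            if last_key is not None and key < last_key:
                raise CountMatrixError("alignments are not coordinate-sorted")
            last_key = key
            n_mapped += 1

            seq = read.query_sequence
            quals = read.query_qualities
            tally = acc.setdefault(contig, {})
            for qpos, rpos in read.get_aligned_pairs(True):
                base = seq[qpos]
                if base == "N":
                    continue
                if quals is not None and quals[qpos] < min_base_quality:
                    continue
                row = tally.get(rpos)
                if row is None:
                    row = tally[rpos] = [0, 0, 0, 0]
                row[BASE_INDEX[base.upper()]] += 1

    rows = [
        (contig, rpos + 1, counts)
        for contig, tally in acc.items()
        for rpos, counts in tally.items()
    ]
    matrix = matrix_from_rows(rows, sample_label=sample_label,
                              library_mapped_reads=n_mapped)
    if regions is not None:
        matrix = matrix.restrict(regions)
    return matrix


def _reference_contigs(reference) -> Mapping[str, int]:
    """Map contig name -> length for FASTA path / pyfaidx / dict inputs."""
    if isinstance(reference, Mapping):
        return {name: len(seq) for name, seq in reference.items()}
    if isinstance(reference, str):
        from pyfaidx import Fasta

        fa = Fasta(reference)
        return {name: len(fa[name]) for name in fa.keys()}
    # pyfaidx.Fasta or similar keyed object
    return {name: len(reference[name]) for name in reference.keys()}


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_HEADER = ["contig", "position", "A", "C", "G", "T"]


def write_count_matrix(matrix: CountMatrix, path: str) -> None:
    """Write a matrix as TSV with 1-based positions, sorted rows."""
    with open(path, "w") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for contig in sorted(matrix.contigs):
            cc = matrix.contigs[contig]
            for pos, row in zip(cc.positions, cc.counts):
                fh.write(f"{contig}\t{pos}\t{row[0]}\t{row[1]}\t{row[2]}\t{row[3]}\n")


def read_count_matrix(path: str, sample_label: str = "",
                      library_mapped_reads: int | None = None) -> CountMatrix:
    """Read a TSV matrix; fails with the 1-based line number on bad rows."""
    rows: list[tuple[str, int, list[int]]] = []
    seen: set[tuple[str, int]] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _HEADER:
            raise CountMatrixError(
                f"{path}: line 1: expected header {'/'.join(_HEADER)}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise CountMatrixError(f"{path}: line {lineno}: expected 6 fields")
            contig = fields[0]
            try:
                pos = int(fields[1])
                counts = [int(x) for x in fields[2:6]]
            except ValueError as exc:
                raise CountMatrixError(f"{path}: line {lineno}: {exc}") from None
            if pos < 1:
                raise CountMatrixError(f"{path}: line {lineno}: position < 1")
            if any(c < 0 for c in counts):
                raise CountMatrixError(f"{path}: line {lineno}: negative count")
            if (contig, pos) in seen:
                raise CountMatrixError(
                    f"{path}: line {lineno}: duplicate position {contig}:{pos}"
                )
            seen.add((contig, pos))
            rows.append((contig, pos, counts))
    return matrix_from_rows(rows, sample_label=sample_label,
                            library_mapped_reads=library_mapped_reads)
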