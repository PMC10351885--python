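"""Transcript-model-aware characterization of called site sets.

Covers per-transcript site counts, editing-fraction comparisons
(Wilcoxon rank-sum with an exact small-sample path), trinucleotide
context profiles, 5'UTR/CDS/3'UTR assignment with fold enrichment and
proportion tests, 3'-directed site shifting, depth normalization, and a
fixed-motif region scan.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _stats

from .calling import EditingSite
from .intervals import GenomicInterval

FEATURES = ("5UTR", "CDS", "3UTR")
#: ambiguity tie-break when isoforms disagree (most 3'-biased first)
FEATURE_PRIORITY = ("3UTR", "5UTR", "CDS")

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


class AnnotationError(ValueError):
    pass


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def fetch_sequence(genome, contig: str, start: int, end: int) -> str:
    """Fetch genome[contig][start:end] (0-based half-open), uppercase.

    ``genome`` may be a mapping of contig -> sequence string or a
    pyfaidx.Fasta-like object.
    """
    if isinstance(genome, Mapping):
        seq = genome[contig][start:end]
    else:
        seq = str(genome[contig][start:end])
    return str(seq).upper()


# ---------------------------------------------------------------------------
# Transcript models
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    ``exons`` are sorted, disjoint 0-based half-open genomic spans.
    ``cds_start``/``cds_end`` bound the genomic CDS span (half-open); both
    are None for non-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise AnnotationError(
                    f"{self.transcript_id}: overlapping exons"
                )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.transcript_id}: bad strand")
        if (self.cds_start is None) != (self.cds_end is None):
            raise AnnotationError(f"{self.transcript_id}: half-specified CDS")
        if self.cds_start is not None:
            span_start, span_end = self.exons[0][0], self.exons[-1][1]
            if not (span_start <= self.cds_start < self.cds_end <= span_end):
                raise AnnotationError(
                    f"{self.transcript_id}: CDS outside exon span"
                )

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def contains(self, position: int) -> bool:
        """Is the 1-based genomic position inside an exon?"""
        p = position - 1
        return any(s <= p < e for s, e in self.exons)

    def to_transcript_coord(self, position: int) -> int:
        """0-based offset from the transcript 5' end of a 1-based position."""
        p = position - 1
        off = 0
        if self.strand == "+":
            for s, e in self.exons:
                if s <= p < e:
                    return off + (p - s)
                off += e - s
        else:
            for s, e in reversed(self.exons):
                if s <= p < e:
                    return off + (e - 1 - p)
                off += e - s
        raise AnnotationError(
            f"position {position} not exonic in {self.transcript_id}"
        )

    def from_transcript_coord(self, offset: int) -> int:
        """Inverse of :meth:`to_transcript_coord` (returns 1-based genomic)."""
        if not 0 <= offset < self.length:
            raise AnnotationError(f"offset {offset} outside transcript")
        if self.strand == "+":
            for s, e in self.exons:
                if offset < e - s:
                    return s + offset + 1
                offset -= e - s
        else:
            for s, e in reversed(self.exons):
                if offset < e - s:
                    return e - offset
                offset -= e - s
        raise AssertionError("unreachable")

    def feature_of(self, position: int) -> str | None:
        """5UTR/CDS/3UTR of an exonic 1-based position; None if non-coding."""
        if not self.is_coding or not self.contains(position):
            return None
        p = position - 1
        if self.cds_start <= p < self.cds_end:
            return "CDS"
        upstream = p < self.cds_start
        if self.strand == "+":
            return "5UTR" if upstream else "3UTR"
        return "3UTR" if upstream else "5UTR"


# ---------------------------------------------------------------------------
# GTF I/O (exon/CDS features only)
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path: str) -> list[TranscriptModel]:
    """Parse exon/CDS features of a GTF into transcript models."""
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise AnnotationError(f"{path}: line {lineno}: bad GTF row")
            contig, _, feature, start, end, _, strand, _, attrs = f[:9]
            if feature not in ("exon", "CDS"):
                continue
            attr = dict(_ATTR_RE.findall(attrs))
            tid = attr.get("transcript_id")
            if tid is None:
                raise AnnotationError(
                    f"{path}: line {lineno}: missing transcript_id"
                )
            gid = attr.get("gene_id", tid)
            meta.setdefault(tid, (gid, contig, strand))
            span = (int(start) - 1, int(end))  # GTF is 1-based inclusive
            (exons if feature == "exon" else cds).setdefault(tid, []).append(span)
    models = []
    for tid, (gid, contig, strand) in meta.items():
        cds_start = cds_end = None
        if tid in cds:
            cds_start = min(s for s, _ in cds[tid])
            cds_end = max(e for _, e in cds[tid])
        models.append(TranscriptModel(tid, gid, contig, strand,
                                      exons.get(tid, []), cds_start, cds_end))
    return models


def write_gtf(models: Sequence[TranscriptModel], path: str,
              source: str = "tribestamp") -> None:
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            for s, e in m.exons:
                fh.write(f"{m.contig}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                         f"{m.strand}\t.\t{attrs}\n")
            if m.is_coding:
                for s, e in m.exons:
                    cs, ce = max(s, m.cds_start), min(e, m.cds_end)
                    if cs < ce:
                        fh.write(f"{m.contig}\t{source}\tCDS\t{cs + 1}\t{ce}\t.\t"
                                 f"{m.strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# Per-transcript site counts
# ---------------------------------------------------------------------------

def sites_per_transcript(sites: Sequence[EditingSite],
                         models: Sequence[TranscriptModel]
                         ) -> tuple[dict[str, int], dict[str, float]]:
    """Count sites per transcript (exonic containment; all isoforms count).

    Returns ``(counts, summary)`` where counts only lists transcripts with
    >=1 site and summary holds mean/median/max over those targets.
    """
    if not models:
        raise AnnotationError("empty annotation")
    by_contig: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_contig.setdefault(m.contig, []).append(m)
    counts: dict[str, int] = {}
    for s in sites:
        for m in by_contig.get(s.contig, []):
            if m.contains(s.position):
                counts[m.transcript_id] = counts.get(m.transcript_id, 0) + 1
    values = np.array(sorted(counts.values()), dtype=float)
    summary = {
        "n_transcripts": int(len(counts)),
        "mean": float(values.mean()) if len(values) else float("nan"),
        "median": float(np.median(values)) if len(values) else float("nan"),
        "max": float(values.max()) if len(values) else float("nan"),
    }
    return counts, summary


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (Mann-Whitney)
# ---------------------------------------------------------------------------

def _exact_ranksum_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided exact rank-sum p by enumerating group assignments.

    Midranks handle ties; doubling makes them integers so the distribution
    of the rank-sum statistic can be counted exactly by dynamic programming
    over all C(n+m, n) assignments.
    """
    pooled = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    ranks2 = np.round(2 * _stats.rankdata(pooled)).astype(int)
    n, total = len(a), len(pooled)
    obs = int(ranks2[:n].sum())
    expected = n * (total + 1)  # mean of doubled rank-sum
    dev = abs(obs - expected)

    # dist[k][s] = #subsets of size k with doubled-rank sum s
    max_sum = int(ranks2.sum())
    dist = np.zeros((n + 1, max_sum + 1), dtype=object)
    dist[0][0] = 1
    for r in ranks2:
        for k in range(min(n, total) - 1, -1, -1):
            row = dist[k]
            nz = np.nonzero(row)[0]
            for s in nz:
                dist[k + 1][s + r] += row[s]
    counts = dist[n]
    extreme = sum(int(counts[s]) for s in range(max_sum + 1)
                  if counts[s] and abs(s - expected) >= dev)
    return extreme / math.comb(total, n)


def editing_fraction_stats(values_a: Sequence[float], values_b: Sequence[float]
                           ) -> dict[str, float]:
    """Compare two editing-fraction samples.

    Returns means, medians and a two-sided Wilcoxon rank-sum p-value —
    exact enumeration when both samples have n <= 12, otherwise the normal
    approximation with tie correction and continuity correction.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise AnnotationError("both samples must be non-empty")
    if len(a) <= 12 and len(b) <= 12:
        p = _exact_ranksum_p(a, b)
        method = "exact"
    else:
        p = float(_stats.mannwhitneyu(a, b, alternative="two-sided",
                                      method="asymptotic").pvalue)
        method = "asymptotic"
    return {
        "mean_a": float(a.mean()), "mean_b": float(b.mean()),
        "median_a": float(np.median(a)), "median_b": float(np.median(b)),
        "n_a": len(a), "n_b": len(b),
        "p_value": min(1.0, p), "method": method,
    }


# ---------------------------------------------------------------------------
# Trinucleotide context
# ---------------------------------------------------------------------------

@dataclass
class ContextProfile:
    fractions: dict[str, float]
    n_sites: int
    n_skipped: int


def triplet_context(sites: Sequence[EditingSite], genome) -> ContextProfile:
    """Transcribed-strand triplets (5' neighbor, edited base, 3' neighbor).

    For a '+' signature the triplet is the reference bases at pos-1..pos+1;
    for '-' it is their reverse complement.  Sites at contig termini are
    skipped and counted in ``n_skipped``.
    """
    counts: dict[str, int] = {}
    skipped = 0
    for s in sites:
        start = s.position - 2  # 0-based index of 5' flank
        if start < 0:
            skipped += 1
            continue
        try:
            tri = fetch_sequence(genome, s.contig, start, start + 3)
        except (KeyError, IndexError):
            raise AnnotationError(f"contig {s.contig!r} missing from genome")
        if len(tri) < 3:
            skipped += 1
            continue
        if s.signature.strand == "-":
            tri = reverse_complement(tri)
        counts[tri] = counts.get(tri, 0) + 1
    n = sum(counts.values())
    fractions = {t: c / n for t, c in sorted(counts.items())} if n else {}
    return ContextProfile(fractions=fractions, n_sites=n, n_skipped=skipped)


# ---------------------------------------------------------------------------
# Feature assignment and fold enrichment
# ---------------------------------------------------------------------------

def assign_feature(position_contig: str, position: int,
                   models_by_contig: Mapping[str, Sequence[TranscriptModel]]
                   ) -> str | None:
    """Majority feature across containing coding isoforms (tie: 3UTR>5UTR>CDS)."""
    votes: dict[str, int] = {}
    for m in models_by_contig.get(position_contig, []):
        feat = m.feature_of(position)
        if feat is not None:
            votes[feat] = votes.get(feat, 0) + 1
    if not votes:
        return None
    best = max(votes.values())
    for feat in FEATURE_PRIORITY:
        if votes.get(feat) == best:
            return feat
    raise AssertionError("unreachable")


def _models_by_contig(models: Sequence[TranscriptModel]
                      ) -> dict[str, list[TranscriptModel]]:
    by: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by.setdefault(m.contig, []).append(m)
    return by


def compute_read_distribution(matrix, models: Sequence[TranscriptModel]
                              ) -> dict[str, float]:
    """Per-feature coverage shares of a count matrix, renormalized over
    5UTR/CDS/3UTR (positions outside coding exons are ignored)."""
    by = _models_by_contig(models)
    totals = dict.fromkeys(FEATURES, 0)
    for contig, cc in matrix.contigs.items():
        cov = cc.coverage
        for pos, c in zip(cc.positions, cov):
            feat = assign_feature(contig, int(pos), by)
            if feat is not None:
                totals[feat] += int(c)
    grand = sum(totals.values())
    if grand == 0:
        raise AnnotationError("no coverage on annotated coding exons")
    return {f: totals[f] / grand for f in FEATURES}


@dataclass
class FeatureStats:
    site_count: int
    site_fraction: float
    read_fraction: float
    fold_enrichment: float
    p_value: float


@dataclass
class FeatureDistribution:
    features: dict[str, FeatureStats]
    n_assigned: int
    n_unassigned: int


def feature_fold_enrichment(sites: Sequence[EditingSite],
                            models: Sequence[TranscriptModel],
                            read_distribution: Mapping[str, float]
                            ) -> FeatureDistribution:
    """Site distribution over 5UTR/CDS/3UTR vs the library read distribution.

    fold = site_fraction / read_fraction; p is a two-sided one-sample
    proportion z-test of the observed site share against the read share.
    """
    total_rd = sum(read_distribution.get(f, 0.0) for f in FEATURES)
    if not math.isclose(total_rd, 1.0, abs_tol=1e-6):
        raise AnnotationError("read_distribution must sum to 1 over features")
    by = _models_by_contig(models)
    counts = dict.fromkeys(FEATURES, 0)
    unassigned = 0
    for s in sites:
        feat = assign_feature(s.contig, s.position, by)
        if feat is None:
            unassigned += 1
        else:
            counts[feat] += 1
    n = sum(counts.values())
    if n == 0:
        raise AnnotationError("no sites fall in annotated coding exons")
    out = {}
    for feat in FEATURES:
        k = counts[feat]
        p_hat = k / n
        p0 = float(read_distribution[feat])
        if p0 == 0.0:
            fold = math.inf if k else 0.0
            p_value = float(_stats.binomtest(k, n, p=0.0).pvalue) if k else 1.0
        else:
            fold = p_hat / p0
            se = math.sqrt(p0 * (1 - p0) / n)
            z = (p_hat - p0) / se
            p_value = float(2 * _stats.norm.sf(abs(z)))
        out[feat] = FeatureStats(k, p_hat, p0, fold, min(1.0, p_value))
    return FeatureDistribution(out, n_assigned=n, n_unassigned=unassigned)


# ---------------------------------------------------------------------------
# 3'-directed shifting
# ---------------------------------------------------------------------------

def shift_toward_3prime(sites: Sequence[EditingSite],
                        models: Sequence[TranscriptModel],
                        shift: int = 50
                        ) -> tuple[list[EditingSite], int]:
    """Move each site ``shift`` bases toward its host transcript's 3' end.

    Movement follows the exon chain in transcript coordinates and clamps at
    the transcript's last base.  The host is the containing transcript that
    places the site closest to a 3' terminus (ties by transcript_id) — the
    assignment most generous to 3'UTR reclassification.  Sites contained by
    no transcript are returned unshifted; their number is the second return
    value.
    """
    by = _models_by_contig(models)
    shifted: list[EditingSite] = []
    n_unshifted = 0
    for s in sites:
        hosts = [(m.length - 1 - m.to_transcript_coord(s.position),
                  m.transcript_id, m)
                 for m in by.get(s.contig, []) if m.contains(s.position)]
        if not hosts:
            shifted.append(s)
            n_unshifted += 1
            continue
        _, _, host = min(hosts, key=lambda t: (t[0], t[1]))
        tpos = host.to_transcript_coord(s.position)
        new_tpos = min(tpos + shift, host.length - 1)
        shifted.append(replace(s, position=host.from_transcript_coord(new_tpos)))
    return shifted, n_unshifted


# ---------------------------------------------------------------------------
# Depth normalization and motif scan
# ---------------------------------------------------------------------------

def normalize_per_million(site_count: int, mapped_reads: int) -> float:
    """Sites per million mapped reads."""
    if mapped_reads <= 0:
        raise AnnotationError(f"mapped_reads must be > 0, got {mapped_reads}")
    return site_count * 1e6 / mapped_reads


def iupac_to_regex(motif: str) -> re.Pattern:
    if not motif:
        raise AnnotationError("empty motif")
    try:
        return re.compile("".join(IUPAC[c] for c in motif.upper()))
    except KeyError as exc:
        raise AnnotationError(f"invalid IUPAC code {exc}") from None


def motif_fraction(regions: Sequence[GenomicInterval], genome,
                   motif: str = "GTGTGT") -> float:
    """Fraction of regions whose sequence matches the motif on either strand."""
    pattern = iupac_to_regex(motif)
    if not regions:
        return float("nan")
    hits = 0
    for iv in regions:
        seq = fetch_sequence(genome, iv.contig, iv.start, iv.end)
        if pattern.search(seq) or pattern.search(reverse_complement(seq)):
            hits += 1
    return hits / len(regions)
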