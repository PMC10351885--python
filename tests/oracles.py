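"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's vectorized code paths: plain Python
loops, exact rational arithmetic (fractions), O(n^2) scans, and full
combinatorial enumeration.
"""

from __future__ import annotations

import itertools
import math
import re
from fractions import Fraction

BASES = "ACGT"


def rows_of(matrix):
    """Flatten a CountMatrix into {(contig, pos): {base: count}} dicts."""
    out = {}
    for bc in matrix:
        out[(bc.contig, bc.position)] = dict(zip(BASES, bc.counts))
    return out


def frac(num, den):
    return Fraction(num, den)


def dec(x):
    """Exact rational value of a decimal threshold literal."""
    return Fraction(str(x))


def editable_oracle(control, enzyme, th):
    """Per-position re-evaluation of the three control criteria."""
    out = set()
    for (contig, pos), counts in rows_of(control).items():
        cov = sum(counts.values())
        if cov < th.control_min_reads:
            continue
        for sig in enzyme.signatures:
            if (frac(counts[sig.ref], cov) >= dec(th.control_min_ref_frac)
                    and frac(counts[sig.alt], cov) < dec(th.control_max_alt_frac)):
                out.add((contig, pos, sig))
    return out


def candidates_oracle(expt, editable, enzyme, th):
    """Per-position re-evaluation of the experimental criteria."""
    rows = rows_of(expt)
    out = set()
    for (contig, pos, sig) in editable:
        if sig not in enzyme.signatures:
            continue
        counts = rows.get((contig, pos))
        if counts is None:
            continue
        cov = sum(counts.values())
        edited = counts[sig.alt]
        if (cov >= th.expt_min_reads
                and edited >= th.expt_min_edited_reads
                and frac(edited, cov) > dec(th.expt_min_edit_frac)):
            out.add((contig, pos, sig))
    return out


def blacklist_oracle(reps, enzyme, th):
    """Union over replicates of the background criteria."""
    out = set()
    for rep in reps:
        for (contig, pos), counts in rows_of(rep).items():
            cov = sum(counts.values())
            if cov < th.background_min_reads:
                continue
            for sig in enzyme.signatures:
                edited = counts[sig.alt]
                if (edited >= th.background_min_edited_reads
                        and frac(edited, cov) >= dec(th.background_edit_frac)):
                    out.add((contig, pos, sig))
    return out


def proximity_merge_oracle(rep1, rep2, window):
    """All-pairs nearest-distance filter; returns kept (contig, pos) keys."""
    kept = set()
    for a_set, b_set in ((rep1, rep2), (rep2, rep1)):
        for s in a_set:
            for t in b_set:
                if s.contig == t.contig and abs(s.position - t.position) <= window:
                    kept.add((s.contig, s.position))
                    break
    return kept


def nearest_site_distance_oracle(site, others):
    best = None
    for t in others:
        if t.contig != site.contig:
            continue
        d = abs(site.position - t.position)
        best = d if best is None else min(best, d)
    return best


def intersect_oracle(set_a, set_b, min_overlap):
    """O(n^2) all-pairs overlap scan."""
    pairs = []
    for a in set_a:
        for b in set_b:
            if a.contig != b.contig:
                continue
            ov = min(a.end, b.end) - max(a.start, b.start)
            if ov >= min_overlap:
                pairs.append((a, b, ov))
    return pairs


def nearest_interval_distance_oracle(query, subjects):
    best = math.inf
    for s in subjects:
        if s.contig != query.contig:
            continue
        ov = min(query.end, s.end) - max(query.start, s.start)
        if ov > 0:
            return 0
        if s.start >= query.end:
            best = min(best, s.start - query.end + 1)
        else:
            best = min(best, query.start - s.end + 1)
    return best


def ranksum_exact_oracle(a, b):
    """Two-sided exact rank-sum p by full C(n+m, n) enumeration."""
    pooled = list(a) + list(b)
    n, total = len(a), len(pooled)
    # midranks
    order = sorted(range(total), key=lambda i: pooled[i])
    ranks = [0.0] * total
    i = 0
    while i < total:
        j = i
        while j + 1 < total and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    obs = sum(ranks[:n])
    mean = n * (total + 1) / 2
    dev = abs(obs - mean)
    extreme = 0
    count = 0
    for combo in itertools.combinations(range(total), n):
        count += 1
        s = sum(ranks[i] for i in combo)
        if abs(s - mean) >= dev - 1e-9:
            extreme += 1
    return extreme / count


def pileup_column_oracle(sam_path):
    """Per-column base tally from a raw SAM text walk (no pysam).

    Handles M/=/X (consume both), I/S (query only), D/N (reference only),
    H/P (neither).  Returns {(contig, 1-based pos): {base: count}}.
    """
    tallies = {}
    with open(sam_path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            flag = int(f[1])
            if flag & 0x4:
                continue
            contig, pos, cigar, seq = f[2], int(f[3]), f[5], f[9]
            qpos, rpos = 0, pos  # rpos 1-based
            for length, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
                length = int(length)
                if op in "M=X":
                    for k in range(length):
                        base = seq[qpos + k].upper()
                        if base != "N":
                            col = tallies.setdefault((contig, rpos + k),
                                                     dict.fromkeys(BASES, 0))
                            col[base] += 1
                    qpos += length
                    rpos += length
                elif op in "IS":
                    qpos += length
                elif op in "DN":
                    rpos += length
    return tallies
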