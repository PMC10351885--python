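"""Synthetic genomes, transcript models and count matrices with planted
editing ground truth.

Every pipeline stage can be exercised offline: the simulator emits a
control (no-enzyme) matrix, enzyme-only background replicates, and fusion
replicates whose edited positions are known.  Noise is independent
per-position multinomial sequencing error split evenly across the three
alternative bases; alignment artifacts are not modeled.

One master seed determines everything; per-sample RNG streams are derived
from it with fixed spawn order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .calling import ADAR, EditingSite, EnzymeSpec, Signature, Thresholds
from .countmatrix import BASES, BASE_INDEX, ContigCounts, CountMatrix
from .annotate import TranscriptModel, reverse_complement

FEATURES = ("5UTR", "CDS", "3UTR")


class SimulationError(ValueError):
    pass


@dataclass
class SimulationParams:
    n_transcripts: int = 200
    transcript_length_mean: int = 1500
    transcript_length_sd: int = 300
    min_transcript_length: int = 300
    utr5_fraction: float = 0.2
    utr3_fraction: float = 0.3
    max_exons: int = 3
    intron_length: tuple[int, int] = (50, 200)
    flank: int = 100
    coverage_mean: float = 100.0
    seq_error_rate: float = 0.001
    n_truth_sites: int = 500
    truth_edit_frac: float = 0.20
    enzyme: EnzymeSpec = field(default_factory=lambda: ADAR)
    context_whitelist: tuple[str, ...] | None = None
    background_rate: float = 0.10
    n_background_sites: int = 100
    feature_bias: Mapping[str, float] | None = None
    reps: int = 2
    rep_jitter_bp: int = 0

    def __post_init__(self) -> None:
        for name in ("utr5_fraction", "utr3_fraction", "seq_error_rate",
                     "truth_edit_frac", "background_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        if self.utr5_fraction + self.utr3_fraction >= 1.0:
            raise SimulationError("UTR fractions must sum to < 1")
        if self.truth_edit_frac + self.seq_error_rate > 1.0:
            raise SimulationError("edit fraction + error rate exceeds 1")


@dataclass(frozen=True)
class TruthSite:
    contig: str
    position: int  # 1-based
    signature: Signature
    edit_frac: float
    feature: str | None
    triplet: str


@dataclass
class TruthTable:
    sites: list[TruthSite]

    def __post_init__(self) -> None:
        keys = [(s.contig, s.position) for s in self.sites]
        if len(set(keys)) != len(keys):
            raise SimulationError("truth positions must be unique")

    def __len__(self) -> int:
        return len(self.sites)

    def positions(self) -> set[tuple[str, int]]:
        return {(s.contig, s.position) for s in self.sites}


@dataclass
class Reference:
    genome: dict[str, str]
    models: list[TranscriptModel]
    contig_lengths: dict[str, int]


# ---------------------------------------------------------------------------
# Reference simulation
# ---------------------------------------------------------------------------

def simulate_reference(params: SimulationParams, seed: int) -> Reference:
    """One contig per transcript: flank + (possibly spliced) gene + flank."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    genome: dict[str, str] = {}
    models: list[TranscriptModel] = []
    lengths: dict[str, int] = {}
    for i in range(params.n_transcripts):
        contig = f"chr{i + 1}"
        tx_len = max(params.min_transcript_length,
                     int(rng.normal(params.transcript_length_mean,
                                    params.transcript_length_sd)))
        n_exons = int(rng.integers(1, params.max_exons + 1))
        # split exonic length into n_exons chunks of >= 50 bp
        cuts = np.sort(rng.integers(50, tx_len - 50, size=n_exons - 1)) \
            if n_exons > 1 else np.array([], dtype=int)
        bounds = np.concatenate([[0], cuts, [tx_len]])
        exon_lens = np.diff(bounds)
        if np.any(exon_lens < 30):  # merge degenerate splits
            exon_lens = np.array([tx_len])
        introns = rng.integers(params.intron_length[0],
                               params.intron_length[1] + 1,
                               size=len(exon_lens) - 1)
        exons = []
        cursor = params.flank
        for j, el in enumerate(exon_lens):
            exons.append((cursor, cursor + int(el)))
            cursor += int(el)
            if j < len(introns):
                cursor += int(introns[j])
        contig_len = cursor + params.flank
        seq = "".join(rng.choice(list(BASES), size=contig_len))
        strand = "+" if rng.random() < 0.5 else "-"

        # UTR/CDS partition in transcript coordinates (5'->3')
        n5 = int(round(params.utr5_fraction * tx_len))
        n3 = int(round(params.utr3_fraction * tx_len))
        n5 = max(1, n5)
        n3 = max(1, n3)
        model = TranscriptModel(f"tx{i + 1}", f"gene{i + 1}", contig, strand,
                                exons)
        cds_lo_t, cds_hi_t = n5, tx_len - n3  # transcript coords, half-open
        g1 = model.from_transcript_coord(cds_lo_t)
        g2 = model.from_transcript_coord(cds_hi_t - 1)
        cds_start = min(g1, g2) - 1
        cds_end = max(g1, g2)
        model = TranscriptModel(model.transcript_id, model.gene_id, contig,
                                strand, exons, cds_start, cds_end)
        genome[contig] = seq
        lengths[contig] = contig_len
        models.append(model)
    return Reference(genome=genome, models=models, contig_lengths=lengths)


def write_fasta(genome: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Truth planting
# ---------------------------------------------------------------------------

def _substrate_positions(reference: Reference, enzyme: EnzymeSpec
                         ) -> list[tuple[str, int, Signature, str, str | None]]:
    """All exonic positions whose transcribed-strand base is the substrate.

    Returns (contig, 1-based position, signature, transcribed-strand
    triplet, feature) tuples.
    """
    sig_plus, sig_minus = enzyme.signatures[0], enzyme.signatures[1]
    out = []
    for m in reference.models:
        seq = reference.genome[m.contig]
        sig = sig_plus if m.strand == "+" else sig_minus
        for s, e in m.exons:
            for p0 in range(max(s, 1), min(e, len(seq) - 1)):
                if seq[p0] != sig.ref:
                    continue
                tri = seq[p0 - 1:p0 + 2]
                if m.strand == "-":
                    tri = reverse_complement(tri)
                out.append((m.contig, p0 + 1, sig, tri, m.feature_of(p0 + 1)))
    return out


def plant_truth_sites(reference: Reference, params: SimulationParams,
                      seed: int,
                      allowed_positions: set[tuple[str, int]] | None = None
                      ) -> TruthTable:
    """Choose planted editing sites among substrate positions.

    ``allowed_positions`` (e.g. control-editable positions) restricts the
    candidate pool so that planted sites are guaranteed discoverable.
    Context whitelists and per-feature placement weights bias the draw.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    candidates = _substrate_positions(reference, params.enzyme)
    if params.context_whitelist is not None:
        wl = set(params.context_whitelist)
        candidates = [c for c in candidates if c[3] in wl]
    if allowed_positions is not None:
        candidates = [c for c in candidates if (c[0], c[1]) in allowed_positions]
    if len(candidates) < params.n_truth_sites:
        raise SimulationError(
            f"only {len(candidates)} candidate positions for "
            f"{params.n_truth_sites} truth sites"
        )
    if params.feature_bias:
        weights = np.array([params.feature_bias.get(c[4] or "", 0.0)
                            for c in candidates], dtype=float)
        if weights.sum() == 0:
            raise SimulationError("feature_bias leaves no candidates")
        weights /= weights.sum()
    else:
        weights = None
    idx = rng.choice(len(candidates), size=params.n_truth_sites,
                     replace=False, p=weights)
    sites = [TruthSite(c[0], c[1], c[2], params.truth_edit_frac, c[4], c[3])
             for c in (candidates[i] for i in sorted(idx))]
    return TruthTable(sites=sites)


def jitter_truth(reference: Reference, truth: TruthTable,
                 params: SimulationParams, seed: int,
                 allowed_positions: set[tuple[str, int]] | None = None
                 ) -> TruthTable:
    """Displace truth positions by |U(0, rep_jitter_bp)| with random sign,
    snapping to the nearest allowed substrate position within 100 bp.

    Models the dispersed editing of APOBEC-like enzymes between replicates.
    With rep_jitter_bp == 0 the table is returned unchanged.
    """
    if params.rep_jitter_bp == 0:
        return truth
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    cand_by_contig: dict[str, list[tuple[int, Signature, str, str | None]]] = {}
    for contig, pos, sig, tri, feat in _substrate_positions(reference,
                                                            params.enzyme):
        if allowed_positions is not None and (contig, pos) not in allowed_positions:
            continue
        cand_by_contig.setdefault(contig, []).append((pos, sig, tri, feat))
    used: set[tuple[str, int]] = set()
    originals = truth.positions()
    out = []
    for s in truth.sites:
        d = int(round(rng.uniform(0, params.rep_jitter_bp)))
        sign = 1 if rng.random() < 0.5 else -1
        target = s.position + sign * d
        best = None
        for pos, sig, tri, feat in cand_by_contig.get(s.contig, []):
            if abs(pos - s.position) > 100 or (s.contig, pos) in used:
                continue
            if d > 0 and (s.contig, pos) in originals:
                continue  # a nonzero displacement must move off rep1's sites
            if best is None or abs(pos - target) < abs(best[0] - target):
                best = (pos, sig, tri, feat)
        if best is None:
            best = (s.position, s.signature, s.triplet, s.feature)
        used.add((s.contig, best[0]))
        out.append(TruthSite(s.contig, best[0], best[1], s.edit_frac,
                             best[3], best[2]))
    return TruthTable(sites=out)


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------

def _exonic_positions(reference: Reference) -> dict[str, np.ndarray]:
    out = {}
    for m in reference.models:
        pos = np.concatenate([np.arange(s + 1, e + 1) for s, e in m.exons])
        prev = out.get(m.contig)
        out[m.contig] = pos if prev is None else np.unique(
            np.concatenate([prev, pos]))
    return out


def _simulate_sample(reference: Reference, params: SimulationParams,
                     rng: np.random.Generator,
                     edited: Mapping[tuple[str, int], float],
                     label: str) -> CountMatrix:
    """Draw one sample's count matrix over all exonic positions."""
    e = params.seq_error_rate
    contigs: dict[str, ContigCounts] = {}
    exonic = _exonic_positions(reference)
    for contig in sorted(exonic, key=lambda c: int(c[3:])):
        positions = exonic[contig]
        seq = reference.genome[contig]
        ref_idx = np.array([BASE_INDEX[seq[p - 1]] for p in positions])
        cov = rng.poisson(params.coverage_mean, size=len(positions))
        counts = np.zeros((len(positions), 4), dtype=np.int64)
        # unedited draws, grouped by reference base
        for b in range(4):
            mask = ref_idx == b
            if not mask.any():
                continue
            pvals = np.full(4, e / 3)
            pvals[b] = 1.0 - e
            counts[mask] = rng.multinomial(cov[mask], pvals)
        # redraw edited positions with the edited-base mass added
        for (c, pos), frac in edited.items():
            if c != contig:
                continue
            i = int(np.searchsorted(positions, pos))
            if i >= len(positions) or positions[i] != pos:
                raise SimulationError(
                    f"edited position {c}:{pos} is not exonic in reference"
                )
            b = ref_idx[i]
            ref_base = BASES[b]
            sig = next(s for s in params.enzyme.signatures if s.ref == ref_base)
            pvals = np.full(4, e / 3)
            pvals[BASE_INDEX[sig.alt]] = frac + e / 3
            pvals[b] = 1.0 - frac - e
            counts[i] = rng.multinomial(int(cov[i]), pvals)
        contigs[contig] = ContigCounts(positions, counts)
    matrix = CountMatrix(contigs, sample_label=label)
    matrix.library_mapped_reads = int(
        sum(cc.counts.sum() for cc in matrix.contigs.values()) // 100
    ) or None
    return matrix


@dataclass
class SimulatedExperiment:
    reference: Reference
    truth: TruthTable
    truth_by_rep: list[TruthTable]
    background: TruthTable
    control: CountMatrix
    enzyme_only: list[CountMatrix]
    fusion: list[CountMatrix]


def simulate_counts(reference: Reference, truth: TruthTable,
                    params: SimulationParams, seed: int,
                    control: CountMatrix | None = None,
                    truth_by_rep: Sequence[TruthTable] | None = None
                    ) -> SimulatedExperiment:
    """Draw control, enzyme-only and fusion matrices for a planted truth.

    The fusion replicates carry the truth edits plus the enzyme-only
    background edits (so blacklist subtraction has real work to do);
    enzyme-only replicates carry only the background edits; the control has
    sequencing error only.
    """
    for s in truth.sites:
        base = reference.genome[s.contig][s.position - 1]
        if base != s.signature.ref:
            raise SimulationError(
                f"truth site {s.contig}:{s.position} reference base {base!r} "
                f"does not match signature {s.signature}"
            )
    if truth_by_rep is None:
        truth_by_rep = [truth] * params.reps
    if len(truth_by_rep) != params.reps:
        raise SimulationError("truth_by_rep length must equal reps")

    if control is None:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 10]))
        control = _simulate_sample(reference, params, rng, {}, "control")

    # background sites: substrate positions disjoint from all truth positions
    rng_bg = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    taken = set().union(*(t.positions() for t in truth_by_rep)) | truth.positions()
    bg_candidates = [c for c in _substrate_positions(reference, params.enzyme)
                     if (c[0], c[1]) not in taken]
    n_bg = min(params.n_background_sites, len(bg_candidates))
    bg_idx = sorted(rng_bg.choice(len(bg_candidates), size=n_bg, replace=False))
    background = TruthTable(sites=[
        TruthSite(c[0], c[1], c[2], params.background_rate, c[4], c[3])
        for c in (bg_candidates[i] for i in bg_idx)
    ])
    bg_edits = {(s.contig, s.position): s.edit_frac for s in background.sites}

    enzyme_only = []
    for r in range(params.reps):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 20 + r]))
        enzyme_only.append(_simulate_sample(reference, params, rng, bg_edits,
                                            f"enzyme_only_rep{r + 1}"))
    fusion = []
    for r in range(params.reps):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 30 + r]))
        edits = dict(bg_edits)
        edits.update({(s.contig, s.position): s.edit_frac
                      for s in truth_by_rep[r].sites})
        fusion.append(_simulate_sample(reference, params, rng, edits,
                                       f"fusion_rep{r + 1}"))
    return SimulatedExperiment(reference=reference, truth=truth,
                               truth_by_rep=list(truth_by_rep),
                               background=background, control=control,
                               enzyme_only=enzyme_only, fusion=fusion)


def simulate_experiment(params: SimulationParams, seed: int,
                        thresholds: Thresholds | None = None
                        ) -> SimulatedExperiment:
    """Full deterministic chain: reference -> control -> truth -> samples.

    Truth sites are restricted to positions whose already-drawn control
    pile is cleanly the reference base (zero alternative reads, coverage
    over the control minimum), so every planted site is control-editable
    and recall targets are meaningful.
    """
    th = thresholds or Thresholds()
    reference = simulate_reference(params, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 10]))
    control = _simulate_sample(reference, params, rng, {}, "control")

    clean: set[tuple[str, int]] = set()
    for contig, cc in control.contigs.items():
        cov = cc.coverage
        ref_is_all = cc.counts.max(axis=1) == cov
        mask = (cov >= max(th.control_min_reads, 1)) & ref_is_all
        for pos in cc.positions[mask]:
            clean.add((contig, int(pos)))

    truth = plant_truth_sites(reference, params, seed, allowed_positions=clean)
    truth_by_rep = [truth]
    for r in range(1, params.reps):
        truth_by_rep.append(jitter_truth(reference, truth, params, seed + r,
                                         allowed_positions=clean))
    return simulate_counts(reference, truth, params, seed, control=control,
                           truth_by_rep=truth_by_rep)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate_calls(called: Sequence[EditingSite], truth: TruthTable,
                   tolerance: int = 0) -> dict[str, float]:
    """Precision/recall of a called site list against planted truth.

    A called site matches if some truth position on the same contig lies
    within ``tolerance`` bp; a truth site is recovered if some called site
    does.  Precision is NaN when nothing was called.
    """
    truth_pos: dict[str, np.ndarray] = {}
    for s in truth.sites:
        truth_pos.setdefault(s.contig, []).append(s.position)
    truth_pos = {c: np.sort(np.array(p)) for c, p in truth_pos.items()}
    called_pos: dict[str, np.ndarray] = {}
    for s in called:
        called_pos.setdefault(s.contig, []).append(s.position)
    called_pos = {c: np.sort(np.array(p)) for c, p in called_pos.items()}

    def _matched(pos: int, arr: np.ndarray | None) -> bool:
        if arr is None or len(arr) == 0:
            return False
        i = int(np.searchsorted(arr, pos))
        for j in (i - 1, i):
            if 0 <= j < len(arr) and abs(int(arr[j]) - pos) <= tolerance:
                return True
        return False

    n_called_matched = sum(
        _matched(s.position, truth_pos.get(s.contig)) for s in called)
    n_truth_matched = sum(
        _matched(s.position, called_pos.get(s.contig)) for s in truth.sites)
    precision = (n_called_matched / len(called)) if called else float("nan")
    recall = (n_truth_matched / len(truth)) if len(truth) else float("nan")

    frac_err = []
    frac_by_key = {(s.contig, s.position): s.edit_frac for s in called}
    for t in truth.sites:
        f = frac_by_key.get((t.contig, t.position))
        if f is not None:
            frac_err.append(abs(f - t.edit_frac))
    return {
        "precision": precision,
        "recall": recall,
        "n_called": len(called),
        "n_truth": len(truth),
        "mean_frac_error": float(np.mean(frac_err)) if frac_err else float("nan"),
    }


def write_truth_bed(truth: TruthTable, path: str) -> None:
    with open(path, "w") as fh:
        for s in truth.sites:
            name = f"{s.signature.ref}>{s.signature.alt}|{s.triplet}"
            fh.write(f"{s.contig}\t{s.position - 1}\t{s.position}\t{name}"
                     f"\t{round(100 * s.edit_frac)}\t{s.signature.strand}\n")
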