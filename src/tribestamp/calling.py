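"""Editing-site calling: control editability screen, experimental
thresholding, and enzyme-only background blacklisting.

The calling logic is deliberately threshold-based (no statistical model):
a genomic position is *editable* when the matched no-enzyme control shows
it to be cleanly the reference base, becomes a *candidate site* when the
fusion sample shows the enzyme's signature change above coverage and
fraction cutoffs, and is discarded when the enzyme-only control edits it
above a background fraction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, fields, replace
from typing import Iterable, Sequence

import numpy as np

from .countmatrix import BASE_INDEX, CountMatrix

logger = logging.getLogger(__name__)

LOW_DEPTH_READS = 12_000_000


class CallingError(ValueError):
    pass


@dataclass(frozen=True)
class Signature:
    """One strand-resolved base change, e.g. A>G on '+' for ADAR."""

    ref: str
    alt: str
    strand: str

    def __str__(self) -> str:  # e.g. "A>G/+"
        return f"{self.ref}>{self.alt}/{self.strand}"


@dataclass(frozen=True)
class EnzymeSpec:
    """Deaminase signature set and replicate-merge mode."""

    name: str
    signatures: tuple[Signature, ...]
    merge_mode: str  # "exact" | "proximity"

    def __post_init__(self) -> None:
        if not self.signatures:
            raise CallingError(f"enzyme {self.name!r} has no signatures")
        refs = [s.ref for s in self.signatures]
        if len(set(refs)) != len(refs):
            raise CallingError("signature reference bases must be disjoint")
        if self.merge_mode not in ("exact", "proximity"):
            raise CallingError(f"unknown merge_mode {self.merge_mode!r}")


#: A-to-I editing read out as A>G; the unstranded library also exposes the
#: minus-strand event as T>C on the reference-forward strand.
ADAR = EnzymeSpec("ADAR", (Signature("A", "G", "+"), Signature("T", "C", "-")),
                  merge_mode="exact")
#: C-to-U editing read out as C>T (plus G>A for minus-strand transcripts).
APOBEC = EnzymeSpec("APOBEC", (Signature("C", "T", "+"), Signature("G", "A", "-")),
                    merge_mode="proximity")

ENZYMES = {"ADAR": ADAR, "APOBEC": APOBEC}


def get_enzyme(name: str, merge_mode: str | None = None) -> EnzymeSpec:
    try:
        enzyme = ENZYMES[name.upper()]
    except KeyError:
        raise CallingError(f"unknown enzyme {name!r} (expected ADAR or APOBEC)")
    if merge_mode is not None and merge_mode != enzyme.merge_mode:
        enzyme = replace(enzyme, merge_mode=merge_mode)
    return enzyme


@dataclass
class Thresholds:
    """Every numeric cutoff of the pipeline.

    Defaults follow the published criteria: the no-enzyme control must carry
    >=80% reference base, <0.5% edited base, and >=9 reads; the experimental
    sample needs >=20 reads, >6% edited fraction and >=2 edited reads;
    enzyme-only background is blacklisted at >=1% editing.
    """

    control_min_ref_frac: float = 0.80
    control_max_alt_frac: float = 0.005
    control_min_reads: int = 9
    expt_min_reads: int = 20
    expt_min_edit_frac: float = 0.06
    expt_min_edited_reads: int = 2
    background_edit_frac: float = 0.01
    background_min_reads: int = 20
    background_min_edited_reads: int = 2
    proximity_window: int = 100
    region_flank: int = 100
    motif_flank: int = 50
    shift_3prime: int = 50

    def __post_init__(self) -> None:
        for name in ("control_min_ref_frac", "control_max_alt_frac",
                     "background_edit_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CallingError(f"{name} must be in [0, 1], got {v}")
        # a strict lower bound; > 1 is vacuous (calls nothing) but legal
        if self.expt_min_edit_frac < 0:
            raise CallingError("expt_min_edit_frac must be >= 0")
        for name in ("control_min_reads", "expt_min_reads",
                     "expt_min_edited_reads", "background_min_reads",
                     "background_min_edited_reads",
                     "proximity_window", "region_flank", "motif_flank",
                     "shift_3prime"):
            if getattr(self, name) < 0:
                raise CallingError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, data: dict) -> "Thresholds":
        known = {f.name for f in fields(cls)}
        bad = set(data) - known
        if bad:
            raise CallingError(f"unknown threshold keys: {sorted(bad)}")
        return cls(**data)


@dataclass(frozen=True)
class EditingSite:
    """A called site at a 1-based genomic position."""

    contig: str
    position: int
    signature: Signature
    coverage: int
    edited_reads: int
    edit_frac: float
    sample_label: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.edited_reads > self.coverage:
            raise CallingError("edited_reads exceeds coverage")
        if not 0.0 < self.edit_frac <= 1.0:
            raise CallingError(f"edit_frac must be in (0, 1], got {self.edit_frac}")

    @property
    def key(self) -> tuple[str, int, Signature]:
        return (self.contig, self.position, self.signature)


EditableSet = set[tuple[str, int, Signature]]


def _qc_depth(matrix: CountMatrix) -> None:
    if (matrix.library_mapped_reads is not None
            and matrix.library_mapped_reads < LOW_DEPTH_READS):
        logger.warning(
            "sample %r has %d uniquely mapped reads (< %d recommended)",
            matrix.sample_label, matrix.library_mapped_reads, LOW_DEPTH_READS,
        )


def control_editable_positions(
    control: CountMatrix, enzyme: EnzymeSpec, th: Thresholds
) -> EditableSet:
    """Screen the no-enzyme control for positions that can report editing.

    A position carries a signature iff coverage >= ``control_min_reads``,
    reference-base fraction >= ``control_min_ref_frac`` and edited-base
    fraction < ``control_max_alt_frac``.  Signature reference bases are
    disjoint, so each position gets at most one signature per enzyme.
    """
    if control.n_positions() == 0:
        warnings.warn("control matrix is empty; nothing is editable")
        return set()
    _qc_depth(control)
    editable: EditableSet = set()
    for contig, cc in control.contigs.items():
        cov = cc.coverage.astype(np.float64)
        covered = cov >= th.control_min_reads
        for sig in enzyme.signatures:
            ref = cc.counts[:, BASE_INDEX[sig.ref]]
            alt = cc.counts[:, BASE_INDEX[sig.alt]]
            with np.errstate(divide="ignore", invalid="ignore"):
                mask = (covered
                        & (ref / cov >= th.control_min_ref_frac)
                        & (alt / cov < th.control_max_alt_frac))
            for pos in cc.positions[mask]:
                editable.add((contig, int(pos), sig))
    return editable


def call_candidate_sites(
    expt: CountMatrix,
    editable: EditableSet,
    enzyme: EnzymeSpec,
    th: Thresholds,
    sample_label: str | None = None,
    replicate_id: str = "",
) -> list[EditingSite]:
    """Threshold the experimental sample at control-editable positions.

    A site is emitted iff the position is editable for the signature,
    coverage >= ``expt_min_reads``, edited reads >= ``expt_min_edited_reads``
    and edited fraction > ``expt_min_edit_frac``.  Positions absent from the
    experimental matrix are not callable.
    """
    _qc_depth(expt)
    label = expt.sample_label if sample_label is None else sample_label
    sites: list[EditingSite] = []
    sigs = set(enzyme.signatures)
    for contig, pos, sig in sorted(editable, key=lambda k: (k[0], k[1], str(k[2]))):
        if sig not in sigs:
            continue
        bc = expt.lookup(contig, pos)
        if bc is None:
            continue
        cov = bc.coverage
        edited = bc.count(sig.alt)
        if cov < th.expt_min_reads or edited < th.expt_min_edited_reads:
            continue
        frac = edited / cov
        if frac > th.expt_min_edit_frac:
            sites.append(EditingSite(contig, pos, sig, cov, edited, frac,
                                     sample_label=label, replicate_id=replicate_id))
    return sites


def background_blacklist(
    enzyme_only_reps: Sequence[CountMatrix],
    enzyme: EnzymeSpec,
    th: Thresholds,
) -> EditableSet:
    """Positions edited in ANY enzyme-only replicate (union semantics).

    A position is blacklisted for a signature iff coverage >=
    ``background_min_reads``, edited fraction >= ``background_edit_frac``
    (inclusive boundary, matching the published script parameter 0.01) and
    edited reads >= ``background_min_edited_reads`` (the same >1-edited-read
    technical-error guard the experimental rule applies; a single erroneous
    read at 100x coverage would otherwise blacklist the position).
    """
    if not enzyme_only_reps:
        raise CallingError("at least one enzyme-only replicate is required")
    blacklist: EditableSet = set()
    for rep in enzyme_only_reps:
        for contig, cc in rep.contigs.items():
            cov = cc.coverage.astype(np.float64)
            covered = cov >= th.background_min_reads
            for sig in enzyme.signatures:
                alt = cc.counts[:, BASE_INDEX[sig.alt]]
                with np.errstate(divide="ignore", invalid="ignore"):
                    mask = (covered
                            & (alt / cov >= th.background_edit_frac)
                            & (alt >= th.background_min_edited_reads))
                for pos in cc.positions[mask]:
                    blacklist.add((contig, int(pos), sig))
    return blacklist


def subtract_blacklist(
    sites: Iterable[EditingSite], blacklist: EditableSet
) -> list[EditingSite]:
    """Drop sites whose (contig, position, signature) is blacklisted."""
    return [s for s in sites if s.key not in blacklist]


# ---------------------------------------------------------------------------
# Site table I/O
# ---------------------------------------------------------------------------

_SITE_HEADER = ["contig", "position", "ref", "alt", "strand", "coverage",
                "edited_reads", "edit_frac", "sample", "replicate"]


def write_sites_tsv(sites: Iterable[EditingSite], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_SITE_HEADER) + "\n")
        for s in sites:
            fh.write(
                f"{s.contig}\t{s.position}\t{s.signature.ref}\t{s.signature.alt}"
                f"\t{s.signature.strand}\t{s.coverage}\t{s.edited_reads}"
                f"\t{s.edit_frac:.6g}\t{s.sample_label}\t{s.replicate_id}\n"
            )


def read_sites_tsv(path: str) -> list[EditingSite]:
    sites = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _SITE_HEADER:
            raise CallingError(f"{path}: unexpected site-table header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != len(_SITE_HEADER):
                raise CallingError(f"{path}: line {lineno}: bad field count")
            sites.append(EditingSite(
                contig=f[0], position=int(f[1]),
                signature=Signature(f[2], f[3], f[4]),
                coverage=int(f[5]), edited_reads=int(f[6]),
                edit_frac=float(f[7]), sample_label=f[8], replicate_id=f[9],
            ))
    return sites


def write_sites_bed(sites: Iterable[EditingSite], path: str) -> None:
    """BED6: 0-based start, name ``ref>alt|sample``, score=round(100*frac)."""
    with open(path, "w") as fh:
        for s in sites:
            name = f"{s.signature.ref}>{s.signature.alt}|{s.sample_label}"
            score = round(100 * s.edit_frac)
            fh.write(f"{s.contig}\t{s.position - 1}\t{s.position}\t{name}"
                     f"\t{score}\t{s.signature.strand}\n")
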