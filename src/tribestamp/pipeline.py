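"""End-to-end orchestration: matrices -> editable -> candidates ->
replicate merge -> background subtraction -> summary statistics."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from . import annotate
from .calling import (
    EnzymeSpec,
    Thresholds,
    background_blacklist,
    call_candidate_sites,
    control_editable_positions,
    get_enzyme,
    subtract_blacklist,
    write_sites_bed,
    write_sites_tsv,
)
from .countmatrix import CountMatrix, read_count_matrix
from .merging import classify_replicate_distances, merge_replicates

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    enzyme: EnzymeSpec
    control: str | CountMatrix
    fusion: list
    enzyme_only: list = field(default_factory=list)
    thresholds: Thresholds = field(default_factory=Thresholds)
    genome: str | None = None
    annotation: str | None = None
    output_dir: str = "tribestamp_out"
    mapped_reads: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.fusion:
            raise ConfigError("at least one fusion replicate is required")
        if len(self.fusion) > 2:
            raise ConfigError("at most two fusion replicates are supported")
        if self.enzyme.merge_mode not in ("exact", "proximity"):
            raise ConfigError(f"bad merge mode {self.enzyme.merge_mode!r}")

    @classmethod
    def from_yaml(cls, path: str,
                  overrides: Mapping[str, object] | None = None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if overrides:
            raw.update({k: v for k, v in overrides.items() if v is not None})
        samples = raw.get("samples") or {}
        control = samples.get("control")
        if not control or isinstance(control, list):
            raise ConfigError("config must name exactly one control sample")
        fusion = samples.get("fusion") or []
        if isinstance(fusion, str):
            fusion = [fusion]
        enzyme_only = samples.get("enzyme_only") or []
        if isinstance(enzyme_only, str):
            enzyme_only = [enzyme_only]
        if "enzyme" not in raw:
            raise ConfigError("config must name the enzyme (ADAR or APOBEC)")
        enzyme = get_enzyme(str(raw["enzyme"]), raw.get("merge_mode"))
        th = Thresholds.from_dict(raw.get("thresholds") or {})
        return cls(
            enzyme=enzyme, control=control, fusion=list(fusion),
            enzyme_only=list(enzyme_only), thresholds=th,
            genome=raw.get("genome"), annotation=raw.get("annotation"),
            output_dir=raw.get("output_dir", "tribestamp_out"),
            mapped_reads=dict(raw.get("mapped_reads") or {}),
        )


def _load(sample, default_label: str) -> CountMatrix:
    if isinstance(sample, CountMatrix):
        return sample
    m = read_count_matrix(sample, sample_label=default_label)
    return m


@dataclass
class PipelineResult:
    editable_count: int
    candidates: list[list]          # per fusion replicate
    merged: list
    blacklist_count: int
    final_sites: list
    summary: dict


def run_pipeline(config: RunConfig, write_outputs: bool = True
                 ) -> PipelineResult:
    """Execute the full calling workflow and write per-stage outputs.

    Stage order: control editability screen -> per-replicate candidate
    calling -> enzyme-appropriate replicate merge -> enzyme-only
    background blacklist subtraction -> summary statistics.  Deterministic:
    identical inputs give byte-identical outputs.
    """
    th = config.thresholds
    enzyme = config.enzyme
    if enzyme.merge_mode == "proximity" and len(config.fusion) < 2:
        raise ConfigError("proximity merge requires two fusion replicates")

    control = _load(config.control, "control")
    fusion = [_load(p, f"fusion_rep{i + 1}")
              for i, p in enumerate(config.fusion)]
    enzyme_only = [_load(p, f"enzyme_only_rep{i + 1}")
                   for i, p in enumerate(config.enzyme_only)]
    for name, matrix in config.mapped_reads.items():
        for m in [control, *fusion, *enzyme_only]:
            if m.sample_label == name:
                m.library_mapped_reads = int(matrix)

    editable = control_editable_positions(control, enzyme, th)
    logger.info("control-editable positions: %d", len(editable))

    candidates = []
    for i, expt in enumerate(fusion):
        sites = call_candidate_sites(expt, editable, enzyme, th,
                                     replicate_id=f"rep{i + 1}")
        logger.info("candidate sites in %s: %d", expt.sample_label, len(sites))
        candidates.append(sites)

    if len(candidates) == 2:
        merged = merge_replicates(candidates[0], candidates[1],
                                  enzyme.merge_mode, window=th.proximity_window)
        if candidates[0] and candidates[1]:
            distances = classify_replicate_distances(
                candidates[0], candidates[1]).as_dict()
        else:
            distances = None
    else:
        merged = list(candidates[0])
        distances = None
    logger.info("merged sites (%s): %d", enzyme.merge_mode, len(merged))

    if enzyme_only:
        blacklist = background_blacklist(enzyme_only, enzyme, th)
    else:
        blacklist = set()
    final_sites = subtract_blacklist(merged, blacklist)
    logger.info("final sites after background subtraction: %d",
                len(final_sites))

    summary = {
        "enzyme": enzyme.name,
        "merge_mode": enzyme.merge_mode,
        "thresholds": th.to_dict(),
        "stage_counts": {
            "control_editable": len(editable),
            "candidates_per_replicate": [len(c) for c in candidates],
            "merged": len(merged),
            "blacklist": len(blacklist),
            "final": len(final_sites),
        },
        "replicate_distances": distances,
    }
    for expt in fusion:
        if expt.library_mapped_reads:
            key = f"sites_per_million[{expt.sample_label}]"
            summary[key] = annotate.normalize_per_million(
                len(final_sites), expt.library_mapped_reads)

    if config.annotation:
        models = annotate.read_gtf(config.annotation)
        counts, per_tx = annotate.sites_per_transcript(final_sites, models) \
            if final_sites else ({}, None)
        summary["sites_per_transcript"] = per_tx
        if config.genome and final_sites:
            from pyfaidx import Fasta

            genome = Fasta(config.genome)
            profile = annotate.triplet_context(final_sites, genome)
            summary["context_top_triplets"] = dict(sorted(
                profile.fractions.items(), key=lambda kv: -kv[1])[:8])
            rd = annotate.compute_read_distribution(control, models)
            dist = annotate.feature_fold_enrichment(final_sites, models, rd)
            summary["feature_enrichment"] = {
                f: {"site_fraction": fs.site_fraction,
                    "read_fraction": fs.read_fraction,
                    "fold_enrichment": fs.fold_enrichment,
                    "p_value": fs.p_value}
                for f, fs in dist.features.items()
            }

    if write_outputs:
        os.makedirs(config.output_dir, exist_ok=True)
        out = config.output_dir
        for i, sites in enumerate(candidates):
            write_sites_tsv(sites, os.path.join(out, f"candidates_rep{i + 1}.tsv"))
        write_sites_tsv(merged, os.path.join(out, "merged_sites.tsv"))
        write_sites_tsv(final_sites, os.path.join(out, "final_sites.tsv"))
        write_sites_bed(final_sites, os.path.join(out, "final_sites.bed"))
        with open(os.path.join(out, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")

    return PipelineResult(
        editable_count=len(editable), candidates=candidates, merged=merged,
        blacklist_count=len(blacklist), final_sites=final_sites,
        summary=summary,
    )
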