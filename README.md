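# tribestamp

Dual-enzyme RNA editing-site calling for deaminase-fusion profiling
experiments, covering both editing chemistries:

* **ADAR-style fusions** — A-to-I editing, read out as A>G (T>C on the
  reference-forward strand for minus-strand transcripts); replicates merged
  by **exact** position.
* **APOBEC-style fusions** — C-to-U editing, read out as C>T (G>A);
  replicates merged by **proximity** (nearest partner within 100 bp), which
  accommodates this enzyme's dispersed editing.

The pipeline goes from per-base nucleotide counts to a final site list:

1. **Count matrices** — per-position A/C/G/T read tallies built from
   coordinate-sorted SAM/BAM (`pileup`) or loaded from TSV.
2. **Editability screen** — a matched no-enzyme control must be cleanly the
   reference base at a position (≥80% reference reads, <0.5% edited reads,
   ≥9 reads); this absorbs SNPs and endogenous editing.
3. **Candidate calling** — the fusion sample must show ≥20 reads, >6%
   edited fraction and ≥2 edited reads at an editable position.
4. **Replicate merging** — exact or proximity rule per enzyme, plus a
   distance classification (identical / ≤100 bp / ≤200 bp / >200 bp).
5. **Background subtraction** — positions edited ≥1% (with ≥20 reads and
   ≥2 edited reads) in *either* enzyme-only replicate are blacklisted.
6. **Characterization** — sites per transcript, editing-fraction
   statistics (Wilcoxon rank-sum with an exact small-sample path),
   trinucleotide context profiles, 5'UTR/CDS/3'UTR fold enrichment with
   proportion tests, 50-bp 3'-directed shifting, sites-per-million
   normalization, interval slop/intersect/nearest, and IUPAC motif scans
   (default `GTGTGT`).

A fully deterministic synthetic-data generator (`tribestamp.simulate`)
emits genomes, transcript models and control / enzyme-only / fusion count
matrices with planted editing ground truth, so the entire pipeline is
testable offline.

## CLI

```sh
# generate a synthetic dataset (FASTA + GTF + matrices + truth BED + config)
tribestamp simulate --seed 1 --outdir demo --n-transcripts 50

# run the full pipeline from the generated config
tribestamp run --config demo/config.yaml

# or stage by stage
tribestamp pileup aligned.sam genome.fa -o expt.tsv
tribestamp call --control control.tsv --expt expt.tsv --enzyme ADAR -o rep1.tsv
tribestamp merge rep1.tsv rep2.tsv --mode proximity --window 100 -o merged.tsv
tribestamp blacklist eo_rep1.tsv eo_rep2.tsv --enzyme ADAR -o bl.tsv
tribestamp subtract --sites merged.tsv --blacklist bl.tsv -o final.tsv
tribestamp context --sites final.tsv --genome genome.fa -o triplets.tsv
tribestamp enrich --sites final.tsv --gtf models.gtf --control control.tsv \
    --shift 50 -o enrichment.tsv
tribestamp overlap sitesA.bed sitesB.bed --flank 100 -o overlap.tsv
tribestamp motif --bed final.bed --genome genome.fa --flank 50
```

Every numeric threshold (control fractions/coverage, experimental
coverage/fraction/edited reads, background cutoff, proximity window,
flanks, shift) is a flag on the relevant subcommands and a field in the
YAML config; CLI flags override the config. Exit codes: 0 success,
2 validation failure, 1 unexpected error.

### Conventions

* Count-matrix TSVs and site tables use **1-based** positions.
* BED files and `GenomicInterval` use **0-based half-open** coordinates.
* Site BED output: name `ref>alt|sample`, score `round(100·edit_frac)`,
  strand = inferred strand of the signature.

## Library use

```python
from tribestamp import (ADAR, Thresholds, RunConfig, run_pipeline,
                        SimulationParams, simulate_experiment, evaluate_calls)

expt = simulate_experiment(SimulationParams(n_transcripts=100), seed=1)
result = run_pipeline(RunConfig(enzyme=ADAR, control=expt.control,
                                fusion=expt.fusion,
                                enzyme_only=expt.enzyme_only),
                      write_outputs=False)
print(evaluate_calls(result.final_sites, expt.truth))
```
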