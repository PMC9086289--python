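# desertscope

Analysis toolkit for brain-region expression trajectories of gene sets
defined by genomic regions of interest (e.g., large introgression deserts
and positively-selected regions). It provides:

- **`desertscope.regions`** — BED/GTF/TSV interval handling, gene-to-region
  assignment (full-containment by default), per-base region intersection,
  length- and gene-density-matched random-region sampling with rejection
  sampling, and empirical region-level permutation tests.
- **`desertscope.expression`** — RPKM matrix I/O with sample metadata,
  log2(x+1) transform with an explicit scale flag, strict median filtering,
  gene subsetting, and structure × stage median/SD summaries across eight
  ordered developmental stages.
- **`desertscope.divergence`** — the headline test: PCA over a gene subset,
  permutation-based ("jackstraw") component significance with a fallback to
  the first two components, per-stage pairwise Euclidean distances between
  structures in the selected component subspace, Wilcoxon rank-sum tests
  with per-stage Bonferroni correction, and a per-(structure, stage)
  "divergent" call (divergent iff significant vs *every* other structure).
- **`desertscope.cohort_stats`** — repeated-measures ANOVA (datasource
  within structure), per-structure post-hoc ANOVAs with Bonferroni, Grubbs
  outlier test, tie-corrected Kruskal-Wallis, nested linear-model F-tests
  and Tukey post-hocs with a repeated-measures correction.
- **`desertscope.trajectory`** — continuous segmented regression of
  single-gene time courses: exhaustive breakpoint search (max 3, min 2
  samples per segment, min mean expression 2), BIC model selection with
  breakpoint locations counted as parameters, a significance requirement on
  every slope change, an adjusted-R² ≥ 0.5 reporting gate and shape labels
  (monotone, peak, V-shape, complex).
- **`desertscope.synthetic`** — deterministic fixture generator: toy genome
  with a gene-density gradient, desert/sweep region sets with a known gene
  manifest, and structure × stage RPKM matrices with planted shifts and
  trajectories.
- **`desertscope.pipeline`** — YAML-configured end-to-end runs (gene-subset
  modes: deserts, deserts∩sweeps, sweeps−deserts, global with median
  filtering, per-chromosome) producing deterministic TSV/JSON reports.

## CLI

```bash
desertscope synth --seed 1 -o fixture/            # generate a synthetic dataset
desertscope regions sample --deserts fixture/deserts.bed \
    --annotation fixture/genes.tsv --genome fixture/chrom.sizes \
    -n 1000 --min-genes 265 --seed 1 -o replicates/
desertscope expr summarize --matrix fixture/matrix.tsv \
    --meta fixture/metadata.tsv -o summary.tsv
desertscope diverge --matrix fixture/matrix.tsv --meta fixture/metadata.tsv \
    --genes subset.txt --alpha 0.01 --seed 1 -o diverge/
desertscope trajectory --matrix fixture/matrix.tsv --meta fixture/metadata.tsv \
    --structure CBC -o traj_cbc.tsv
desertscope stats battery --table means.tsv -o reports/
desertscope run --config run.yaml -o report/
```

`run.yaml` takes the keys of `desertscope.pipeline.RunConfig`
(`deserts_bed`, `sweeps_bed`, `annotation`, `matrix`, `metadata`, `mode`,
`alpha_divergence`, `alpha_pcs`, `r2_min`, `median_filter_threshold`,
`jackstraw_perms`, `trajectory_structures`, `seed`, ...).

## Conventions

- Coordinates are 0-based half-open (BED) everywhere internally; 1-based
  inclusive input is accepted via `one_based=True` on readers.
- "Genes within a region" means full gene-body containment by default;
  any-overlap is available via `mode="overlap"`.
- All randomness flows from explicit integer seeds; identical configs give
  byte-identical outputs.
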