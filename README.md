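# avmeth

Analysis pipeline for comparing DNA methylation and gene expression between
paired arterial and venous endothelial cell samples measured on a two-channel
methylation array. It takes probe-level intensities, detection p-values, a
sample sheet and a gene-level log2 expression matrix, and produces:

- QC-filtered beta and M-value matrices (detection-p and sex-chromosome
  filters; simplified type-II-to-type-I quantile normalization),
- global-methylation summaries (mean beta per sample/group),
- variability-based probe selection and hierarchical sample clustering,
- per-probe differential methylation with empirical-Bayes moderated t-tests
  on M-values, Benjamini–Hochberg FDR and a beta-scale effect-size gate,
- differentially methylated region (DMR) calling by chaining consecutive
  same-direction probes,
- per-gene expression log fold changes and methylation–expression quadrant
  ("starburst") integration with genomic-region attribution tables,
- a synthetic-data generator with a planted-truth ledger, so the whole
  pipeline is testable without access to real array data.

## Quick start

The CLI is driven by a single YAML config with a mandatory seed. A synthetic
run:

```yaml
# config.yaml
seed: 42
simulate:
  n_genes: 2500
  probes_per_gene_range: [5, 10]
  sex_chrom_fraction: 0.05
  n_pairs: 9
  truth:
    n_dmr_genes: 100
    delta_beta: 0.3
    n_reciprocal: 40
    logfc: 1.0
    global_offset: 0.045
analysis:
  paired_design: false
```

```sh
avmeth run --config config.yaml --out run1      # full pipeline
avmeth report --run-dir run1                    # heatmap / starburst / gene profile
```

`avmeth simulate|preprocess|dmp|integrate` expose the individual stages. To
analyse real data, replace the `simulate` block with an `inputs` block naming
the manifest CSV, meth/unmeth/detection-p TSVs, sample-sheet CSV and
expression TSV (see `avmeth.pipeline._load_inputs`).

All outputs are plain text (TSV/CSV/JSON/BED); reruns with the same config
and seed are bit-identical.

## Conventions

- Effect sign: delta beta and expression logFC are always arterial minus
  venous.
- DMP call: BH-adjusted p <= 0.05 (inclusive) *and* |delta beta| >= 0.10
  (inclusive). Quadrant gates are strict (> 0.10 / > 0.5) — the two
  thresholds are separate config entries.
- Tests run on M-values; effect sizes are reported on the beta scale.
- Manifest positions are 1-based; BED exports are 0-based half-open.

## Tests and acceptance report

```sh
python -m pytest tests/                      # unit + property + acceptance tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes, from scratch, the criterion metrics
(step-up FDR oracle agreement, moderated-t limits and hyperparameter
recovery, null false-discovery control, planted-effect and DMR recovery,
quadrant classification of reference gene values, global-offset recovery,
clustering accuracy, and end-to-end determinism) and writes them as JSON.
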