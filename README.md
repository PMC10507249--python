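# lcmseq

Analysis pipeline for laser-capture-microdissected (LCM) single-cell
3′-RNA-seq of ovarian sections, exercisable end to end on synthetic data
with known ground truth.

The package implements the downstream analysis chain for this assay:

- **Amplification QC** — Smirnov–Grubbs gating of qPCR Ct plates
  (iterative, masking-robust peel-and-test on the high-Ct side), cell-level
  filters (mapping rate, detectable genes, correlation screen).
- **Quantification** — RPM / log2(RPM+1) normalization, ERCC spike-in
  copy-number calibration (log2–log2 OLS over spikes with positive reads),
  detectable-gene counting in raw and copy modes.
- **Section-bias profiling** — per-gene two-proportion z-tests on detection
  rates and t-tests on expression levels between paired fresh/section
  cohorts, with expression-rank stratification.
- **Size–transcriptome model** — PCA of oocyte transcriptomes (genes with
  log2(RPM+1) > 4 in ≥ 1 cell), regression of PC1/PC2 on oocyte diameter,
  reconstruction of the transcriptome on a 10–100 μm grid, Spearman
  best-matching of each oocyte to a grid diameter, and growth-retardation
  flagging (> 20 μm mismatch); per-gene diameter correlations and
  4-parameter logistic (sigmoid) fits of average Z-score trajectories.
- **Differential expression** — two-group DEG calling (|Δlog2| > 1.8,
  t-test p < 0.05, BH FDR < 0.05, expression floor) and a one-way ANOVA
  stage filter.
- **Mixed-profile detection** — Gaussian-mixture bimodality test of each
  granulosa cell's expression over oocyte-signature genes (operationalizes
  contour-plot mode inspection).
- **Exon/junction profiling** — from-scratch TMM normalization (doubly
  trimmed, precision-weighted mean of M-values), strict > 2 TMM
  detectability, per-gene exon detection rates with best-transcript
  selection.
- **Synthetic data** — generators for every input (oocyte cohorts with
  sigmoid diameter trajectories and planted growth-retarded cells,
  positional granulosa cohorts with planted DEGs and contamination
  mixtures, paired fresh/section cohorts with planted detection errors and
  biases, ERCC ladders, Ct plates, exon models with 3′-biased coverage),
  each returning a full ground-truth record.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (parameter
recovery, detector sensitivities, statistical calibration, oracle
equivalences, determinism); the rest are per-module unit and property
tests.

## CLI

```sh
lcmseq run-all --seed 1 --out out/            # full chain on synthetic data
lcmseq simulate --config cfg.yaml --out out/  # single stages (+ dependencies)
lcmseq model    --config cfg.yaml --out out/
```

Stages: `simulate`, `qc`, `quantify`, `bias`, `model`, `deg`, `junctions`,
`run-all`. Each stage writes TSV tables plus a JSON run summary; identical
config + seed gives byte-identical outputs. The YAML config (see
`lcmseq.config.PipelineConfig`) records every threshold; defaults are the
published cutoffs.

## Layout

```
src/lcmseq/
  config.py     thresholds, diameter grid, pipeline config (YAML round-trip)
  io.py         count-matrix (TSV/MTX) and metadata readers/writers
  simulate.py   synthetic-data generators + ground truth (SimConfig/SimTruth)
  qc.py         Grubbs test, amplification gate, cell filters, mixed profiles
  quantify.py   RPM/log2, ERCC copy models, detectable genes
  bias.py       fresh-vs-section detection/bias tests, rank stratification
  sizemodel.py  PCA, PC-diameter regressions, reconstruction, matching, sigmoids
  deg.py        BH adjustment, two-group DEG, ANOVA stage filter
  junctions.py  TMM, detectability, exon detection rates
  pipeline.py   stage orchestration and report bundle
  cli.py        click entry points
```
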