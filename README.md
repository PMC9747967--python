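# hexniche

Density-based analysis of cytokine microenvironments on Visium-style
spatial transcriptomics data.

A handful of cytokine transcripts (IFNG, IL13, IL17A) in inflamed skin
sit at the center of much larger responder-gene amplification zones.
`hexniche` implements the full analysis as a tested pipeline:

* **spatial_io** — read/write Visium-dialect datasets (MatrixMarket
  matrix + features/barcodes TSV per sample, `tissue_positions_list.csv`
  in the Space Ranger v1 headerless dialect with header auto-detection,
  layer-annotation and sample-metadata CSVs), with strict validation
  (hex parity, closed layer vocabulary, unique keys).
* **preprocess** — spot/gene QC (min detected genes, UMI window,
  mitochondrial fraction; then under-observed genes), library-size
  size factors (geometric mean 1) and `log10(count/sf + 1)`
  normalization. Note the base-10 log with pseudocount 1 — not the
  usual `log1p`. Raw counts are always retained.
* **annotate** — leukocyte labeling (≥1 UMI of CD2/CD3D/CD3E/CD3G/
  CD247/PTPRC), per-cytokine positivity, Wilcoxon signed-rank layer
  enrichment on per-sample group sums, per-disease cytokine
  distribution.
* **signatures** — responder-gene derivation: stimulation-table filter
  (p < 0.05, padj < 0.05, log2FC > 1.5 for IFNG/IL17A or > 1 for IL13,
  all strict), intersection with spatial DEGs, cross-signature
  purification, literature supplementation.
* **dge** — per-gene negative-binomial GLM on raw counts with
  log(size-factor) offset and fixed effects (cdr, project, patient,
  annotation), moments-seeded dispersion MLE, Wald test, BH correction,
  inclusive calling cutoffs (|log2FC| ≥ 1, p ≤ 0.05), plus the
  cytokine-positive-vs-unclustered contrast.
* **hexcluster** — the core method: hex neighbourhoods in array-index
  space (radius-r ball has 3r²+3r+1 spots), KD-tree adjacency of
  cytokine⁺ spots at Euclidean index distance ≤ 2.0, connected-component
  seeds, radius expansion, transitive overlap merging, per-cluster
  cytokine/responder count readout. The ≤ 2.0 rule links the
  non-physical (±2, 0) offset too; `strict_hex=True` restricts adjacency
  to the six physical neighbours.
* **spatial_correlation** — weighted Spearman (weighted Pearson on
  mid-ranks; t-approximation with df = n−2, seeded permutation test by
  flag), cluster-level and per-section pseudo-bulk correlation, radius
  sweep over 0–9 with argmax selection (ties to the smaller radius),
  origin-constrained least-squares line fit.
* **synthetic_data** — a Visium-like generator with planted ground truth
  (hex grid with depth-ordered layer bands, sparse cytokine spots with
  1–15 UMIs, co-located leukocyte markers, gamma-Poisson counts,
  responder means amplified within a planted hex radius, spatially
  correlated baseline field, MT and housekeeping genes) plus synthetic
  stimulation DEG tables. Every distributional choice is a documented
  stand-in; `SimConfig.recovery_protocol()` yields the configuration
  used for parameter-recovery testing.
* **cli_pipeline** — YAML-configured orchestration with per-stage
  logging, deterministic seeding and a run manifest.

## Command line

```sh
# full pipeline on synthetic data (simulate -> qc -> label -> dge ->
# signatures -> radius sweep -> correlations -> non-cluster DEG)
hexniche run-all --seed 7 --out out/

# individual stages
hexniche simulate --seed 7 --out sim/
hexniche qc --input sim/dataset --out qc/
hexniche label --input sim/dataset --out labels.csv
hexniche sweep --input sim/dataset --cytokine IFNG \
    --signature-genes RESP-IFNG-01,RESP-IFNG-02 --out sweep.json
hexniche cluster --input sim/dataset --cytokine IL17A --radius 0 \
    --signature-genes RESP-IL17A-01 --out clusters.csv
```

All commands accept `--config config.yaml`; the committed default
(`src/hexniche/data/default_config.yaml`) mirrors the published
thresholds (QC cuts, marker panel, signature thresholds, radii 0–9).
Unknown config keys are rejected. Exit codes: 0 success, 2 config
error, 3 data error, 4 stage failure.

To analyse real data, point `run-all` at a dataset directory and a
stimulation DEG table (`gene,cytokine,log2FC,p_value,adj_p_value`):

```sh
hexniche run-all --input data/ --stim-table stim.csv --out out/
```

## Notable deviations and caveats

* Size factors are library-size ratios (geometric mean 1), not pooled
  deconvolution factors; externally computed factors can be supplied to
  `compute_norm_factors`.
* The NB GLM is a reimplementation (IRLS via statsmodels with per-gene
  dispersion MLE), not a port of quasi-likelihood shrinkage machinery.
* The synthetic generator's distributions are stand-ins chosen so that
  parameter-recovery tests are well-posed, not fits to real data.
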