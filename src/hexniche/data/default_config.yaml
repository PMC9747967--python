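# Default hexniche pipeline configuration.
# QC thresholds, marker/cytokine panels, signature filter cuts and the
# swept radius range follow the published analysis defaults.
seed: 0
qc:
  min_genes_per_spot: 30
  min_spots_per_gene: 20
  min_umi: 50
  max_umi: 500000
  max_mt_fraction: 0.25
  mt_prefix: "MT-"
markers: [CD2, CD3D, CD3E, CD3G, CD247, PTPRC]
cytokines: [IFNG, IL13, IL17A]
signatures:
  p_cut: 0.05
  padj_cut: 0.05
  fc_thresholds:
    IFNG: 1.5
    IL17A: 1.5
    IL13: 1.0
  use_adjusted_spatial_p: false
  literature_genes:
    IL13: []
design:
  covariates: [cdr, project, patient, annotation]
cluster:
  radii: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9]
  require_leukocyte: true
  strict_hex: false
  p_method: t
simulate: {}
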