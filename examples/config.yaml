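# Full-defaults germkit configuration template.
# Any omitted key falls back to the built-in default shown here.

seed: 0
output_dir: germkit_out
scale_factor: 10000.0

contrast:
  group_key: stage
  level_a: mid_secretory       # receptive level; positive log2fc = receptive-high
  level_b: early_secretory
  cell_type: secretory_glandular_epithelium

derivation:
  lfc_min: 2.0                 # strict |log2FC| cutoff
  fdr_max: 1.0e-7              # strict FDR cutoff (single-cell table)
  bulk_fdr_max: 0.05
  sc_fdr_max: 0.05
  filter_on: sc                # or "both"

enrichment:
  metric: signed_logp          # or "lfc"
  n_perm: 2000
  weight: 1.0

panel_scoring:
  n_bins: 24
  n_ctrl: 100

stromal_rules:
  decidual_marker: SCARA5
  senescent_marker: DIO2
  fos_marker: FOS
  cxcl14_marker: CXCL14
  z_threshold: 0.5

# Simulation block: any SimConfig field may be overridden here.
simulation: {}

# Input paths for derive/score/enrich/annotate subcommands.
inputs: {}
#  bulk_de: examples/toy_bulk_de.tsv
#  sc_de: examples/toy_sc_de.tsv
#  counts_dir: germkit_out/simulated
#  rnk: ranked.rnk
#  signature_gmt: germkit_out/signature.gmt
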