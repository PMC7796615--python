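# Demo pipeline run: six synthetic species from one ancestral plastome,
# 0-5 inversions each, coupled expression divergence, edits injected.
seed: 42
outdir: demo_out
k_inversions: [0, 1, 2, 3, 4, 5]
coupling: coupled
n_edit_sites: 4
distance: dcj
window: 100
sim:
  n_genes: 24
  n_operons: 8
  n_read_pairs: 10000
  read_length: 80
  base_error_rate: 0.001
  readthrough_prob: 0.2
  antisense_rate: 0.02
caller:
  min_coverage: 50
  min_variant_frequency: 0.1
  max_p_value: 1.0e-6
  base_error_rate: 0.001
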