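alpha: 0.05
ct: null
energy_max: -50.0
expression: null
fasta: null
fc: 2.0
gmt: null
groups: null
gtf: null
mcl: {}
min_pairs: 10
outdir: lncnet_out
positive_only: false
r_min: 0.8
reference_gene: ACTB
seed: 11
sim:
  de_fraction: 0.25
  genome_len: 60000000
  module_spec:
  - - 16
    - 0.92
  - - 12
    - 0.9
  n_chroms: 4
  n_cis_pairs: 8
  n_duplex_pairs: 8
  n_genes: 240
  n_lnc: 80
  tx_len_range:
  - 300
  - 900
simulate: true
top_k: 120
window: 300000
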