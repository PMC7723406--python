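# 14-tip demo: the full study design at a reduced gene count.
# Run with:  radmut run-all --config examples/demo_run.yaml --out demo_out
simulation:
  n_pairs: 6
  n_extra: 2
  n_genes: 150
  sites_per_gene: 30
  theta: 0.02
  seed: 42
seed: 42
outdir: demo_out
holm_k: 18
position_filters: [all, third]
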