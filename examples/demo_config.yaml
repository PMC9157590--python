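# Demo pipeline configuration: small synthetic run of all stages.
#   senoscreen run --config examples/demo_config.yaml --seed 7 --out demo_out
seed: 7
out_dir: demo_out
stages: [screen, lifespan, rls]
simulate:
  n_genes: 500
  n_de_genes: 60
  n_null_compounds: 20
  n_reversers: 3
  n_mimickers: 3
screen:
  n_perm: 500
  min_overlap: 3
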