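# Demo pipeline config: synthetic biologics-for-asthma database with
# planted ear and eosinophil associations for the IgE-blocking antibody.
# Run:  pvsignal run --config examples/demo.yaml --outdir out/
seed: 42
simulate:
  preset: asthma-biologics
  n_reports: 20000
  seed: 42
targets:
  - omalizumab
  - mepolizumab
  - benralizumab
  - reslizumab
  - dupilumab
criteria:
  min_reports: 3
  prr_min: 2.0
  ror_min: 2.0
  ic025_min: 0.0
  ic025_strict: true
subset_soc: Ear and labyrinth disorders
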