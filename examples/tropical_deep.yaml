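# A constant-environment scenario: tropical deep-diving lifestyle.
# Run with:  spectralife solve --config examples/tropical_deep.yaml --out results/
label: tropical_deep
environment:
  type: constant
  tau_c: 21.85
  kappa: 1.0
  spawn_all_year: true
spectrum:
  kappa: 1.0
  h: 8.0
# body / metabolism fields may be overridden here; defaults are the
# tuna-calibrated values (see docs/methods.md)
grid:
  n_lengths: 200
  n_stores: 51
  n_alloc: 21
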